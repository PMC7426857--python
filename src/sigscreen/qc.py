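"""Well- and probe-level quality filters with an auditable report.

Filter order is fixed and asserted: wells first, then probes.  Removing a
well never changes another well's pass/fail status for the read filter, but
it does change per-plate probe totals, so probe filtering must see the
retained wells only.

Rules (strict inequalities throughout):

* a well is removed iff its cell count is below ``cell_frac`` (default 40%)
  of the mean cell count of the untreated wells on the *same plate*, or its
  total reads are below ``min_total_reads`` (default 100,000);
* a probe is removed from the combined analysis iff its total reads over
  retained wells are below ``min_probe_plate_total`` (default 2,000) on
  *any* plate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["QCError", "QCReport", "filter_wells", "filter_probes", "run_qc"]

SCHEMA_VERSION = "sigscreen.qc_report.v1"


class QCError(ValueError):
    pass


@dataclass
class QCReport:
    """Record of every removal with the measured value and violated threshold."""

    thresholds: dict = field(default_factory=dict)
    removed_wells: list = field(default_factory=list)    # plate_id, well_id, reason, value, threshold
    removed_probes: list = field(default_factory=list)   # probe_id, plate_id, plate_total, threshold
    n_compounds_removed: int = 0
    compounds_removed: list = field(default_factory=list)
    n_wells_removed: int = 0

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "thresholds": self.thresholds,
            "removed_wells": self.removed_wells,
            "removed_probes": self.removed_probes,
            "n_wells_removed": self.n_wells_removed,
            "n_compounds_removed": self.n_compounds_removed,
            "compounds_removed": self.compounds_removed,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "QCReport":
        d = json.loads(Path(path).read_text())
        return cls(
            thresholds=d["thresholds"],
            removed_wells=d["removed_wells"],
            removed_probes=d["removed_probes"],
            n_compounds_removed=d["n_compounds_removed"],
            compounds_removed=d["compounds_removed"],
            n_wells_removed=d["n_wells_removed"],
        )

    def merged_with(self, other: "QCReport") -> "QCReport":
        return QCReport(
            thresholds={**self.thresholds, **other.thresholds},
            removed_wells=self.removed_wells + other.removed_wells,
            removed_probes=self.removed_probes + other.removed_probes,
            n_compounds_removed=self.n_compounds_removed + other.n_compounds_removed,
            compounds_removed=self.compounds_removed + other.compounds_removed,
            n_wells_removed=self.n_wells_removed + other.n_wells_removed,
        )


def filter_wells(
    counts: pd.DataFrame,
    wells: pd.DataFrame,
    cell_frac: float = 0.40,
    min_total_reads: float = 100_000,
) -> tuple[pd.DataFrame, pd.DataFrame, QCReport]:
    """Drop wells with low cell counts or low total reads.

    The cell-count reference is the per-plate mean over untreated wells
    (both genotypes pooled).  A well failing both rules is recorded twice,
    once per reason.  Retained wells' counts are returned unchanged.
    """
    if not counts.index.equals(wells.index):
        raise QCError("counts and well table must share the same (plate_id, well_id) index")

    plates = wells.index.get_level_values("plate_id")
    untreated = wells["treatment"] == "untreated"
    for plate in plates.unique():
        if not untreated[plates == plate].any():
            raise QCError(
                f"plate {plate!r} has no untreated wells; cell-count reference undefined"
            )
    ref_mean = wells.loc[untreated, "cell_count"].groupby(level="plate_id").mean()

    total_reads = counts.sum(axis=1)
    cell_threshold = plates.map(ref_mean) * cell_frac
    low_cell = wells["cell_count"].to_numpy() < cell_threshold.to_numpy()
    low_reads = total_reads.to_numpy() < min_total_reads

    report = QCReport(thresholds={"cell_frac": cell_frac, "min_total_reads": min_total_reads})
    for i, (plate, well) in enumerate(wells.index):
        if low_cell[i]:
            report.removed_wells.append(
                {"plate_id": plate, "well_id": well, "reason": "low_cell_count",
                 "value": float(wells["cell_count"].iloc[i]),
                 "threshold": float(cell_threshold[i])}
            )
        if low_reads[i]:
            report.removed_wells.append(
                {"plate_id": plate, "well_id": well, "reason": "low_total_reads",
                 "value": float(total_reads.iloc[i]), "threshold": float(min_total_reads)}
            )

    keep = ~(low_cell | low_reads)
    kept_wells = wells.loc[keep]
    kept_counts = counts.loc[keep]
    report.n_wells_removed = int((~keep).sum())

    removed_cmp = set(wells.loc[~keep, "compound_id"]) - {""}
    surviving_cmp = set(kept_wells["compound_id"]) - {""}
    gone = sorted(removed_cmp - surviving_cmp)
    report.compounds_removed = gone
    report.n_compounds_removed = len(gone)
    return kept_counts, kept_wells, report


def filter_probes(
    counts: pd.DataFrame,
    panel: pd.DataFrame,
    min_probe_plate_total: float = 2_000,
) -> tuple[pd.DataFrame, pd.DataFrame, QCReport]:
    """Drop probes whose per-plate read total is low on any plate.

    A probe failing on a single plate is removed globally so the combined
    cross-plate matrix stays rectangular.  Housekeeping probes failing the
    filter trigger a warning naming them (losing one changes the
    normalization denominator).
    """
    plate_totals = counts.groupby(level="plate_id").sum()
    failing = plate_totals < min_probe_plate_total

    report = QCReport(thresholds={"min_probe_plate_total": min_probe_plate_total})
    bad_probes = []
    for probe in counts.columns:
        for plate in plate_totals.index:
            if failing.loc[plate, probe]:
                report.removed_probes.append(
                    {"probe_id": probe, "plate_id": plate,
                     "plate_total": float(plate_totals.loc[plate, probe]),
                     "threshold": float(min_probe_plate_total)}
                )
        if failing[probe].any():
            bad_probes.append(probe)

    hk_lost = [p for p in bad_probes if bool(panel.loc[p, "is_housekeeping"])]
    if hk_lost:
        warnings.warn(f"housekeeping probes failed the per-plate read filter: {hk_lost}",
                      stacklevel=2)

    kept = [p for p in counts.columns if p not in bad_probes]
    if not kept:
        raise QCError("all probes removed by the per-plate read filter")
    return counts[kept], panel.loc[kept], report


def run_qc(
    counts: pd.DataFrame,
    wells: pd.DataFrame,
    panel: pd.DataFrame,
    cell_frac: float = 0.40,
    min_total_reads: float = 100_000,
    min_probe_plate_total: float = 2_000,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, QCReport]:
    """Apply both filters in the fixed order (wells, then probes)."""
    counts_w, wells_w, rep_w = filter_wells(counts, wells, cell_frac, min_total_reads)
    counts_p, panel_p, rep_p = filter_probes(counts_w, panel, min_probe_plate_total)
    return counts_p, wells_w, panel_p, rep_w.merged_with(rep_p)
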