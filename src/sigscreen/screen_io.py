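"""Reading, writing and cross-validation of the screen's tabular formats.

All tables are tab-delimited UTF-8 with '.' decimals.  Raw count matrices
hold integers only; normalized matrices are written by :mod:`.normalize`
with an explicit schema line so the two can never be confused.  Writers are
deterministic: stable row/column order, floats at 6 significant digits.

Files of a screen bundle:

``counts.tsv``
    wells x probes integer counts; first two columns ``plate_id``,
    ``well_id``.
``layout.tsv``
    per-well metadata: plate_id, well_id, genotype, treatment, compound_id,
    cell_count.
``panel.tsv``
    probe panel: probe_id, gene_symbol, category, is_housekeeping.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ScreenValidationError",
    "load_screen",
    "write_screen",
    "write_score_table",
    "read_score_table",
]

_FLOAT_FMT = "%.6g"
_SCORE_SCHEMA = "sigscreen.score_table.v1"

_LAYOUT_COLS = ["plate_id", "well_id", "genotype", "treatment", "compound_id", "cell_count"]
_PANEL_COLS = ["probe_id", "gene_symbol", "category", "is_housekeeping"]
_VALID_GENOTYPES = {"WT", "KO"}
_VALID_TREATMENTS = {"untreated", "compound"}


class ScreenValidationError(ValueError):
    """Raised with the full list of validation failures, one per line."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("screen validation failed:\n" + "\n".join(f"- {p}" for p in problems))


def write_screen(counts: pd.DataFrame, wells: pd.DataFrame, panel: pd.DataFrame,
                 outdir: str | Path) -> dict[str, Path]:
    """Write a screen bundle (counts/layout/panel TSVs) into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "layout": outdir / "layout.tsv",
        "panel": outdir / "panel.tsv",
    }
    counts.reset_index().to_csv(paths["counts"], sep="\t", index=False)
    wells.reset_index().to_csv(paths["layout"], sep="\t", index=False,
                               float_format=_FLOAT_FMT)
    panel.reset_index(drop=True).to_csv(paths["panel"], sep="\t", index=False)
    return paths


def load_screen(counts_path: str | Path, layout_path: str | Path,
                panel_path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Load and cross-validate a screen bundle.

    All identifier mismatches between the three tables are collected and
    reported together in a single :class:`ScreenValidationError` so a broken
    export can be fixed in one pass.
    """
    for p in (counts_path, layout_path, panel_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"missing input file: {p}")

    counts_raw = pd.read_csv(counts_path, sep="\t", dtype={"plate_id": str, "well_id": str})
    layout = pd.read_csv(layout_path, sep="\t",
                         dtype={"plate_id": str, "well_id": str, "compound_id": str},
                         keep_default_na=False, na_values=[])
    panel = pd.read_csv(panel_path, sep="\t")

    problems: list[str] = []

    missing = [c for c in _LAYOUT_COLS if c not in layout.columns]
    if missing:
        problems.append(f"layout is missing columns: {missing}")
    missing = [c for c in _PANEL_COLS if c not in panel.columns]
    if missing:
        problems.append(f"panel is missing columns: {missing}")
    for col in ("plate_id", "well_id"):
        if col not in counts_raw.columns:
            problems.append(f"count matrix is missing column: {col}")
    if problems:
        raise ScreenValidationError(problems)

    layout["cell_count"] = pd.to_numeric(layout["cell_count"], errors="coerce")
    panel["is_housekeeping"] = panel["is_housekeeping"].astype(bool)

    dup = panel["probe_id"][panel["probe_id"].duplicated()].tolist()
    if dup:
        problems.append(f"duplicate probe_ids in panel: {sorted(set(dup))}")
    if int(panel["is_housekeeping"].sum()) < 1:
        problems.append("panel must contain at least one housekeeping probe")
    n_target = int((panel["category"] == "target").sum())
    if n_target > 1:
        problems.append(f"panel flags {n_target} probes as category=target; at most one allowed")

    key = list(zip(layout["plate_id"], layout["well_id"]))
    dup_wells = sorted({k for k, c in pd.Series(key).value_counts().items() if c > 1})
    if dup_wells:
        problems.append(f"duplicate (plate_id, well_id) in layout: {dup_wells}")

    probe_cols = [c for c in counts_raw.columns if c not in ("plate_id", "well_id")]
    unknown_probes = sorted(set(probe_cols) - set(panel["probe_id"]))
    if unknown_probes:
        problems.append(f"count matrix probes absent from panel: {unknown_probes}")
    absent_probes = sorted(set(panel["probe_id"]) - set(probe_cols))
    if absent_probes:
        problems.append(f"panel probes absent from count matrix: {absent_probes}")

    count_key = set(zip(counts_raw["plate_id"], counts_raw["well_id"]))
    layout_key = set(key)
    only_layout = sorted(layout_key - count_key)
    if only_layout:
        problems.append(f"layout wells absent from count matrix: {only_layout}")
    only_counts = sorted(count_key - layout_key)
    if only_counts:
        problems.append(f"count-matrix wells absent from layout: {only_counts}")

    mat = counts_raw[probe_cols]
    non_numeric = [c for c in probe_cols if not np.issubdtype(mat[c].dtype, np.number)]
    if non_numeric:
        problems.append(f"non-numeric counts in columns: {non_numeric}")
    else:
        if not all(np.issubdtype(mat[c].dtype, np.integer) for c in probe_cols):
            frac = mat.to_numpy(dtype=float)
            if not np.allclose(frac, np.rint(frac)):
                problems.append("raw count matrix contains non-integer values")
        if (mat.to_numpy() < 0).any():
            problems.append("raw count matrix contains negative values")

    bad_geno = sorted(set(layout["genotype"]) - _VALID_GENOTYPES)
    if bad_geno:
        problems.append(f"unknown genotypes in layout: {bad_geno}")
    bad_trt = sorted(set(layout["treatment"]) - _VALID_TREATMENTS)
    if bad_trt:
        problems.append(f"unknown treatments in layout: {bad_trt}")
    if "treatment" in layout.columns:
        untreated_with_cmp = layout[(layout["treatment"] == "untreated")
                                    & (layout["compound_id"] != "")]
        if len(untreated_with_cmp):
            problems.append(
                f"{len(untreated_with_cmp)} untreated wells carry a compound_id"
            )

    if problems:
        raise ScreenValidationError(problems)

    # this screen design treats only KO cells with compounds; other designs
    # are legal but unexpected, so warn rather than fail
    odd = layout[(layout["treatment"] == "compound") & (layout["genotype"] != "KO")]
    if len(odd):
        warnings.warn(
            f"{len(odd)} compound-treated wells are not genotype KO", stacklevel=2
        )

    wells = layout.set_index(["plate_id", "well_id"])
    counts = counts_raw.set_index(["plate_id", "well_id"])[probe_cols].astype(np.int64)
    counts = counts.loc[wells.index]
    panel_order = [p for p in panel["probe_id"] if p in probe_cols]
    counts = counts[panel_order]
    panel = panel.set_index("probe_id", drop=False)
    return counts, wells, panel


def write_score_table(scores: pd.DataFrame, path: str | Path) -> None:
    """Write a per-well score table as TSV with a schema-version line."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# schema={_SCORE_SCHEMA}\n")
        scores.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_score_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"plate_id": str, "well_id": str, "compound_id": str})
    return df
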