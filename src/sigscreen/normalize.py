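"""Housekeeping-sum normalization and cross-plate combination.

Each well's counts are divided by that well's summed housekeeping-probe
counts, making every value a fraction of the housekeeping signal.  The
normalization is invariant to uniform rescaling of a well's raw counts
(library size cancels), and no additional scale factor is applied: any
common constant would cancel again in the per-gene z-scoring performed
before distance computation.  Plates are combined by plain row
concatenation — no cross-plate rescaling beyond the housekeeping
normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["NormalizeError", "NormalizedMatrix", "normalize_housekeeping", "combine_plates"]

_SCHEMA = "sigscreen.normalized.v1 normalized=true"


class NormalizeError(ValueError):
    pass


@dataclass
class NormalizedMatrix:
    """Wells x probes housekeeping-normalized values.

    ``housekeeping_sum`` keeps each retained well's raw denominator;
    ``plates`` records provenance; ``removed_wells`` lists wells dropped
    because their housekeeping sum was zero.
    """

    values: pd.DataFrame
    housekeeping_sum: pd.Series
    plates: list = field(default_factory=list)
    removed_wells: list = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"# schema={_SCHEMA}\n")
            out = self.values.copy()
            out.insert(0, "housekeeping_sum", self.housekeeping_sum)
            out.reset_index().to_csv(fh, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NormalizedMatrix":
        with Path(path).open() as fh:
            first = fh.readline()
            if "normalized=true" not in first:
                raise NormalizeError(
                    f"{path} lacks the normalized=true schema flag; refusing to load "
                    "a possibly raw matrix as normalized"
                )
            df = pd.read_csv(fh, sep="\t", dtype={"plate_id": str, "well_id": str})
        df = df.set_index(["plate_id", "well_id"])
        hk_sum = df.pop("housekeeping_sum")
        plates = sorted(df.index.get_level_values("plate_id").unique())
        return cls(values=df, housekeeping_sum=hk_sum, plates=plates)


def normalize_housekeeping(counts: pd.DataFrame, panel: pd.DataFrame) -> NormalizedMatrix:
    """Divide each well's counts by its housekeeping-probe sum.

    Wells whose housekeeping sum is zero carry no usable signal and are
    removed (recorded with reason ``zero_housekeeping``).  All probes,
    housekeeping included, are kept in the output, so the housekeeping
    columns of every well sum to exactly 1.
    """
    hk = [p for p in counts.columns if bool(panel.loc[p, "is_housekeeping"])]
    if not hk:
        raise NormalizeError("no housekeeping probes present after QC; cannot normalize")
    hk_sum = counts[hk].sum(axis=1).astype(float)
    zero = hk_sum == 0
    removed = [
        {"plate_id": plate, "well_id": well, "reason": "zero_housekeeping"}
        for plate, well in counts.index[zero]
    ]
    kept = counts.loc[~zero]
    values = kept.div(hk_sum[~zero], axis=0)
    plates = sorted(values.index.get_level_values("plate_id").unique())
    return NormalizedMatrix(values=values, housekeeping_sum=hk_sum[~zero],
                            plates=plates, removed_wells=removed)


def combine_plates(matrices: list[NormalizedMatrix]) -> NormalizedMatrix:
    """Row-concatenate per-plate normalized matrices into one analysis matrix.

    Requires identical probe columns on every input (guaranteed upstream by
    the global probe drop in QC); performs no rescaling.
    """
    if not matrices:
        raise NormalizeError("no matrices to combine")
    ref_cols = list(matrices[0].values.columns)
    diffs = []
    for i, m in enumerate(matrices[1:], start=2):
        cols = list(m.values.columns)
        if cols != ref_cols:
            extra = sorted(set(cols) - set(ref_cols))
            missing = sorted(set(ref_cols) - set(cols))
            diffs.append(f"input {i}: extra probes {extra}, missing probes {missing}")
    if diffs:
        raise NormalizeError("probe-set mismatch across plates:\n" + "\n".join(diffs))

    values = pd.concat([m.values for m in matrices])
    if values.index.duplicated().any():
        dup = sorted(set(values.index[values.index.duplicated()]))
        raise NormalizeError(f"duplicate (plate_id, well_id) after combining: {dup}")
    hk_sum = pd.concat([m.housekeeping_sum for m in matrices])
    plates = []
    for m in matrices:
        plates.extend(m.plates)
    removed = [r for m in matrices for r in m.removed_wells]
    return NormalizedMatrix(values=values, housekeeping_sum=hk_sum,
                            plates=plates, removed_wells=removed)
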