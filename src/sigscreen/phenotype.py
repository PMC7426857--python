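"""Batch normalization of orthogonal per-well phenotype readouts.

Activity assays (e.g. a fluorescent cysteine-cathepsin probe read per well)
run on different days carry arbitrary batch-level gain.  Batches are made
poolable by dividing every raw value by the mean raw value of the
KO-untreated wells of the same batch, setting the KO reference mean to 1
within each batch.  Statistical comparisons downstream are left to standard
routines; this module only prepares the normalized table.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["PhenotypeError", "normalize_activity"]

REQUIRED_COLS = ["batch_id", "genotype", "raw_value"]


class PhenotypeError(ValueError):
    pass


def _is_untreated(records: pd.DataFrame) -> pd.Series:
    if "treatment" in records.columns:
        return records["treatment"] == "untreated"
    if "compound_id" in records.columns:
        cmp = records["compound_id"]
        return cmp.isna() | (cmp.astype(str) == "")
    raise PhenotypeError("records need a 'treatment' or 'compound_id' column "
                         "to identify untreated reference wells")


def normalize_activity(records: pd.DataFrame) -> pd.DataFrame:
    """Add ``normalized_value`` = raw_value / batch KO-untreated mean.

    Vehicle-only wells count as untreated if flagged so in the treatment
    column.  A batch without any KO-untreated reference well cannot be
    normalized and is a hard error naming the batch.
    """
    missing = [c for c in REQUIRED_COLS if c not in records.columns]
    if missing:
        raise PhenotypeError(f"activity records missing columns: {missing}")

    out = records.copy()
    ref_mask = (out["genotype"] == "KO") & _is_untreated(out)
    ref_means = out.loc[ref_mask].groupby("batch_id")["raw_value"].mean()

    batches = out["batch_id"].unique()
    missing_ref = sorted(set(batches) - set(ref_means.index))
    if missing_ref:
        raise PhenotypeError(f"batches without KO-untreated reference wells: {missing_ref}")
    zero_ref = sorted(ref_means.index[ref_means == 0])
    if zero_ref:
        raise PhenotypeError(f"KO reference mean is zero in batches: {zero_ref}")

    out["normalized_value"] = out["raw_value"] / out["batch_id"].map(ref_means)
    return out
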