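"""Distance scoring of compound-treated wells against the WT centroid.

Signature genes are standardized (mean 0, sample sd 1, n-1 denominator)
over a fit population, giving each gene equal weight.  Each well w is then
the point q(w) in signature space, and its score is the Euclidean distance

    d(w) = sqrt( sum_i (q_i(w) - p_i)^2 )

to the WT centroid p (per-gene mean over WT untreated control wells).  The
reference distance d_ref is the distance between the KO and WT centroids; a
compound-treated well is a hit iff d < d_ref (strictly), i.e. its profile
lies closer to WT than the untreated KO average does.  The relative score
d - d_ref puts KO at 0, with hits below 0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .normalize import NormalizedMatrix
from .signature import SignatureSet

__all__ = [
    "ScoringError",
    "StandardizedMatrix",
    "Centroid",
    "standardize",
    "centroid_of",
    "euclidean_score",
    "call_hits",
    "rank_compounds",
]

SCORE_COLUMNS = ["plate_id", "well_id", "compound_id", "distance", "d_ref",
                 "relative_score", "rank", "is_hit"]


class ScoringError(ValueError):
    pass


@dataclass
class StandardizedMatrix:
    """Wells x signature-genes z-scores with the fitted constants retained."""

    values: pd.DataFrame
    means: pd.Series
    sds: pd.Series
    fit_wells: pd.MultiIndex

    def constants_to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "schema_version": "sigscreen.standardization.v1",
            "mean": {g: float(m) for g, m in self.means.items()},
            "sd": {g: float(s) for g, s in self.sds.items()},
            "n_fit_wells": len(self.fit_wells),
        }, indent=1) + "\n")


@dataclass
class Centroid:
    """Per-gene mean of standardized values over a named well group."""

    values: pd.Series
    group: str
    n_wells: int


def standardize(
    norm: NormalizedMatrix | pd.DataFrame,
    signature: SignatureSet,
    fit_wells: pd.MultiIndex | None = None,
) -> StandardizedMatrix:
    """Z-score the signature genes; constants fitted over ``fit_wells``.

    By default the constants are fitted over all retained wells (controls
    and treated together) and applied to every well.  A zero-variance
    signature gene carries no information and is a hard error.
    """
    values = norm.values if isinstance(norm, NormalizedMatrix) else norm
    missing = [g for g in signature.genes if g not in values.columns]
    if missing:
        raise ScoringError(f"signature genes absent from matrix: {missing}")
    X = values[signature.genes]
    fit = X if fit_wells is None else X.loc[fit_wells]
    means = fit.mean(axis=0)
    sds = fit.std(axis=0, ddof=1)
    # a numerically constant column has sd at rounding level, not exactly 0
    tol = 1e-12 * np.maximum(1.0, means.abs())
    dead = list(sds.index[~np.isfinite(sds) | (sds <= tol)])
    if dead:
        raise ScoringError(f"zero-variance signature genes over fit wells: {dead}")
    Z = (X - means) / sds
    return StandardizedMatrix(values=Z, means=means, sds=sds,
                              fit_wells=fit.index if fit_wells is None else fit_wells)


def centroid_of(std: StandardizedMatrix, well_index: pd.MultiIndex, group: str) -> Centroid:
    sub = std.values.loc[well_index]
    if len(sub) < 1:
        raise ScoringError(f"no wells available for {group} centroid")
    return Centroid(values=sub.mean(axis=0), group=group, n_wells=len(sub))


def euclidean_score(std: StandardizedMatrix | pd.DataFrame, centroid: Centroid) -> pd.Series:
    """Per-well Euclidean distance to a centroid over the signature genes.

    Wells with a missing value in any signature dimension cannot be placed
    in the space; they are excluded with a warning.
    """
    Z = std.values if isinstance(std, StandardizedMatrix) else std
    if list(Z.columns) != list(centroid.values.index):
        raise ScoringError("signature dimensions of matrix and centroid differ")
    complete = ~Z.isna().any(axis=1)
    if (~complete).any():
        warnings.warn(f"excluding {int((~complete).sum())} wells with missing "
                      "signature values from distance scoring", stacklevel=2)
    diff = Z.loc[complete].to_numpy() - centroid.values.to_numpy()[None, :]
    return pd.Series(np.sqrt((diff**2).sum(axis=1)), index=Z.index[complete],
                     name="distance")


def call_hits(
    std: StandardizedMatrix,
    wells: pd.DataFrame,
    wt_centroid: Centroid,
    ko_centroid: Centroid,
) -> pd.DataFrame:
    """Score every compound-treated well and call hits against d_ref.

    Returns the score table sorted by rank (ascending distance, ties broken
    by compound_id for determinism).
    """
    for c in (wt_centroid, ko_centroid):
        if c.n_wells < 2:
            raise ScoringError(f"{c.group} centroid built from {c.n_wells} well(s); "
                               "need >= 2 control wells")
    d_ref = float(np.sqrt(((ko_centroid.values - wt_centroid.values) ** 2).sum()))

    wells = wells.loc[std.values.index]
    treated = wells.loc[wells["treatment"] == "compound"]
    all_distances = euclidean_score(std, wt_centroid)
    distances = all_distances.loc[all_distances.index.intersection(treated.index)]

    table = pd.DataFrame({
        "plate_id": [p for p, _ in distances.index],
        "well_id": [w for _, w in distances.index],
        "compound_id": treated.loc[distances.index, "compound_id"].to_numpy(),
        "distance": distances.to_numpy(),
    })
    table["d_ref"] = d_ref
    table["relative_score"] = table["distance"] - d_ref
    table = table.sort_values(["distance", "compound_id"], kind="mergesort")
    table["rank"] = np.arange(1, len(table) + 1)
    table["is_hit"] = table["distance"] < d_ref
    return table[SCORE_COLUMNS].reset_index(drop=True)


def rank_compounds(score_table: pd.DataFrame, top_n: int) -> pd.DataFrame:
    """Return the top_n compounds by ascending distance (rank order)."""
    if top_n > len(score_table):
        warnings.warn(f"top_n={top_n} exceeds {len(score_table)} scored wells; "
                      "returning all", stacklevel=2)
        top_n = len(score_table)
    return score_table.sort_values("rank").head(top_n).reset_index(drop=True)
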