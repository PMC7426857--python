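"""Differential signature between KO and WT control wells.

The signature gene set is defined on housekeeping-normalized values as the
genes with fold change (KO mean over WT mean) above ``fc_thresh`` or below
``1/fc_thresh`` and Welch two-sample t-test p-value below ``p_thresh`` on
log2-transformed values (a pseudocount of half the smallest positive value
guards log(0)).  The knocked-out target gene always passes by construction
and is reported but force-excluded from the signature used for scoring.

Control-well outliers are detected unbiasedly: Ward-linkage hierarchical
clustering (Euclidean distance on per-gene z-scored signature values of the
control wells) is cut at two clusters, and any control well whose genotype
is the minority of its assigned cluster is flagged.  Flagging is one-shot:
flagged wells are removed and the signature recomputed once, without
iteration.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .normalize import NormalizedMatrix

__all__ = [
    "SignatureError",
    "SignatureSet",
    "OutlierReport",
    "differential_signature",
    "detect_outlier_controls",
    "derive_signature",
    "ward_order",
]


class SignatureError(ValueError):
    pass


@dataclass
class SignatureSet:
    """Ordered selected signature genes (target-gene probe excluded)."""

    genes: list
    excluded_target: str | None
    fc_thresh: float
    p_thresh: float

    @property
    def n_dimensions(self) -> int:
        return len(self.genes)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "schema_version": "sigscreen.signature.v1",
            "genes": self.genes,
            "excluded_target": self.excluded_target,
            "fc_thresh": self.fc_thresh,
            "p_thresh": self.p_thresh,
        }, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureSet":
        d = json.loads(Path(path).read_text())
        return cls(genes=d["genes"], excluded_target=d["excluded_target"],
                   fc_thresh=d["fc_thresh"], p_thresh=d["p_thresh"])


@dataclass
class OutlierReport:
    """Control wells that did not cluster with their genotype group."""

    flagged: list = field(default_factory=list)  # plate_id, well_id, genotype, assigned_cluster
    linkage_method: str = "ward"

    @property
    def flagged_index(self) -> list[tuple[str, str]]:
        return [(f["plate_id"], f["well_id"]) for f in self.flagged]


def _as_values(norm: NormalizedMatrix | pd.DataFrame) -> pd.DataFrame:
    return norm.values if isinstance(norm, NormalizedMatrix) else norm


def _control_groups(values: pd.DataFrame, wells: pd.DataFrame,
                    exclude: list[tuple[str, str]] | None = None):
    wells = wells.loc[values.index]
    mask = wells["treatment"] == "untreated"
    if exclude:
        drop = pd.MultiIndex.from_tuples(exclude, names=values.index.names)
        mask &= ~wells.index.isin(drop)
    controls = wells.loc[mask]
    wt = values.loc[controls.index[controls["genotype"] == "WT"]]
    ko = values.loc[controls.index[controls["genotype"] == "KO"]]
    return wt, ko


def differential_signature(
    norm: NormalizedMatrix | pd.DataFrame,
    wells: pd.DataFrame,
    panel: pd.DataFrame,
    fc_thresh: float = 1.5,
    p_thresh: float = 0.05,
    exclude_wells: list[tuple[str, str]] | None = None,
) -> tuple[SignatureSet, pd.DataFrame]:
    """Select signature genes from KO-vs-WT control wells.

    Returns the signature set and the full per-gene table (every probe,
    including housekeeping and the excluded target, with its fold change,
    Welch p-value and selection flags).  ``exclude_wells`` removes flagged
    outlier control wells before computing the statistics.
    """
    values = _as_values(norm)
    wt, ko = _control_groups(values, wells, exclude_wells)
    if len(wt) < 2 or len(ko) < 2:
        raise SignatureError(
            f"need >= 2 control wells per genotype, have WT={len(wt)}, KO={len(ko)}"
        )

    positive = values.to_numpy()[values.to_numpy() > 0]
    eps = positive.min() / 2.0 if positive.size else 1.0

    mean_wt = wt.mean(axis=0)
    mean_ko = ko.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = (mean_ko / mean_wt).to_numpy()
    fc = np.where(mean_wt.to_numpy() == 0, np.inf, fc)

    t_res = stats.ttest_ind(np.log2(ko.to_numpy() + eps), np.log2(wt.to_numpy() + eps),
                            axis=0, equal_var=False)
    pvals = np.where(np.isnan(t_res.pvalue), 1.0, t_res.pvalue)

    finite = np.isfinite(fc) & (fc > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.where(finite, np.log2(np.where(finite, fc, 1.0)), np.nan)
    passes = finite & ((fc > fc_thresh) | (fc < 1.0 / fc_thresh)) & (pvals < p_thresh)

    is_target = (panel.loc[values.columns, "category"] == "target").to_numpy()
    target_gene = values.columns[is_target][0] if is_target.any() else None
    selected = passes & ~is_target

    table = pd.DataFrame({
        "probe_id": values.columns,
        "gene_symbol": panel.loc[values.columns, "gene_symbol"].to_numpy(),
        "mean_wt": mean_wt.to_numpy(),
        "mean_ko": mean_ko.to_numpy(),
        "fc": fc,
        "log2fc": log2fc,
        "p_value": pvals,
        "direction": np.where(fc > 1, "up_in_KO", "down_in_KO"),
        "passes_thresholds": passes,
        "selected": selected,
    })
    sig = SignatureSet(genes=list(values.columns[selected]), excluded_target=target_gene,
                       fc_thresh=fc_thresh, p_thresh=p_thresh)
    return sig, table


def detect_outlier_controls(
    norm: NormalizedMatrix | pd.DataFrame,
    wells: pd.DataFrame,
    signature: SignatureSet,
) -> OutlierReport:
    """Flag control wells whose genotype is the minority of their Ward cluster.

    Clustering runs on per-gene z-scored (sample sd, n-1) signature values
    of the control wells, Ward linkage with Euclidean distance, cut at
    k = 2.  Genotype ties within a cluster flag nobody.
    """
    values = _as_values(norm)
    wells = wells.loc[values.index]
    controls = wells.loc[wells["treatment"] == "untreated"]
    for g in ("WT", "KO"):
        if (controls["genotype"] == g).sum() < 3:
            raise SignatureError(f"need >= 3 {g} control wells for outlier detection")
    if not signature.genes:
        raise SignatureError("empty signature; nothing to cluster on")

    X = values.loc[controls.index, signature.genes]
    sd = X.std(axis=0, ddof=1)
    usable = sd > 0
    if not usable.any():
        warnings.warn("all signature genes constant across controls; no outliers flagged",
                      stacklevel=2)
        return OutlierReport()
    Z = (X.loc[:, usable] - X.loc[:, usable].mean(axis=0)) / sd[usable]

    link = hierarchy.linkage(Z.to_numpy(), method="ward")
    assign = hierarchy.fcluster(link, t=2, criterion="maxclust")

    report = OutlierReport()
    genotypes = controls["genotype"].to_numpy()
    for cluster in np.unique(assign):
        members = assign == cluster
        n_wt = int((genotypes[members] == "WT").sum())
        n_ko = int((genotypes[members] == "KO").sum())
        if n_wt == n_ko:
            continue
        minority = "WT" if n_wt < n_ko else "KO"
        for (plate, well), geno, m in zip(controls.index, genotypes, members):
            if m and geno == minority:
                report.flagged.append({"plate_id": plate, "well_id": well,
                                       "genotype": geno, "assigned_cluster": int(cluster)})
    return report


def derive_signature(
    norm: NormalizedMatrix | pd.DataFrame,
    wells: pd.DataFrame,
    panel: pd.DataFrame,
    fc_thresh: float = 1.5,
    p_thresh: float = 0.05,
) -> tuple[SignatureSet, pd.DataFrame, OutlierReport]:
    """Full signature derivation: select, flag outlier controls, reselect once."""
    sig, table = differential_signature(norm, wells, panel, fc_thresh, p_thresh)
    if not sig.genes:
        return sig, table, OutlierReport()
    outliers = detect_outlier_controls(norm, wells, sig)
    if outliers.flagged:
        sig, table = differential_signature(norm, wells, panel, fc_thresh, p_thresh,
                                            exclude_wells=outliers.flagged_index)
    return sig, table, outliers


def ward_order(matrix: pd.DataFrame | np.ndarray, axis: int = 0) -> list:
    """Deterministic Ward/Euclidean dendrogram leaf order for heatmap export.

    ``axis=0`` orders rows, ``axis=1`` columns.  Returns labels for a
    DataFrame, positional indices for an array.  Ties follow input order
    (scipy's linkage is deterministic for identical input).
    """
    labels = None
    if isinstance(matrix, pd.DataFrame):
        labels = list(matrix.index if axis == 0 else matrix.columns)
        X = matrix.to_numpy()
    else:
        X = np.asarray(matrix)
    if axis == 1:
        X = X.T
    if X.shape[0] < 2:
        return labels if labels is not None else list(range(X.shape[0]))
    link = hierarchy.linkage(X, method="ward")
    order = hierarchy.leaves_list(link).tolist()
    return [labels[i] for i in order] if labels is not None else order
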