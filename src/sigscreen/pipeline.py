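"""End-to-end screen analysis: QC, normalization, signature, scoring.

``analyze_screen`` chains the stages in the fixed order the analysis
requires (well filter, probe filter, per-plate housekeeping normalization,
plate combination, signature derivation with one-shot control-outlier
removal, standardization, distance scoring and hit calling) and returns
every intermediate product for audit.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .qc import QCReport, run_qc
from .normalize import NormalizedMatrix, normalize_housekeeping, combine_plates
from .signature import SignatureSet, OutlierReport, derive_signature, SignatureError
from .scoring import (
    StandardizedMatrix,
    Centroid,
    standardize,
    centroid_of,
    call_hits,
    euclidean_score,
)

__all__ = ["ScreenResult", "analyze_screen"]


@dataclass
class ScreenResult:
    qc_report: QCReport
    normalized: NormalizedMatrix
    signature: SignatureSet
    gene_table: pd.DataFrame
    outliers: OutlierReport
    standardized: StandardizedMatrix
    wt_centroid: Centroid
    ko_centroid: Centroid
    scores: pd.DataFrame
    control_distances: pd.DataFrame


def analyze_screen(
    counts: pd.DataFrame,
    wells: pd.DataFrame,
    panel: pd.DataFrame,
    cell_frac: float = 0.40,
    min_total_reads: float = 100_000,
    min_probe_plate_total: float = 2_000,
    fc_thresh: float = 1.5,
    p_thresh: float = 0.05,
    fit: str = "all",
    zscore: bool = True,
) -> ScreenResult:
    """Run the full analysis on a raw screen bundle.

    ``fit`` chooses the population over which standardization constants are
    fitted (``"all"`` retained wells, the default, or ``"controls"``);
    ``zscore=False`` scores distances on housekeeping-normalized values
    directly (sensitivity analysis; genes then carry unequal weight).
    """
    counts_q, wells_q, panel_q, qc_report = run_qc(
        counts, wells, panel, cell_frac, min_total_reads, min_probe_plate_total
    )

    per_plate = [
        normalize_housekeeping(counts_q.loc[[plate]], panel_q)
        for plate in counts_q.index.get_level_values("plate_id").unique()
    ]
    norm = combine_plates(per_plate)
    wells_n = wells_q.loc[norm.values.index]

    sig, gene_table, outliers = derive_signature(norm, wells_n, panel_q,
                                                 fc_thresh, p_thresh)
    if not sig.genes:
        raise SignatureError("no signature genes selected; cannot score the screen")

    clean = norm.values.index[~norm.values.index.isin(
        pd.MultiIndex.from_tuples(outliers.flagged_index or [("", "")],
                                  names=norm.values.index.names)
    )] if outliers.flagged else norm.values.index
    wells_clean = wells_n.loc[clean]

    if zscore:
        fit_wells = None
        if fit == "controls":
            fit_wells = wells_clean.index[wells_clean["treatment"] == "untreated"]
        elif fit != "all":
            raise ValueError(f"fit must be 'all' or 'controls', got {fit!r}")
        std = standardize(norm.values.loc[clean], sig, fit_wells)
    else:
        X = norm.values.loc[clean, sig.genes]
        std = StandardizedMatrix(
            values=X,
            means=pd.Series(0.0, index=sig.genes),
            sds=pd.Series(1.0, index=sig.genes),
            fit_wells=X.index,
        )

    controls = wells_clean.loc[wells_clean["treatment"] == "untreated"]
    wt_idx = controls.index[controls["genotype"] == "WT"]
    ko_idx = controls.index[controls["genotype"] == "KO"]
    wt_centroid = centroid_of(std, wt_idx, "WT")
    ko_centroid = centroid_of(std, ko_idx, "KO")

    scores = call_hits(std, wells_clean, wt_centroid, ko_centroid)

    ctrl_d = euclidean_score(std, wt_centroid).loc[controls.index]
    control_distances = pd.DataFrame({
        "plate_id": [p for p, _ in ctrl_d.index],
        "well_id": [w for _, w in ctrl_d.index],
        "genotype": controls.loc[ctrl_d.index, "genotype"].to_numpy(),
        "distance": ctrl_d.to_numpy(),
    })

    return ScreenResult(
        qc_report=qc_report,
        normalized=norm,
        signature=sig,
        gene_table=gene_table,
        outliers=outliers,
        standardized=std,
        wt_centroid=wt_centroid,
        ko_centroid=ko_centroid,
        scores=scores,
        control_distances=control_distances,
    )
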