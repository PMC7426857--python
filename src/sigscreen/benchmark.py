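"""Recovery experiments on synthetic screens.

Multi-seed benchmarks quantifying how well the pipeline recovers what the
generator programmed: sensitivity/specificity of signature-gene selection,
and rank-enrichment AUC for true rescuer compounds in the distance ranking.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.metrics import roc_auc_score

from .synthetic_screen import SimulationConfig, simulate_screen
from .qc import run_qc
from .normalize import normalize_housekeeping, combine_plates
from .signature import derive_signature
from .pipeline import analyze_screen

__all__ = ["SIGNATURE_BENCH_CONFIG", "signature_recovery", "hit_recovery"]

# Signature-recovery conditions: one plate with 16 control wells per
# genotype, the full 42-probe panel, one-log2-unit programmed shifts,
# NB dispersion 0.05.  Compounds are irrelevant to selection, so only a
# token number is carried along.
SIGNATURE_BENCH_CONFIG = SimulationConfig(
    n_plates=1,
    wells_per_plate=384,
    n_compounds=20,
    n_wt_controls_per_plate=16,
    n_ko_controls_per_plate=16,
    signature_log2fc=1.0,
    nb_dispersion=0.05,
    frac_toxic=0.0,
    frac_lowread=0.0,
)


def signature_recovery(seeds: list[int],
                       config: SimulationConfig = SIGNATURE_BENCH_CONFIG) -> dict:
    """Average sensitivity/specificity of signature selection over seeds.

    Candidates are the retained non-target probes; truth is the generator's
    ``is_signature_true`` flag.
    """
    sens, spec = [], []
    for seed in seeds:
        counts, wells, panel, truth = simulate_screen(
            dataclasses.replace(config, seed=seed)
        )
        counts_q, wells_q, panel_q, _ = run_qc(counts, wells, panel)
        nm = combine_plates([
            normalize_housekeeping(counts_q.loc[[p]], panel_q)
            for p in counts_q.index.get_level_values("plate_id").unique()
        ])
        sig, table, _ = derive_signature(nm, wells_q.loc[nm.values.index], panel_q)
        genes = truth.genes.set_index("probe_id")
        cand = table[~table["probe_id"].isin(
            genes.index[genes["is_target"]])].set_index("probe_id")
        true = genes.loc[cand.index, "is_signature_true"].to_numpy()
        picked = cand["selected"].to_numpy()
        sens.append((picked & true).sum() / true.sum())
        spec.append((~picked & ~true).sum() / (~true).sum())
    return {
        "sensitivity": float(np.mean(sens)),
        "specificity": float(np.mean(spec)),
        "n_seeds": len(seeds),
        "n_controls_per_genotype": config.n_wt_controls_per_plate * config.n_plates,
    }


def hit_recovery(seeds: list[int],
                 config: SimulationConfig = SimulationConfig()) -> dict:
    """Full-pipeline rescuer recovery over seeds at the default screen layout.

    For each seed, runs the complete analysis and measures the AUC of the
    distance ranking against the generator's rescuer truth (rescue fraction
    > 0), plus screen-level summaries averaged over seeds.
    """
    aucs, n_hits, d_mean, d_min, d_max, n_sig, n_removed = [], [], [], [], [], [], []
    for seed in seeds:
        counts, wells, panel, truth = simulate_screen(
            dataclasses.replace(config, seed=seed)
        )
        res = analyze_screen(counts, wells, panel)
        merged = res.scores.merge(truth.compounds, on="compound_id")
        aucs.append(roc_auc_score(merged["rescue_fraction"] > 0, -merged["distance"]))
        n_hits.append(int(res.scores["is_hit"].sum()))
        d_mean.append(res.scores["distance"].mean())
        d_min.append(res.scores["distance"].min())
        d_max.append(res.scores["distance"].max())
        n_sig.append(res.signature.n_dimensions)
        n_removed.append(res.qc_report.n_compounds_removed)
    return {
        "auc": float(np.mean(aucs)),
        "auc_per_seed": [float(a) for a in aucs],
        "n_hits": float(np.mean(n_hits)),
        "n_compounds_removed": float(np.mean(n_removed)),
        "n_signature_genes": float(np.mean(n_sig)),
        "distance_mean": float(np.mean(d_mean)),
        "distance_min": float(np.mean(d_min)),
        "distance_max": float(np.mean(d_max)),
        "n_seeds": len(seeds),
        "n_compounds": config.n_compounds,
    }
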