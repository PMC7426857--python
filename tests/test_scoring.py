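"""Standardization, Euclidean scoring, hit calling and ranking."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from sigscreen import (
    SimulationConfig,
    simulate_screen,
    analyze_screen,
    standardize,
    centroid_of,
    euclidean_score,
    call_hits,
    rank_compounds,
    SignatureSet,
)
from sigscreen.scoring import Centroid, ScoringError, StandardizedMatrix


def _frame(X, genes=None):
    X = np.asarray(X, dtype=float)
    index = pd.MultiIndex.from_tuples([("p1", f"A{i + 1:02d}") for i in range(len(X))],
                                      names=["plate_id", "well_id"])
    genes = genes or [f"g{i}" for i in range(X.shape[1])]
    return pd.DataFrame(X, index=index, columns=genes)


def _sig(genes):
    return SignatureSet(genes=list(genes), excluded_target=None,
                        fc_thresh=1.5, p_thresh=0.05)


def test_two_value_column_standardizes_to_plus_minus_invsqrt2():
    values = _frame([[1.0], [3.0]])
    std = standardize(values, _sig(values.columns))
    np.testing.assert_allclose(std.values.to_numpy().ravel(),
                               [-0.7071, 0.7071], atol=5e-5)


def test_fitted_columns_have_mean_zero_sd_one():
    values = _frame(np.random.default_rng(0).lognormal(size=(40, 6)))
    std = standardize(values, _sig(values.columns))
    assert np.abs(std.values.mean(axis=0)).max() < 1e-12
    assert np.abs(std.values.std(axis=0, ddof=1) - 1).max() < 1e-12


def test_standardization_invariant_to_positive_per_gene_scaling():
    rng = np.random.default_rng(1)
    values = _frame(rng.lognormal(size=(30, 5)))
    scales = rng.uniform(0.1, 50, size=5)
    std_a = standardize(values, _sig(values.columns))
    std_b = standardize(values * scales, _sig(values.columns))
    np.testing.assert_allclose(std_a.values, std_b.values, atol=1e-10)


def test_zero_variance_gene_is_named_in_error():
    values = _frame(np.random.default_rng(2).normal(size=(10, 3)))
    values["g1"] = 4.2
    with pytest.raises(ScoringError, match="g1"):
        standardize(values, _sig(values.columns))


def test_fit_population_switch_changes_constants_not_contract():
    values = _frame(np.random.default_rng(3).lognormal(size=(20, 4)))
    fit_idx = values.index[:8]
    std = standardize(values, _sig(values.columns), fit_wells=fit_idx)
    sub = std.values.loc[fit_idx]
    assert np.abs(sub.mean(axis=0)).max() < 1e-12
    assert np.abs(sub.std(axis=0, ddof=1) - 1).max() < 1e-12


def test_distance_to_self_is_zero_and_3_4_5_triangle():
    Z = _frame([[0.0, 0.0], [3.0, 4.0]])
    centroid = Centroid(values=pd.Series([0.0, 0.0], index=Z.columns),
                        group="WT", n_wells=2)
    d = euclidean_score(Z, centroid)
    assert d.iloc[0] == 0.0
    assert d.iloc[1] == pytest.approx(5.0)


def test_vectorized_distance_equals_double_loop_oracle():
    rng = np.random.default_rng(4)
    Z = _frame(rng.normal(size=(50, 11)))
    p = pd.Series(rng.normal(size=11), index=Z.columns)
    centroid = Centroid(values=p, group="WT", n_wells=5)
    d = euclidean_score(Z, centroid)
    for w in range(50):
        acc = 0.0
        for i in range(11):
            acc += (Z.iloc[w, i] - p.iloc[i]) ** 2
        assert abs(d.iloc[w] - np.sqrt(acc)) < 1e-12


def test_distances_invariant_to_per_gene_translation():
    """A constant added to one gene pre-standardization is absorbed by m_i."""
    rng = np.random.default_rng(5)
    values = _frame(rng.lognormal(size=(25, 4)))
    shifted = values.copy()
    shifted["g2"] = shifted["g2"] + 7.3
    sig = _sig(values.columns)

    def dists(v):
        std = standardize(v, sig)
        centroid = centroid_of(std, v.index[:5], "WT")
        return euclidean_score(std, centroid)

    np.testing.assert_allclose(dists(values), dists(shifted), atol=1e-10)


def _hit_setup(distance_rows):
    """Wells at controlled distances from a WT centroid at the origin."""
    n = len(distance_rows)
    rows = [[d, 0.0] for d in distance_rows]
    Z = _frame([[0.0, 0.0], [0.0, 0.0], [4.0, 0.0], [4.0, 0.0]] + rows)
    wells = pd.DataFrame({
        "genotype": ["WT", "WT", "KO", "KO"] + ["KO"] * n,
        "treatment": ["untreated"] * 4 + ["compound"] * n,
        "compound_id": ["", "", "", ""] + [f"C{i:02d}" for i in range(n)],
        "cell_count": 1.0,
    }, index=Z.index)
    std = StandardizedMatrix(values=Z, means=pd.Series(0.0, index=Z.columns),
                             sds=pd.Series(1.0, index=Z.columns), fit_wells=Z.index)
    wt = centroid_of(std, Z.index[:2], "WT")
    ko = centroid_of(std, Z.index[2:4], "KO")
    return std, wells, wt, ko


def test_hit_rule_is_strictly_below_reference():
    std, wells, wt, ko = _hit_setup([4.0, 3.999, 4.001, 0.0])
    table = call_hits(std, wells, wt, ko)
    assert table["d_ref"].iloc[0] == pytest.approx(4.0)
    by_cmp = table.set_index("compound_id")
    assert not by_cmp.loc["C00", "is_hit"]          # exactly d_ref
    assert bool(by_cmp.loc["C01", "is_hit"])
    assert not by_cmp.loc["C02", "is_hit"]
    assert bool(by_cmp.loc["C03", "is_hit"])
    np.testing.assert_allclose(table["relative_score"], table["distance"] - 4.0)


def test_hit_calling_is_monotone_in_distance():
    rng = np.random.default_rng(6)
    std, wells, wt, ko = _hit_setup(list(rng.uniform(0, 8, size=30)))
    table = call_hits(std, wells, wt, ko).sort_values("rank")
    hits = table["is_hit"].to_numpy()
    assert not np.any(~hits[:-1] & hits[1:])  # no hit ranked below a non-hit


def test_tied_distances_rank_by_compound_id():
    std, wells, wt, ko = _hit_setup([2.0, 2.0, 1.0])
    table = call_hits(std, wells, wt, ko).sort_values("rank")
    assert list(table["compound_id"]) == ["C02", "C00", "C01"]
    assert list(table["rank"]) == [1, 2, 3]


def test_too_few_centroid_wells_rejected():
    std, wells, wt, ko = _hit_setup([1.0])
    lone = centroid_of(std, std.values.index[:1], "WT")
    with pytest.raises(ScoringError, match=">= 2"):
        call_hits(std, wells, lone, ko)


def test_rank_compounds_top_subset_and_reconstruction():
    std, wells, wt, ko = _hit_setup(list(np.linspace(5, 1, 9)))
    table = call_hits(std, wells, wt, ko)
    top1 = rank_compounds(table, 1)
    assert top1["distance"].iloc[0] == table["distance"].min()
    top4 = rank_compounds(table, 4)
    rest = table.sort_values("rank").iloc[4:]
    recon = pd.concat([top4, rest]).reset_index(drop=True)
    pd.testing.assert_frame_equal(recon, table.sort_values("rank").reset_index(drop=True))
    with pytest.warns(UserWarning, match="exceeds"):
        assert len(rank_compounds(table, 99)) == len(table)


def test_missing_signature_value_excludes_well_with_warning():
    std, wells, wt, ko = _hit_setup([1.0, 2.0])
    std.values.iloc[-1, 0] = np.nan
    with pytest.warns(UserWarning, match="missing"):
        table = call_hits(std, wells, wt, ko)
    assert list(table["compound_id"]) == ["C00"]


@pytest.fixture(scope="module")
def noiseless_screen():
    cfg = SimulationConfig(
        n_plates=2, wells_per_plate=96, n_compounds=60, n_probes=20,
        n_housekeeping=4, n_signature_true=5,
        n_wt_controls_per_plate=8, n_ko_controls_per_plate=8,
        frac_rescuers=0.3, rescue_fraction_range=(0.0, 1.0),
        frac_toxic=0.0, frac_lowread=0.0,
        library_size_cv=0.0, library_size_mean=1e6,
        noiseless=True, seed=21,
    )
    counts, wells, panel, truth = simulate_screen(cfg)
    return counts, wells, panel, truth


def test_noiseless_full_rescue_scores_zero_and_hits(noiseless_screen):
    counts, wells, panel, truth = noiseless_screen
    cfg = truth.config
    full = dataclasses.replace(cfg, rescue_fraction_range=(1.0, 1.0), seed=22)
    counts, wells, panel, truth = simulate_screen(full)
    res = analyze_screen(counts, wells, panel)
    rescued = set(truth.compounds.loc[truth.compounds["rescue_fraction"] == 1.0,
                                      "compound_id"])
    assert rescued
    scored = res.scores.set_index("compound_id")
    assert (scored.loc[sorted(rescued), "distance"] < 1e-12).all()
    assert scored.loc[sorted(rescued), "is_hit"].all()
    assert (scored["d_ref"] > 0).all()


def test_noiseless_distance_monotone_in_rescue_fraction(noiseless_screen):
    counts, wells, panel, truth = noiseless_screen
    res = analyze_screen(counts, wells, panel)
    merged = res.scores.merge(truth.compounds, on="compound_id")
    merged = merged.sort_values("rescue_fraction")
    d = merged["distance"].to_numpy()
    # integer rounding of expected counts leaves only hairline wiggles
    assert (np.diff(d) <= 1e-2 * d.max()).all()


def test_target_probe_exclusion_is_real(noiseless_screen):
    """Adding the target probe to the signature must change distances."""
    counts, wells, panel, truth = noiseless_screen
    res = analyze_screen(counts, wells, panel)
    assert res.signature.excluded_target == "Grn"
    with_target = SignatureSet(genes=res.signature.genes + ["Grn"],
                               excluded_target=None, fc_thresh=1.5, p_thresh=0.05)
    clean = res.standardized.values.index
    std2 = standardize(res.normalized.values.loc[clean], with_target)
    wells_c = wells.loc[clean]
    ctrl = wells_c[wells_c["treatment"] == "untreated"]
    wt2 = centroid_of(std2, ctrl.index[ctrl["genotype"] == "WT"], "WT")
    d2 = euclidean_score(std2, wt2)
    d1 = euclidean_score(res.standardized, res.wt_centroid)
    assert not np.allclose(d1, d2.loc[d1.index])
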