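"""Transcriptional coupling: normalization, CGE, distance decay, gene
contribution scores, cell markers, and resampling enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest

import hubwire
from hubwire.expression import (
    cge_matrix,
    derive_cell_markers,
    fit_distance_decay,
    gcs_link_tstat,
    gene_contribution_scores,
    gene_score_resampling,
    read_gmt,
    srs_normalize,
)


def _coords_and_distances(n, rng, span=160.0):
    xyz = rng.uniform(0, span, size=(n, 3))
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=2)
    return xyz, d


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def test_srs_normalize_bounds_and_monotonicity():
    rng = np.random.default_rng(0)
    raw = pd.DataFrame(rng.lognormal(2, 1, size=(15, 40)))
    atlas = srs_normalize(raw)
    x = atlas.data.to_numpy()
    assert x.min() >= 0.0 and x.max() <= 1.0
    assert np.allclose(x.min(axis=0), 0.0) and np.allclose(x.max(axis=0), 1.0)
    # each pass is monotone along its own axis: reproduce pass 1 with a
    # reference sigmoid and check rank preservation per row, then per column
    r = raw.to_numpy()
    med = np.median(r, axis=1, keepdims=True)
    iqr = np.subtract(*np.percentile(r, [75, 25], axis=1, keepdims=True))
    s1 = 1.0 / (1.0 + np.exp(-(r - med) / (iqr / 1.35)))
    s1 = (s1 - s1.min(axis=1, keepdims=True)) / np.ptp(s1, axis=1, keepdims=True)
    for i in range(0, 15, 3):  # pass 1: row ranks equal raw row ranks
        assert (np.argsort(s1[i]) == np.argsort(r[i])).all()
    for j in range(0, 40, 7):  # pass 2: column ranks equal pass-1 column ranks
        assert (np.argsort(x[:, j]) == np.argsort(s1[:, j])).all()


def test_srs_constant_gene_maps_to_half_and_flagged():
    rng = np.random.default_rng(1)
    raw = pd.DataFrame(rng.normal(size=(10, 5)), columns=list("abcde"))
    raw["c"] = 7.0
    atlas = srs_normalize(raw)
    assert np.allclose(atlas.data["c"], 0.5)
    assert "c" in atlas.flagged_genes


def test_srs_multi_donor_average():
    rng = np.random.default_rng(2)
    d1 = pd.DataFrame(rng.normal(size=(8, 6)), index=range(8))
    d2 = pd.DataFrame(rng.normal(size=(8, 6)), index=range(8))
    combined = srs_normalize({"d1": d1, "d2": d2})
    solo1 = srs_normalize(d1).data
    solo2 = srs_normalize(d2).data
    assert np.allclose(combined.data, (solo1 + solo2) / 2)


# ---------------------------------------------------------------------------
# CGE
# ---------------------------------------------------------------------------


def test_cge_toy_matches_direct_pearson():
    data = pd.DataFrame(
        [[0.1, 0.5, 0.9, 0.2], [0.3, 0.4, 0.8, 0.1], [0.9, 0.2, 0.1, 0.7]],
        index=["r0", "r1", "r2"],
    )
    cge = cge_matrix(data)
    expect = np.corrcoef(data.to_numpy())
    assert np.allclose(cge.to_numpy(), expect)
    assert np.allclose(np.diag(cge), 1.0)


def test_cge_duplicate_and_negated_profiles():
    base = np.array([0.2, 0.8, 0.4, 0.6, 0.1])
    data = pd.DataFrame([base, base, 1 - base])
    cge = cge_matrix(data).to_numpy()
    assert cge[0, 1] == pytest.approx(1.0)
    assert cge[0, 2] == pytest.approx(-1.0)


def test_cge_zero_variance_region_undefined():
    data = pd.DataFrame([[1.0, 2.0, 3.0], [3.0, 3.0, 3.0], [2.0, 1.0, 3.0]])
    cge = cge_matrix(data)
    assert cge.iloc[1].isna().all() and cge.iloc[:, 1].isna().all()


# ---------------------------------------------------------------------------
# distance decay
# ---------------------------------------------------------------------------


def test_noiseless_decay_fit_recovers_parameters_exactly():
    rng = np.random.default_rng(3)
    _, d = _coords_and_distances(60, rng)
    a_true, b_true, n_true = 0.64, -0.19, 90.4
    cge = a_true * np.exp(-d / n_true) + b_true
    np.fill_diagonal(cge, 1.0)
    fit = fit_distance_decay(cge, d)
    assert abs(fit.amplitude - a_true) / abs(a_true) < 1e-4
    assert abs(fit.offset - b_true) / abs(b_true) < 1e-4
    assert abs(fit.scale - n_true) / n_true < 1e-4
    # residuals of fitted pairs vanish
    resid = fit.residuals.to_numpy()
    iu, ju = np.triu_indices(60, k=1)
    assert np.nanmax(np.abs(resid[iu, ju])) < 1e-8


def test_noisy_decay_fit_recovers_amplitude():
    rng = np.random.default_rng(4)
    _, d = _coords_and_distances(180, rng)
    cge = 0.64 * np.exp(-d / 90.4) - 0.19 + rng.normal(0, 0.05, size=d.shape)
    cge = (cge + cge.T) / 2
    np.fill_diagonal(cge, 1.0)
    fit = fit_distance_decay(cge, d)
    assert abs(fit.amplitude - 0.64) < 0.05


def test_refit_on_residuals_is_flat():
    rng = np.random.default_rng(5)
    _, d = _coords_and_distances(80, rng)
    cge = 0.5 * np.exp(-d / 60.0) - 0.1
    np.fill_diagonal(cge, 1.0)
    fit = fit_distance_decay(cge, d)
    resid = fit.residuals.to_numpy().copy()
    np.fill_diagonal(resid, 1.0)
    with pytest.warns(UserWarning, match="flat"):
        refit = fit_distance_decay(resid, d)
    assert abs(refit.amplitude) < 1e-5 or refit.scale > 1e5


def test_residualization_removes_distance_correlation():
    from scipy.stats import spearmanr

    rng = np.random.default_rng(6)
    _, d = _coords_and_distances(100, rng)
    cge = 0.6 * np.exp(-d / 80.0) - 0.15 + rng.normal(0, 0.01, size=d.shape)
    cge = (cge + cge.T) / 2
    np.fill_diagonal(cge, 1.0)
    fit = fit_distance_decay(cge, d)
    iu, ju = np.triu_indices(100, k=1)
    rho = spearmanr(d[iu, ju], fit.residuals.to_numpy()[iu, ju]).statistic
    assert abs(rho) < 0.05


# ---------------------------------------------------------------------------
# gene contribution scores
# ---------------------------------------------------------------------------


def test_mean_gcs_reproduces_residual_cge_exactly():
    """The module's central conservation law at numerical precision."""
    rng = np.random.default_rng(7)
    _, d = _coords_and_distances(40, rng)
    expr = pd.DataFrame(rng.normal(size=(40, 120)))
    cge = cge_matrix(expr)
    fit = fit_distance_decay(cge, d)
    iu, ju = np.triu_indices(40, k=1)
    gcs, genes = gene_contribution_scores(expr, fit, d, iu, ju)
    assert genes.size == 120
    resid = fit.residuals.to_numpy()[iu, ju]
    assert np.max(np.abs(gcs.mean(axis=1) - resid)) < 1e-10


def test_single_gene_gcs_is_zproduct_minus_trend():
    rng = np.random.default_rng(8)
    _, d = _coords_and_distances(12, rng)
    expr = pd.DataFrame(rng.normal(size=(12, 1)))
    # trend from an unrelated larger fit; only its r(d) values matter here
    cge = 0.3 * np.exp(-d / 50.0) + 0.05
    np.fill_diagonal(cge, 1.0)
    fit = fit_distance_decay(cge, d)
    iu, ju = np.triu_indices(12, k=1)
    with pytest.warns(UserWarning, match="single-gene"):
        gcs, _ = gene_contribution_scores(expr, fit, d, iu, ju)
    x = expr.to_numpy()[:, 0]
    z = (x - x.mean()) / x.std()
    expect = z[iu] * z[ju] - fit.trend(d[iu, ju])
    assert np.allclose(gcs[:, 0], expect)


def test_gcs_tstat_antisymmetric_and_near_zero_under_null():
    rng = np.random.default_rng(9)
    gcs = rng.normal(size=(60, 200))
    rich = np.arange(0, 20)
    peri = np.arange(30, 60)
    t_fwd = gcs_link_tstat(gcs, rich, peri)
    t_rev = gcs_link_tstat(gcs, peri, rich)
    assert np.allclose(t_fwd, -t_rev)
    assert abs(np.mean(t_fwd)) < 0.1


def test_planted_coupling_genes_rank_high(cohort, distances):
    spec = hubwire.ExpressionSimSpec(
        n_genes=400, hub_coupling_boost=0.15, hub_coupled_fraction=0.25, seed=10
    )
    expr, info = hubwire.simulate_expression(spec, cohort.nodes, cohort.hubs)
    cge = cge_matrix(expr)
    fit = fit_distance_decay(cge, distances)
    hub_mask = np.zeros(len(cohort.nodes), dtype=bool)
    hub_mask[cohort.hubs] = True
    iu, ju = np.triu_indices(len(cohort.nodes), k=1)
    gcs, genes = gene_contribution_scores(expr, fit, distances, iu, ju)
    rich = np.where(hub_mask[iu] & hub_mask[ju])[0]
    peri = np.where(~hub_mask[iu] & ~hub_mask[ju])[0]
    t = gcs_link_tstat(gcs, rich, peri, genes)
    coupled = info["hub_coupled"].to_numpy()
    assert t[coupled].mean() > t[~coupled].mean()
    top_decile = set(t.sort_values(ascending=False).index[:40])
    planted = set(info.index[coupled])
    assert len(top_decile & planted) > 20  # strong enrichment of planted genes


# ---------------------------------------------------------------------------
# cell markers
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "astro,neuron,expect",
    [(10.0, 1.0, "astro"), (10.0, 5.0, "none"), (4.9, 0.0, "none")],
)
def test_marker_level_and_fold_rules(astro, neuron, expect):
    table = pd.DataFrame({"g": [astro, neuron]}, index=["astro", "neuron"])
    assert derive_cell_markers(table)["g"] == expect


def test_markers_require_two_classes():
    with pytest.raises(ValueError):
        derive_cell_markers(pd.DataFrame({"g": [10.0]}, index=["astro"]))


# ---------------------------------------------------------------------------
# gene score resampling
# ---------------------------------------------------------------------------


def test_gsr_identical_scores_give_p_one():
    scores = pd.Series(2.0, index=[f"g{i}" for i in range(50)])
    sets = {"s1": [f"g{i}" for i in range(10)], "s2": [f"g{i}" for i in range(20, 30)]}
    res = gene_score_resampling(scores, sets, n_iter=500, size_bounds=(5, 30), seed=0)
    assert (res["p"] == 1.0).all()


def test_gsr_top_scoring_set_extreme_p():
    rng = np.random.default_rng(11)
    scores = pd.Series(rng.normal(size=300), index=[f"g{i}" for i in range(300)])
    top = list(scores.sort_values(ascending=False).index[:10])
    res = gene_score_resampling(scores, {"top": top}, n_iter=2000, seed=0)
    assert res.loc[res.gene_set == "top", "p"].iloc[0] == pytest.approx(1 / 2001)


def test_gsr_matches_exhaustive_oracle_on_tiny_universe():
    """Resampled upper-tail p converges to the exhaustive same-size draw
    probability on a 6-gene universe."""
    scores = pd.Series([3.0, 2.0, 1.0, 0.0, -1.0, -2.0],
                       index=[f"g{i}" for i in range(6)])
    target = ["g0", "g2"]  # mean 2.0
    obs = scores[target].mean()
    combos = [np.mean(c) for c in itertools.combinations(scores, 2)]
    exact = sum(m >= obs for m in combos) / len(combos)
    res = gene_score_resampling(
        scores, {"t": target}, n_iter=40000, size_bounds=(2, 6), seed=1
    )
    p = res["p"].iloc[0]
    assert p == pytest.approx(exact, abs=0.01)


def test_gsr_excludes_sets_outside_size_bounds():
    scores = pd.Series(np.arange(30, dtype=float), index=[f"g{i}" for i in range(30)])
    sets = {"tiny": ["g0", "g1"], "ok": [f"g{i}" for i in range(8)]}
    res = gene_score_resampling(scores, sets, n_iter=200, size_bounds=(5, 20), seed=0)
    assert np.isnan(res.loc[res.gene_set == "tiny", "p"].iloc[0])
    assert np.isfinite(res.loc[res.gene_set == "ok", "p"].iloc[0])


def test_read_gmt_roundtrip(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text("setA\tdesc\tg1\tg2\tg3\nsetB\tdesc\tg4\tg5\n")
    sets = read_gmt(path)
    assert sets == {"setA": ["g1", "g2", "g3"], "setB": ["g4", "g5"]}
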