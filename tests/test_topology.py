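"""Group connectome, rich-club statistics, communicability, link curves.

Rich-club coefficients are checked against a brute-force subgraph
enumeration oracle; communicability against its truncated power series and
hand-derived closed forms.
"""

import math

import numpy as np
import pytest
from scipy.linalg import expm

import hubwire
from hubwire.topology import (
    Connectome,
    build_group_connectome,
    classify_links,
    communicability,
    degree_preserving_rewire,
    link_type_curve,
    normalized_rich_club_curve,
    rich_club_coefficient,
    weighted_rich_club_coefficient,
)
from conftest import random_symmetric


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def brute_phi(weights: np.ndarray, k: int, weighted: bool = False) -> float:
    """Direct subgraph enumeration of the (weighted) rich-club coefficient."""
    mask = weights > 0
    deg = mask.sum(axis=1)
    rich = [i for i in range(len(deg)) if deg[i] > k]
    if len(rich) < 2:
        return float("nan")
    sub_edges = [
        (i, j) for a, i in enumerate(rich) for j in rich[a + 1:] if mask[i, j]
    ]
    if not weighted:
        return 2.0 * len(sub_edges) / (len(rich) * (len(rich) - 1))
    if not sub_edges:
        return float("nan")
    w_rich = sum(weights[i, j] for i, j in sub_edges)
    all_w = sorted(
        (weights[i, j] for i in range(len(deg)) for j in range(i + 1, len(deg)) if mask[i, j]),
        reverse=True,
    )
    return w_rich / sum(all_w[: len(sub_edges)])


# ---------------------------------------------------------------------------
# group connectome
# ---------------------------------------------------------------------------


def test_density_thresholding_retains_round_tau_pairs():
    """A 360-node connectome thresholded to 20% density keeps 12,924 edges."""
    rng = np.random.default_rng(0)
    n = 360
    subj = np.stack([random_symmetric(n, rng, density=0.9) for _ in range(3)])
    conn = build_group_connectome(subj, density_target=0.20)
    assert conn.n_edges == 12924 == round(0.20 * n * (n - 1) / 2)


def test_consistency_rule_excludes_rare_strong_edge():
    rng = np.random.default_rng(1)
    n = 12
    subj = np.stack([random_symmetric(n, rng, density=0.6) for _ in range(10)])
    subj[:, 0, 1] = subj[:, 1, 0] = 0.0
    subj[0, 0, 1] = subj[0, 1, 0] = 1e6  # present once, huge weight
    conn = build_group_connectome(subj, consistency_min=0.30, density_target=1.0)
    assert not conn.mask[0, 1]


def test_full_density_zero_consistency_gives_union_mask():
    rng = np.random.default_rng(2)
    subj = np.stack([random_symmetric(10, rng, density=0.3) for _ in range(4)])
    with pytest.warns(UserWarning, match="unreachable"):
        conn = build_group_connectome(subj, consistency_min=0.0, density_target=1.0)
    union = (subj > 0).any(axis=0)
    assert np.array_equal(conn.mask, union)


def test_asymmetric_subject_matrix_rejected():
    bad = np.zeros((1, 4, 4))
    bad[0, 0, 1] = 1.0
    with pytest.raises(ValueError, match="symmetric"):
        build_group_connectome(bad, density_target=0.5)


# ---------------------------------------------------------------------------
# link classification
# ---------------------------------------------------------------------------


def test_star_graph_classification():
    w = np.zeros((5, 5))
    w[0, 1:] = w[1:, 0] = 1.0
    cls = classify_links(Connectome(w), k=1)
    assert set(cls.hubs) == {0}
    assert (cls.edge_class == "feeder").all() and cls.edge_class.size == 4


def test_k0_makes_every_edge_rich_and_classes_partition(group_conn):
    cls0 = classify_links(group_conn, k=0)
    assert (cls0.edge_class == "rich").all()
    for k in (5, 10, 20):
        cls = classify_links(group_conn, k)
        counts = {c: (cls.edge_class == c).sum() for c in ("rich", "feeder", "peripheral")}
        assert sum(counts.values()) == group_conn.n_edges


# ---------------------------------------------------------------------------
# rich-club coefficients
# ---------------------------------------------------------------------------


def test_complete_graph_and_path_closed_forms():
    k4 = np.ones((4, 4)) - np.eye(4)
    assert rich_club_coefficient(Connectome(k4), 2) == 1.0
    p4 = np.zeros((4, 4))
    for i in range(3):
        p4[i, i + 1] = p4[i + 1, i] = 1.0
    # nodes with degree > 1 are the two (connected) middle nodes
    assert rich_club_coefficient(Connectome(p4), 1) == 1.0
    assert math.isnan(rich_club_coefficient(Connectome(p4), 2))  # k = max degree


def test_uniform_weights_give_weighted_coefficient_one(group_conn):
    uni = Connectome((group_conn.mask * 2.5))
    for k in (3, 8, 15):
        phi_w = weighted_rich_club_coefficient(uni, k)
        if not math.isnan(phi_w):
            assert phi_w == pytest.approx(1.0)


@pytest.mark.parametrize("n_nodes", [4, 5, 6])
def test_rich_club_matches_enumeration_oracle(n_nodes):
    rng = np.random.default_rng(3)
    for rep in range(40):
        w = random_symmetric(n_nodes, rng, density=0.5)
        conn = Connectome(w)
        for k in range(0, n_nodes):
            assert np.isclose(
                rich_club_coefficient(conn, k), brute_phi(w, k), equal_nan=True
            )
            assert np.isclose(
                weighted_rich_club_coefficient(conn, k),
                brute_phi(w, k, weighted=True),
                equal_nan=True,
            )


# ---------------------------------------------------------------------------
# null models
# ---------------------------------------------------------------------------


def test_rewiring_preserves_degree_sequence_and_edge_count(group_conn):
    null = degree_preserving_rewire(group_conn, swaps_per_edge=5, seed=0)
    assert np.array_equal(null.sum(axis=1), group_conn.degrees)
    assert null.sum() == group_conn.mask.sum()
    assert not np.array_equal(null, group_conn.mask)  # something actually moved
    assert np.all(np.diag(null) == 0)


def test_triangle_has_no_valid_swap():
    k3 = np.ones((3, 3)) - np.eye(3)
    null = degree_preserving_rewire(Connectome(k3), swaps_per_edge=50, seed=1)
    assert np.array_equal(null, k3 > 0)


def test_weight_permutation_null_uniform_weights_norm_one(group_conn):
    uni = Connectome(group_conn.mask * 1.7)
    curve = normalized_rich_club_curve(uni, n_null=20, mode="weighted", seed=0)
    defined = np.isfinite(curve.phi_norm)
    assert np.allclose(curve.phi_norm[defined], 1.0)


def test_permutation_p_uses_add_one_rule(group_conn):
    curve = normalized_rich_club_curve(group_conn, n_null=19, seed=4)
    defined = np.isfinite(curve.p)
    assert np.all(curve.p[defined] >= 1.0 / 20.0)
    assert np.all(curve.p[defined] <= 1.0)


def test_planted_rich_club_detected():
    spec = hubwire.SyntheticCohortSpec(
        n_nodes=120, n_subjects=15, richclub_boost=0.8, seed=1
    )
    coh = hubwire.simulate_cohort_connectomes(spec)
    conn = build_group_connectome(coh.sc, density_target=0.10)
    deg = conn.degrees
    hub_deg = np.sort(deg[coh.hubs])
    lo = int(np.delete(deg, coh.hubs).max())
    hi = int(np.percentile(hub_deg, 33))
    curve = normalized_rich_club_curve(conn, ks=np.arange(lo, hi), n_null=100, seed=0)
    assert np.all(curve.phi_norm > 1.0)
    assert np.all(curve.p < 0.05)


# ---------------------------------------------------------------------------
# communicability
# ---------------------------------------------------------------------------


def test_empty_graph_communicability_is_identity():
    conn = Connectome(np.zeros((4, 4)))
    assert np.allclose(communicability(conn), np.eye(4))


def test_single_edge_and_triangle_closed_forms():
    w = np.zeros((2, 2))
    w[0, 1] = w[1, 0] = 1.0
    c = communicability(Connectome(w))
    assert c[0, 1] == pytest.approx(math.sinh(1.0), abs=1e-12)
    assert c[0, 0] == pytest.approx(math.cosh(1.0), abs=1e-12)
    k3 = np.ones((3, 3)) - np.eye(3)
    c3 = communicability(Connectome(k3))
    assert c3[0, 1] == pytest.approx((math.e**2 - math.e**-1) / 3.0, abs=1e-12)


def test_weighted_two_node_strength_normalization_cancels():
    base = None
    for w_val in (0.1, 1.0, 42.0):
        w = np.zeros((2, 2))
        w[0, 1] = w[1, 0] = w_val
        c = communicability(Connectome(w), mode="weighted")
        if base is None:
            base = c
        assert np.allclose(c, base, atol=1e-12)


def test_communicability_matches_truncated_series():
    rng = np.random.default_rng(5)
    for _ in range(10):
        w = random_symmetric(7, rng, density=0.35, weighted=False)
        if np.max(np.abs(np.linalg.eigvalsh(w))) > 3:
            continue
        series = sum(
            np.linalg.matrix_power(w, l) / math.factorial(l) for l in range(21)
        )
        assert np.allclose(communicability(Connectome(w)), series, atol=1e-9)


def test_isolated_node_weighted_mode_identity_row():
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 2.0
    with pytest.warns(UserWarning, match="isolated"):
        c = communicability(Connectome(w), mode="weighted")
    assert c[2, 2] == pytest.approx(1.0)
    assert c[2, 0] == pytest.approx(0.0) and c[2, 1] == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# link-type curves
# ---------------------------------------------------------------------------


def test_constant_metric_gives_t0_p_half(group_conn):
    vals = np.full(group_conn.n_edges, 3.14)
    curve = link_type_curve(group_conn, vals, ks=[5, 10])
    ok = curve.dropna(subset=["t"])
    assert np.allclose(ok["t"], 0.0)
    assert np.allclose(ok["p"], 0.5)


def test_class_means_average_to_global_mean(group_conn):
    rng = np.random.default_rng(6)
    vals = rng.normal(size=group_conn.n_edges)
    curve = link_type_curve(group_conn, vals, ks=[8])
    pooled = (curve["mean"] * curve["n"]).sum() / curve["n"].sum()
    assert pooled == pytest.approx(vals.mean(), abs=1e-12)
    assert pooled == pytest.approx(curve["network_mean"].iloc[0], abs=1e-12)


def test_boosted_rich_links_detected(group_conn):
    cls = classify_links(group_conn, k=int(np.percentile(group_conn.degrees, 80)))
    rng = np.random.default_rng(7)
    vals = rng.normal(size=group_conn.n_edges)
    vals[cls.edge_class == "rich"] += 2.0
    curve = link_type_curve(group_conn, vals, ks=[cls.k])
    rich_row = curve[curve.link_class == "rich"].iloc[0]
    assert rich_row["p"] < 0.05 and rich_row["t"] > 0
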