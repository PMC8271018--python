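"""Connectome topology: group-connectome construction, hubs, rich club,
communicability, and link-type comparison curves.

Degree is always computed on the binary mask.  At a hub-defining threshold k,
nodes with degree > k are hubs; edges are classified as rich (hub–hub),
feeder (hub–nonhub), or peripheral (nonhub–nonhub).  The topological
rich-club coefficient phi(k) is the density of the subgraph of nodes with
degree > k; the weighted variant divides the subgraph's weight sum by the sum
of the equally many strongest weights anywhere in the network.  Both are
normalized against null ensembles (degree-preserving rewiring for the binary
coefficient, weight permutation on the fixed topology for the weighted one),
with permutation p-values using the add-one rule so p is never exactly 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy import stats

__all__ = [
    "Connectome",
    "LinkClassification",
    "RichClubCurve",
    "build_group_connectome",
    "classify_links",
    "rich_club_coefficient",
    "weighted_rich_club_coefficient",
    "degree_preserving_rewire",
    "normalized_rich_club_curve",
    "communicability",
    "link_type_curve",
    "welch_onesided",
]


@dataclass
class Connectome:
    """Symmetric weighted network with optional node metadata.

    ``weights`` is an n × n nonnegative symmetric matrix with zero diagonal;
    the binary ``mask`` is implied by weights > 0.
    """

    weights: np.ndarray
    ids: np.ndarray | None = None
    coords: np.ndarray | None = None
    modules: np.ndarray | None = None
    channel: str = "SC"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be exactly symmetric")
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        np.fill_diagonal(w, 0.0)
        self.weights = w
        if self.ids is None:
            self.ids = np.arange(w.shape[0])

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def mask(self) -> np.ndarray:
        return self.weights > 0

    @property
    def degrees(self) -> np.ndarray:
        return self.mask.sum(axis=1)

    @property
    def strengths(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    def edge_list(self) -> tuple[np.ndarray, np.ndarray]:
        """Upper-triangle endpoints (i < j) of the masked edges."""
        iu, ju = np.where(np.triu(self.mask, k=1))
        return iu, ju

    @property
    def n_edges(self) -> int:
        return int(self.mask.sum() // 2)


@dataclass
class LinkClassification:
    """Hub set and rich/feeder/peripheral partition of the masked edges."""

    k: int
    degrees: np.ndarray
    hub_mask: np.ndarray
    edge_i: np.ndarray
    edge_j: np.ndarray
    edge_class: np.ndarray  # elements of {"rich", "feeder", "peripheral"}

    @property
    def hubs(self) -> np.ndarray:
        return np.where(self.hub_mask)[0]


@dataclass
class RichClubCurve:
    """phi(k) with null statistics over a k grid (NaN marks undefined k)."""

    k: np.ndarray
    phi: np.ndarray
    null_mean: np.ndarray
    phi_norm: np.ndarray
    p: np.ndarray
    n_null: int
    mode: str = "binary"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.k, "phi": self.phi, "null_mean": self.null_mean,
             "phi_norm": self.phi_norm, "p": self.p}
        )


# ---------------------------------------------------------------------------
# group connectome
# ---------------------------------------------------------------------------


def build_group_connectome(
    subject_weights: np.ndarray,
    consistency_min: float = 0.30,
    density_target: float = 0.20,
    weight_stat: str = "median",
    ids: np.ndarray | None = None,
    coords: np.ndarray | None = None,
    modules: np.ndarray | None = None,
    channel: str = "SC",
) -> Connectome:
    """Consistency- and density-thresholded group-representative connectome.

    Retains edges that are (i) present in at least ``consistency_min`` of
    subjects and (ii) among the ``round(density_target * n*(n-1)/2)``
    strongest edges by the cross-subject ``weight_stat`` (median or mean,
    computed over the subjects in which the edge is present).  Ties at the
    density boundary are broken by higher consistency, then by lower node
    index pair, so the output is deterministic.
    """
    w = np.asarray(subject_weights, dtype=float)
    if w.ndim != 3 or w.shape[1] != w.shape[2]:
        raise ValueError("subject_weights must have shape (n_subjects, n, n)")
    for s in range(w.shape[0]):
        if not np.allclose(w[s], w[s].T):
            raise ValueError(f"subject {s}: matrix not symmetric")
    n = w.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    vals = w[:, iu, ju]  # (S, n_pairs)
    present = vals > 0
    consistency = present.mean(axis=0)

    stat_fn = {"median": np.median, "mean": np.mean}[weight_stat]
    group_w = np.zeros(iu.size)
    any_present = present.any(axis=0)
    for p_i in np.where(any_present)[0]:
        group_w[p_i] = stat_fn(vals[present[:, p_i], p_i])

    n_target = int(round(density_target * n * (n - 1) / 2))
    candidate = (consistency >= consistency_min) & any_present
    # order: weight desc, consistency desc, then (i, j) asc for determinism
    order = np.lexsort((ju, iu, -consistency, -group_w))
    order = order[candidate[order]]
    keep = order[:n_target]
    if keep.size < n_target:
        warnings.warn(
            f"density target {density_target:.3f} unreachable after consistency "
            f"filter: retained {keep.size} of {n_target} edges "
            f"(actual density {keep.size / (n * (n - 1) / 2):.4f})",
            stacklevel=2,
        )
    out = np.zeros((n, n))
    out[iu[keep], ju[keep]] = group_w[keep]
    out += out.T
    return Connectome(out, ids=ids, coords=coords, modules=modules, channel=channel)


# ---------------------------------------------------------------------------
# hubs and link classes
# ---------------------------------------------------------------------------


def classify_links(conn: Connectome, k: int) -> LinkClassification:
    """Partition edges into rich/feeder/peripheral at hub threshold k."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    deg = conn.degrees
    hub = deg > k
    iu, ju = conn.edge_list()
    n_hub_ends = hub[iu].astype(int) + hub[ju].astype(int)
    edge_class = np.array(["peripheral", "feeder", "rich"], dtype=object)[n_hub_ends]
    return LinkClassification(
        k=k, degrees=deg, hub_mask=hub, edge_i=iu, edge_j=ju, edge_class=edge_class
    )


# ---------------------------------------------------------------------------
# rich-club coefficients
# ---------------------------------------------------------------------------


def rich_club_coefficient(conn: Connectome | np.ndarray, k: int) -> float:
    """Topological rich-club coefficient phi(k) = 2 E_>k / (N_>k (N_>k - 1)).

    Returns NaN when fewer than two nodes exceed degree k (undefined).
    """
    mask = conn.mask if isinstance(conn, Connectome) else np.asarray(conn) > 0
    deg = mask.sum(axis=1)
    rich = deg > k
    n_rich = int(rich.sum())
    if n_rich < 2:
        return float("nan")
    e_rich = int(mask[np.ix_(rich, rich)].sum() // 2)
    return 2.0 * e_rich / (n_rich * (n_rich - 1))


def weighted_rich_club_coefficient(conn: Connectome, k: int) -> float:
    """Weighted rich-club coefficient phi_w(k).

    Ratio of the subgraph weight sum W_>k to the sum of the E_>k largest
    edge weights anywhere in the network.  NaN when the subgraph has no
    nodes or edges.
    """
    mask = conn.mask
    deg = mask.sum(axis=1)
    rich = deg > k
    if rich.sum() < 2:
        return float("nan")
    sub = np.triu(mask[np.ix_(rich, rich)], k=1)
    e_rich = int(sub.sum())
    if e_rich == 0:
        return float("nan")
    w_rich = float(conn.weights[np.ix_(rich, rich)][sub].sum())
    iu, ju = conn.edge_list()
    all_w = np.sort(conn.weights[iu, ju])[::-1]
    return w_rich / float(all_w[:e_rich].sum())


# ---------------------------------------------------------------------------
# null models
# ---------------------------------------------------------------------------


def degree_preserving_rewire(
    conn: Connectome | np.ndarray,
    swaps_per_edge: int = 50,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Maslov–Sneppen double-edge-swap null on the binary mask.

    Attempts ``swaps_per_edge * n_edges`` swaps of uniformly chosen edge
    pairs, rejecting any swap that would create a self-loop or duplicate
    edge; the degree sequence is preserved exactly.  Returns the rewired
    binary adjacency matrix.
    """
    mask = conn.mask if isinstance(conn, Connectome) else np.asarray(conn) > 0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    adj = mask.copy()
    iu, ju = np.where(np.triu(adj, k=1))
    a = iu.copy()
    b = ju.copy()
    m = a.size
    if m < 2:
        return adj
    n_attempts = swaps_per_edge * m
    picks = rng.integers(0, m, size=(n_attempts, 2))
    flips = rng.random(n_attempts) < 0.5
    for t in range(n_attempts):
        e1, e2 = picks[t]
        if e1 == e2:
            continue
        x1, y1 = a[e1], b[e1]
        x2, y2 = a[e2], b[e2]
        if flips[t]:
            x2, y2 = y2, x2
        # proposed: (x1, y2) and (x2, y1)
        if x1 == y2 or x2 == y1:
            continue
        if adj[x1, y2] or adj[x2, y1]:
            continue
        adj[x1, y1] = adj[y1, x1] = False
        adj[x2, y2] = adj[y2, x2] = False
        adj[x1, y2] = adj[y2, x1] = True
        adj[x2, y1] = adj[y1, x2] = True
        a[e1], b[e1] = x1, y2
        a[e2], b[e2] = x2, y1
    return adj


def _default_k_grid(deg: np.ndarray) -> np.ndarray:
    return np.arange(int(deg.min()), int(deg.max()))


def _phi_curve_binary(adj: np.ndarray, ks: np.ndarray) -> np.ndarray:
    """phi(k) for all k at once via the min-endpoint-degree histogram."""
    deg = adj.sum(axis=1)
    iu, ju = np.where(np.triu(adj, k=1))
    min_deg = np.minimum(deg[iu], deg[ju])
    deg_sorted = np.sort(deg)
    phi = np.full(ks.size, np.nan)
    for k_i, k in enumerate(ks):
        n_rich = deg_sorted.size - np.searchsorted(deg_sorted, k, side="right")
        if n_rich < 2:
            continue
        e_rich = int((min_deg > k).sum())
        phi[k_i] = 2.0 * e_rich / (n_rich * (n_rich - 1))
    return phi


def normalized_rich_club_curve(
    conn: Connectome,
    ks: np.ndarray | None = None,
    n_null: int = 1000,
    mode: str = "binary",
    seed: int = 0,
    swaps_per_edge: int = 50,
) -> RichClubCurve:
    """Normalized rich-club curve Phi_norm(k) with permutation p-values.

    ``binary`` mode compares phi(k) against degree-preserving rewired nulls;
    ``weighted`` mode compares phi_w(k) against nulls that permute the edge
    weights while keeping the binary topology fixed.  p(k) uses the add-one
    rule ``(1 + #{phi_rand >= phi}) / (1 + n_null)``.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    if mode not in ("binary", "weighted"):
        raise ValueError("mode must be 'binary' or 'weighted'")
    deg = conn.degrees
    if ks is None:
        ks = _default_k_grid(deg)
    ks = np.asarray(ks, dtype=int)
    rng = np.random.default_rng(seed)

    if mode == "binary":
        phi = _phi_curve_binary(conn.mask, ks)
        null = np.full((n_null, ks.size), np.nan)
        for r in range(n_null):
            adj = degree_preserving_rewire(conn, swaps_per_edge, rng)
            null[r] = _phi_curve_binary(adj, ks)
    else:
        iu, ju = conn.edge_list()
        w = conn.weights[iu, ju]
        min_deg = np.minimum(deg[iu], deg[ju])
        w_desc_cumsum = np.cumsum(np.sort(w)[::-1])
        deg_sorted = np.sort(deg)

        def phi_w_from(weights: np.ndarray) -> np.ndarray:
            out = np.full(ks.size, np.nan)
            for k_i, k in enumerate(ks):
                n_rich = deg_sorted.size - np.searchsorted(deg_sorted, k, "right")
                if n_rich < 2:
                    continue
                sel = min_deg > k
                e_rich = int(sel.sum())
                if e_rich == 0:
                    continue
                out[k_i] = weights[sel].sum() / w_desc_cumsum[e_rich - 1]
            return out

        phi = phi_w_from(w)
        null = np.full((n_null, ks.size), np.nan)
        for r in range(n_null):
            null[r] = phi_w_from(rng.permutation(w))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        null_mean = np.nanmean(null, axis=0)
        phi_norm = phi / null_mean
        n_ge = np.nansum(null >= phi[None, :], axis=0)
    p = (1.0 + n_ge) / (1.0 + n_null)
    p[~np.isfinite(phi)] = np.nan
    return RichClubCurve(
        k=ks, phi=phi, null_mean=null_mean, phi_norm=phi_norm, p=p,
        n_null=n_null, mode=mode,
    )


# ---------------------------------------------------------------------------
# communicability
# ---------------------------------------------------------------------------


def communicability(conn: Connectome, mode: str = "binary") -> np.ndarray:
    """Network communicability: matrix exponential of the (normalized) graph.

    Binary mode returns ``expm(A)`` for the binary mask A.  Weighted mode
    returns ``expm(S^{-1/2} W S^{-1/2})`` with S the diagonal matrix of node
    strengths; isolated nodes contribute only their identity term (their
    rows/columns are left at e^0) and trigger a warning.
    """
    if mode == "binary":
        return expm(conn.mask.astype(float))
    if mode != "weighted":
        raise ValueError("mode must be 'binary' or 'weighted'")
    s = conn.strengths.copy()
    isolated = s <= 0
    if isolated.any():
        warnings.warn(
            f"{int(isolated.sum())} isolated node(s) in weighted communicability; "
            "their rows/columns carry only the identity contribution",
            stacklevel=2,
        )
        s[isolated] = 1.0
    d = 1.0 / np.sqrt(s)
    return expm(conn.weights * np.outer(d, d))


# ---------------------------------------------------------------------------
# link-type comparison curves
# ---------------------------------------------------------------------------


def welch_onesided(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """One-sided Welch t-test (alternative: mean(a) > mean(b))."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        return float("nan"), float("nan")
    tol = 1e-24 * max(1.0, float(a.mean()) ** 2, float(b.mean()) ** 2)
    if a.var(ddof=1) <= tol and b.var(ddof=1) <= tol:
        # degenerate: identical constants carry no evidence either way
        if math.isclose(a.mean(), b.mean(), rel_tol=1e-12, abs_tol=1e-12):
            return 0.0, 0.5
        return (math.inf, 0.0) if a.mean() > b.mean() else (-math.inf, 1.0)
    res = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def link_type_curve(
    conn: Connectome,
    edge_values: np.ndarray,
    ks: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean ± SEM of an edge metric per link class across hub thresholds.

    ``edge_values`` must align with ``conn.edge_list()`` (NaN = missing).
    For each k and class the one-sided Welch t-test compares the class
    values against all remaining edges (alternative: class mean greater).
    Returns a tidy frame with columns
    ``k, link_class, n, mean, sem, t, p, network_mean``; classes with fewer
    than two finite values get NaN statistics.
    """
    iu, ju = conn.edge_list()
    vals = np.asarray(edge_values, dtype=float)
    if vals.shape[0] != iu.size:
        raise ValueError("edge_values must align with the connectome edge list")
    if ks is None:
        ks = _default_k_grid(conn.degrees)
    deg = conn.degrees
    finite = np.isfinite(vals)
    network_mean = float(vals[finite].mean()) if finite.any() else float("nan")

    rows = []
    for k in np.asarray(ks, dtype=int):
        hub = deg > k
        n_hub_ends = hub[iu].astype(int) + hub[ju].astype(int)
        for cls, code in (("peripheral", 0), ("feeder", 1), ("rich", 2)):
            sel = (n_hub_ends == code) & finite
            rest = (n_hub_ends != code) & finite
            v = vals[sel]
            if v.size == 0:
                continue  # class means only over non-empty classes
            mean = float(v.mean())
            sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else np.nan
            t, p = welch_onesided(v, vals[rest])
            rows.append(
                dict(k=int(k), link_class=cls, n=int(v.size), mean=mean,
                     sem=sem, t=t, p=p, network_mean=network_mean)
            )
    return pd.DataFrame(rows)
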