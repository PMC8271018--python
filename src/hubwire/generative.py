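"""Probabilistic growth models of connectome wiring.

Networks grow one edge at a time from an empty graph.  At each iteration
every absent edge (i, j) receives a score

    theta_ij = d_ij^eta * (t_ij + epsilon)^gamma,

where d is Euclidean distance (wiring cost, exponent eta <= 0 so cost is
penalized), t a topological property of the current graph recomputed every
iteration (one of 13 rules; exponent gamma may take either sign), and
epsilon a small stabilizer that prevents zero-probability lockout at the
empty start.  The next edge is sampled with probability theta_ij / sum of
theta over absent edges.

Genetic variants replace or extend the factors with g_ij^lambda, where g is
the residual correlated gene expression min–max rescaled to [epsilon, 1]
over candidate edges: S = d^eta, G = g^lambda, SG = d^eta * g^lambda,
TG = (t + eps)^gamma * g^lambda and ST = d^eta * (t + eps)^gamma, both with
t the average-degree rule.

Model fit is scored by the maximum Kolmogorov–Smirnov distance (the
"energy") between model and target distributions of degree, clustering,
betweenness, and edge length, plus the Spearman correlation of the degree
*sequences*, which measures whether hubs sit on the same nodes.  Parameters
are optimized by several rounds of space-filling sampling in which later
rounds draw preferentially from the nearest-sampled-point (Voronoi-style)
cells of the best evaluations so far.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats
from scipy.spatial import cKDTree

__all__ = [
    "TOPOLOGICAL_RULES",
    "GENETIC_RULES",
    "GenerativeSpec",
    "EnergyReport",
    "OptimizationTrace",
    "wiring_scores",
    "grow_network",
    "model_energy",
    "optimize_parameters",
]

TOPOLOGICAL_RULES = (
    "sptl",
    "clu-avg", "clu-diff", "clu-max", "clu-min", "clu-prod",
    "deg-avg", "deg-diff", "deg-max", "deg-min", "deg-prod",
    "matching", "neighbors",
)
GENETIC_RULES = ("S", "G", "SG", "TG", "ST")

# exponent bounds: wiring cost is always penalized (eta <= 0); the
# topological exponent may take either sign; lambda is nonnegative
ETA_BOUNDS = (-15.0, 0.0)
GAMMA_BOUNDS = (-4.0, 4.0)
LAMBDA_BOUNDS = (0.0, 200.0)

_FREE_PARAMS = {
    "sptl": ("eta",),
    "S": ("eta",),
    "G": ("lam",),
    "SG": ("eta", "lam"),
    "TG": ("gamma", "lam"),
    "ST": ("eta", "gamma"),
}
_STATIC_RULES = {"sptl", "S", "G", "SG"}  # theta does not depend on the graph


@dataclass(frozen=True)
class GenerativeSpec:
    """Wiring rule with exponents, stabilizer, target edge count, and seed."""

    rule: str
    eta: float = -2.0
    gamma: float = 0.0
    lam: float = 0.0
    epsilon: float = 1e-5
    n_edges: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rule not in TOPOLOGICAL_RULES + GENETIC_RULES:
            raise ValueError(f"unknown rule {self.rule!r}")
        if not ETA_BOUNDS[0] <= self.eta <= ETA_BOUNDS[1]:
            raise ValueError(f"eta must lie in {ETA_BOUNDS}")
        if not GAMMA_BOUNDS[0] <= self.gamma <= GAMMA_BOUNDS[1]:
            raise ValueError(f"gamma must lie in {GAMMA_BOUNDS}")
        if not LAMBDA_BOUNDS[0] <= self.lam <= LAMBDA_BOUNDS[1]:
            raise ValueError(f"lambda must lie in {LAMBDA_BOUNDS}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    @property
    def free_params(self) -> tuple[str, ...]:
        return _FREE_PARAMS.get(self.rule, ("eta", "gamma"))


@dataclass
class EnergyReport:
    """KS distances of the four fitted distributions plus the degree-sequence
    Spearman correlation; energy is the maximum KS."""

    ks_degree: float
    ks_clustering: float
    ks_betweenness: float
    ks_length: float
    degree_rho: float

    @property
    def energy(self) -> float:
        return max(self.ks_degree, self.ks_clustering,
                   self.ks_betweenness, self.ks_length)


@dataclass
class OptimizationTrace:
    """Evaluations per round, the cumulative per-round best, and the top-100."""

    evaluations: pd.DataFrame
    per_round_best: np.ndarray
    top: pd.DataFrame
    objective: str


# ---------------------------------------------------------------------------
# topological terms
# ---------------------------------------------------------------------------


def _clustering_coefficients(adj: np.ndarray) -> np.ndarray:
    a = adj.astype(float)
    deg = a.sum(axis=1)
    tri = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = deg * (deg - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    return c


def _topology_term(adj: np.ndarray, rule: str) -> np.ndarray:
    """Table of t_ij values for the current binary adjacency."""
    n = adj.shape[0]
    a = adj.astype(float)
    if rule == "sptl":
        return np.ones((n, n))
    if rule.startswith("clu") or rule.startswith("deg"):
        v = _clustering_coefficients(adj) if rule.startswith("clu") else a.sum(axis=1)
        kind = rule.split("-")[1]
        if kind == "avg":
            return (v[:, None] + v[None, :]) / 2.0
        if kind == "diff":
            return np.abs(v[:, None] - v[None, :])
        if kind == "max":
            return np.maximum(v[:, None], v[None, :])
        if kind == "min":
            return np.minimum(v[:, None], v[None, :])
        if kind == "prod":
            return v[:, None] * v[None, :]
    if rule == "neighbors":
        return a @ a
    if rule == "matching":
        cn = a @ a
        deg = a.sum(axis=1)
        union = deg[:, None] + deg[None, :] - 2.0 * a - cn
        with np.errstate(divide="ignore", invalid="ignore"):
            m = np.where(union > 0, cn / union, 0.0)
        np.fill_diagonal(m, 0.0)
        return m
    raise ValueError(f"unknown topological rule {rule!r}")


def _rescale_cge(cge_resid: np.ndarray, epsilon: float) -> np.ndarray:
    """Min–max rescale residual CGE to [epsilon, 1] over candidate edges."""
    g = np.asarray(cge_resid, dtype=float).copy()
    iu, ju = np.triu_indices(g.shape[0], k=1)
    vals = g[iu, ju]
    finite = np.isfinite(vals)
    lo, hi = vals[finite].min(), vals[finite].max()
    if hi <= lo:
        scaled = np.full_like(vals, 1.0)
    else:
        scaled = epsilon + (1.0 - epsilon) * (vals - lo) / (hi - lo)
    scaled = np.where(finite, scaled, epsilon)
    out = np.zeros_like(g)
    out[iu, ju] = scaled
    out += out.T
    return out


def wiring_scores(
    adj: np.ndarray,
    distances: np.ndarray,
    spec: GenerativeSpec,
    cge_resid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Edge scores theta and connection probabilities over absent edges.

    Returns ``(theta, P)`` as symmetric matrices; P is normalized so that it
    sums to 1 over absent upper-triangle pairs (present edges and the
    diagonal have P = 0).  An all-zero score table falls back to uniform
    probabilities with a warning.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    if (d[iu, ju] <= 0).any():
        raise ValueError("distances must be positive off the diagonal")
    adj = np.asarray(adj) > 0
    eps = spec.epsilon

    rule = spec.rule
    if rule in GENETIC_RULES:
        if rule in ("G", "SG", "TG") and cge_resid is None:
            raise ValueError(f"rule {rule!r} requires residual CGE values")
        ghat = _rescale_cge(cge_resid, eps) if cge_resid is not None else None
        theta = np.ones((n, n))
        if rule in ("S", "SG", "ST"):
            with np.errstate(divide="ignore"):
                dpow = np.where(d > 0, d, 1.0) ** spec.eta
            theta = theta * dpow
        if rule in ("G", "SG", "TG"):
            theta = theta * ghat**spec.lam
        if rule in ("TG", "ST"):
            t = _topology_term(adj, "deg-avg")
            theta = theta * (t + eps) ** spec.gamma
    else:
        t = _topology_term(adj, rule)
        with np.errstate(divide="ignore"):
            dpow = np.where(d > 0, d, 1.0) ** spec.eta
        theta = dpow * (t + eps) ** spec.gamma
    np.fill_diagonal(theta, 0.0)

    absent = ~adj
    np.fill_diagonal(absent, False)
    scores = np.where(absent, theta, 0.0)
    total = scores[iu, ju].sum()
    if not np.isfinite(total) or total <= 0:
        warnings.warn("all-zero wiring scores: falling back to uniform "
                      "probabilities over absent edges", stacklevel=2)
        scores = absent.astype(float)
        total = scores[iu, ju].sum()
    p = scores / total
    return theta, p


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------


def grow_network(
    spec: GenerativeSpec,
    distances: np.ndarray,
    cge_resid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Grow a binary network to exactly ``spec.n_edges`` edges.

    Starts from the empty graph and adds one edge per iteration, sampled
    according to the current wiring scores (topological terms recomputed
    each iteration).  Returns ``(adjacency, order)`` where ``order`` is the
    (n_edges, 2) array of edges in order of addition.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    max_edges = n * (n - 1) // 2
    if not 0 < spec.n_edges <= max_edges:
        raise ValueError(f"n_edges must lie in [1, {max_edges}]")
    rng = np.random.default_rng(spec.seed)
    iu, ju = np.triu_indices(n, k=1)

    adj = np.zeros((n, n), dtype=bool)
    absent = np.ones(iu.size, dtype=bool)
    order = np.empty((spec.n_edges, 2), dtype=int)

    static = spec.rule in _STATIC_RULES
    theta_pairs = None
    for step in range(spec.n_edges):
        if theta_pairs is None or not static:
            theta, _ = wiring_scores(adj, d, spec, cge_resid)
            theta_pairs = theta[iu, ju]
        w = np.where(absent, theta_pairs, 0.0)
        total = w.sum()
        if not np.isfinite(total) or total <= 0:
            w = absent.astype(float)
            total = w.sum()
        cum = np.cumsum(w)
        pick = int(np.searchsorted(cum, rng.random() * total, side="right"))
        pick = min(pick, iu.size - 1)
        i, j = iu[pick], ju[pick]
        adj[i, j] = adj[j, i] = True
        absent[pick] = False
        order[step] = (i, j)
    return adj, order


# ---------------------------------------------------------------------------
# energy
# ---------------------------------------------------------------------------


def _ks(x: np.ndarray, y: np.ndarray) -> float:
    return float(stats.ks_2samp(x, y, method="asymp").statistic)


def model_energy(
    model_adj: np.ndarray,
    target_adj: np.ndarray,
    distances: np.ndarray,
) -> EnergyReport:
    """KS-energy of a model network against a target on the same node set.

    KS distances are computed for the node-level distributions of degree,
    clustering, and betweenness and the edge-level distribution of
    connection distance; the degree-sequence Spearman rho (average-rank
    ties) measures spatial topography rather than distribution shape.
    """
    a = np.asarray(model_adj) > 0
    b = np.asarray(target_adj) > 0
    if a.shape != b.shape:
        raise ValueError("model and target must share a node set")
    d = np.asarray(distances, dtype=float)

    deg_a, deg_b = a.sum(axis=1), b.sum(axis=1)
    clu_a = _clustering_coefficients(a)
    clu_b = _clustering_coefficients(b)
    btw_a = np.array(list(nx.betweenness_centrality(nx.from_numpy_array(a)).values()))
    btw_b = np.array(list(nx.betweenness_centrality(nx.from_numpy_array(b)).values()))
    len_a = d[np.triu(a, k=1)]
    len_b = d[np.triu(b, k=1)]

    rho = stats.spearmanr(deg_a, deg_b).statistic if deg_a.std() > 0 and deg_b.std() > 0 else np.nan
    return EnergyReport(
        ks_degree=_ks(deg_a, deg_b),
        ks_clustering=_ks(clu_a, clu_b),
        ks_betweenness=_ks(btw_a, btw_b),
        ks_length=_ks(len_a, len_b) if len_a.size and len_b.size else 1.0,
        degree_rho=float(rho),
    )


# ---------------------------------------------------------------------------
# parameter optimization
# ---------------------------------------------------------------------------

_BOUNDS = {"eta": ETA_BOUNDS, "gamma": GAMMA_BOUNDS, "lam": LAMBDA_BOUNDS}


def optimize_parameters(
    spec_template: GenerativeSpec,
    target_adj: np.ndarray,
    distances: np.ndarray,
    cge_resid: np.ndarray | None = None,
    n_per_round: int = 2000,
    n_rounds: int = 5,
    objective: str = "energy",
    seed: int = 0,
    top_n: int = 100,
    candidate_factor: int = 5,
) -> tuple[OptimizationTrace, GenerativeSpec]:
    """Voronoi-style preferential sampling of the exponent space.

    Round 1 samples the free parameters of the rule uniformly within their
    bounds; each later round draws candidates uniformly, assigns them to the
    nearest previously evaluated point (a Voronoi cell), and keeps them with
    probability proportional to the inverse objective rank of their cell, so
    sampling concentrates around the best cells.  ``objective`` is either
    ``"energy"`` (minimized) or ``"degree_rho"`` (maximized).  Returns the
    trace (all evaluations, cumulative per-round best, sorted top-``top_n``)
    and the best spec found.
    """
    if objective not in ("energy", "degree_rho"):
        raise ValueError("objective must be 'energy' or 'degree_rho'")
    params = spec_template.free_params
    bounds = np.array([_BOUNDS[p] for p in params])
    if np.any(bounds[:, 1] <= bounds[:, 0]):
        raise ValueError("degenerate parameter bounds")
    widths = bounds[:, 1] - bounds[:, 0]
    n_edges = int(np.triu(np.asarray(target_adj) > 0, k=1).sum())
    template = replace(spec_template, n_edges=n_edges)

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    sign = 1.0 if objective == "energy" else -1.0  # internally minimize

    pts: list[np.ndarray] = []
    objs: list[float] = []
    rows: list[dict] = []
    per_round_best = []

    def evaluate(x: np.ndarray, round_idx: int) -> None:
        kw = dict(zip(params, (float(v) for v in x)))
        child = int(rng.integers(2**31))
        spec = replace(template, seed=child, **kw)
        adj, _ = grow_network(spec, distances, cge_resid)
        rep = model_energy(adj, target_adj, distances)
        val = rep.energy if objective == "energy" else rep.degree_rho
        pts.append(x)
        objs.append(val)
        rows.append({"round": round_idx, **kw, "energy": rep.energy,
                     "degree_rho": rep.degree_rho, "objective": val})

    for rnd in range(n_rounds):
        if rnd == 0:
            xs = bounds[:, 0] + rng.random((n_per_round, len(params))) * widths
        else:
            n_cand = candidate_factor * n_per_round
            cand = bounds[:, 0] + rng.random((n_cand, len(params))) * widths
            tree = cKDTree(np.array(pts) / widths)
            owner = tree.query(cand / widths)[1]
            ranks = stats.rankdata(sign * np.array(objs), method="ordinal")
            wts = 1.0 / ranks[owner]
            wts /= wts.sum()
            idx = rng.choice(n_cand, size=n_per_round, replace=True, p=wts)
            xs = cand[idx]
        for x in xs:
            evaluate(x, rnd)
        best_so_far = min(sign * v for v in objs) * sign
        per_round_best.append(best_so_far)

    evaluations = pd.DataFrame(rows)
    order = np.argsort(sign * np.array(objs), kind="stable")
    top = evaluations.iloc[order[:top_n]].reset_index(drop=True)
    best_row = evaluations.iloc[order[0]]
    best_spec = replace(
        template,
        seed=spec_template.seed,
        **{p: float(best_row[p]) for p in params},
    )
    trace = OptimizationTrace(
        evaluations=evaluations,
        per_round_best=np.array(per_round_best),
        top=top,
        objective=objective,
    )
    return trace, best_spec
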