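"""Synthetic data generators for every pipeline stage.

Each generator emulates the *statistical* structure the downstream analyses
assume — geometric connectomes with planted, spatially distributed hubs;
twin/sibling phenotypes with prescribed A/C/T/E variance fractions;
region × gene expression whose correlated gene expression (CGE) decays
exponentially with distance plus an extra hub–hub coupling; cell-class
marker tables; and depth-wise cortical intensity profiles with block
cytoarchitectonic similarity — without attempting anatomical realism.

All generators are deterministic under a fixed seed: a single
``numpy.random.default_rng(seed)`` stream drives each call, and the seed is
recorded on the returned objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hubwire.heritability import FamilyCohort

__all__ = [
    "SyntheticCohortSpec",
    "TwinSimSpec",
    "ExpressionSimSpec",
    "CohortConnectomes",
    "simulate_cohort_connectomes",
    "simulate_twin_cohort",
    "simulate_expression",
    "simulate_cell_type_profiles",
    "simulate_intensity_profiles",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of the geometric hub-planted connectome cohort.

    Edge presence probability decays exponentially with Euclidean distance
    (scale ``decay_scale`` mm, amplitude ``base_prob`` at zero distance) and
    is raised by ``richclub_boost`` between the planted hubs, which occupy a
    ``hub_fraction`` of nodes chosen by farthest-point sampling so that they
    are spatially distributed.
    """

    n_nodes: int = 100
    n_subjects: int = 20
    hub_fraction: float = 0.1
    richclub_boost: float = 0.5
    decay_scale: float = 60.0
    weight_noise_sd: float = 0.2
    seed: int = 0
    base_prob: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 < self.hub_fraction < 1.0:
            raise ValueError("hub_fraction must lie in (0, 1)")
        if self.n_nodes < 10:
            raise ValueError("n_nodes must be >= 10")
        if self.decay_scale <= 0:
            raise ValueError("decay_scale must be positive")
        if self.richclub_boost < 0:
            raise ValueError("richclub_boost must be nonnegative")
        if self.weight_noise_sd < 0:
            raise ValueError("weight_noise_sd must be nonnegative")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


@dataclass(frozen=True)
class TwinSimSpec:
    """Cohort sizes and per-edge variance fractions of the twin simulator.

    Default sizes mirror a typical large twin imaging cohort: 117 MZ pairs
    with 69 non-twin siblings and 60 DZ pairs with 48 siblings.  The variance
    fractions ``a2`` (additive genetic), ``c2`` (twin non-specific common
    environment), ``t2`` (twin-specific common environment), and ``e2``
    (unique environment) must be nonnegative and sum to 1 per edge; scalars
    or per-edge arrays are accepted.
    """

    n_mz_pairs: int = 117
    n_dz_pairs: int = 60
    n_mz_sibs: int = 69
    n_dz_sibs: int = 48
    a2: float | np.ndarray = 0.5
    c2: float | np.ndarray = 0.1
    t2: float | np.ndarray = 0.0
    e2: float | np.ndarray = 0.4
    beta_age: float = 0.0
    beta_sex: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("a2", "c2", "t2", "e2"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"{name} must be nonnegative")
        total = (
            np.asarray(self.a2)
            + np.asarray(self.c2)
            + np.asarray(self.t2)
            + np.asarray(self.e2)
        )
        if not np.allclose(total, 1.0):
            raise ValueError("variance fractions must sum to 1 per edge")
        if self.n_mz_sibs > self.n_mz_pairs or self.n_dz_sibs > self.n_dz_pairs:
            raise ValueError("at most one sibling per twin pair")


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Parameters of the latent-covariance expression generator.

    The target region × region CGE is ``A * exp(-d / n_scale) + B`` plus
    ``hub_coupling_boost`` on hub–hub pairs; gene profiles are drawn from a
    region-level latent Gaussian with that correlation structure, which makes
    the implied CGE exact in expectation.  When the boost is positive it is
    carried by a planted ``hub_coupled_fraction`` of genes.
    """

    n_genes: int = 500
    amplitude: float = 0.64
    offset: float = -0.19
    n_scale: float = 90.4
    hub_coupling_boost: float = 0.0
    hub_coupled_fraction: float = 0.2
    noise_sd: float = 0.0
    n_cell_classes: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_scale <= 0:
            raise ValueError("n_scale must be positive")
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if self.noise_sd < 0 or self.hub_coupling_boost < 0:
            raise ValueError("noise_sd and hub_coupling_boost must be nonnegative")


# ---------------------------------------------------------------------------
# connectome cohort
# ---------------------------------------------------------------------------


@dataclass
class CohortConnectomes:
    """Synthetic subject cohort: node table plus two weight channels."""

    nodes: pd.DataFrame
    sc: np.ndarray  # (n_subjects, n, n) streamline-count-like weights
    fa: np.ndarray  # (n_subjects, n, n) FA-like weights in (0, 1)
    hubs: np.ndarray  # planted hub node indices
    spec: SyntheticCohortSpec = field(repr=False)


def _farthest_point_sample(coords: np.ndarray, m: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy max-min selection of m spatially spread points."""
    n = coords.shape[0]
    chosen = [int(rng.integers(n))]
    d = np.linalg.norm(coords - coords[chosen[0]], axis=1)
    for _ in range(m - 1):
        nxt = int(np.argmax(d))
        chosen.append(nxt)
        d = np.minimum(d, np.linalg.norm(coords - coords[nxt], axis=1))
    return np.sort(np.array(chosen))


def simulate_cohort_connectomes(spec: SyntheticCohortSpec) -> CohortConnectomes:
    """Generate a subject cohort of geometric connectomes with planted hubs.

    Returns a :class:`CohortConnectomes` whose per-subject matrices are
    symmetric, zero-diagonal, and nonnegative.  Edge presence probability is
    ``base_prob * exp(-d/decay_scale)``, raised additively by
    ``richclub_boost`` between planted hubs.  Two weight channels are drawn
    on present edges: a heavy-tailed streamline-count-like channel (``sc``)
    and a bounded (0, 1) FA-like channel (``fa``).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes

    # brain-like bounding box (mm); x sign encodes hemisphere
    coords = rng.uniform(low=[-70, -50, -40], high=[70, 50, 40], size=(n, 3))
    hemisphere = np.where(coords[:, 0] < 0, "L", "R")

    # spatially contiguous module labels from random centroids
    n_modules = min(6, max(2, n // 15))
    centroids = coords[rng.choice(n, size=n_modules, replace=False)]
    module = np.argmin(
        np.linalg.norm(coords[:, None, :] - centroids[None, :, :], axis=2), axis=1
    )

    n_hubs = max(1, int(round(spec.hub_fraction * n)))
    hubs = _farthest_point_sample(coords, n_hubs, rng)
    is_hub = np.zeros(n, dtype=bool)
    is_hub[hubs] = True

    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    iu, ju = np.triu_indices(n, k=1)
    # hub-end factor: 1 for rich (hub–hub), 0.25 for feeder, 0 for peripheral —
    # hubs are moderately high-degree overall but *strongly* interconnected,
    # so the planted club exceeds its degree-preserving null expectation
    n_hub_ends = is_hub[iu].astype(int) + is_hub[ju].astype(int)
    hub_factor = np.choose(n_hub_ends, [0.0, 0.25, 1.0])
    p_edge = np.clip(
        spec.base_prob * np.exp(-d[iu, ju] / spec.decay_scale)
        + spec.richclub_boost * hub_factor,
        0.0,
        1.0,
    )
    n_pairs = iu.size

    sc = np.zeros((spec.n_subjects, n, n))
    fa = np.zeros((spec.n_subjects, n, n))
    # SC: lognormal, mean decreasing with distance; FA: logistic-Gaussian
    log_sc_mu = 3.0 - d[iu, ju] / (2.0 * spec.decay_scale)
    fa_mu = -0.2 + 0.8 * np.exp(-d[iu, ju] / spec.decay_scale)
    # rich/feeder links are strong as well as consistently present
    log_sc_mu = log_sc_mu + 1.5 * spec.richclub_boost * hub_factor
    fa_mu = fa_mu + spec.richclub_boost * hub_factor
    for s in range(spec.n_subjects):
        present = rng.random(n_pairs) < p_edge
        w_sc = np.exp(rng.normal(log_sc_mu, 0.6 + spec.weight_noise_sd))
        w_fa = 1.0 / (1.0 + np.exp(-rng.normal(fa_mu, 0.3 + spec.weight_noise_sd)))
        sc[s][iu[present], ju[present]] = w_sc[present]
        fa[s][iu[present], ju[present]] = w_fa[present]
        sc[s] += sc[s].T
        fa[s] += fa[s].T

    nodes = pd.DataFrame(
        {
            "id": np.arange(n),
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "module": module,
            "hemisphere": hemisphere,
            "is_hub": is_hub,
        }
    )
    nodes.attrs["seed"] = spec.seed
    return CohortConnectomes(nodes=nodes, sc=sc, fa=fa, hubs=hubs, spec=spec)


# ---------------------------------------------------------------------------
# twin cohort
# ---------------------------------------------------------------------------


def simulate_twin_cohort(spec: TwinSimSpec, n_edges: int) -> FamilyCohort:
    """Simulate twin + sibling families with prescribed variance fractions.

    Each phenotype is the sum of additive-genetic, common-environment,
    twin-specific-environment, and unique-environment draws with the classic
    sharing structure: MZ co-twins share the genetic factor fully; DZ
    co-twins and every twin–sibling pair share it with coefficient 0.5; C is
    shared by all family members; T only by the twins.  Linear age and sex
    effects are added to the mean.  Implied covariances (per unit variance):

    * MZ twins: ``a2 + c2 + t2``
    * DZ twins: ``0.5*a2 + c2 + t2``
    * any twin with the sibling: ``0.5*a2 + c2``
    """
    rng = np.random.default_rng(spec.seed)

    a = np.sqrt(np.broadcast_to(np.asarray(spec.a2, dtype=float), (n_edges,)))
    c = np.sqrt(np.broadcast_to(np.asarray(spec.c2, dtype=float), (n_edges,)))
    t = np.sqrt(np.broadcast_to(np.asarray(spec.t2, dtype=float), (n_edges,)))
    e = np.sqrt(np.broadcast_to(np.asarray(spec.e2, dtype=float), (n_edges,)))

    rows = []
    phen = []
    subj = 0

    def add_member(fam, zyg, role, age, sex, geno, shared_c, shared_t):
        nonlocal subj
        rows.append(
            {
                "subject_id": f"S{subj:04d}",
                "family_id": fam,
                "zygosity": zyg,
                "role": role,
                "age": age,
                "sex": sex,
            }
        )
        y = (
            a * geno
            + c * shared_c
            + t * shared_t
            + e * rng.standard_normal(n_edges)
            + spec.beta_age * age
            + spec.beta_sex * sex
        )
        phen.append(y)
        subj += 1

    fam_idx = 0
    for zyg, n_pairs, n_sibs in (
        ("MZ", spec.n_mz_pairs, spec.n_mz_sibs),
        ("DZ", spec.n_dz_pairs, spec.n_dz_sibs),
    ):
        has_sib = np.zeros(n_pairs, dtype=bool)
        has_sib[rng.choice(n_pairs, size=n_sibs, replace=False)] = True
        for p in range(n_pairs):
            fam = f"F{fam_idx:04d}"
            fam_idx += 1
            fam_age = rng.normal(29.0, 3.5)
            pair_sex = int(rng.integers(2))  # same-sex twin pairs
            shared_c = rng.standard_normal(n_edges)
            shared_t = rng.standard_normal(n_edges)
            g_fam = rng.standard_normal(n_edges)  # family-shared genetic factor
            if zyg == "MZ":
                g1 = g2 = g_fam
            else:
                r = np.sqrt(0.5)
                g1 = r * g_fam + r * rng.standard_normal(n_edges)
                g2 = r * g_fam + r * rng.standard_normal(n_edges)
            add_member(fam, zyg, "twin1", fam_age, pair_sex, g1, shared_c, shared_t)
            add_member(fam, zyg, "twin2", fam_age, pair_sex, g2, shared_c, shared_t)
            if has_sib[p]:
                sib_age = fam_age + rng.normal(0.0, 3.0)
                sib_sex = int(rng.integers(2))
                # sibling's own T draw (variance kept, sharing dropped)
                sib_t = rng.standard_normal(n_edges)
                if zyg == "MZ":
                    # cov with each twin = 0.5*a2: 0.5*g_fam + sqrt(0.75)*own
                    g_s = 0.5 * g_fam + np.sqrt(0.75) * rng.standard_normal(n_edges)
                else:
                    r = np.sqrt(0.5)
                    g_s = r * g_fam + r * rng.standard_normal(n_edges)
                add_member(fam, zyg, "sibling", sib_age, sib_sex, g_s, shared_c, sib_t)

    subjects = pd.DataFrame(rows)
    subjects.attrs["seed"] = spec.seed
    phenotypes = np.vstack(phen)
    edge_labels = [f"e{j}" for j in range(n_edges)]
    return FamilyCohort(subjects=subjects, phenotypes=phenotypes, edge_labels=edge_labels)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(
    spec: ExpressionSimSpec,
    nodes: pd.DataFrame,
    hubs: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a region × gene expression table with planted CGE structure.

    Gene profiles are sampled from a region-level latent correlation matrix
    whose off-diagonal entries follow ``A*exp(-d/n_scale) + B``; hub–hub
    pairs additionally receive ``hub_coupling_boost``, carried by a planted
    subset of "hub-coupled" genes.  Returns ``(expression, gene_info)`` where
    ``gene_info`` maps each gene to a cell class and flags the planted
    hub-coupled genes.
    """
    for col in ("x", "y", "z"):
        if nodes[col].isna().any():
            raise ValueError("coordinates required for all regions")
    rng = np.random.default_rng(spec.seed)
    coords = nodes[["x", "y", "z"]].to_numpy(dtype=float)
    n_regions = coords.shape[0]
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)

    base = spec.amplitude * np.exp(-d / spec.n_scale) + spec.offset
    np.fill_diagonal(base, 1.0)

    boost = np.zeros_like(base)
    if hubs is not None and spec.hub_coupling_boost > 0:
        hub_mask = np.zeros(n_regions, dtype=bool)
        hub_mask[np.asarray(hubs)] = True
        boost[np.ix_(hub_mask, hub_mask)] = spec.hub_coupling_boost
        np.fill_diagonal(boost, 0.0)

    genes = np.array([f"g{j:05d}" for j in range(spec.n_genes)])
    n_coupled = (
        int(round(spec.hub_coupled_fraction * spec.n_genes))
        if spec.hub_coupling_boost > 0
        else 0
    )
    coupled = np.zeros(spec.n_genes, dtype=bool)
    coupled[:n_coupled] = True

    def factor(sigma: np.ndarray) -> np.ndarray:
        sigma = np.clip(sigma, -0.99, 0.99)
        np.fill_diagonal(sigma, 1.0)
        vals, vecs = np.linalg.eigh(sigma)
        if vals.min() < 1e-10:
            # minimal diagonal inflation to restore positive definiteness
            warnings.warn(
                "implied region covariance not positive definite; "
                f"inflating diagonal by {-vals.min() + 1e-8:.3g}",
                stacklevel=2,
            )
            vals = vals - vals.min() + 1e-8
        return vecs * np.sqrt(vals)

    L_base = factor(base.copy())
    X = np.empty((n_regions, spec.n_genes))
    n_plain = spec.n_genes - n_coupled
    X[:, ~coupled] = L_base @ rng.standard_normal((n_regions, n_plain))
    if n_coupled:
        L_boost = factor(base + boost / max(spec.hub_coupled_fraction, 1e-12))
        X[:, coupled] = L_boost @ rng.standard_normal((n_regions, n_coupled))
    if spec.noise_sd > 0:
        X += rng.normal(0.0, spec.noise_sd, size=X.shape)

    region_ids = (
        nodes["id"].to_numpy() if "id" in nodes.columns else np.arange(n_regions)
    )
    expression = pd.DataFrame(X, index=region_ids, columns=genes)
    expression.attrs["seed"] = spec.seed

    classes = [f"class{j}" for j in range(spec.n_cell_classes)]
    gene_info = pd.DataFrame(
        {
            "gene": genes,
            "cell_class": rng.choice(classes, size=spec.n_genes),
            "hub_coupled": coupled,
        }
    ).set_index("gene")
    return expression, gene_info


# ---------------------------------------------------------------------------
# cell-type marker fixture
# ---------------------------------------------------------------------------


def simulate_cell_type_profiles(
    n_genes: int,
    n_classes: int,
    marker_fraction: float,
    seed: int = 0,
    level_min: float = 5.0,
    fold_min: float = 4.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Cell-class × gene expression table with planted class markers.

    Planted markers express above ``level_min`` in exactly one class with at
    least a ``fold_min``-fold margin over every other class; non-markers are
    near-uniform across classes so they fail the fold rule.  Returns
    ``(profiles, truth)`` where ``truth`` holds the planted class per gene
    ("none" for non-markers).
    """
    if not 0.0 < marker_fraction < 1.0:
        raise ValueError("marker_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    if n_classes == 1:
        warnings.warn("n_classes=1 is degenerate: every expressed gene is trivially "
                      "class-enriched", stacklevel=2)
    classes = [f"class{j}" for j in range(n_classes)]
    genes = [f"g{j:05d}" for j in range(n_genes)]
    n_markers = int(round(marker_fraction * n_genes))

    X = rng.uniform(2.0, 8.0, size=(n_classes, n_genes))
    X *= rng.uniform(0.85, 1.15, size=(n_classes, n_genes))  # fold << fold_min
    truth = np.array(["none"] * n_genes, dtype=object)
    if n_classes > 1:
        marker_class = rng.integers(n_classes, size=n_markers)
        for g, cl in enumerate(marker_class):
            X[:, g] = rng.uniform(0.1, level_min / fold_min * 0.5, size=n_classes)
            X[cl, g] = rng.uniform(2.5 * level_min, 10 * level_min)
            truth[g] = classes[cl]
    profiles = pd.DataFrame(X, index=classes, columns=genes)
    profiles.attrs["seed"] = seed
    return profiles, pd.Series(truth, index=genes, name="cell_class")


# ---------------------------------------------------------------------------
# intensity profiles
# ---------------------------------------------------------------------------


def simulate_intensity_profiles(
    n_regions: int,
    n_surfaces: int = 16,
    n_blocks: int = 4,
    seed: int = 0,
    noise_sd: float = 0.3,
    y_slope: float = 0.05,
    block_assignment: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Depth-wise intensity profiles with block cytoarchitectonic similarity.

    Regions in the same block share a smooth depth-profile template plus
    Gaussian noise; a linear trend in the per-region midsurface
    y-coordinate is injected at every depth so that residualization is
    exercised downstream.  Returns ``(profiles, y)`` where ``profiles`` has
    columns ``v1..v{n_surfaces}`` ordered pial → white.
    """
    if n_surfaces < 2:
        raise ValueError("n_surfaces must be >= 2")
    rng = np.random.default_rng(seed)
    depth = np.linspace(0.0, 1.0, n_surfaces)
    # smooth random templates: low-order cosine series
    templates = np.zeros((n_blocks, n_surfaces))
    for b in range(n_blocks):
        coef = rng.normal(0.0, 1.0, size=4)
        templates[b] = sum(
            coef[m] * np.cos(np.pi * (m + 1) * depth) for m in range(4)
        )
    if block_assignment is None:
        block_assignment = rng.integers(n_blocks, size=n_regions)
    y = rng.uniform(-60.0, 60.0, size=n_regions)
    X = templates[block_assignment] + rng.normal(0.0, noise_sd, size=(n_regions, n_surfaces))
    X = X + y_slope * y[:, None]
    cols = [f"v{j + 1}" for j in range(n_surfaces)]
    profiles = pd.DataFrame(X, columns=cols)
    profiles.insert(0, "block", block_assignment)
    profiles.attrs["seed"] = seed
    return profiles, y
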