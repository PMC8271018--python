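"""Edge-wise biometric variance decomposition on twin + sibling cohorts.

Implements the classic ACTE family of structural-equation twin models fitted
by maximum likelihood to each connectome edge: phenotypic variance is split
into additive genetic (A), twin non-specific common environmental (C),
twin-specific common environmental (T), and unique environmental (E)
components, with age and sex entering the mean model as fixed effects.

Families contribute independent multivariate-normal likelihoods with the
sharing structure (per unit component variance):

* ``var``           = a2 + c2 + t2 + e2 for every member
* ``cov(MZ twins)`` = a2 + c2 + t2
* ``cov(DZ twins)`` = 0.5*a2 + c2 + t2
* ``cov(twin,sib)`` = 0.5*a2 + c2

Nonnegativity of the variance components is enforced through a squared-path
parameterization (the optimizer works on unconstrained path coefficients
whose squares are the variances).  Covariate coefficients are profiled out
by generalized least squares at each likelihood evaluation, so the numeric
search runs only over the (at most four) variance parameters.  Families with
missing members contribute the marginal likelihood of their observed members.
Candidate models are compared by AIC = 2p - 2 ln L and the narrow-sense
heritability h2 is the standardized A component of the AIC-best model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "FamilyCohort",
    "ModelFit",
    "BiometricFit",
    "iqr_filter",
    "fit_biometric_model",
    "select_model",
    "edgewise_heritability",
    "CANDIDATE_MODELS",
]

CANDIDATE_MODELS = ("ACTE", "ACE", "AE", "CE", "E")

# free variance components per candidate model
_MODEL_COMPONENTS = {
    "ACTE": ("a", "c", "t", "e"),
    "ACE": ("a", "c", "e"),
    "AE": ("a", "e"),
    "CE": ("c", "e"),
    "E": ("e",),
}

# member order within a family: twin1, twin2, sibling
_K_A = {
    "MZ": np.array([[1.0, 1.0, 0.5], [1.0, 1.0, 0.5], [0.5, 0.5, 1.0]]),
    "DZ": np.array([[1.0, 0.5, 0.5], [0.5, 1.0, 0.5], [0.5, 0.5, 1.0]]),
}
_K_C = np.ones((3, 3))
_K_T = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
_K_E = np.eye(3)


@dataclass
class FamilyCohort:
    """Pedigree-structured subject table plus per-subject edge phenotypes.

    ``subjects`` must provide columns ``subject_id``, ``family_id``,
    ``zygosity`` (MZ/DZ), ``role`` (twin1/twin2/sibling), ``age``, ``sex``;
    ``phenotypes`` is a subjects × edges array (NaN = missing).
    """

    subjects: pd.DataFrame
    phenotypes: np.ndarray
    edge_labels: list[str]

    def __post_init__(self) -> None:
        self.phenotypes = np.asarray(self.phenotypes, dtype=float)
        if self.phenotypes.shape[0] != len(self.subjects):
            raise ValueError("phenotype rows must match subject table")
        if self.phenotypes.shape[1] != len(self.edge_labels):
            raise ValueError("phenotype columns must match edge labels")
        roles = self.subjects.groupby("family_id")["role"].apply(list)
        for fam, rr in roles.items():
            if rr.count("sibling") > 1 or len([r for r in rr if r.startswith("twin")]) > 2:
                raise ValueError(f"family {fam}: at most 2 twins and 1 sibling allowed")
        zyg = self.subjects.groupby("family_id")["zygosity"].nunique()
        if (zyg > 1).any():
            raise ValueError("zygosity must be constant within family")

    @property
    def n_edges(self) -> int:
        return len(self.edge_labels)

    def edge_index(self, edge: int | str) -> int:
        if isinstance(edge, str):
            return self.edge_labels.index(edge)
        return int(edge)


@dataclass
class ModelFit:
    """Maximum-likelihood fit of one candidate biometric model to one edge."""

    model: str
    a2: float
    c2: float
    t2: float
    e2: float
    std: dict[str, float]
    beta: np.ndarray
    loglik: float
    n_params: int
    aic: float
    converged: bool

    @property
    def h2(self) -> float:
        return self.std["a2"]


@dataclass
class BiometricFit:
    """All candidate-model fits for one edge plus the AIC selection."""

    edge: str
    fits: dict[str, ModelFit]
    best_model: str
    h2: float
    h2_acte: float
    n_used: int
    n_outliers: int


# ---------------------------------------------------------------------------
# outlier rule
# ---------------------------------------------------------------------------


def iqr_filter(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Tukey-fence outlier rule with strict inequalities.

    Keeps values w with ``Q1 - 1.5*IQR < w < Q3 + 1.5*IQR`` where the
    quartiles are computed by linear interpolation of order statistics over
    the finite values.  Returns ``(retained_values, outlier_mask)``; NaNs are
    never flagged as outliers (they are simply missing).
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if finite.sum() < 4:
        raise ValueError("need at least 4 finite values for the IQR rule")
    q1, q3 = np.percentile(values[finite], [25, 75])
    iqr = q3 - q1
    if iqr == 0:
        # identical (or majority-identical) values: the fences collapse onto
        # the data and the strict rule would discard everything — keep all
        outlier = np.zeros_like(finite)
    else:
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        outlier = finite & ~((values > lo) & (values < hi))
    return values[finite & ~outlier], outlier


# ---------------------------------------------------------------------------
# likelihood machinery
# ---------------------------------------------------------------------------


def _sym_inv_logdet(sigma_flat: np.ndarray, k: int):
    """Closed-form inverse and log-determinant of a small symmetric matrix.

    ``sigma_flat`` is the row-major flattening of a k × k symmetric matrix
    (k <= 3 in the twin design).  Returns ``(inverse_flat, logdet)`` or
    ``None`` if the matrix is not positive definite.
    """
    if k == 1:
        s = float(sigma_flat[0])
        if s <= 0:
            return None
        return np.array([1.0 / s]), math.log(s)
    if k == 2:
        s00, s01, _, s11 = sigma_flat
        det = s00 * s11 - s01 * s01
        if det <= 0 or s00 <= 0:
            return None
        return np.array([s11, -s01, -s01, s00]) / det, math.log(det)
    if k == 3:
        s00, s01, s02, _, s11, s12, _, _, s22 = sigma_flat
        c00 = s11 * s22 - s12 * s12
        c01 = s02 * s12 - s01 * s22
        c02 = s01 * s12 - s02 * s11
        det = s00 * c00 + s01 * c01 + s02 * c02
        c22 = s00 * s11 - s01 * s01
        if det <= 0 or s00 <= 0 or c22 <= 0:
            return None
        c11 = s00 * s22 - s02 * s02
        c12 = s01 * s02 - s00 * s12
        inv = np.array([c00, c01, c02, c01, c11, c12, c02, c12, c22]) / det
        return inv, math.log(det)
    sigma = np.asarray(sigma_flat).reshape(k, k)
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return None
    return np.linalg.inv(sigma).ravel(), logdet


class _EdgeData:
    """One edge's observations grouped by family structure.

    Families sharing (zygosity, observed-member pattern) have identical
    covariance matrices, so their likelihood contributions vectorize.
    """

    def __init__(self, cohort: FamilyCohort, edge: int, covariates: tuple[str, ...]):
        subj = cohort.subjects
        y = cohort.phenotypes[:, edge]
        role_pos = {"twin1": 0, "twin2": 1, "sibling": 2}

        fam_members: dict[str, list[tuple[int, int]]] = {}
        fam_zyg: dict[str, str] = {}
        for i, row in enumerate(subj.itertuples(index=False)):
            fam_members.setdefault(row.family_id, []).append((role_pos[row.role], i))
            fam_zyg[row.family_id] = row.zygosity

        cov_cols = [subj[c].to_numpy(dtype=float) for c in covariates]
        groups: dict[tuple[str, tuple[int, ...]], list[list[int]]] = {}
        for fam, members in fam_members.items():
            members = sorted(members)
            obs = [(pos, i) for pos, i in members if np.isfinite(y[i])]
            if not obs:
                continue
            pattern = tuple(pos for pos, _ in obs)
            key = (fam_zyg[fam], pattern)
            groups.setdefault(key, []).append([i for _, i in obs])

        self.groups: list[dict] = []
        self.n_obs = 0
        for (zyg, pattern), fam_rows in groups.items():
            idx = np.array(fam_rows)  # (m, k)
            m, k = idx.shape
            Y = y[idx]
            X = np.ones((m, k, 1 + len(covariates)))
            for c_i, col in enumerate(cov_cols):
                X[:, :, 1 + c_i] = col[idx]
            sel = np.array(pattern)
            p_dim = 1 + len(covariates)
            tperm = np.arange(k * k).reshape(k, k).T.ravel()  # transpose index
            self.groups.append(
                {
                    "Ka": _K_A[zyg][np.ix_(sel, sel)].ravel(),
                    "Kc": _K_C[np.ix_(sel, sel)].ravel(),
                    "Kt": _K_T[np.ix_(sel, sel)].ravel(),
                    "Ke": np.eye(k).ravel(),
                    "Y": Y,
                    "m": m,
                    "k": k,
                    "zyg": zyg,
                    "pattern": pattern,
                    "tperm": tperm,
                    # flattened sufficient statistics: likelihood evaluations
                    # are O(1) in the number of families
                    "XX": np.einsum("mkp,mlq->klpq", X, X).reshape(k * k, p_dim * p_dim),
                    "XY": np.einsum("mkp,ml->klp", X, Y).reshape(k * k, p_dim),
                    "YY": np.einsum("mk,ml->kl", Y, Y).ravel(),
                }
            )
            self.n_obs += m * k
        self.n_beta = 1 + len(covariates)

    def loglik(self, a2: float, c2: float, t2: float, e2: float):
        """Profile log-likelihood (betas solved by GLS) at given variances."""
        p = self.n_beta
        A = np.zeros((p, p))
        b = np.zeros(p)
        logdet_total = 0.0
        sinvs = []
        for g in self.groups:
            sigma = a2 * g["Ka"] + c2 * g["Kc"] + t2 * g["Kt"] + e2 * g["Ke"]
            out = _sym_inv_logdet(sigma, g["k"])
            if out is None:
                return -np.inf, np.zeros(p)
            sinv, logdet = out
            sinvs.append(sinv)
            logdet_total += g["m"] * logdet
            A += (sinv @ g["XX"]).reshape(p, p)
            b += sinv @ g["XY"]
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return -np.inf, np.zeros(p)
        quad = 0.0
        bb = np.outer(beta, beta).ravel()
        for g, sinv in zip(self.groups, sinvs):
            xyb = g["XY"] @ beta  # flat (k*k,)
            m_flat = g["YY"] - xyb - xyb[g["tperm"]] + g["XX"] @ bb
            quad += float(sinv @ m_flat)
        ll = -0.5 * (self.n_obs * np.log(2.0 * np.pi) + logdet_total + quad)
        return ll, beta

    def moment_summaries(self):
        """Phenotypic variance and MZ/DZ twin-pair covariances (for starts)."""
        all_y = np.concatenate([g["Y"].ravel() for g in self.groups])
        v = float(np.var(all_y)) if all_y.size > 1 else 1.0
        covs = {"MZ": 0.0, "DZ": 0.0}
        for zyg in ("MZ", "DZ"):
            pairs = [
                g["Y"][:, :2]
                for g in self.groups
                if g["zyg"] == zyg and g["pattern"][:2] == (0, 1)
            ]
            if pairs:
                yy = np.vstack(pairs)
                if yy.shape[0] >= 3:
                    covs[zyg] = float(np.cov(yy[:, 0], yy[:, 1])[0, 1])
        return v, covs["MZ"], covs["DZ"]


def _fit_on_data(
    data: _EdgeData,
    model: str,
    n_starts: int,
    rng: np.random.Generator,
) -> ModelFit:
    comps = _MODEL_COMPONENTS[model]
    n_var = len(comps)
    v, c_mz, c_dz = data.moment_summaries()
    v = max(v, 1e-12)

    # E model: ordinary least squares in closed form
    if model == "E":
        ll0, beta0 = data.loglik(0.0, 0.0, 0.0, 1.0)  # only beta matters here
        rss = 0.0
        bb0 = np.outer(beta0, beta0).ravel()
        for g in data.groups:
            xyb = g["XY"] @ beta0
            m_flat = g["YY"] - xyb - xyb[g["tperm"]] + g["XX"] @ bb0
            rss += float(g["Ke"] @ m_flat)  # trace of the residual SSCP
        e2 = max(rss / data.n_obs, 1e-12)
        ll, beta = data.loglik(0.0, 0.0, 0.0, e2)
        return _finalize(model, {"e": e2}, beta, ll, data, converged=True)

    def unpack(x: np.ndarray) -> dict[str, float]:
        return {c: float(x[i] ** 2) for i, c in enumerate(comps)}

    def neg_ll(x: np.ndarray) -> float:
        var = dict.fromkeys(("a", "c", "t", "e"), 0.0)
        var.update(unpack(x))
        ll, _ = data.loglik(var["a"], var["c"], var["t"], var["e"])
        if not np.isfinite(ll):
            return 1e12
        return -ll

    # moment-informed start
    a0 = float(np.clip(2.0 * (c_mz - c_dz), 0.05 * v, 0.95 * v))
    c0 = float(np.clip(2.0 * c_dz - c_mz, 0.05 * v, 0.95 * v))
    start_map = {"a": a0, "c": c0, "t": 0.05 * v, "e": max(v - a0 - c0, 0.1 * v)}
    starts = [np.sqrt([start_map[c] for c in comps])]
    for _ in range(max(0, n_starts - 1)):
        frac = rng.dirichlet(np.ones(n_var))
        starts.append(np.sqrt(np.maximum(frac * v, 1e-8)))

    best = None
    for x0 in starts:
        res = minimize(neg_ll, x0, method="L-BFGS-B", options={"ftol": 1e-12, "gtol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
    converged = bool(best is not None and np.isfinite(best.fun) and best.fun < 1e11)
    if not converged:
        nan = float("nan")
        return ModelFit(
            model, nan, nan, nan, nan,
            {"a2": nan, "c2": nan, "t2": nan, "e2": nan},
            np.full(data.n_beta, nan), nan, n_var + data.n_beta, nan, False,
        )
    var = unpack(best.x)
    full = dict.fromkeys(("a", "c", "t", "e"), 0.0)
    full.update(var)
    ll, beta = data.loglik(full["a"], full["c"], full["t"], full["e"])
    return _finalize(model, var, beta, ll, data, converged=True)


def _finalize(model, var, beta, ll, data, converged) -> ModelFit:
    full = dict.fromkeys(("a", "c", "t", "e"), 0.0)
    full.update(var)
    total = full["a"] + full["c"] + full["t"] + full["e"]
    total = max(total, 1e-300)
    std = {f"{c}2": full[c] / total for c in ("a", "c", "t", "e")}
    n_params = len(_MODEL_COMPONENTS[model]) + data.n_beta
    aic = 2.0 * n_params - 2.0 * ll
    return ModelFit(
        model=model,
        a2=full["a"],
        c2=full["c"],
        t2=full["t"],
        e2=full["e"],
        std=std,
        beta=np.asarray(beta),
        loglik=float(ll),
        n_params=n_params,
        aic=float(aic),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# public fitting API
# ---------------------------------------------------------------------------


def fit_biometric_model(
    cohort: FamilyCohort,
    edge: int | str,
    model: str = "ACTE",
    covariates: tuple[str, ...] = ("age", "sex"),
    n_starts: int = 3,
    seed: int = 0,
) -> ModelFit:
    """Fit one candidate biometric model to one edge by maximum likelihood.

    ``n_starts`` counts the moment-informed start plus random restarts of the
    quasi-Newton search over squared path coefficients.  No outlier filtering
    is applied here; see :func:`edgewise_heritability` for the full per-edge
    protocol.
    """
    if model not in _MODEL_COMPONENTS:
        raise ValueError(f"unknown model {model!r}; choose from {CANDIDATE_MODELS}")
    data = _EdgeData(cohort, cohort.edge_index(edge), tuple(covariates))
    n_fam_multi = sum(g["m"] for g in data.groups if g["k"] >= 2)
    if n_fam_multi < 2:
        raise ValueError("need >= 2 families with >= 2 phenotyped members")
    return _fit_on_data(data, model, n_starts, np.random.default_rng(seed))


def select_model(fits: dict[str, ModelFit] | list[ModelFit]) -> ModelFit:
    """AIC-argmin over converged fits; ties broken toward fewer parameters."""
    if isinstance(fits, dict):
        fits = list(fits.values())
    ok = [f for f in fits if f.converged and np.isfinite(f.aic)]
    if not ok:
        raise ValueError("no converged fit to select from")
    return min(ok, key=lambda f: (f.aic, f.n_params))


def edgewise_heritability(
    cohort: FamilyCohort,
    edges: list[int | str] | None = None,
    models: tuple[str, ...] = CANDIDATE_MODELS,
    covariates: tuple[str, ...] = ("age", "sex"),
    n_starts: int = 3,
    seed: int = 0,
    apply_iqr: bool = True,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Full per-edge protocol: IQR filter, fit all candidates, select by AIC.

    Returns ``(results, proportions)`` where ``results`` has one row per edge
    (standardized components of the best model, best-model h2, full-ACTE h2,
    log-likelihood/AIC of the best model, sample sizes) and ``proportions``
    gives the fraction of edges best fitted by each candidate model
    (summing to 1 over edges with at least one converged fit).
    """
    if edges is None:
        edges = list(range(cohort.n_edges))
    edge_ids = [cohort.edge_index(e) for e in edges]
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(edge_ids)) % (2**31)

    rows = []
    best_counts: dict[str, int] = dict.fromkeys(models, 0)
    n_selected = 0
    for e_i, edge in enumerate(edge_ids):
        label = cohort.edge_labels[edge]
        y = cohort.phenotypes[:, edge].copy()
        n_out = 0
        if apply_iqr and np.isfinite(y).sum() >= 4:
            _, outlier = iqr_filter(y)
            y[outlier] = np.nan
            n_out = int(outlier.sum())
        work = FamilyCohort(
            subjects=cohort.subjects,
            phenotypes=y[:, None],
            edge_labels=[label],
        )
        data = _EdgeData(work, 0, tuple(covariates))
        rng = np.random.default_rng(child_seeds[e_i])
        fits = {m: _fit_on_data(data, m, n_starts, rng) for m in models}
        try:
            best = select_model(fits)
        except ValueError:
            warnings.warn(f"edge {label}: no converged fit, excluded", stacklevel=2)
            rows.append(
                dict(edge=label, best_model="none", a2=np.nan, c2=np.nan, t2=np.nan,
                     e2=np.nan, h2=np.nan, h2_acte=np.nan, loglik=np.nan, aic=np.nan,
                     n_used=int(np.isfinite(y).sum()), n_outliers=n_out)
            )
            continue
        n_selected += 1
        best_counts[best.model] += 1
        h2_acte = fits["ACTE"].std["a2"] if "ACTE" in fits and fits["ACTE"].converged else np.nan
        rows.append(
            dict(
                edge=label,
                best_model=best.model,
                a2=best.std["a2"],
                c2=best.std["c2"],
                t2=best.std["t2"],
                e2=best.std["e2"],
                h2=best.std["a2"],
                h2_acte=h2_acte,
                loglik=best.loglik,
                aic=best.aic,
                n_used=int(np.isfinite(y).sum()),
                n_outliers=n_out,
            )
        )
    results = pd.DataFrame(rows)
    proportions = {
        m: (best_counts[m] / n_selected if n_selected else np.nan) for m in models
    }
    return results, proportions
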