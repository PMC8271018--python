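"""Transcriptional coupling: CGE, distance correction, gene contribution
scores, cell markers, and gene-score-resampling enrichment.

Correlated gene expression (CGE) between two regions is the Pearson
correlation of their normalized expression profiles across genes.  Because
CGE decays approximately exponentially with separation distance, an
exponential trend ``r(d) = A * exp(-d/n) + B`` is fitted to the CGE–distance
scatter and its residuals ``CGE_ij - r(d_ij)`` are used in all downstream
comparisons.  The per-gene contribution to an edge's residual CGE is the
gene contribution score ``GCS_ij^a = z_i^a * z_j^a - r(d_ij)``, where z is
the region profile z-scored across genes with the population (1/N) divisor —
the convention under which the mean GCS over genes reproduces the residual
CGE exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy import stats

__all__ = [
    "ExpressionAtlas",
    "DistanceDecayFit",
    "srs_normalize",
    "cge_matrix",
    "fit_distance_decay",
    "gene_contribution_scores",
    "gcs_link_tstat",
    "derive_cell_markers",
    "gene_score_resampling",
    "read_gmt",
]


@dataclass
class ExpressionAtlas:
    """Region × gene expression table with region ids matching a connectome."""

    data: pd.DataFrame
    flagged_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.isna().all(axis=0).any():
            raise ValueError("atlas contains all-missing gene columns")

    @property
    def regions(self) -> np.ndarray:
        return self.data.index.to_numpy()

    @property
    def genes(self) -> np.ndarray:
        return self.data.columns.to_numpy()


@dataclass
class DistanceDecayFit:
    """Exponential distance trend of CGE and its residual matrix."""

    amplitude: float  # A
    offset: float  # B
    scale: float  # n, mm
    residuals: pd.DataFrame = field(repr=False)

    def trend(self, d: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-np.asarray(d, dtype=float) / self.scale) + self.offset


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def _srs_axis(df: pd.DataFrame, axis: int, flagged: set[str]) -> pd.DataFrame:
    """Scaled robust sigmoid along one axis (0: per column, 1: per row)."""
    x = df.to_numpy(dtype=float)
    med = np.nanmedian(x, axis=axis, keepdims=True)
    q75 = np.nanpercentile(x, 75, axis=axis, keepdims=True)
    q25 = np.nanpercentile(x, 25, axis=axis, keepdims=True)
    iqr = q75 - q25
    degenerate = (iqr <= 0) | ~np.isfinite(iqr)
    safe_iqr = np.where(degenerate, 1.0, iqr)
    y = 1.0 / (1.0 + np.exp(-(x - med) / (safe_iqr / 1.35)))
    y = np.where(np.broadcast_to(degenerate, y.shape), 0.5, y)
    # min–max rescale to [0, 1] along the same axis
    ymin = np.nanmin(y, axis=axis, keepdims=True)
    ymax = np.nanmax(y, axis=axis, keepdims=True)
    rng_ = ymax - ymin
    flat = rng_ <= 0
    y = np.where(
        np.broadcast_to(flat, y.shape), 0.5, (y - ymin) / np.where(flat, 1.0, rng_)
    )
    if axis == 0:
        for j in np.where(degenerate.ravel() | flat.ravel())[0]:
            flagged.add(str(df.columns[j]))
    return pd.DataFrame(y, index=df.index, columns=df.columns)


def srs_normalize(
    raw: pd.DataFrame | dict[str, pd.DataFrame],
) -> ExpressionAtlas:
    """Two-pass scaled-robust-sigmoid normalization of raw expression.

    First every sample (row) is normalized across genes, then every gene
    (column) across samples; each pass maps through the robust sigmoid
    ``1 / (1 + exp(-(x - median) / (IQR / 1.35)))`` followed by min–max
    rescaling to [0, 1].  A dict of per-donor frames is normalized per donor
    and then averaged per region (rows aligned on the region index).
    Zero-IQR features map to a constant 0.5 and are flagged.
    """
    donors = raw if isinstance(raw, dict) else {"donor0": raw}
    flagged: set[str] = set()
    normed = []
    for name, df in donors.items():
        if df.shape[0] < 2 or df.shape[1] < 2:
            raise ValueError(f"donor {name}: need >= 2 regions and >= 2 genes")
        step1 = _srs_axis(df, axis=1, flagged=flagged)  # per sample across genes
        step2 = _srs_axis(step1, axis=0, flagged=flagged)  # per gene across samples
        normed.append(step2)
    combined = pd.concat(normed).groupby(level=0).mean()
    return ExpressionAtlas(data=combined, flagged_genes=sorted(flagged))


# ---------------------------------------------------------------------------
# CGE
# ---------------------------------------------------------------------------


def cge_matrix(atlas: ExpressionAtlas | pd.DataFrame) -> pd.DataFrame:
    """Region × region correlated gene expression (Pearson, pairwise-complete).

    Symmetric with unit diagonal; rows/columns of zero-variance region
    profiles are NaN (undefined markers).
    """
    data = atlas.data if isinstance(atlas, ExpressionAtlas) else atlas
    if data.shape[1] < 3:
        raise ValueError("need >= 3 genes to compute CGE")
    cge = data.T.corr()  # pairwise-complete over genes
    np.fill_diagonal(cge.values, 1.0)
    var0 = data.std(axis=1, ddof=0) == 0
    if var0.any():
        cge.loc[var0, :] = np.nan
        cge.loc[:, var0] = np.nan
    return cge


def fit_distance_decay(
    cge: pd.DataFrame | np.ndarray,
    distances: np.ndarray,
    scale_starts: tuple[float, ...] = (10.0, 30.0, 90.0, 300.0),
) -> DistanceDecayFit:
    """Fit ``r(d) = A*exp(-d/n) + B`` to the CGE–distance scatter.

    Nonlinear least squares with multiple starting values of the length
    scale n; the best (lowest-SSE) converged start wins.  Residuals are
    ``CGE - r(d)`` with NaN on the diagonal.
    """
    cge_arr = cge.to_numpy(dtype=float) if isinstance(cge, pd.DataFrame) else np.asarray(cge, float)
    d = np.asarray(distances, dtype=float)
    iu, ju = np.triu_indices(cge_arr.shape[0], k=1)
    x = d[iu, ju]
    y = cge_arr[iu, ju]
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 10 or np.ptp(x) <= 0:
        raise ValueError("need >= 10 region pairs spanning a distance range")

    def model(dd, a, b, n):
        return a * np.exp(-dd / n) + b

    best = None
    for n0 in scale_starts:
        try:
            popt, _ = curve_fit(
                model, x, y, p0=[max(y.max() - y.min(), 0.1), y.min(), n0],
                bounds=([-2.0, -2.0, 1e-6], [2.0, 2.0, 1e6]), maxfev=20000,
            )
        except RuntimeError:
            continue
        sse = float(np.sum((y - model(x, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise RuntimeError(
            "distance-decay fit did not converge from any start "
            f"(starts tried: {scale_starts})"
        )
    a, b, n = best[1]
    if abs(a) < 1e-6 or n > 0.5e6:
        warnings.warn(
            "CGE–distance trend is nearly flat; amplitude ~ 0 or scale very "
            "large — residuals equal the centered CGE", stacklevel=2,
        )
    resid = cge_arr - model(d, a, b, n)
    np.fill_diagonal(resid, np.nan)
    if isinstance(cge, pd.DataFrame):
        resid = pd.DataFrame(resid, index=cge.index, columns=cge.columns)
    else:
        resid = pd.DataFrame(resid)
    return DistanceDecayFit(amplitude=float(a), offset=float(b), scale=float(n), residuals=resid)


# ---------------------------------------------------------------------------
# gene contribution scores
# ---------------------------------------------------------------------------


def gene_contribution_scores(
    atlas: ExpressionAtlas | pd.DataFrame,
    decay_fit: DistanceDecayFit,
    distances: np.ndarray,
    edge_i: np.ndarray,
    edge_j: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge per-gene contribution scores GCS_ij^a = z_i^a z_j^a - r(d_ij).

    Region profiles are z-scored across genes with the population divisor,
    so the mean over genes of GCS_ij equals the distance-residual CGE_ij
    exactly.  Zero-variance genes are excluded (recorded in the returned
    gene array).  Returns ``(gcs, genes)`` with ``gcs`` of shape
    (n_edges, n_genes_kept).
    """
    data = atlas.data if isinstance(atlas, ExpressionAtlas) else atlas
    keep = data.std(axis=0, ddof=0) > 0
    if (~keep).any():
        warnings.warn(
            f"excluding {int((~keep).sum())} zero-variance gene(s) from GCS",
            stacklevel=2,
        )
    x = data.loc[:, keep].to_numpy(dtype=float)
    if x.shape[1] == 1:
        # degenerate single-gene atlas: per-region standardization is
        # impossible, so standardize the gene across regions instead
        warnings.warn(
            "single-gene atlas: standardizing the gene across regions",
            stacklevel=2,
        )
        z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
    else:
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=0, keepdims=True)
        if (sd <= 0).any():
            raise ValueError("region profile with zero variance; GCS undefined")
        z = (x - mu) / sd
    d = np.asarray(distances, dtype=float)
    r_d = decay_fit.trend(d[edge_i, edge_j])
    gcs = z[edge_i] * z[edge_j] - r_d[:, None]
    return gcs, data.columns[keep].to_numpy()


def gcs_link_tstat(
    gcs: np.ndarray,
    rich_edges: np.ndarray,
    peripheral_edges: np.ndarray,
    genes: np.ndarray | None = None,
) -> pd.Series | np.ndarray:
    """Per-gene Welch t-statistic of GCS for rich minus peripheral links.

    Vectorized Welch t over all genes at once; genes need >= 2 values per
    edge set for a defined statistic.
    """
    rich_edges = np.asarray(rich_edges)
    peripheral_edges = np.asarray(peripheral_edges)
    if rich_edges.size == 0 or peripheral_edges.size == 0:
        raise ValueError("both edge sets must be non-empty")
    a = gcs[rich_edges]
    b = gcs[peripheral_edges]
    if a.shape[0] < 2 or b.shape[0] < 2:
        t = np.full(gcs.shape[1], np.nan)
    else:
        ma, mb = a.mean(axis=0), b.mean(axis=0)
        va = a.var(axis=0, ddof=1) / a.shape[0]
        vb = b.var(axis=0, ddof=1) / b.shape[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (ma - mb) / np.sqrt(va + vb)
    if genes is not None:
        return pd.Series(t, index=genes, name="gcs_t")
    return t


# ---------------------------------------------------------------------------
# cell markers
# ---------------------------------------------------------------------------


def derive_cell_markers(
    class_expression: pd.DataFrame,
    level_min: float = 5.0,
    fold_min: float = 4.0,
) -> pd.Series:
    """Assign genes to cell classes by an expression-level and fold rule.

    A gene is a marker of a class iff its expression there exceeds
    ``level_min`` and is at least ``fold_min`` times its expression in every
    other class; genes qualifying nowhere are labeled "none".  Input rows
    are cell classes, columns genes.
    """
    if class_expression.shape[0] < 2:
        raise ValueError("need >= 2 cell classes to derive markers")
    x = class_expression.to_numpy(dtype=float)
    top = np.argmax(x, axis=0)
    cols = np.arange(x.shape[1])
    top_val = x[top, cols]
    others = x.copy()
    others[top, cols] = -np.inf
    max_other = others.max(axis=0)
    ok = (top_val > level_min) & (top_val >= fold_min * max_other)
    labels = np.where(ok, class_expression.index.to_numpy()[top], "none")
    return pd.Series(labels, index=class_expression.columns, name="cell_class")


# ---------------------------------------------------------------------------
# gene score resampling
# ---------------------------------------------------------------------------


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT gene-set file (set name, description, member genes)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def gene_score_resampling(
    scores: pd.Series,
    gene_sets: dict[str, list[str]],
    n_iter: int = 10**6,
    size_bounds: tuple[int, int] = (5, 100),
    seed: int = 0,
    chunk: int = 2000,
) -> pd.DataFrame:
    """Mean-score gene-set enrichment by full gene score resampling.

    For each retained set (size within ``size_bounds`` after intersecting
    with the scored genes) the observed mean score is compared against
    ``n_iter`` means of random same-size gene draws without replacement;
    the upper-tail p uses the add-one rule and Benjamini–Hochberg FDR is
    applied across retained sets.  Returns a frame with columns
    ``gene_set, size, mean_score, p, q`` (excluded sets appear with NaN p).
    """
    scores = scores.dropna()
    vals = scores.to_numpy(dtype=float)
    index = {g: i for i, g in enumerate(scores.index)}
    n_genes = vals.size

    records = []
    by_size: dict[int, list[str]] = {}
    for name, members in gene_sets.items():
        idx = [index[g] for g in members if g in index]
        size = len(idx)
        if not size_bounds[0] <= size <= size_bounds[1]:
            records.append(dict(gene_set=name, size=size, mean_score=np.nan,
                                p=np.nan, retained=False))
            continue
        records.append(dict(gene_set=name, size=size,
                            mean_score=float(vals[idx].mean()), retained=True))
        by_size.setdefault(size, []).append(name)

    rng = np.random.default_rng(seed)
    obs = {r["gene_set"]: r["mean_score"] for r in records if r.get("retained")}
    counts = dict.fromkeys(obs, 0)
    for size, names in sorted(by_size.items()):
        obs_vals = np.array([obs[n] for n in names])
        done = 0
        while done < n_iter:
            m = min(chunk, n_iter - done)
            keys = rng.random((m, n_genes))
            pick = np.argpartition(keys, size - 1, axis=1)[:, :size]
            null_means = vals[pick].mean(axis=1)
            ge = (null_means[:, None] >= obs_vals[None, :]).sum(axis=0)
            for n_i, name in enumerate(names):
                counts[name] += int(ge[n_i])
            done += m
    out = pd.DataFrame(records).drop(columns="retained")
    out["p"] = [
        (1.0 + counts[r]) / (1.0 + n_iter) if r in counts else np.nan
        for r in out["gene_set"]
    ]
    retained = out["p"].notna()
    q = np.full(len(out), np.nan)
    if retained.any():
        from statsmodels.stats.multitest import multipletests

        q[retained.to_numpy()] = multipletests(
            out.loc[retained, "p"].to_numpy(), method="fdr_bh"
        )[1]
    out["q"] = q
    return out
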