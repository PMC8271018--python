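"""Microstructural profile covariance (MPC) from depth-wise intensity
profiles.

Regional intensity profiles sampled at a fixed number of intracortical
depths (16 by default) are first corrected for the midsurface y-coordinate
(each depth column regressed on y, residuals standardized per column), then
every region pair is correlated across depth while controlling for the
cortex-wide mean profile (a partial correlation).  Positive partial
correlations r are mapped through ``log(r / (1 - r))``; non-positive values
are floored to the minimum transformed value so the matrix stays dense.  The
raw partial-correlation matrix is returned alongside the transformed one so
an alternative transform can be substituted downstream.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["residualize_profiles", "mpc_matrix"]


def residualize_profiles(
    profiles: np.ndarray | pd.DataFrame,
    y: np.ndarray,
) -> np.ndarray:
    """Regress each depth column on the midsurface y-coordinate.

    Returns standardized residual profiles (per-depth zero mean, unit
    population variance).  A constant y-coordinate makes the correction
    impossible; the slope step is then skipped (centering only) with a
    warning.
    """
    x = (
        profiles.to_numpy(dtype=float)
        if isinstance(profiles, pd.DataFrame)
        else np.asarray(profiles, dtype=float)
    )
    if x.shape[0] < 3:
        raise ValueError("need >= 3 regions")
    y = np.asarray(y, dtype=float)
    if y.shape[0] != x.shape[0]:
        raise ValueError("y must have one value per region")
    yc = y - y.mean()
    denom = float(yc @ yc)
    resid = x - x.mean(axis=0, keepdims=True)
    if denom <= 0:
        warnings.warn("constant y-coordinate: trend correction skipped", stacklevel=2)
    else:
        slope = (yc @ resid) / denom  # per depth column
        resid = resid - np.outer(yc, slope)
    sd = resid.std(axis=0, ddof=0)
    safe = np.where(sd > 0, sd, 1.0)
    return resid / safe


def mpc_matrix(
    residual_profiles: np.ndarray,
    var_tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Microstructural profile covariance from standardized residual profiles.

    For each region pair, the Pearson correlation across depth of the two
    profiles is computed partialling out the cortex-wide mean profile.
    Returns ``(mpc, raw_r)``: ``raw_r`` holds the partial correlations;
    ``mpc`` maps r > 0 through ``log(r / (1 - r))`` and floors r <= 0 at the
    minimum transformed value.  Diagonals are NaN, as are rows/columns of
    regions whose residual profile variance vanishes.
    """
    x = np.asarray(residual_profiles, dtype=float)
    n_regions, n_depth = x.shape
    if n_regions < 3:
        raise ValueError("need >= 3 regions")
    mean_profile = x.mean(axis=0)

    # remove the mean profile from each region's profile (across depth)
    m = mean_profile - mean_profile.mean()
    xc = x - x.mean(axis=1, keepdims=True)
    mm = float(m @ m)
    if mm > 0:
        coef = (xc @ m) / mm
        xr = xc - np.outer(coef, m)
    else:
        xr = xc
    sd = np.sqrt((xr * xr).sum(axis=1))
    degenerate = sd <= np.sqrt(var_tol)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} region(s) with zero residual profile "
            "variance: MPC undefined on their rows/columns", stacklevel=2,
        )
    safe = np.where(degenerate, 1.0, sd)
    u = xr / safe[:, None]
    r = u @ u.T
    r = np.clip(r, -1.0, 1.0)
    r[degenerate, :] = np.nan
    r[:, degenerate] = np.nan
    np.fill_diagonal(r, np.nan)

    with np.errstate(divide="ignore", invalid="ignore"):
        rc = np.minimum(r, 1.0 - 1e-12)  # keep the transform finite at r == 1
        t = np.where(r > 0, np.log(rc / (1.0 - rc)), np.nan)
    pos = np.isfinite(t)
    floor = np.nanmin(t[pos]) if pos.any() else 0.0
    mpc = np.where(np.isfinite(r) & ~pos, floor, t)
    return mpc, r
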