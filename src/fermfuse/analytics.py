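"""Multi-batch key-feature analytics: correlation screening and PCA views.

Two complementary questions about a set of comparable batches:

* *Which process factors track performance?*  A Spearman rank-correlation
  screen between targets (titer, rate, yield, biomass, ...) and process
  factors, with two-sided p-values (exact permutation enumeration for
  very small n, t approximation otherwise).
* *Which batches and which moments differ?*  Two PCA procedures:

  - **flat** — each batch flattened to one row (variable x time-point
    columns); batches become points in (PC1, PC2) score space, so outlier
    batches separate from the stable cluster;
  - **time** — all batches stacked as (batch, time) rows over process
    variables; PC1/PC2 become per-batch time trajectories, smoothed with
    a Savitzky-Golay filter, and the loading vector attributes trajectory
    excursions to variables.

Columns are z-scored before both PCA procedures (variables span
incommensurate units); component signs are fixed so each loading vector's
largest-magnitude element is positive.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import savgol_filter
from sklearn.decomposition import PCA

from .model import FusedFrame, RangeError

__all__ = [
    "CorrelationScreen",
    "BatchMatrixFlat",
    "BatchMatrixStacked",
    "resample_common_grid",
    "spearman_screen",
    "pca_flat",
    "pca_time",
]

EXACT_PERMUTATION_MAX_N = 8  # exact p-value enumeration bound; t approx above


@dataclass
class CorrelationScreen:
    """Spearman rho and two-sided p per target x factor pair (DataFrames)."""

    rho: pd.DataFrame  # index: factors, columns: targets
    p: pd.DataFrame
    n: pd.DataFrame  # paired observations used


@dataclass
class BatchMatrixFlat:
    """One row per batch; columns are (variable, grid time) pairs."""

    values: np.ndarray
    batch_ids: list[str]
    columns: list[tuple[str, float]]
    grid: np.ndarray


@dataclass
class BatchMatrixStacked:
    """Rows are (batch, grid time); columns are process variables."""

    values: np.ndarray
    variables: list[str]
    batch_index: np.ndarray  # per-row batch ordinal
    batch_ids: list[str]
    times: np.ndarray  # per-row grid time
    grid: np.ndarray


def resample_common_grid(
    batches: list[FusedFrame],
    grid=None,
    variables: list[str] | None = None,
    *,
    max_points: int = 2000,
    stacked: bool = False,
):
    """Linearly resample several fused batches onto one shared grid.

    The default grid spans the intersection of the batch spans at the
    first batch's cadence, subsampled to at most ``max_points``.  Every
    batch must cover the grid and provide every variable.
    """
    if not batches:
        raise RangeError("no batches to resample")
    if variables is None:
        variables = list(batches[0].data.columns)
    for b in batches:
        missing = [v for v in variables if v not in b.data.columns]
        if missing:
            bid = b.meta.batch_id if b.meta else "?"
            raise RangeError(f"batch {bid!r} missing variable(s) {missing}")
    if grid is None:
        lo = max(b.times[0] for b in batches)
        hi = min(b.times[-1] for b in batches)
        if hi <= lo:
            raise RangeError("batch spans do not overlap; no common grid")
        step = np.median(np.diff(batches[0].times))
        npts = min(int(np.floor((hi - lo) / step)) + 1, max_points)
        grid = np.linspace(lo, hi, npts)
    grid = np.asarray(grid, dtype=float)
    for b in batches:
        if grid[0] < b.times[0] - 1e-12 or grid[-1] > b.times[-1] + 1e-12:
            bid = b.meta.batch_id if b.meta else "?"
            raise RangeError(f"batch {bid!r} span does not cover the grid")
    ids = [(b.meta.batch_id if b.meta else f"batch{i}") for i, b in enumerate(batches)]
    cube = np.empty((len(batches), grid.size, len(variables)))
    for bi, b in enumerate(batches):
        for vi, v in enumerate(variables):
            cube[bi, :, vi] = np.interp(grid, b.times, b.column(v))
    if stacked:
        values = cube.reshape(len(batches) * grid.size, len(variables))
        batch_index = np.repeat(np.arange(len(batches)), grid.size)
        times = np.tile(grid, len(batches))
        return BatchMatrixStacked(values=values, variables=list(variables),
                                  batch_index=batch_index, batch_ids=ids,
                                  times=times, grid=grid)
    # flat: variable-major columns (v0@t0..v0@tN, v1@t0..)
    values = np.transpose(cube, (0, 2, 1)).reshape(len(batches), -1)
    columns = [(v, float(t)) for v in variables for t in grid]
    return BatchMatrixFlat(values=values, batch_ids=ids, columns=columns, grid=grid)


# ---------------------------------------------------------------------------
# Spearman screening

def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for |rho| >= |rho_obs| (small n only)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = rx.size
    ry_c = ry - ry.mean()
    rx_c = rx - rx.mean()
    denom = math.sqrt(float(np.sum(rx_c**2) * np.sum(ry_c**2)))
    if denom == 0:
        return float("nan")
    count = 0
    total = 0
    target = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        r = float(np.dot(rx_c[list(perm)], ry_c)) / denom
        if abs(r) >= target:
            count += 1
        total += 1
    return count / total


def spearman_screen(
    data: pd.DataFrame,
    targets: list[str],
    factors: list[str] | None = None,
    *,
    bh_correct: bool = False,
) -> CorrelationScreen:
    """Rank-correlate each target with each factor over paired observations.

    ``data`` holds one observation per row (e.g. one batch, or one
    batch x time sample).  Rows with NaN in a pair are dropped pairwise;
    at least 3 paired observations are required per pair.  Constant
    columns yield NaN (rho undefined).  ``bh_correct`` applies a
    Benjamini-Hochberg adjustment across the screen.
    """
    if factors is None:
        factors = [c for c in data.columns if c not in targets]
    for name in [*targets, *factors]:
        if name not in data.columns:
            raise RangeError(f"column {name!r} not in data")
    rho = pd.DataFrame(index=factors, columns=targets, dtype=float)
    pval = pd.DataFrame(index=factors, columns=targets, dtype=float)
    nobs = pd.DataFrame(index=factors, columns=targets, dtype=float)
    for f in factors:
        for t in targets:
            pair = data[[f, t]].dropna()
            n = len(pair)
            nobs.loc[f, t] = n
            if n < 3:
                raise RangeError(f"pair ({f!r}, {t!r}): need >= 3 paired observations, have {n}")
            x = pair[f].to_numpy(dtype=float)
            y = pair[t].to_numpy(dtype=float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                rho.loc[f, t] = np.nan
                pval.loc[f, t] = np.nan
                continue
            r, p = stats.spearmanr(x, y)
            if n <= EXACT_PERMUTATION_MAX_N:
                p = _exact_spearman_p(x, y, float(r))
            rho.loc[f, t] = float(r)
            pval.loc[f, t] = float(p)
    if bh_correct:
        flat = pval.to_numpy().ravel()
        ok = ~np.isnan(flat)
        adj = flat.copy()
        adj[ok] = stats.false_discovery_control(flat[ok], method="bh")
        pval = pd.DataFrame(adj.reshape(pval.shape), index=factors, columns=targets)
    return CorrelationScreen(rho=rho, p=pval, n=nobs)


# ---------------------------------------------------------------------------
# PCA procedures

def _zscore_columns(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mu) / sd


def _fix_signs(components: np.ndarray, scores: np.ndarray):
    """Make each loading vector's largest-|.| element positive (reproducible)."""
    for k in range(components.shape[0]):
        j = int(np.argmax(np.abs(components[k])))
        if components[k, j] < 0:
            components[k] *= -1.0
            scores[:, k] *= -1.0
    return components, scores


def pca_flat(m: BatchMatrixFlat, n_components: int = 2):
    """Score each batch as a point in (PC1..PCk) space.

    Returns ``(scores, explained_variance_ratio)`` where ``scores`` is a
    DataFrame indexed by batch id.  Batches far from the cluster centroid
    are candidate outlier batches (contamination, stunted growth, ...).
    """
    n_batches = m.values.shape[0]
    if n_batches < n_components:
        raise RangeError(f"need >= {n_components} batches, have {n_batches}")
    X = _zscore_columns(m.values)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    comps, scores = _fix_signs(pca.components_.copy(), scores)
    cols = [f"PC{k + 1}" for k in range(n_components)]
    return (
        pd.DataFrame(scores, index=pd.Index(m.batch_ids, name="batch"), columns=cols),
        pca.explained_variance_ratio_.copy(),
    )


def pca_time(
    m: BatchMatrixStacked,
    sg_window: int = 11,
    sg_order: int = 3,
    n_components: int = 2,
):
    """Per-batch principal-component trajectories with SG smoothing.

    Returns ``(trajectories, loadings, explained_variance_ratio)``:
    ``trajectories`` maps batch id to a DataFrame (index: grid time,
    columns PC1..PCk, smoothed); ``loadings`` is a DataFrame (index:
    variable, one column per component, unit norm).  A step disturbance
    in one variable shows up as a trajectory excursion whose loading
    pattern names the variable.
    """
    if sg_window % 2 == 0 or sg_window <= sg_order:
        raise RangeError(f"SG window must be odd and > order, got {sg_window}/{sg_order}")
    if m.values.shape[0] < m.values.shape[1]:
        raise RangeError("need at least as many stacked rows as variables")
    X = _zscore_columns(m.values)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    comps, scores = _fix_signs(pca.components_.copy(), scores)
    cols = [f"PC{k + 1}" for k in range(n_components)]
    loadings = pd.DataFrame(comps.T, index=pd.Index(m.variables, name="variable"), columns=cols)
    trajectories: dict[str, pd.DataFrame] = {}
    npts = m.grid.size
    for bi, bid in enumerate(m.batch_ids):
        sel = m.batch_index == bi
        traj = scores[sel]
        if npts >= sg_window:
            traj = savgol_filter(traj, sg_window, sg_order, axis=0)
        trajectories[bid] = pd.DataFrame(traj, index=pd.Index(m.grid, name="time_h"), columns=cols)
    return trajectories, loadings, pca.explained_variance_ratio_.copy()
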