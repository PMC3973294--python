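"""Probe-level array normalization.

Two-color MAP/ChIP-vs-input arrays are summarized per probe as
M = log2(ch2/ch1) and A = (log2 ch1 + log2 ch2)/2, loess-normalized
(M regressed on A with a robust locally weighted linear fit, the trend
subtracted) and then scaled so every array in a comparison set shares the
same median absolute deviation. One-color expression arrays are quantile
normalized and summarized per transcript by Tukey's median polish.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    pass


class DegenerateArrayError(ValueError):
    pass


def mad(x: np.ndarray) -> float:
    """Median absolute deviation, without the 1.4826 consistency constant
    (it cancels in every ratio this module takes)."""
    x = np.asarray(x, dtype=float)
    return float(np.median(np.abs(x - np.median(x))))


# ---------------------------------------------------------------------------
# M/A computation
# ---------------------------------------------------------------------------

def compute_ma(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Per-probe (M, A) from a two-color intensity table (probe_id, ch1, ch2).

    Probes with a non-positive intensity in either channel are dropped (a
    ratio cannot be fabricated for them); the number dropped is returned
    and logged.
    """
    ch1 = table["ch1"].to_numpy(dtype=float)
    ch2 = table["ch2"].to_numpy(dtype=float)
    ok = (ch1 > 0) & (ch2 > 0) & np.isfinite(ch1) & np.isfinite(ch2)
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("dropped %d probes with non-positive intensities", n_dropped)
    l1, l2 = np.log2(ch1[ok]), np.log2(ch2[ok])
    out = pd.DataFrame(
        {
            "probe_id": table["probe_id"].to_numpy()[ok],
            "M": l2 - l1,
            "A": 0.5 * (l1 + l2),
        }
    )
    return out, n_dropped


# ---------------------------------------------------------------------------
# loess
# ---------------------------------------------------------------------------

def _tricube(u: np.ndarray) -> np.ndarray:
    u = np.clip(np.abs(u), 0.0, 1.0)
    return (1.0 - u**3) ** 3


def _neighbor_window(xs: np.ndarray, x0: float, k: int) -> tuple[int, int]:
    """Start/end (half-open) of the k nearest sorted x values to x0."""
    n = len(xs)
    if k >= n:
        return 0, n
    j = int(np.searchsorted(xs, x0))
    lo = max(0, j - k)
    hi = min(j, n - k)
    if hi < lo:
        hi = lo
    starts = np.arange(lo, hi + 1)
    d = np.maximum(x0 - xs[starts], xs[starts + k - 1] - x0)
    best = int(starts[int(np.argmin(d))])
    return best, best + k


def _local_linear(xw, yw, w, x0) -> float:
    sw = w.sum()
    if sw <= 0:
        return float(np.mean(yw))
    xm = (w * xw).sum() / sw
    ym = (w * yw).sum() / sw
    dx = xw - xm
    sxx = (w * dx * dx).sum()
    if sxx <= 1e-12 * max(1.0, xm * xm):
        return float(ym)
    beta = (w * dx * (yw - ym)).sum() / sxx
    return float(ym + beta * (x0 - xm))

def loess_fit(
    x: np.ndarray,
    y: np.ndarray,
    span: float = 0.3,
    iterations: int = 4,
    eval_x: np.ndarray | None = None,
    max_fit_points: int = 20000,
    n_anchors: int = 200,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Robust locally weighted linear regression of y on x.

    Returns the fitted trend evaluated at ``eval_x`` (default: at ``x``).
    At each evaluation point the span-fraction nearest neighbors get
    tricube distance weights and a weighted linear fit; ``iterations``
    bisquare reweighting passes downweight outliers. For speed the trend is
    fitted exactly at up to ``n_anchors`` quantile anchor points and
    linearly interpolated in between whenever there are more evaluation
    points than anchors; above ``max_fit_points`` probes the fit uses a
    seeded random subsample (the trend is smooth in A, so subsampling
    changes it negligibly).
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    eval_x = x if eval_x is None else np.asarray(eval_x, dtype=float)

    if len(x) > max_fit_points:
        rng = rng or np.random.default_rng(0)
        idx = rng.choice(len(x), size=max_fit_points, replace=False)
        x, y = x[idx], y[idx]

    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n = len(xs)
    k = max(2, int(np.ceil(span * n)))

    if len(eval_x) > n_anchors and n > n_anchors:
        qs = np.linspace(0.0, 1.0, n_anchors)
        fit_x = np.unique(np.quantile(xs, qs))
    else:
        # exact mode: fit at every data point too, so the robustness
        # weights use exact (not interpolated) residuals
        fit_x = np.unique(np.concatenate([xs, np.asarray(eval_x, dtype=float)]))

    rw = np.ones(n)
    fitted_at_anchor = np.zeros(len(fit_x))
    for it in range(iterations + 1):
        for i, x0 in enumerate(fit_x):
            a, b = _neighbor_window(xs, x0, k)
            xw, yw = xs[a:b], ys[a:b]
            d = np.abs(xw - x0)
            dmax = d.max()
            w = (_tricube(d / dmax) if dmax > 0 else np.ones_like(d)) * rw[a:b]
            fitted_at_anchor[i] = _local_linear(xw, yw, w, x0)
        if it < iterations:
            yhat = np.interp(xs, fit_x, fitted_at_anchor)
            resid = ys - yhat
            s = np.median(np.abs(resid))
            if s <= 0:
                break
            rw = np.clip(1.0 - (resid / (6.0 * s)) ** 2, 0.0, None) ** 2
    return np.interp(eval_x, fit_x, fitted_at_anchor)


@dataclass
class NormalizedArray:
    """Per-probe normalized M values for one array.

    ``data`` holds probe_id, M (trend-removed, possibly MAD-scaled) and A.
    """

    data: pd.DataFrame
    label: str = ""
    n_dropped: int = 0
    scale_factor: float = 1.0
    pre_mad: float = float("nan")
    post_mad: float = float("nan")


def loess_normalize(
    table: pd.DataFrame,
    span: float = 0.3,
    iterations: int = 4,
    label: str = "",
    min_probes: int = 50,
    rng: np.random.Generator | None = None,
) -> NormalizedArray:
    """Loess-normalize one two-color array: M' = M - fhat(A)."""
    ma, n_dropped = compute_ma(table)
    if len(ma) < min_probes:
        raise InsufficientDataError(
            f"array {label!r}: {len(ma)} finite probes, need >= {min_probes}"
        )
    trend = loess_fit(ma["A"].to_numpy(), ma["M"].to_numpy(), span=span,
                      iterations=iterations, rng=rng)
    out = pd.DataFrame(
        {"probe_id": ma["probe_id"], "M": ma["M"].to_numpy() - trend, "A": ma["A"]}
    )
    m = mad(out["M"].to_numpy())
    return NormalizedArray(data=out, label=label, n_dropped=n_dropped,
                           pre_mad=m, post_mad=m)


def mad_scale(arrays: list[NormalizedArray]) -> list[NormalizedArray]:
    """Scale every array to the median of the arrays' MADs.

    Multiplicative, so probe ranking, signs and zeros are untouched.
    """
    mads = [mad(a.data["M"].to_numpy()) for a in arrays]
    for a, m in zip(arrays, mads):
        if m <= 0:
            raise DegenerateArrayError(f"array {a.label!r} has zero MAD")
    target = float(np.median(mads))
    out = []
    for a, m in zip(arrays, mads):
        factor = target / m
        data = a.data.copy()
        data["M"] = data["M"].to_numpy() * factor
        out.append(
            NormalizedArray(
                data=data,
                label=a.label,
                n_dropped=a.n_dropped,
                scale_factor=factor,
                pre_mad=m,
                post_mad=mad(data["M"].to_numpy()),
            )
        )
    return out


# ---------------------------------------------------------------------------
# one-color: quantile normalization and median polish
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common distribution (mean of the sorted
    columns); ties within a column share the mean of their would-be
    quantiles. Missing cells are rank-skipped with a warning."""
    if matrix.shape[1] == 1:
        warnings.warn("quantile_normalize: single column, returned unchanged")
        return matrix.copy()
    vals = matrix.to_numpy(dtype=float)
    n = vals.shape[0]
    if np.isnan(vals).any():
        warnings.warn("quantile_normalize: missing cells handled by rank skipping")
        # reference distribution from per-column quantiles of observed values
        grid = (np.arange(1, n + 1) - 0.5) / n
        cols_q = [
            np.quantile(col[~np.isnan(col)], grid) for col in vals.T
        ]
        ref = np.mean(cols_q, axis=0)
        out = np.full_like(vals, np.nan)
        for j in range(vals.shape[1]):
            col = vals[:, j]
            obs = ~np.isnan(col)
            m = obs.sum()
            ranks = pd.Series(col[obs]).rank(method="average").to_numpy()
            p = (ranks - 0.5) / m
            out[obs, j] = np.interp(p, grid, ref)
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    ref = np.sort(vals, axis=0).mean(axis=1)
    ranks = pd.DataFrame(vals).rank(method="average").to_numpy()
    out = np.interp(ranks, np.arange(1, n + 1), ref)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def median_polish(
    x: np.ndarray, tol: float = 1e-6, max_iter: int = 20
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey's median polish of a (..., rows, cols) stack of matrices.

    Alternating row/column median sweeps until the largest absolute change
    in the residuals falls below ``tol`` or ``max_iter`` sweeps. Returns
    (overall, row effects, column effects, residuals); the leading axes are
    broadcast, so many same-shape matrices polish in one call.
    """
    resid = np.asarray(x, dtype=float).copy()
    overall = np.zeros(resid.shape[:-2])
    row = np.zeros(resid.shape[:-1])
    col = np.zeros(resid.shape[:-2] + (resid.shape[-1],))
    for _ in range(max_iter):
        before = resid.copy()
        rdelta = np.median(resid, axis=-1)
        resid -= rdelta[..., None]
        row += rdelta
        delta = np.median(col, axis=-1)
        col -= delta[..., None]
        overall = overall + delta
        cdelta = np.median(resid, axis=-2)
        resid -= cdelta[..., None, :]
        col += cdelta
        delta = np.median(row, axis=-1)
        row -= delta[..., None]
        overall = overall + delta
        if np.max(np.abs(resid - before)) < tol:
            break
    return overall, row, col, resid


def median_polish_summarize(
    matrix: np.ndarray, tol: float = 1e-6, max_iter: int = 20
) -> np.ndarray:
    """Per-sample summary of a probes x samples matrix: overall effect plus
    the sample's column effect. A single-probe transcript summarizes to its
    own values."""
    overall, _, col, _ = median_polish(np.atleast_2d(matrix), tol=tol, max_iter=max_iter)
    return overall[..., None] + col
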