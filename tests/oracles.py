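"""Independent brute-force reference implementations used as test oracles.

Everything here is written naively (explicit loops, textbook definitions)
and never calls the package's own fast paths.
"""

from __future__ import annotations

import numpy as np


def brute_force_loess(x, y, span, iterations, eval_points):
    """Naive robust locally weighted linear regression.

    Per evaluation point: take the ceil(span*n) nearest neighbors by
    absolute distance, tricube-weight them, and solve the weighted linear
    least-squares fit with lstsq. Robustifying passes recompute the fit at
    every data point, then bisquare-downweight by residual.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    k = max(2, int(np.ceil(span * n)))

    def fit_at(x0, rw):
        d = np.abs(x - x0)
        idx = np.argsort(d, kind="stable")[:k]
        dmax = d[idx].max()
        u = d[idx] / dmax if dmax > 0 else np.zeros(k)
        w = (1 - np.clip(u, 0, 1) ** 3) ** 3 * rw[idx]
        sw = np.sqrt(w)
        A = np.column_stack([np.ones(k), x[idx]]) * sw[:, None]
        b = y[idx] * sw
        coef, *_ = np.linalg.lstsq(A, b, rcond=None)
        return coef[0] + coef[1] * x0

    rw = np.ones(n)
    for it in range(iterations + 1):
        if it < iterations:
            resid = y - np.array([fit_at(xi, rw) for xi in x])
            s = np.median(np.abs(resid))
            if s <= 0:
                break
            rw = np.clip(1 - (resid / (6 * s)) ** 2, 0, None) ** 2
    return np.array([fit_at(x0, rw) for x0 in eval_points])


def brute_force_bh(p):
    """Definitional BH step-up: adj p_(i) = min_{j>=i} m*p_(j)/j, cap 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    for i in range(m):
        adj_sorted[i] = min(
            min(m * p[order[j]] / (j + 1) for j in range(i, m)), 1.0
        )
    out = np.empty(m)
    for rank, idx in enumerate(order):
        out[idx] = adj_sorted[rank]
    return out


def median_polish_sweeps(x, n_sweeps):
    """Sweep-by-sweep median polish with explicit loops.

    Sweep order matches the documented algorithm: row medians, re-center
    column effects, column medians, re-center row effects.
    """
    resid = [list(map(float, row)) for row in x]
    nr, nc = len(resid), len(resid[0])
    overall, row, col = 0.0, [0.0] * nr, [0.0] * nc

    def med(v):
        s = sorted(v)
        h = len(s) // 2
        return s[h] if len(s) % 2 else 0.5 * (s[h - 1] + s[h])

    for _ in range(n_sweeps):
        for i in range(nr):
            d = med(resid[i])
            row[i] += d
            for j in range(nc):
                resid[i][j] -= d
        d = med(col)
        overall += d
        for j in range(nc):
            col[j] -= d
        for j in range(nc):
            d = med([resid[i][j] for i in range(nr)])
            col[j] += d
            for i in range(nr):
                resid[i][j] -= d
        d = med(row)
        overall += d
        for i in range(nr):
            row[i] -= d
    return overall, row, col, resid


def brute_force_window_membership(promoters, probes, lo, hi):
    """All (gene_id, probe_id) pairs whose probe midpoint falls in the
    transcription-axis window [lo, hi), by scanning every pair."""
    hits = set()
    for _, pr in promoters.iterrows():
        for _, pb in probes.iterrows():
            if pb["chrom"] != pr["chrom"]:
                continue
            mid = (pb["start"] + pb["end"]) / 2.0
            t = mid - pr["tss"] if pr["strand"] == "+" else pr["tss"] - mid
            if lo <= t < hi:
                hits.add((pr["gene_id"], pb["probe_id"]))
    return hits


def brute_force_peak_overlap(windows, peaks):
    """windows: list of (chrom, start, end); peaks likewise. Returns the
    boolean hit vector by checking every pair (half-open overlap >=1bp)."""
    out = []
    for wc, ws, we in windows:
        hit = False
        for pc, ps, pe in peaks:
            if pc == wc and ps < we and pe > ws:
                hit = True
                break
        out.append(hit)
    return out
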