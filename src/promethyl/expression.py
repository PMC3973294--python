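"""One-color expression analysis with moderated-t contrasts and Group 1-6
pattern assignment.

Per transcript an ordinary least-squares one-way model over the five
conditions (parent; hTERT and TSR lines at 50 and 100 pd) yields contrast
log-ratios M and a residual variance s_g^2 on d_g degrees of freedom.
Variances are moderated empirical-Bayes style: a scaled inverse-chi-square
prior (d0, s0^2) is estimated from all transcripts by matching the first
two moments of log s_g^2 to the theoretical log-F model, and the posterior
variance s~_g^2 = (d0*s0^2 + d_g*s_g^2)/(d0 + d_g) drives a t statistic
with d0 + d_g degrees of freedom. P-values are Benjamini-Hochberg
adjusted; a transcript is differential when FDR < 0.05 and the linear fold
change is at least 3 (both config-exposed).

Group semantics (all relative to the parental line):
  1 up in both derived lines, expressed in parent ("upregulated")
  2 up in both derived lines, not detected in parent ("activated")
  3 down in both derived lines
  4 down in hTERT at 100 pd but not in TSR
  5 up in TSR vs both parent and hTERT
  6 up in hTERT, with TSR at parent-comparable level
Groups 4-6 additionally require the hTERT-vs-TSR (transformation) contrast
itself to be significant, and are only evaluated for transcripts outside
Groups 1-3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from promethyl.normalization import median_polish_summarize, quantile_normalize

CONDITIONS = ("parent", "hTERT_50", "hTERT_100", "TSR_50", "TSR_100")

#: contrasts the group logic needs, as condition-coefficient mappings
DEFAULT_CONTRASTS: dict[str, dict[str, float]] = {
    "hTERT_50-parent": {"hTERT_50": 1, "parent": -1},
    "hTERT_100-parent": {"hTERT_100": 1, "parent": -1},
    "TSR_50-parent": {"TSR_50": 1, "parent": -1},
    "TSR_100-parent": {"TSR_100": 1, "parent": -1},
    "TSR_100-hTERT_100": {"TSR_100": 1, "hTERT_100": -1},
}


class RankDeficientDesignError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Transcripts x arrays log2 summary values plus the array->condition
    map (a Series indexed by array label)."""

    values: pd.DataFrame
    conditions: pd.Series

    def __post_init__(self) -> None:
        counts = self.conditions.value_counts()
        if (counts < 2).any():
            bad = counts[counts < 2].index.tolist()
            raise ValueError(f"conditions with < 2 replicates: {bad}")


def summarize_transcripts(
    probe_values: pd.DataFrame,
    probe_to_transcript: pd.Series,
    conditions: pd.Series,
    already_log2: bool = False,
) -> ExpressionMatrix:
    """Quantile-normalize probe intensities across arrays, then summarize
    each transcript's probes into one log2 value per array by median
    polish. ``probe_values``: probes x arrays raw intensities."""
    vals = probe_values if already_log2 else np.log2(probe_values)
    norm = quantile_normalize(pd.DataFrame(vals))
    out = {}
    groups = probe_to_transcript.reindex(norm.index)
    # batch transcripts by probe count so each batch polishes as one 3-D stack
    by_tx = norm.groupby(groups).indices
    sizes: dict[int, list] = {}
    for tx, idx in by_tx.items():
        sizes.setdefault(len(idx), []).append(tx)
    for size, txs in sizes.items():
        stack = np.stack([norm.iloc[by_tx[tx]].to_numpy() for tx in txs])
        summaries = median_polish_summarize(stack)
        for tx, row in zip(txs, summaries):
            out[tx] = row
    values = pd.DataFrame.from_dict(out, orient="index", columns=norm.columns)
    values = values.sort_index()
    return ExpressionMatrix(values=values, conditions=conditions)


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------

def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if -dif / y < 1e-10:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment estimator of the scaled inverse-chi-square variance prior
    (d0, s0^2) from per-transcript sample variances on df degrees of
    freedom, via the distribution of log s^2. A non-positive excess
    variance of log s^2 means the variances are consistent with a single
    common value: d0 = inf and s0^2 the common variance. Degenerate input
    (non-finite moments) falls back to d0 = 0 (no moderation) with a
    warning."""
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    if ok.sum() < 2:
        warnings.warn("variance prior: too few positive variances; no moderation")
        return 0.0, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if not np.isfinite(emean) or not np.isfinite(evar):
        warnings.warn("variance prior: non-finite moments; no moderation")
        return 0.0, float(np.exp(np.median(z)))
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * trigamma_inverse(evar)
    s02 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s02


def squeeze_variances(s2: np.ndarray, df: float, d0: float, s02: float) -> np.ndarray:
    """Posterior variances s~^2 = (d0*s0^2 + df*s^2)/(d0 + df)."""
    if np.isinf(d0):
        return np.full_like(np.asarray(s2, dtype=float), s02)
    if d0 == 0:
        return np.asarray(s2, dtype=float)
    return (d0 * s02 + df * np.asarray(s2, dtype=float)) / (d0 + df)


@dataclass
class ExpressionStats:
    """Per-transcript contrast statistics.

    coef/t/p/padj: transcripts x contrasts DataFrames; fold: signed linear
    fold change (2^|M| with the sign of M); s2/df: residual variances and
    their df; d0/s02: the fitted variance prior.
    """

    coef: pd.DataFrame
    t: pd.DataFrame
    p: pd.DataFrame
    padj: pd.DataFrame
    fold: pd.DataFrame
    s2: pd.Series
    df: float
    d0: float
    s02: float
    s2_post: pd.Series = field(default=None)


def fit_contrasts(
    matrix: ExpressionMatrix,
    contrasts: dict[str, dict[str, float]] | None = None,
    d0_override: float | None = None,
) -> ExpressionStats:
    """OLS condition-means model per transcript + moderated-t contrasts.

    ``d0_override`` pins the prior df (0 recovers the ordinary t; inf
    fully shrinks every variance to s0^2), mainly for validation.
    """
    contrasts = contrasts or DEFAULT_CONTRASTS
    conds = list(dict.fromkeys(matrix.conditions))
    arrays = list(matrix.values.columns)
    X = np.zeros((len(arrays), len(conds)))
    for i, a in enumerate(arrays):
        X[i, conds.index(matrix.conditions[a])] = 1.0
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        empty = [c for j, c in enumerate(conds) if X[:, j].sum() == 0]
        raise RankDeficientDesignError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"empty/collinear condition columns: {empty or conds}"
        )
    Y = matrix.values.to_numpy(dtype=float)
    n, p = X.shape
    df = n - p
    if df < 1:
        raise ValueError("no residual degrees of freedom")
    XtXinv = np.linalg.inv(X.T @ X)
    B = Y @ X @ XtXinv  # G x p condition means
    resid = Y - B @ X.T
    s2 = (resid**2).sum(axis=1) / df

    if d0_override is not None:
        d0 = float(d0_override)
        _, s02 = fit_variance_prior(s2, df)
        if d0 == 0:
            s02 = float(np.median(s2))
    else:
        d0, s02 = fit_variance_prior(s2, df)
    s2_post = squeeze_variances(s2, df, d0, s02)

    coef, tstat, pval, fold = {}, {}, {}, {}
    total_df = df + d0 if np.isfinite(d0) else np.inf
    for name, spec in contrasts.items():
        c = np.zeros(p)
        for cond, w in spec.items():
            if cond not in conds:
                raise KeyError(f"contrast {name!r}: unknown condition {cond!r}")
            c[conds.index(cond)] = w
        m = B @ c
        unit = float(c @ XtXinv @ c)
        se = np.sqrt(s2_post * unit)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = m / se
        if np.isfinite(total_df):
            pv = 2.0 * stats.t.sf(np.abs(t), total_df)
        else:
            pv = 2.0 * stats.norm.sf(np.abs(t))
        coef[name], tstat[name], pval[name] = m, t, pv
        fold[name] = np.sign(m) * 2.0 ** np.abs(m)
    idx = matrix.values.index
    coef = pd.DataFrame(coef, index=idx)
    tstat = pd.DataFrame(tstat, index=idx)
    pval = pd.DataFrame(pval, index=idx)
    padj = pval.apply(lambda col: pd.Series(bh_adjust(col.to_numpy()), index=idx))
    fold = pd.DataFrame(fold, index=idx)
    return ExpressionStats(
        coef=coef, t=tstat, p=pval, padj=padj, fold=fold,
        s2=pd.Series(s2, index=idx), df=float(df), d0=float(d0), s02=float(s02),
        s2_post=pd.Series(s2_post, index=idx),
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj p_(i) = min_{j >= i} (m * p_(j) / j), capped at 1; returned in the
    input order, stable under reordering.
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def call_de(
    stats_: ExpressionStats, fold_threshold: float = 3.0, fdr_threshold: float = 0.05
) -> pd.DataFrame:
    """Significance flags: FDR < fdr_threshold AND |linear fold| >=
    fold_threshold (fold boundary inclusive)."""
    return (stats_.padj < fdr_threshold) & (stats_.fold.abs() >= fold_threshold)


def detect_expressed(matrix: ExpressionMatrix, detection_percentile: float = 25.0) -> pd.DataFrame:
    """Detection status per transcript per condition.

    The detection floor is the mean over arrays of each array's
    ``detection_percentile``-th value; a transcript is expressed in a
    condition iff its mean log2 summary there exceeds the floor.
    """
    floor = float(
        np.mean(np.percentile(matrix.values.to_numpy(), detection_percentile, axis=0))
    )
    cond_means = matrix.values.T.groupby(matrix.conditions).mean().T
    return cond_means > floor


def assign_groups(
    stats_: ExpressionStats,
    matrix: ExpressionMatrix,
    fold_threshold: float = 3.0,
    fdr_threshold: float = 0.05,
    detection_percentile: float = 25.0,
) -> pd.Series:
    """Group 1-6 labels per transcript ('none' when no pattern applies)."""
    sig = call_de(stats_, fold_threshold, fdr_threshold)
    up = sig & (stats_.coef > 0)
    down = sig & (stats_.coef < 0)
    detected = detect_expressed(matrix, detection_percentile)

    up_h = up["hTERT_100-parent"]
    up_t = up["TSR_100-parent"]
    down_h = down["hTERT_100-parent"]
    down_t = down["TSR_100-parent"]
    trans_sig = sig["TSR_100-hTERT_100"]
    trans_up = up["TSR_100-hTERT_100"]

    immortal_up = up_h & up_t
    immortal_down = down_h & down_t
    in_parent = detected["parent"]

    labels = pd.Series("none", index=stats_.coef.index)
    labels[immortal_up & in_parent] = "1"
    labels[immortal_up & ~in_parent] = "2"
    labels[immortal_down & ~immortal_up] = "3"

    free = labels == "none"
    tsr_near_parent = stats_.fold["TSR_100-parent"].abs() < fold_threshold
    g4 = free & trans_sig & down_h & ~down_t
    labels[g4] = "4"
    free = labels == "none"
    g5 = free & trans_sig & trans_up & up_t
    labels[g5] = "5"
    free = labels == "none"
    g6 = free & trans_sig & up_h & tsr_near_parent
    labels[g6] = "6"
    return labels
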