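"""Promoter chromatin states from ChIP/input arrays and external peak sets.

ChIP-chip arrays (e.g. H3ac, H3K27me3 in the parental line) are scored by
the same normalize/aggregate pipeline as the methylation arrays; a promoter
is *marked* for a modification when its core-window median log2 ChIP/input
reaches the enrichment threshold. Externally mapped modifications (e.g.
H3K4me3/H3K36me3 peak calls from a related fibroblast line) contribute
boolean presence by >=1 bp overlap with the core window. The composition of
a promoter set over the primary states {K27me3-marked, H3ac-marked,
neither} uses K27me3 > H3ac precedence so the three states partition the
set; bivalent promoters are also counted separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from promethyl.annotation import ProbeAssignment, WindowSpec
from promethyl.methylation import MethylationConfig, aggregate_promoter_scores
from promethyl.normalization import NormalizedArray


@dataclass
class ChromatinProfile:
    """scores: promoters x modifications median log2 ChIP/input; marked:
    boolean calls at the enrichment threshold; presence: boolean overlap
    with external peak sets."""

    scores: pd.DataFrame
    marked: pd.DataFrame
    presence: pd.DataFrame | None = None
    threshold: float = 1.0


def score_chip_promoters(
    arrays: dict[str, NormalizedArray],
    assignment: ProbeAssignment,
    theta_chip: float = 1.0,
    min_probes: int = 3,
    promoter_order: list[str] | None = None,
) -> ChromatinProfile:
    """Median core-window log2 ChIP/input per promoter per modification;
    marked iff score >= theta_chip (boundary inclusive)."""
    cfg = MethylationConfig(cutoff=max(theta_chip, 1e-9), min_probes=min_probes)
    scores = aggregate_promoter_scores(arrays, assignment, cfg,
                                       promoter_order=promoter_order).core
    marked = scores.ge(theta_chip) & scores.notna()
    return ChromatinProfile(scores=scores, marked=marked, threshold=theta_chip)


def annotate_with_peaks(
    promoters: pd.DataFrame,
    peaks: dict[str, pd.DataFrame],
    spec: WindowSpec | None = None,
) -> pd.DataFrame:
    """Presence matrix: promoter x modification, True iff any peak interval
    overlaps the promoter's core window by >= 1 bp (half-open arithmetic)."""
    spec = spec or WindowSpec()
    win = promoters.apply(
        lambda r: spec.genomic_interval(int(r["tss"]), r["strand"], "core"), axis=1
    )
    w_start = np.array([w[0] for w in win])
    w_end = np.array([w[1] for w in win])
    chroms = promoters["chrom"].to_numpy()
    out = pd.DataFrame(False, index=promoters["gene_id"].to_numpy(),
                       columns=list(peaks.keys()))
    for mod, bed in peaks.items():
        hit = np.zeros(len(promoters), dtype=bool)
        for chrom, sub in bed.groupby("chrom", sort=False):
            sel = chroms == chrom
            if not sel.any():
                continue
            ps = np.sort(sub["start"].to_numpy())
            pe_sorted_by_start = sub.sort_values("start")["end"].to_numpy()
            cummax_end = np.maximum.accumulate(pe_sorted_by_start)
            ws, we = w_start[sel], w_end[sel]
            # candidate peaks: start < window end; overlap iff some such
            # peak also has end > window start, i.e. running max end > start
            k = np.searchsorted(ps, we, side="left")
            has = np.zeros(len(ws), dtype=bool)
            nz = k > 0
            has[nz] = cummax_end[k[nz] - 1] > ws[nz]
            hit[sel] = has
        out[mod] = hit
    return out


@dataclass
class ChromatinComposition:
    """Counts and percentages of the primary chromatin states over a
    promoter set, plus H3K36me3 overlap and bivalent counts."""

    n_total: int
    counts: dict[str, int] = field(default_factory=dict)
    percentages: dict[str, float] = field(default_factory=dict)
    bivalent_count: int = 0
    k36_count: int | None = None
    k36_percentage: float | None = None


def compose_states(
    promoter_set,
    profile: ChromatinProfile,
    k27_col: str = "H3K27me3",
    ac_col: str = "H3ac",
    k36_col: str = "H3K36me3",
) -> ChromatinComposition:
    """Partition a promoter set into {K27me3, H3ac, neither} with K27me3
    precedence; also report the (independent) H3K36me3 overlap fraction.

    Percentages are 100 * count / |set| and the three primary states sum
    to 100 up to rounding. An empty set yields an empty composition.
    """
    members = sorted(promoter_set)
    comp = ChromatinComposition(n_total=len(members))
    if not members:
        comp.counts = {"K27me3": 0, "H3ac": 0, "neither": 0}
        comp.percentages = {}
        return comp
    missing = [g for g in members if g not in profile.marked.index]
    if missing:
        raise KeyError(f"profile does not cover promoters {missing[:3]}...")
    k27 = profile.marked.loc[members, k27_col].to_numpy(dtype=bool)
    ac = profile.marked.loc[members, ac_col].to_numpy(dtype=bool)
    n = len(members)
    n_k27 = int(k27.sum())
    n_ac_only = int((ac & ~k27).sum())
    n_neither = n - n_k27 - n_ac_only
    comp.counts = {"K27me3": n_k27, "H3ac": n_ac_only, "neither": n_neither}
    comp.percentages = {k: 100.0 * v / n for k, v in comp.counts.items()}
    comp.bivalent_count = int((k27 & ac).sum())
    if profile.presence is not None and k36_col in profile.presence.columns:
        k36 = profile.presence.loc[members, k36_col].to_numpy(dtype=bool)
        comp.k36_count = int(k36.sum())
        comp.k36_percentage = 100.0 * comp.k36_count / n
    return comp


def zscore_matrix(matrix: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Column-wise Z-scores ((x - mean)/sd, population sd by default, set
    ddof=1 for the sample convention); a zero-variance column becomes all
    zeros with a warning."""
    vals = matrix.to_numpy(dtype=float)
    mean = np.nanmean(vals, axis=0)
    sd = np.nanstd(vals, axis=0, ddof=ddof)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"zscore_matrix: zero-variance columns {list(matrix.columns[zero])} set to 0"
        )
    sd = np.where(zero, 1.0, sd)
    z = (vals - mean) / sd
    z[:, zero] = 0.0
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
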