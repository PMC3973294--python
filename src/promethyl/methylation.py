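"""Promoter-level methylation scoring, differential calls and timing classes.

Normalized, MAD-scaled probe log2 MAP/input values are aggregated into a
single median per promoter window; a promoter gains methylation in a
derived line when its score exceeds the parental score by at least the
log2 cutoff (default 1, i.e. a 2-fold change in enrichment). Per line the
two sampled timepoints (50 and 100 population doublings) give a timing
class: *early* (gained by 50 pd and maintained), *late* (gained between 50
and 100 pd), *loss*, *stable*, or *inconsistent* (gained at 50 pd but not
at 100 pd, which violates maintenance of established methylation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from promethyl.annotation import ProbeAssignment
from promethyl.normalization import NormalizedArray

SAMPLES = ("parent", "hTERT_50", "hTERT_100", "TSR_50", "TSR_100")
LINES = {"hTERT": ("hTERT_50", "hTERT_100"), "TSR": ("TSR_50", "TSR_100")}


@dataclass(frozen=True)
class MethylationConfig:
    """cutoff: minimal promoter-level log2 difference vs the reference
    (boundary inclusive); min_probes: windows with fewer probes score as
    missing; reference: the parental sample label."""

    cutoff: float = 1.0
    min_probes: int = 3
    reference: str = "parent"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")


def cutoff_fold_change(cutoff: float = 1.0) -> float:
    """Linear fold change in methylation enrichment corresponding to a
    log2 score cutoff (cutoff 1 <-> 2-fold)."""
    return float(2.0**cutoff)


@dataclass
class PromoterScoreMatrix:
    """Window-median log2 enrichment scores per promoter and sample.

    ``core``/``upstream``: promoters x samples DataFrames (NaN = missing,
    never 0); ``core_counts``/``upstream_counts``: contributing probe
    numbers.
    """

    core: pd.DataFrame
    upstream: pd.DataFrame
    core_counts: pd.DataFrame
    upstream_counts: pd.DataFrame


def aggregate_promoter_scores(
    arrays: dict[str, NormalizedArray],
    assignment: ProbeAssignment,
    config: MethylationConfig | None = None,
    promoter_order: list[str] | None = None,
) -> PromoterScoreMatrix:
    """Median of core-window probe M values per promoter per sample (ditto
    for the upstream window). Windows with fewer than ``min_probes``
    contributing probes are marked missing (NaN)."""
    config = config or MethylationConfig()
    probe_m = pd.DataFrame(
        {label: a.data.set_index("probe_id")["M"] for label, a in arrays.items()}
    )
    samples = list(arrays.keys())
    merged = assignment.table.merge(
        probe_m, left_on="probe_id", right_index=True, how="inner"
    )
    grouped = merged.groupby(["window", "gene_id"], sort=False)
    med = grouped[samples].median()
    cnt = grouped[samples].count()

    if promoter_order is None:
        promoter_order = sorted(
            pd.unique(assignment.table["gene_id"]).tolist()
            + assignment.no_core_probes
        )
        promoter_order = list(dict.fromkeys(promoter_order))

    def _take(window: str, frame: pd.DataFrame, fill) -> pd.DataFrame:
        if window in frame.index.get_level_values(0):
            sub = frame.loc[window]
        else:
            sub = pd.DataFrame(columns=samples, dtype=float)
        out = sub.reindex(promoter_order)
        return out if fill is None else out.astype(float).fillna(fill)

    core = _take("core", med, None)
    upstream = _take("upstream", med, None)
    core_counts = _take("core", cnt, 0).astype(int)
    upstream_counts = _take("upstream", cnt, 0).astype(int)
    core = core.mask(core_counts < config.min_probes)
    upstream = upstream.mask(upstream_counts < config.min_probes)
    core.index.name = upstream.index.name = "gene_id"
    return PromoterScoreMatrix(core, upstream, core_counts, upstream_counts)


@dataclass
class DifferentialCalls:
    """Per-promoter, per-sample state vs the reference.

    ``delta``: score - reference score; ``calls``: one of
    {'gain', 'loss', 'none', 'no_call'} (missing scores give 'no_call')."""

    delta: pd.DataFrame
    calls: pd.DataFrame
    reference: str
    cutoff: float


def call_differential(
    scores: pd.DataFrame, config: MethylationConfig | None = None
) -> DifferentialCalls:
    """Threshold each sample's promoter scores against the reference.

    gain iff delta >= cutoff; loss iff delta <= -cutoff (boundaries
    inclusive); otherwise none; missing scores propagate to 'no_call'.
    """
    config = config or MethylationConfig()
    if config.reference not in scores.columns:
        raise KeyError(f"reference sample {config.reference!r} not in score matrix")
    ref = scores[config.reference]
    others = [c for c in scores.columns if c != config.reference]
    delta = scores[others].sub(ref, axis=0)
    calls = pd.DataFrame("none", index=delta.index, columns=delta.columns)
    calls = calls.mask(delta >= config.cutoff, "gain")
    calls = calls.mask(delta <= -config.cutoff, "loss")
    calls = calls.mask(delta.isna(), "no_call")
    return DifferentialCalls(delta=delta, calls=calls, reference=config.reference,
                             cutoff=config.cutoff)


@dataclass
class TrajectoryResult:
    """Timing classification per promoter and cell line.

    ``table`` columns: per line '<line>_class', plus delta columns
    'd50_<line>', 'd100_<line>' and a cross-line 'consensus'
    ({'shared', 'hTERT-only', 'TSR-only', 'none'}). ``de_novo``: per-line
    de novo (early|late) promoter sets plus their union/intersection.
    ``line_comparison``: hTERT-vs-TSR score differences at matched pd and
    the count exceeding the cutoff (the 'no significant differences
    between lines' check).
    """

    table: pd.DataFrame
    de_novo: dict[str, set] = field(default_factory=dict)
    line_comparison: pd.DataFrame | None = None


def _line_class(call50: str, call100: str) -> str:
    if call50 == "no_call" or call100 == "no_call":
        return "no_call"
    if call100 == "loss" or (call50 == "loss" and call100 != "gain"):
        return "loss"
    if call50 == "gain" and call100 == "gain":
        return "early"
    if call100 == "gain":
        return "late"
    if call50 == "gain":
        return "inconsistent"
    return "stable"


def classify_trajectories(
    calls: DifferentialCalls,
    config: MethylationConfig | None = None,
    scores: pd.DataFrame | None = None,
    lines: dict[str, tuple[str, str]] | None = None,
) -> TrajectoryResult:
    """Per-line timing classes, cross-line consensus and de-novo sets."""
    config = config or MethylationConfig()
    lines = lines or LINES
    table = pd.DataFrame(index=calls.calls.index)
    for line, (s50, s100) in lines.items():
        table[f"{line}_class"] = [
            _line_class(c50, c100)
            for c50, c100 in zip(calls.calls[s50], calls.calls[s100])
        ]
        table[f"d50_{line}"] = calls.delta[s50]
        table[f"d100_{line}"] = calls.delta[s100]

    line_names = list(lines)
    cls = table[[f"{ln}_class" for ln in line_names]]

    def _consensus(row) -> str:
        non_stable = {ln: row[f"{ln}_class"] for ln in line_names
                      if row[f"{ln}_class"] not in ("stable", "no_call")}
        if not non_stable:
            return "none"
        if len(non_stable) == len(line_names) and len(set(non_stable.values())) == 1:
            return "shared"
        if len(non_stable) == 1:
            return f"{next(iter(non_stable))}-only"
        return "discordant"

    table["consensus"] = [_consensus(row) for _, row in cls.iterrows()]

    de_novo: dict[str, set] = {}
    for ln in line_names:
        de_novo[ln] = set(table.index[table[f"{ln}_class"].isin(("early", "late"))])
    de_novo["union"] = set().union(*(de_novo[ln] for ln in line_names))
    de_novo["intersection"] = set.intersection(*(de_novo[ln] for ln in line_names))

    line_comparison = None
    if scores is not None and len(line_names) == 2:
        a, b = line_names
        rows = {}
        for pd_label, (sa, sb) in zip(("50", "100"),
                                      zip(lines[a], lines[b])):
            d = scores[sa] - scores[sb]
            rows[pd_label] = {
                "mean_delta": float(np.nanmean(d)),
                "n_exceeding_cutoff": int((d.abs() >= config.cutoff).sum()),
            }
        line_comparison = pd.DataFrame(rows).T
    return TrajectoryResult(table=table, de_novo=de_novo, line_comparison=line_comparison)


_CLASS_RANK = {"early": 0, "late": 1, "loss": 2, "inconsistent": 3}


def trajectory_heatmap_matrix(
    result: TrajectoryResult,
    calls: DifferentialCalls,
    lines: dict[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Delta-vs-parent matrix over the de novo union set, deterministically
    ordered by (timing class, mean delta at 100 pd descending, gene id)."""
    lines = lines or LINES
    rows = sorted(result.de_novo.get("union", set()))
    if not rows:
        return pd.DataFrame(columns=list(calls.delta.columns))
    sub = calls.delta.loc[rows]
    cls = result.table.loc[rows]
    line_names = list(lines)
    rank = cls[[f"{ln}_class" for ln in line_names]].apply(
        lambda r: min(_CLASS_RANK.get(v, 9) for v in r), axis=1
    )
    d100 = sub[[lines[ln][1] for ln in line_names]].mean(axis=1)
    order = pd.DataFrame({"rank": rank, "neg_d100": -d100, "gene": rows}, index=rows)
    order = order.sort_values(["rank", "neg_d100", "gene"], kind="stable")
    return sub.loc[order.index]
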