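"""End-to-end recovery benchmarks on ground-truth synthetic data.

These harnesses run the full analysis path (simulate -> normalize ->
aggregate -> call -> classify, or simulate -> quantile/median-polish ->
moderated-t -> groups) and score the result against the generator's truth.
They define the study conditions the package validates itself under; the
per-run metrics are what the acceptance machinery reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from promethyl import expression as xpr
from promethyl.annotation import WindowSpec, assign_probes_to_windows
from promethyl.methylation import (
    MethylationConfig,
    aggregate_promoter_scores,
    call_differential,
    classify_trajectories,
)
from promethyl.normalization import DegenerateArrayError, loess_normalize, mad_scale
from promethyl.simulate import SimulationConfig, generate_annotation, generate_ground_truth, simulate_map_arrays


@dataclass
class MethylationRecovery:
    sensitivity: float
    fdp: float
    timing_accuracy: float
    n_true: int
    n_called: int
    n_inconsistent: int


def run_methylation_pipeline(config: SimulationConfig) -> MethylationRecovery:
    """Simulate MAP arrays under ``config``, run the full methylation
    pipeline, and score the de-novo union set against truth.

    Sensitivity/false-discovery proportion are over the union (across both
    derived lines) of promoters classified early or late; timing accuracy
    is the fraction of correctly recovered promoters whose per-line timing
    class matches the truth label.
    """
    promoters, probes = generate_annotation(config)
    truth = generate_ground_truth(promoters, config)
    arrays = simulate_map_arrays(probes, truth, config)

    rng = np.random.default_rng(config.seed + 10)
    normalized = {
        s: loess_normalize(tbl, label=s, rng=rng) for s, tbl in arrays.items()
    }
    try:
        scaled = mad_scale(list(normalized.values()))
    except DegenerateArrayError:
        # noise-free arrays have zero spread; scaling is then a no-op
        scaled = list(normalized.values())
    scaled_map = {a.label: a for a in scaled}

    assignment = assign_probes_to_windows(promoters, probes, WindowSpec())
    mcfg = MethylationConfig()
    scores = aggregate_promoter_scores(
        scaled_map, assignment, mcfg, promoter_order=list(promoters["gene_id"])
    )
    calls = call_differential(scores.core, mcfg)
    traj = classify_trajectories(calls, mcfg, scores=scores.core)

    called = traj.de_novo["union"]
    true_set = truth.de_novo
    tp = called & true_set
    sensitivity = len(tp) / len(true_set) if true_set else float("nan")
    fdp = len(called - true_set) / len(called) if called else 0.0

    if tp:
        pred = traj.table.loc[sorted(tp), "hTERT_class"]
        truth_lab = truth.promoters.loc[sorted(tp), "hTERT"]
        timing_accuracy = float((pred.to_numpy() == truth_lab.to_numpy()).mean())
    else:
        timing_accuracy = float("nan")
    n_inc = int(
        (traj.table[["hTERT_class", "TSR_class"]] == "inconsistent").to_numpy().sum()
    )
    return MethylationRecovery(
        sensitivity=sensitivity,
        fdp=fdp,
        timing_accuracy=timing_accuracy,
        n_true=len(true_set),
        n_called=len(called),
        n_inconsistent=n_inc,
    )


#: the reference simulation the methylation benchmark runs under:
#: 5000 promoters with 150 early, 150 late and 100 loss events, a
#: 1.5-log2 effect, per-probe noise sd 0.3, 12 probes per window and the
#: default dye-bias/array-spread injection
METHYLATION_BENCHMARK = dict(
    n_promoters=5000,
    frac_early=0.03,
    frac_late=0.03,
    frac_loss=0.02,
    effect_log2=1.5,
    probe_noise_sd=0.3,
    probes_per_window=12,
)


def methylation_recovery_study(
    n_seeds: int = 20, base_seed: int = 0, **overrides
) -> pd.DataFrame:
    """Run the methylation benchmark across seeds; one metrics row each."""
    rows = []
    params = {**METHYLATION_BENCHMARK, **overrides}
    for i in range(n_seeds):
        cfg = SimulationConfig(seed=(base_seed + 1000 * i) % (2**31 - 1), **params)
        r = run_methylation_pipeline(cfg)
        rows.append(vars(r))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionRecovery:
    recovery: float
    spurious: float
    n_true_labelled: int
    n_null: int
    per_group: dict = field(default_factory=dict)


EXPRESSION_BENCHMARK = dict(
    n_transcripts=2000,
    expr_frac_up=0.05,
    expr_frac_activated=0.05,
    expr_frac_down=0.05,
    expr_frac_g4=0.05,
    expr_frac_g5=0.05,
    expr_frac_g6=0.05,
    expr_fold=(4.0, 8.0),
    expr_noise_sd=0.25,
    replicate_count=3,
)


def run_expression_pipeline(config: SimulationConfig) -> ExpressionRecovery:
    """Simulate expression arrays, run normalization/summarization/
    moderated-t/group assignment, and score the Group labels exactly."""
    arrays, sheet, probe_tx, truth = xpr_simulate(config)
    probe_values = pd.DataFrame(
        {row["array"]: arrays[row["array"]].set_index("probe_id")["intensity"]
         for _, row in sheet.iterrows()}
    )
    conditions = pd.Series(sheet["condition"].to_numpy(), index=sheet["array"].to_numpy())
    matrix = xpr.summarize_transcripts(probe_values, probe_tx, conditions)
    stats_ = xpr.fit_contrasts(matrix)
    labels = xpr.assign_groups(stats_, matrix)

    truth_lab = truth["group"].reindex(labels.index)
    labelled = truth_lab != "none"
    null = ~labelled
    recovery = float((labels[labelled] == truth_lab[labelled]).mean())
    spurious = float((labels[null] != "none").mean())
    per_group = {
        g: float((labels[truth_lab == g] == g).mean())
        for g in ("1", "2", "3", "4", "5", "6")
        if (truth_lab == g).any()
    }
    return ExpressionRecovery(
        recovery=recovery,
        spurious=spurious,
        n_true_labelled=int(labelled.sum()),
        n_null=int(null.sum()),
        per_group=per_group,
    )


def xpr_simulate(config: SimulationConfig):
    from promethyl.simulate import simulate_expression_arrays

    return simulate_expression_arrays(config)


def expression_recovery_study(
    n_seeds: int = 20, base_seed: int = 0, **overrides
) -> pd.DataFrame:
    rows = []
    params = {**EXPRESSION_BENCHMARK, **overrides}
    for i in range(n_seeds):
        cfg = SimulationConfig(seed=(base_seed + 1000 * i + 17) % (2**31 - 1), **params)
        r = run_expression_pipeline(cfg)
        rows.append({"recovery": r.recovery, "spurious": r.spurious})
    return pd.DataFrame(rows)


def null_pvalue_ks(
    n_transcripts: int = 500, n_seeds: int = 20, base_seed: int = 0
) -> list[float]:
    """KS statistics (vs uniform) of moderated-t p-values on pure-noise
    data, one per seed: a calibration check on the contrast machinery."""
    out = []
    for i in range(n_seeds):
        cfg = SimulationConfig(
            n_transcripts=n_transcripts,
            expr_frac_up=0.0, expr_frac_activated=0.0, expr_frac_down=0.0,
            expr_frac_g4=0.0, expr_frac_g5=0.0, expr_frac_g6=0.0,
            seed=(base_seed + 31 * i + 5) % (2**31 - 1),
        )
        arrays, sheet, probe_tx, _ = xpr_simulate(cfg)
        probe_values = pd.DataFrame(
            {row["array"]: arrays[row["array"]].set_index("probe_id")["intensity"]
             for _, row in sheet.iterrows()}
        )
        conditions = pd.Series(sheet["condition"].to_numpy(), index=sheet["array"].to_numpy())
        matrix = xpr.summarize_transcripts(probe_values, probe_tx, conditions)
        stats_ = xpr.fit_contrasts(matrix)
        p = stats_.p["hTERT_100-parent"].to_numpy()
        out.append(float(sps.kstest(p, "uniform").statistic))
    return out
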