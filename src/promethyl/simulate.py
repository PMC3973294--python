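"""Ground-truth synthetic data for the promoter methylation/expression
pipeline.

The generator emulates the structure of the study design: five sample
conditions (parent fibroblast line; hTERT-immortalized and
oncogene-transformed derivatives each at 50 and 100 population doublings),
two-color MAP/input promoter arrays with ~12 probes per 1-kb promoter
window, an intensity-dependent dye bias and array-to-array spread
differences, triplicate one-color expression arrays with Group 1-6 effect
patterns, and bisulfite clone sequences. Every draw flows from a single
seed, so identical configs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from promethyl.annotation import CpgClassSpec, classify_cpg_density

SAMPLES = ("parent", "hTERT_50", "hTERT_100", "TSR_50", "TSR_100")
TRAJECTORY_LABELS = ("stable", "early", "late", "loss")
GROUP_LABELS = ("none", "1", "2", "3", "4", "5", "6")


class ConfigError(ValueError):
    pass


class ConsistencyError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic dataset.

    Methylation side: ``frac_early``/``frac_late``/``frac_loss`` set the
    proportions of promoters that gain methylation by 50 pd, between 50
    and 100 pd, or lose it; ``effect_log2`` is the mean log2 MAP/input
    gain at a methylated promoter and ``probe_noise_sd`` the per-probe
    Gaussian noise. ``intensity_bias`` are polynomial coefficients of an
    A-dependent dye-bias curve added to raw M values; ``array_spread``
    multiplies each array's (signal+noise) so raw MADs differ (median 1,
    undone by MAD scaling). Expression side: ``expr_frac_*`` give the
    proportions of transcripts in Groups 1-6 and ``expr_fold`` the linear
    fold-effect range.
    """

    n_promoters: int = 1000
    probes_per_window: int = 12
    samples: tuple[str, ...] = SAMPLES
    frac_early: float = 0.03
    frac_late: float = 0.03
    frac_loss: float = 0.02
    effect_log2: float = 1.5
    probe_noise_sd: float = 0.3
    intensity_bias: tuple[float, ...] = (0.3, 0.06)
    array_spread: tuple[float, ...] = (1.0, 1.15, 0.9, 1.05, 0.95)
    expr_frac_up: float = 0.05
    expr_frac_activated: float = 0.05
    expr_frac_down: float = 0.05
    expr_frac_g4: float = 0.05
    expr_frac_g5: float = 0.05
    expr_frac_g6: float = 0.05
    expr_fold: tuple[float, float] = (4.0, 8.0)
    expr_noise_sd: float = 0.25
    replicate_count: int = 3
    n_transcripts: int | None = None
    probes_per_transcript: int = 4
    cpg_class_probs: tuple[float, float, float] = (0.3, 0.3, 0.4)  # LCP, ICP, HCP
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_promoters <= 0:
            raise ConfigError("n_promoters must be positive")
        if self.probes_per_window < 1:
            raise ConfigError("probes_per_window must be >= 1")
        if self.effect_log2 <= 0:
            raise ConfigError("effect_log2 must be > 0")
        fracs = (self.frac_early, self.frac_late, self.frac_loss,
                 self.expr_frac_up, self.expr_frac_activated, self.expr_frac_down,
                 self.expr_frac_g4, self.expr_frac_g5, self.expr_frac_g6)
        if any(not 0 <= f <= 1 for f in fracs):
            raise ConfigError("all proportions must be in [0, 1]")
        if self.frac_early + self.frac_late + self.frac_loss > 1:
            raise ConfigError("frac_early + frac_late + frac_loss must be <= 1")
        if self.replicate_count < 2:
            raise ConfigError("replicate_count must be >= 2 (contrast fitting needs replication)")
        if isinstance(self.expr_fold, (int, float)):
            self.expr_fold = (float(self.expr_fold), float(self.expr_fold))
        lo, hi = self.expr_fold
        if lo < 1 or hi < lo:
            raise ConfigError("expr_fold must be >= 1 with lo <= hi")


@dataclass
class GroundTruth:
    """Machine-readable truth behind a simulated dataset.

    ``promoters``: gene_id-indexed frame with per-line trajectory labels
    (identical for both derived lines by default, mirroring the observed
    shared behaviour) ; ``true_scores``: promoter x sample noise-free log2
    enrichment; ``transcripts``: transcript_id-indexed frame with the
    Group label and baseline.
    """

    promoters: pd.DataFrame
    true_scores: pd.DataFrame
    transcripts: pd.DataFrame | None = None

    @property
    def de_novo(self) -> set:
        lab = self.promoters["hTERT"]
        return set(lab.index[lab.isin(("early", "late"))])


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

_PROMOTER_SPACING = 10_000
_N_CHROMS = 5
_PROBE_LEN = 50


def generate_annotation(
    config: SimulationConfig, sequences: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame] | tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Promoter annotation and probe layout.

    Promoters are spaced along five synthetic chromosomes with random
    strands; probes (50 bp) tile the transcription axis from -1500 to +500
    with ``probes_per_window`` per 1-kb window, mapped to genomic
    coordinates by reflection on the minus strand. CpG classes are drawn
    per ``cpg_class_probs``; with ``sequences=True`` a 1-kb core-window
    sequence consistent with each promoter's class is generated too.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_promoters
    idx = np.arange(n)
    gene_ids = np.array([f"G{i:05d}" for i in idx])
    chroms = np.array([f"chr{(i % _N_CHROMS) + 1}" for i in idx])
    tss = (_PROMOTER_SPACING * (idx // _N_CHROMS + 1)).astype(int)
    strands = rng.choice(["+", "-"], size=n)
    classes = rng.choice(["LCP", "ICP", "HCP"], size=n, p=config.cpg_class_probs)
    promoters = pd.DataFrame(
        {"gene_id": gene_ids, "chrom": chroms, "tss": tss, "strand": strands,
         "cpg_class": classes}
    )

    ppw = config.probes_per_window
    step = 1000.0 / ppw
    t_centers = np.concatenate(
        [-1500 + (np.arange(ppw) + 0.5) * step, -500 + (np.arange(ppw) + 0.5) * step]
    )
    windows = np.array(["upstream"] * ppw + ["core"] * ppw)
    sign = np.where(strands == "+", 1, -1)
    mids = tss[:, None] + sign[:, None] * t_centers[None, :]
    starts = np.rint(mids).astype(int) - _PROBE_LEN // 2
    probes = pd.DataFrame(
        {
            "probe_id": [f"{g}_p{j:02d}" for g in gene_ids for j in range(2 * ppw)],
            "chrom": np.repeat(chroms, 2 * ppw),
            "start": starts.ravel(),
            "end": starts.ravel() + _PROBE_LEN,
            "gene_id": np.repeat(gene_ids, 2 * ppw),
            "window": np.tile(windows, n),
        }
    )
    if not sequences:
        return promoters, probes
    seqs = {
        g: generate_class_sequence(c, rng=rng)
        for g, c in zip(gene_ids, classes)
    }
    return promoters, probes, seqs


_CLASS_TARGETS = {
    # (CpG obs/exp target, GC fraction target)
    "HCP": (1.0, 0.65),
    "ICP": (0.60, 0.50),
    "LCP": (0.20, 0.45),
}


def generate_class_sequence(
    cpg_class: str,
    length: int = 1000,
    rng: np.random.Generator | None = None,
    spec: CpgClassSpec | None = None,
    max_tries: int = 25,
) -> str:
    """Random sequence whose CpG obs/exp ratio and GC content land in the
    requested density class. Only class consistency is guaranteed, not
    biological realism: a base-composition draw is repaired by planting or
    destroying CpG dinucleotides until the target ratio is hit, then
    verified against the classifier."""
    rng = rng or np.random.default_rng(0)
    ratio_target, gc = _CLASS_TARGETS[cpg_class]
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    for _ in range(max_tries):
        seq = list(rng.choice(list("ACGT"), size=length, p=p))
        n_c = seq.count("C")
        n_g = seq.count("G")
        target_cpg = max(1, int(round(ratio_target * n_c * n_g / length)))

        def cpg_positions() -> list[int]:
            return [i for i in range(length - 1) if seq[i] == "C" and seq[i + 1] == "G"]

        pos = cpg_positions()
        guard = 0
        while len(pos) != target_cpg and guard < 5 * length:
            guard += 1
            if len(pos) < target_cpg:
                i = int(rng.integers(0, length - 1))
                if (seq[i], seq[i + 1]) != ("C", "G"):
                    seq[i], seq[i + 1] = "C", "G"
            else:
                i = pos[int(rng.integers(0, len(pos)))]
                seq[i] = "T"
            pos = cpg_positions()
        cand = "".join(seq)
        if classify_cpg_density(cand, spec) == cpg_class:
            return cand
    raise RuntimeError(f"could not generate a {cpg_class} sequence in {max_tries} tries")


# ---------------------------------------------------------------------------
# ground truth and MAP arrays
# ---------------------------------------------------------------------------

def generate_ground_truth(promoters: pd.DataFrame, config: SimulationConfig) -> GroundTruth:
    """Trajectory labels and noise-free promoter scores.

    Early and late labels are shared between the hTERT and TSR lineages
    (the default behaviour the analysis is meant to recover); counts are
    round(frac * n). Noise-free scores: 0 when unmethylated,
    ``effect_log2`` when methylated, with early promoters methylated at
    both derived timepoints, late ones only at 100 pd, and loss promoters
    methylated only in the parent.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = len(promoters)
    genes = promoters["gene_id"].to_numpy()
    n_early = int(round(config.frac_early * n))
    n_late = int(round(config.frac_late * n))
    n_loss = int(round(config.frac_loss * n))
    perm = rng.permutation(n)
    labels = np.array(["stable"] * n, dtype=object)
    labels[perm[:n_early]] = "early"
    labels[perm[n_early : n_early + n_late]] = "late"
    labels[perm[n_early + n_late : n_early + n_late + n_loss]] = "loss"

    e = config.effect_log2
    score_map = {
        "stable": {s: 0.0 for s in config.samples},
        "early": {"parent": 0.0, "hTERT_50": e, "hTERT_100": e, "TSR_50": e, "TSR_100": e},
        "late": {"parent": 0.0, "hTERT_50": 0.0, "hTERT_100": e, "TSR_50": 0.0, "TSR_100": e},
        "loss": {"parent": e, "hTERT_50": 0.0, "hTERT_100": 0.0, "TSR_50": 0.0, "TSR_100": 0.0},
    }
    true_scores = pd.DataFrame(
        [score_map[l] for l in labels], index=genes, columns=list(config.samples)
    )
    prom_truth = pd.DataFrame({"hTERT": labels, "TSR": labels}, index=genes)
    prom_truth.index.name = "gene_id"
    return GroundTruth(promoters=prom_truth, true_scores=true_scores)


def _dye_bias(a: np.ndarray, coeffs: Sequence[float], center: float = 10.0) -> np.ndarray:
    bias = np.zeros_like(a)
    for k, c in enumerate(coeffs, start=1):
        bias += c * (a - center) ** k
    return bias


def simulate_map_arrays(
    probes: pd.DataFrame,
    truth: GroundTruth,
    config: SimulationConfig,
) -> dict[str, pd.DataFrame]:
    """Two-color probe intensity tables, one per sample.

    Per probe the raw log ratio is spread * (true promoter score + noise)
    plus the A-dependent dye-bias polynomial; channels are reconstructed as
    ch1 = 2^(A - M/2), ch2 = 2^(A + M/2) with A ~ N(10, 1).
    """
    missing = set(probes["gene_id"]) - set(truth.true_scores.index)
    if missing:
        raise ConsistencyError(f"truth does not cover promoters {sorted(missing)[:3]}...")
    rng = np.random.default_rng(config.seed + 2)
    spread = list(config.array_spread)
    while len(spread) < len(config.samples):
        spread.append(1.0)
    out = {}
    n = len(probes)
    for s_i, sample in enumerate(config.samples):
        true_m = truth.true_scores[sample].reindex(probes["gene_id"]).to_numpy()
        a = rng.normal(10.0, 1.0, size=n)
        noise = rng.normal(0.0, config.probe_noise_sd, size=n)
        m = spread[s_i] * (true_m + noise) + _dye_bias(a, config.intensity_bias)
        out[sample] = pd.DataFrame(
            {
                "probe_id": probes["probe_id"].to_numpy(),
                "ch1": 2.0 ** (a - m / 2.0),
                "ch2": 2.0 ** (a + m / 2.0),
            }
        )
    return out


# ---------------------------------------------------------------------------
# expression arrays
# ---------------------------------------------------------------------------

_BASELINE_MEAN = 8.0
_BASELINE_SD = 1.5
#: analytic 25th percentile of the baseline distribution, used to place
#: "activated" (Group 2/5) baselines safely below the detection floor and
#: Group 1 baselines safely above it
_DETECTION_FLOOR = _BASELINE_MEAN - 0.6745 * _BASELINE_SD


def generate_expression_truth(config: SimulationConfig) -> pd.DataFrame:
    """Transcript Group labels and baseline log2 levels."""
    rng = np.random.default_rng(config.seed + 3)
    n = config.n_transcripts or config.n_promoters
    tx = np.array([f"T{i:05d}" for i in range(n)])
    fracs = [
        ("1", config.expr_frac_up),
        ("2", config.expr_frac_activated),
        ("3", config.expr_frac_down),
        ("4", config.expr_frac_g4),
        ("5", config.expr_frac_g5),
        ("6", config.expr_frac_g6),
    ]
    counts = [int(round(f * n)) for _, f in fracs]
    if sum(counts) > n:
        raise ConfigError("expression group proportions exceed 1")
    labels = np.array(["none"] * n, dtype=object)
    perm = rng.permutation(n)
    at = 0
    for (name, _), c in zip(fracs, counts):
        labels[perm[at : at + c]] = name
        at += c

    baseline = rng.normal(_BASELINE_MEAN, _BASELINE_SD, size=n)
    # groups whose pattern requires "not detected" in specific conditions
    low = np.isin(labels, ("2", "5"))
    baseline[low] = rng.normal(_DETECTION_FLOOR - 1.8, 0.3, size=low.sum())
    # group 1 must be detected in the parent; group 4 is highly expressed
    g1 = labels == "1"
    baseline[g1] = np.clip(rng.normal(8.5, 1.0, size=g1.sum()), _DETECTION_FLOOR + 0.7, None)
    g4 = labels == "4"
    baseline[g4] = rng.normal(9.0, 0.8, size=g4.sum())

    lo, hi = config.expr_fold
    log2f = np.log2(rng.uniform(lo, hi, size=n))
    return pd.DataFrame({"group": labels, "baseline": baseline, "log2_fold": log2f},
                        index=pd.Index(tx, name="transcript_id"))


#: per-group log2 effect multipliers by condition (x the transcript's fold)
_GROUP_EFFECTS = {
    "none": {},
    "1": {"hTERT_50": 0.5, "hTERT_100": 1.0, "TSR_50": 0.5, "TSR_100": 1.0},
    "2": {"hTERT_50": 0.5, "hTERT_100": 1.0, "TSR_50": 0.5, "TSR_100": 1.0},
    "3": {"hTERT_50": -0.5, "hTERT_100": -1.0, "TSR_50": -0.5, "TSR_100": -1.0},
    "4": {"hTERT_50": -0.5, "hTERT_100": -1.0},
    "5": {"TSR_50": 0.5, "TSR_100": 1.0},
    "6": {"hTERT_50": 0.5, "hTERT_100": 1.0},
}


def simulate_expression_arrays(
    config: SimulationConfig,
    truth: pd.DataFrame | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, pd.Series, pd.DataFrame]:
    """Replicate one-color probe tables.

    Returns (arrays, sample_sheet, probe_to_transcript, truth): one linear
    intensity table per array, the array/condition/replicate sheet, the
    probe-to-transcript map, and the transcript truth used. Per probe the
    log2 intensity is baseline + group effect (half strength at 50 pd,
    full at 100 pd) + a fixed probe affinity + Gaussian replicate noise.
    """
    if truth is None:
        truth = generate_expression_truth(config)
    rng = np.random.default_rng(config.seed + 4)
    n = len(truth)
    ppt = config.probes_per_transcript
    probe_ids = [f"{tx}_e{j}" for tx in truth.index for j in range(ppt)]
    probe_tx = pd.Series(np.repeat(truth.index.to_numpy(), ppt), index=probe_ids)
    affinity = rng.normal(0.0, 0.5, size=n * ppt)

    effect = np.zeros((n, len(config.samples)))
    for j, cond in enumerate(config.samples):
        mult = np.array([_GROUP_EFFECTS[g].get(cond, 0.0) for g in truth["group"]])
        effect[:, j] = mult * truth["log2_fold"].to_numpy()
    base = truth["baseline"].to_numpy()

    arrays: dict[str, pd.DataFrame] = {}
    sheet_rows = []
    for j, cond in enumerate(config.samples):
        for rep in range(1, config.replicate_count + 1):
            label = f"{cond}_r{rep}"
            log2v = (
                np.repeat(base + effect[:, j], ppt)
                + affinity
                + rng.normal(0.0, config.expr_noise_sd, size=n * ppt)
            )
            arrays[label] = pd.DataFrame(
                {"probe_id": probe_ids, "intensity": 2.0**log2v}
            )
            sheet_rows.append((label, cond, rep))
    sheet = pd.DataFrame(sheet_rows, columns=["array", "condition", "replicate"])
    return arrays, sheet, probe_tx, truth


# ---------------------------------------------------------------------------
# bisulfite clones
# ---------------------------------------------------------------------------

def simulate_bisulfite_clones(
    reference: str,
    methylation_pattern: Sequence[float],
    n_clones: int,
    conversion_rate: float = 1.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Bisulfite-converted clone sequences from a reference amplicon.

    ``methylation_pattern`` gives the per-CpG methylation probability (one
    entry per CpG in the reference, 5'->3'). Non-CpG cytosines convert
    C->T independently with probability ``conversion_rate``; a CpG
    cytosine converts (at the same rate) only when the clone's drawn state
    is unmethylated. Returns (clones as (id, sequence) pairs, boolean
    clones x CpGs methylation-state matrix).
    """
    reference = reference.upper()
    rng = np.random.default_rng(seed)
    cpg_pos = [i for i in range(len(reference) - 1)
               if reference[i] == "C" and reference[i + 1] == "G"]
    if len(methylation_pattern) != len(cpg_pos):
        raise ConsistencyError(
            f"pattern has {len(methylation_pattern)} entries but the reference "
            f"has {len(cpg_pos)} CpGs"
        )
    if not 0 <= conversion_rate <= 1:
        raise ConfigError("conversion_rate must be in [0, 1]")
    pattern = np.asarray(methylation_pattern, dtype=float)
    clones = []
    states = np.zeros((n_clones, len(cpg_pos)), dtype=bool)
    cpg_set = set(cpg_pos)
    for c in range(n_clones):
        meth = rng.random(len(cpg_pos)) < pattern
        states[c] = meth
        meth_at = {p for p, m in zip(cpg_pos, meth) if m}
        seq = []
        for i, b in enumerate(reference):
            if b == "C":
                if i in cpg_set:
                    if i in meth_at:
                        seq.append("C")
                    else:
                        seq.append("T" if rng.random() < conversion_rate else "C")
                else:
                    seq.append("T" if rng.random() < conversion_rate else "C")
            else:
                seq.append(b)
        clones.append((f"clone_{c + 1:03d}", "".join(seq)))
    return clones, states
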