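"""Deterministic calculators for the validation assays.

* Growth curves: per-passage mean population doublings,
  MPD = 3.32 * (log10 n - log10 n0), accumulated over passages.
* qPCR relative quantification by the efficiency-corrected (Pfaffl) ratio
  E_target^dCt_target / E_ref^dCt_ref, which reduces to the ddCt rule
  2^(dCt_target - dCt_ref) when both efficiencies are 2.
* MeDIP enrichment as percent of input, with the input Ct adjusted for the
  fraction of input material assayed.
* Bisulfite clone sequencing: clones are globally aligned (end gaps free)
  against the in-silico converted reference, each reference CpG is called
  methylated/unmethylated/ambiguous from the aligned base, and clones
  failing conversion-rate or identity QC are rejected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

MPD_CONSTANT = 3.32  # doublings per 10-fold expansion: 1/log10(2) rounded as reported


def mpd(n0: float, n: float) -> float:
    """Mean population doublings for one passage: 3.32*(log10 n - log10 n0)."""
    if n0 <= 0 or n <= 0:
        raise ValueError("cell counts must be positive")
    return MPD_CONSTANT * (math.log10(n) - math.log10(n0))


def mpd_curve(passages: pd.DataFrame) -> pd.DataFrame:
    """Growth-curve table from per-passage records (columns n0, n and
    optionally days): adds mpd, cumulative_pd and cumulative_days."""
    if (passages["n0"] <= 0).any() or (passages["n"] <= 0).any():
        raise ValueError("cell counts must be positive")
    out = passages.copy()
    out["mpd"] = [mpd(a, b) for a, b in zip(out["n0"], out["n"])]
    out["cumulative_pd"] = out["mpd"].cumsum()
    if "days" in out.columns:
        out["cumulative_days"] = out["days"].cumsum()
    return out


@dataclass(frozen=True)
class QpcrMeasurement:
    """Efficiencies (amplification factor per cycle, in (1, 2]) and Ct
    values for the target and reference amplicons in control and sample."""

    e_target: float
    ct_target_control: float
    ct_target_sample: float
    e_ref: float
    ct_ref_control: float
    ct_ref_sample: float

    def __post_init__(self) -> None:
        for e in (self.e_target, self.e_ref):
            if not 1.0 < e <= 2.0:
                raise ValueError(f"efficiency {e} outside (1, 2]")
        for ct in (self.ct_target_control, self.ct_target_sample,
                   self.ct_ref_control, self.ct_ref_sample):
            if ct <= 0:
                raise ValueError("Ct values must be positive")


def pfaffl_ratio(q: QpcrMeasurement) -> float:
    """Efficiency-corrected relative expression ratio."""
    dct_t = q.ct_target_control - q.ct_target_sample
    dct_r = q.ct_ref_control - q.ct_ref_sample
    return q.e_target**dct_t / q.e_ref**dct_r


def medip_percent_input(ct_ip: float, ct_input: float, input_fraction: float) -> float:
    """MeDIP enrichment as percent of input.

    The measured input Ct is first adjusted to 100% input
    (Ct + log2(fraction), fraction in (0, 1]); percent =
    100 * 2^(adjusted input Ct - IP Ct).
    """
    if not 0 < input_fraction <= 1:
        raise ValueError("input_fraction must be in (0, 1]")
    if ct_ip <= 0 or ct_input <= 0:
        raise ValueError("Ct values must be positive")
    ct_input_100 = ct_input + math.log2(input_fraction)
    return 100.0 * 2.0 ** (ct_input_100 - ct_ip)


# ---------------------------------------------------------------------------
# bisulfite clone analysis
# ---------------------------------------------------------------------------

@dataclass
class BisulfiteClone:
    """Per-clone methylation calls and QC metrics."""

    clone_id: str
    calls: list[str]  # per reference CpG: 'methylated'/'unmethylated'/'ambiguous'
    conversion_rate: float
    identity: float
    strand: str = "+"
    accepted: bool = True
    rejection_reason: str = ""


@dataclass
class BisulfiteReport:
    """Clone-level calls plus the lollipop summary.

    ``lollipop`` rows are clones x CpGs with the conventional coding:
    filled circle = methylated, open circle = unmethylated, dot =
    ambiguous. ``cpg_percent`` is per-CpG percent methylation over
    accepted clones with an unambiguous call at that CpG.
    """

    clones: list[BisulfiteClone] = field(default_factory=list)
    cpg_positions: list[int] = field(default_factory=list)
    cpg_percent: list[float] = field(default_factory=list)

    @property
    def accepted_clones(self) -> list[BisulfiteClone]:
        return [c for c in self.clones if c.accepted]

    def lollipop(self) -> str:
        symbol = {"methylated": "●", "unmethylated": "○", "ambiguous": "·"}
        lines = []
        for c in self.accepted_clones:
            lines.append(f"{c.clone_id}\t" + "".join(symbol[x] for x in c.calls))
        return "\n".join(lines)


def _converted_reference(reference: str) -> tuple[str, list[int], list[int]]:
    """In-silico fully converted reference: non-CpG C -> T, CpG C -> 'Y'
    (an ambiguity letter matching both C and T). Returns the converted
    string and the CpG / non-CpG cytosine position lists."""
    reference = reference.upper()
    conv = list(reference)
    cpg, non_cpg = [], []
    for i, b in enumerate(reference):
        if b != "C":
            continue
        if i + 1 < len(reference) and reference[i + 1] == "G":
            conv[i] = "Y"
            cpg.append(i)
        else:
            conv[i] = "T"
            non_cpg.append(i)
    return "".join(conv), cpg, non_cpg


def _make_aligner() -> Align.PairwiseAligner:
    alphabet = "ACGTYN"
    mat = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            mat[a, b] = 1.0 if a == b else -1.0
    for b in ("C", "T"):
        mat["Y", b] = mat[b, "Y"] = 1.0
    for b in alphabet:
        mat["N", b] = mat[b, "N"] = 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    try:
        aligner.open_end_gap_score = 0.0
        aligner.extend_end_gap_score = 0.0
    except AttributeError:  # biopython < 1.88 naming
        aligner.end_open_gap_score = 0.0
        aligner.end_extend_gap_score = 0.0
    return aligner


def _clone_base_map(alignment) -> dict[int, str]:
    """reference position -> aligned clone base for one alignment."""
    out: dict[int, str] = {}
    target = alignment.target
    query = alignment.query
    for (t0, t1), (q0, q1) in zip(*alignment.aligned):
        for k in range(t1 - t0):
            out[t0 + k] = str(query[q0 + k])
    return out


def call_clone_methylation(
    reference: str,
    clones: list[tuple[str, str]],
    min_conversion: float = 0.95,
    min_identity: float = 0.80,
) -> BisulfiteReport:
    """Call per-CpG methylation for each bisulfite clone.

    Each clone (and its reverse complement; the better-scoring orientation
    is kept) is aligned globally with free end gaps against the converted
    reference. Per reference CpG an aligned C is methylated, T
    unmethylated, anything else ambiguous. The conversion rate is the
    converted fraction of aligned non-CpG reference cytosines; clones
    below ``min_conversion`` or below ``min_identity`` sequence identity
    are rejected with a reason.
    """
    conv_ref, cpg_pos, non_cpg_pos = _converted_reference(reference)
    if not cpg_pos:
        raise ValueError("reference contains no CpG dinucleotide")
    aligner = _make_aligner()
    report = BisulfiteReport(cpg_positions=list(cpg_pos))
    if not clones:
        report.cpg_percent = [float("nan")] * len(cpg_pos)
        return report

    for clone_id, seq in clones:
        seq = "".join(b if b in "ACGT" else "N" for b in seq.upper())
        best = None
        best_strand = "+"
        for strand, s in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
            aln = aligner.align(conv_ref, s)[0]
            if best is None or aln.score > best.score:
                best, best_strand = aln, strand
        base_at = _clone_base_map(best)

        calls = []
        for p in cpg_pos:
            b = base_at.get(p)
            if b == "C":
                calls.append("methylated")
            elif b == "T":
                calls.append("unmethylated")
            else:
                calls.append("ambiguous")
        n_conv = sum(1 for p in non_cpg_pos if base_at.get(p) == "T")
        n_unconv = sum(1 for p in non_cpg_pos if base_at.get(p) == "C")
        informative = n_conv + n_unconv
        conv_rate = n_conv / informative if informative else float("nan")
        aligned = [(p, b) for p, b in base_at.items()]
        n_match = sum(
            1 for p, b in aligned
            if b == conv_ref[p] or (conv_ref[p] == "Y" and b in "CT")
        )
        identity = n_match / len(conv_ref)

        clone = BisulfiteClone(
            clone_id=clone_id, calls=calls, conversion_rate=conv_rate,
            identity=identity, strand=best_strand,
        )
        if not informative:
            clone.accepted = False
            clone.rejection_reason = "no informative non-CpG cytosines aligned"
        elif conv_rate < min_conversion:
            clone.accepted = False
            clone.rejection_reason = f"conversion rate {conv_rate:.3f} < {min_conversion}"
        elif identity < min_identity:
            clone.accepted = False
            clone.rejection_reason = f"identity {identity:.3f} < {min_identity}"
        report.clones.append(clone)

    for j in range(len(cpg_pos)):
        calls = [c.calls[j] for c in report.accepted_clones if c.calls[j] != "ambiguous"]
        if calls:
            pct = 100.0 * sum(x == "methylated" for x in calls) / len(calls)
        else:
            pct = float("nan")
        report.cpg_percent.append(pct)
    return report


def lollipop_table(report: BisulfiteReport) -> pd.DataFrame:
    """Clones x CpGs call matrix plus the per-CpG percent methylation row."""
    sym = {"methylated": "●", "unmethylated": "○", "ambiguous": "·"}
    cols = [f"CpG_{p}" for p in report.cpg_positions]
    rows = {c.clone_id: [sym[x] for x in c.calls] for c in report.accepted_clones}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    df.loc["percent_methylated"] = [
        f"{p:.1f}" if np.isfinite(p) else "NA" for p in report.cpg_percent
    ]
    return df
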