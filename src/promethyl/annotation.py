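"""Promoter/probe annotation I/O and strand-aware window assignment.

Coordinates are 0-based half-open genomic intervals throughout. Promoter
windows are defined on the transcription axis (position ``t`` relative to
the TSS, positive downstream) and mapped to genomic coordinates by
reflection for minus-strand promoters: a genomic midpoint ``m`` sits at
``t = m - tss`` on the plus strand and ``t = tss - m`` on the minus strand.
Window membership is always ``lower <= t < upper`` on that axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CPG_CLASSES = ("unassigned", "LCP", "ICP", "HCP")
_CPG_CODE = {name: i for i, name in enumerate(CPG_CLASSES)}


class ParseError(ValueError):
    """Malformed record in an annotation file (reports the line number)."""


@dataclass(frozen=True)
class WindowSpec:
    """Core and upstream promoter windows on the transcription axis.

    Offsets are relative to the TSS, downstream positive. Defaults: a 1-kb
    core window spanning -500..+500 around the TSS and a 1-kb upstream
    window spanning -1500..-500.
    """

    core: tuple[int, int] = (-500, 500)
    upstream: tuple[int, int] = (-1500, -500)

    def __post_init__(self) -> None:
        for lo, hi in (self.core, self.upstream):
            if lo >= hi:
                raise ValueError(f"empty window ({lo}, {hi})")
        lo_c, hi_c = self.core
        lo_u, hi_u = self.upstream
        if max(lo_c, lo_u) < min(hi_c, hi_u):
            raise ValueError("core and upstream windows overlap")

    def genomic_interval(self, tss: int, strand: str, which: str = "core") -> tuple[int, int]:
        """Half-open genomic interval covered by a window for one promoter.

        On the minus strand the transcription-axis interval [lo, hi)
        reflects to genomic (tss - hi, tss - lo], returned as the half-open
        integer interval [tss - hi + 1, tss - lo + 1).
        """
        lo, hi = self.core if which == "core" else self.upstream
        if strand == "+":
            return tss + lo, tss + hi
        return tss - hi + 1, tss - lo + 1


@dataclass
class ProbeAssignment:
    """Probe-to-window assignment table plus QC flags.

    ``table`` has one row per (promoter, probe, window) membership with
    columns gene_id, probe_id, window ('core'/'upstream'). A probe may
    serve several overlapping promoters. ``no_core_probes`` lists promoters
    whose core window captured no probe midpoint.
    """

    table: pd.DataFrame
    no_core_probes: list[str] = field(default_factory=list)

    def probes_for(self, gene_id: str, window: str = "core") -> list[str]:
        t = self.table
        sel = (t["gene_id"] == gene_id) & (t["window"] == window)
        return t.loc[sel, "probe_id"].tolist()


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def write_promoters(promoters: pd.DataFrame, path) -> None:
    """Write promoters as BED6: the TSS as a 1-bp interval, gene id in the
    name column and the CpG-class code (0=unassigned,1=LCP,2=ICP,3=HCP) in
    the score column."""
    cls = promoters.get("cpg_class", pd.Series("unassigned", index=promoters.index))
    out = pd.DataFrame(
        {
            "chrom": promoters["chrom"],
            "start": promoters["tss"].astype(int),
            "end": promoters["tss"].astype(int) + 1,
            "name": promoters["gene_id"],
            "score": [_CPG_CODE[c] for c in cls],
            "strand": promoters["strand"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_promoters(path) -> pd.DataFrame:
    """Read a BED6 promoter file written by :func:`write_promoters`.

    Returns a DataFrame with columns gene_id, chrom, tss, strand,
    cpg_class. Raises :class:`ParseError` naming the offending line.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: expected 6 BED columns, got {len(parts)}")
            chrom, start, end, name, score, strand = parts[:6]
            try:
                tss = int(start)
                code = int(score)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            if tss < 0 or int(end) != tss + 1:
                raise ParseError(f"{path}:{lineno}: promoter record must be a 1-bp TSS interval")
            if not 0 <= code < len(CPG_CLASSES):
                raise ParseError(f"{path}:{lineno}: bad CpG class code {code}")
            rows.append((name, chrom, tss, strand, CPG_CLASSES[code]))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand", "cpg_class"])
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ParseError(f"{path}: duplicate gene_id {dup!r}")
    return df


def write_probes(probes: pd.DataFrame, path) -> None:
    probes[["probe_id", "chrom", "start", "end"]].to_csv(path, sep="\t", index=False)


def read_probes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    missing = {"probe_id", "chrom", "start", "end"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if (df["start"] >= df["end"]).any():
        bad = df.index[df["start"] >= df["end"]][0]
        raise ParseError(f"{path}: probe row {bad}: start >= end")
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        raise ParseError(f"{path}: duplicate probe_id {dup!r}")
    return df


def read_peaks_bed(path) -> pd.DataFrame:
    """Read a BED3+ peak file into (chrom, start, end)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------
# window assignment
# ---------------------------------------------------------------------------

def assign_probes_to_windows(
    promoters: pd.DataFrame,
    probes: pd.DataFrame,
    spec: WindowSpec | None = None,
) -> ProbeAssignment:
    """Assign each probe (by midpoint) to the promoter windows it falls in.

    A probe belongs to a window iff its midpoint, projected onto the
    promoter's transcription axis, satisfies ``lower <= t < upper``.
    Probes may hit several overlapping promoters; promoters with no core
    probe are flagged, not dropped.
    """
    spec = spec or WindowSpec()
    parts: list[pd.DataFrame] = []
    probe_mid = (probes["start"].to_numpy() + probes["end"].to_numpy()) / 2.0
    for chrom, prom_idx in promoters.groupby("chrom", sort=False).groups.items():
        pmask = probes["chrom"].to_numpy() == chrom
        if not pmask.any():
            continue
        mids = probe_mid[pmask]
        pids = probes["probe_id"].to_numpy()[pmask]
        order = np.argsort(mids, kind="stable")
        mids_s, pids_s = mids[order], pids[order]
        sub = promoters.loc[prom_idx]
        for gene, tss, strand in zip(sub["gene_id"], sub["tss"], sub["strand"]):
            for window, (lo, hi) in (("core", spec.core), ("upstream", spec.upstream)):
                if strand == "+":
                    g_lo, g_hi = tss + lo, tss + hi
                    i0 = np.searchsorted(mids_s, g_lo, side="left")
                    i1 = np.searchsorted(mids_s, g_hi, side="left")
                    hit = pids_s[i0:i1]
                else:
                    # t = tss - m in [lo, hi)  <=>  m in (tss - hi, tss - lo]
                    g_lo, g_hi = tss - hi, tss - lo
                    i0 = np.searchsorted(mids_s, g_lo, side="right")
                    i1 = np.searchsorted(mids_s, g_hi, side="right")
                    hit = pids_s[i0:i1]
                if len(hit):
                    parts.append(
                        pd.DataFrame({"gene_id": gene, "probe_id": hit, "window": window})
                    )
    if parts:
        table = pd.concat(parts, ignore_index=True)
    else:
        table = pd.DataFrame(columns=["gene_id", "probe_id", "window"])
    with_core = set(table.loc[table["window"] == "core", "gene_id"])
    flagged = [g for g in promoters["gene_id"] if g not in with_core]
    return ProbeAssignment(table=table, no_core_probes=flagged)


# ---------------------------------------------------------------------------
# CpG density classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CpgClassSpec:
    """Thresholds for the HCP/ICP/LCP promoter classes.

    HCP: some 500-bp window with CpG obs/exp > hcp_ratio and GC fraction >
    hcp_gc. LCP: no window reaches lcp_ratio. ICP: everything else.
    obs/exp = (#CpG * L) / (#C * #G) within the window.
    """

    hcp_ratio: float = 0.75
    hcp_gc: float = 0.55
    lcp_ratio: float = 0.48
    window: int = 500
    step: int = 5


def cpg_obs_exp(seq: str) -> tuple[float, float]:
    """(obs/exp CpG ratio, GC fraction) of a sequence."""
    seq = seq.upper()
    n_c = seq.count("C")
    n_g = seq.count("G")
    n_cpg = seq.count("CG")
    length = len(seq)
    gc = (n_c + n_g) / length if length else 0.0
    ratio = (n_cpg * length) / (n_c * n_g) if n_c and n_g else 0.0
    return ratio, gc


def classify_cpg_density(seq: str, spec: CpgClassSpec | None = None) -> str:
    """Classify a promoter sequence as HCP, ICP or LCP by sliding windows.

    Sequences shorter than the window are scored on the full sequence.
    """
    spec = spec or CpgClassSpec()
    seq = seq.upper()
    n = len(seq)
    if n == 0:
        raise ValueError("empty sequence")
    w = spec.window
    if n <= w:
        windows = [seq]
    else:
        starts = list(range(0, n - w + 1, spec.step))
        if starts[-1] != n - w:
            starts.append(n - w)
        windows = [seq[s : s + w] for s in starts]
    best_ratio = 0.0
    is_hcp = False
    for sub in windows:
        ratio, gc = cpg_obs_exp(sub)
        best_ratio = max(best_ratio, ratio)
        if ratio > spec.hcp_ratio and gc > spec.hcp_gc:
            is_hcp = True
    if is_hcp:
        return "HCP"
    if best_ratio < spec.lcp_ratio:
        return "LCP"
    return "ICP"
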