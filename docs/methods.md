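# Methods

This note documents the models, parameter choices and numerical behaviour
of the promethyl pipeline: what each stage assumes, what the synthetic
generator does and does not emulate, and the design decisions taken where
the problem was genuinely open.

## Probe model and two-color normalization

A two-color array observes, per probe, channel intensities (ch1 = input,
ch2 = MAP or ChIP fraction). The working quantities are
M = log2(ch2/ch1) and A = ½(log2 ch1 + log2 ch2). Probes with a
non-positive intensity in either channel are dropped (with a logged
count), never floored: flooring fabricates ratios.

**Loess.** Dye bias is modelled as a smooth function of A and removed as
M′ = M − f̂(A), where f̂ is a locally weighted linear regression:
at each evaluation point the span-fraction nearest neighbors receive
tricube distance weights, a weighted degree-1 fit is solved in closed
form, and `iterations` bisquare re-weighting passes (weights
(1 − (r/6s)²)² with s the median absolute residual) downweight outliers
such as genuinely enriched probes. Defaults: span 0.3, degree 1, 4
robustifying iterations — standard two-color practice. Numerically the
trend is evaluated exactly at up to 200 quantile anchors of A and
linearly interpolated in between; above 20 000 probes the fit uses a
seeded random subsample of 20 000. Both shortcuts exploit that the dye
bias is smooth in A; the anchor-free exact mode (used by the
oracle-equivalence tests) fits at every point. Whether the original
analysis regressed M on A or on array position is not recorded anywhere;
M-on-A is the assumption.

**MAD scaling.** For cross-array comparability every array's M′ values
are multiplied by (target MAD / own MAD), target = median of the arrays'
MADs. The 1.4826 consistency constant is omitted — it cancels in the
ratio. The map is a positive scalar, so signs, zeros and within-array
ranking are untouched; an array with zero MAD (identically distributed
values, e.g. noise-free input) is a degenerate-array error. One known
second-order effect: arrays carrying more enriched probes have a slightly
inflated MAD, so their signal is shrunk by a few percent relative to
signal-poor arrays (see *Maintenance margin* below). This is inherent to
scale-to-common-MAD normalization, not an implementation artifact.

## Windows, aggregation and methylation calls

Windows are defined on the transcription axis (t relative to the TSS,
downstream positive): core −500..+500, upstream −1500..−500, membership
lower ≤ t < upper by probe midpoint. Minus-strand promoters reflect the
axis (t = tss − midpoint), so a minus-strand core window occupies genomic
(tss−500, tss+500]. Midpoint membership (rather than overlap fraction)
is robust to probe length. Promoter scores are the exact median of the
contributing probes' normalized M per sample; windows with fewer than
`min_probes` (default 3, to avoid single-probe medians) are missing
(NaN), never 0.

Differential calls use a pure fold-change rule: gain iff
Δ = score − parent ≥ cutoff, loss iff Δ ≤ −cutoff, with cutoff 1.0 on the
log2 scale (2-fold) and the boundary inclusive ("minimal cut-off of 1").
No per-promoter statistical test is attempted — with one array per
condition there is no within-condition replication. Timing classes per
derived line: early = gain at 50 and 100 pd; late = gain at 100 only;
inconsistent = gain at 50 only (violates maintenance and is flagged);
loss = loss call at 100 pd; stable otherwise; any no-call propagates.
The de-novo set union and intersection across the two lines are both
reported (the union drives the heat-map matrix); rows are ordered by
(timing class, mean Δ100 descending, gene id) so output is deterministic.

**Maintenance margin.** With effect 1.5, cutoff 1, probe sd 0.3 and 12
probes/window, a true early promoter's Δ100 estimator has sd ≈ 0.15 and
(after the MAD-inflation shrinkage above) mean ≈ 1.42, a ~2.9σ margin:
each early line-call carries a ≈0.2% chance of an inconsistent label.
Zero inconsistent labels is therefore exact in the noise-free limit and
holds with high probability per default-sized run, but not identically at
arbitrary scale; the acceptance script reports the realized rate.

## Chromatin states

ChIP/input arrays (H3ac, H3K27me3 measured in the parental line) go
through the identical normalize/aggregate path; a promoter is marked when
its core-window median reaches θ_chip = 1 (chosen by analogy with the
methylation cutoff; the enrichment threshold used for the published
percentages is not recorded, so those percentages are not a validation
surface here). External peak sets (H3K4me3, H3K36me3 from a related
fibroblast line) contribute presence by ≥1 bp half-open overlap with the
core window. Composition over a promoter set uses K27me3 > H3ac > neither
precedence so the three primary states partition the set (their
percentages sum to 100); bivalent promoters are counted under K27me3 and
reported separately, and H3K36me3 overlap is an independent percentage
over the same set. Z-scores are per column with the population (n)
denominator (flag for n−1); zero-variance columns z-score to 0 with a
warning.

## Expression model

Probe intensities are log2-transformed and quantile normalized (every
column mapped onto the mean of the sorted columns; ties share the mean of
their would-be quantiles; missing cells rank-skip with a warning), then
summarized per transcript by Tukey's median polish (alternating row and
column median sweeps to tolerance 1e-6 or 20 sweeps; summary = overall +
column effect; a single-probe transcript is its own summary).

Per transcript a one-way least-squares model over the five conditions
yields contrast coefficients M and a residual variance s²_g on d_g df.
The variance prior (d₀, s₀²) is the closed-form moment estimator on
log s²_g: e_g = log s²_g − ψ(d_g/2) + log(d_g/2), d₀ = 2·ψ′⁻¹(Var(e) −
ψ′(d_g/2)), s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)), with ψ′⁻¹ solved
by Newton iteration. When Var(e) does not exceed the theoretical
log-variance ψ′(d_g/2) the variances are consistent with a single common
value and d₀ = ∞ (full shrinkage to s₀²) is the correct limit — this,
rather than d₀ = 0, is the fallback used, matching the estimator's own
limit case; d₀ = 0 (no moderation, ordinary t) is reserved for degenerate
inputs with non-finite moments, with a warning. Moderated
t̃ = M/(s̃·√u) (u the contrast's design factor) is referred to a t
distribution on d₀ + d_g df, and p-values are BH step-up adjusted
(adj p₍ᵢ₎ = min over j≥i of m·p₍ⱼ₎/j, capped at 1, stable under input
reordering).

A transcript is differential when FDR < 0.05 and |linear fold| ≥ 3
(boundary inclusive). "Expressed/detected" in a condition means the
condition mean exceeds the mean across arrays of each array's 25th
percentile — the source analysis never defines detection, so the
percentile is config-exposed. Group logic: Groups 1/2/3 need the
immortality contrast significant with concordant sign in *both* derived
lines at 100 pd (Group 1 vs 2 split by parental detection; Group 3 =
down); transcripts outside 1–3 are eligible for Groups 4/5/6, all of
which additionally require the hTERT-vs-TSR transformation contrast to be
significant (4 = down in hTERT but not TSR; 5 = up in TSR vs both parent
and hTERT; 6 = up in hTERT with TSR within ±fold of parent), evaluated in
that order so labels partition. The 3-fold rule is applied to the
transformation groups as well (whether the original analysis did so for
its transformation-associated transcripts is not stated).

## Validation assays

* MPD = 3.32·(log₁₀ n − log₁₀ n₀) per passage (3.32 is the published
  constant ≈ 1/log₁₀2), accumulated over passages; additive under
  passage splitting by construction.
* Pfaffl ratio = E_t^(Ct_t,control − Ct_t,sample) / E_r^(Ct_r,control −
  Ct_r,sample); at E_t = E_r = 2 this is exactly the ΔΔCt rule.
* MeDIP percent of input = 100·2^((Ct_input + log2 f) − Ct_IP), where f
  is the assayed input fraction — f must be supplied explicitly because
  volumes/masses alone do not determine it.
* Bisulfite clones are aligned globally (end gaps free; match 1,
  mismatch −1, gap open −2, extend −0.5; clone and reverse complement
  both tried) against the converted reference in which non-CpG C→T and
  CpG C becomes an ambiguity letter matching C or T. Per reference CpG:
  aligned C = methylated, T = unmethylated, else ambiguous. Conversion
  rate = converted fraction of aligned non-CpG reference cytosines;
  QC rejects clones below 0.95 conversion or 0.80 identity (common
  bisulfite practice; config-exposed, since the thresholds used with the
  original clone-analysis software are not recorded).

## Synthetic data: what it emulates and what it does not

The generator reproduces the study design: five conditions (parent;
hTERT and TSR lines at 50 and 100 pd), ~12 probes per 1-kb window tiling
−1500..+500 around each TSS on synthetic chromosomes, an A-dependent
polynomial dye bias (default 0.3·(A−10) + 0.06·(A−10)²), per-array spread
multipliers (1.0/1.15/0.9/1.05/0.95, median 1) so raw MADs genuinely
differ, Gaussian per-probe noise (sd 0.3), and a promoter effect of
1.5 log2 at methylated promoters. Early/late/loss labels are shared
between the two derived lineages by default — the observed biology the
pipeline is meant to recover — and early promoters stay methylated at
100 pd. Defaults plant 3% early, 3% late and 2% loss promoters; the
acceptance benchmark uses 5000 promoters (150/150/100). The real arrays'
probe count per promoter is not published; 12 per window is a free
parameter.

Expression arrays: transcript baselines ~N(8, 1.5) on the log2 scale,
four probes per transcript with fixed N(0, 0.5) affinities, N(0, 0.25)
replicate noise, triplicates, fold effects drawn uniformly from 4–8×
(half effect at 50 pd, full at 100 pd). "Activated" groups (2 and 5) get
baselines ~1.8 log2 below the analytic 25th percentile of the baseline
distribution so they sit below the detection floor; Group 1 baselines are
clipped above it. CpG classes are drawn (30% LCP / 30% ICP / 40% HCP) and
can be accompanied by generated sequences whose CpG obs/exp ratio and GC
content land in the requested class (Weber-style thresholds: HCP ratio
> 0.75 and GC > 0.55 in some 500-bp window; LCP ratio < 0.48 everywhere);
only class consistency is guaranteed, not sequence realism.

Not emulated: scanner-level artifacts, print-tip/spatial effects (array
geometry is not in the data model), mappability filtering, copy-number
changes, probe cross-hybridization, and any genuine coupling between
chromatin state, CpG class and methylation propensity — marks are
assigned independently where the chromatin stage is simulated. Passing
recovery benchmarks therefore demonstrates correctness of the
computational chain under the stated noise model, not robustness to every
real-array pathology.

## Problem sizes and determinism

The self-validation studies run twenty seeds of the 5000-promoter
methylation benchmark (~3 s each), twenty seeds of the 2000-transcript
expression benchmark, and twenty 500-transcript null calibrations —
sizes chosen to give stable recovery estimates at desk scale. Every
random draw flows from an explicit seed (simulation streams are offset
per stage so adding a stage does not reshuffle others); identical
configs give byte-identical outputs, which the pipeline manifest records
as SHA-256 checksums. Published headline counts from the original arrays
(e.g. 301 de-novo promoters, 1193/571 up/down transcripts) depend on the
deposited datasets and unrecorded thresholds and are deliberately not
reproduction targets; the analytic worked examples (2-fold/log2-1
correspondence, the MPD constant, the qPCR closed forms) are.
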