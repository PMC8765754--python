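# Methods

## Forward model of synchronized nascent transcription

After release from a DRB block at time 0, polymerases spawn at the TSS as a
homogeneous Poisson process with rate σ (min⁻¹) and elongate at a constant
speed v (nt/min). Perfect synchronization is assumed: no polymerase is past
the TSS at release, and none re-enters. Each intron i carries an exponential
splicing clock with rate sᵢ that starts when its 3′ splice site is fully
transcribed (intron-definition assumption; the clock does not run while the
intron is only partially made). The transcript carries an exponential
cleavage clock with rate c that starts when the polymerase reaches the TES.
Spliced intron RNA and cleaved transcripts leave the chromatin fraction.

Expected chromatin coverage at position x and time t integrates σ over spawn
times τ ∈ [0, t − x/v], weighted by the splicing survival
exp(−sᵢ·max(0, t−τ−e3ᵢ/v)) when x is intronic and by the cleavage survival
exp(−c·max(0, t−τ−L/v)) everywhere. The integral is evaluated by trapezoid
quadrature with step ≤ 0.05 min (configurable; the integrand is piecewise
smooth with kinks at the clock starts, and halving the step changes fitted
rates by far less than the fit tolerances). Coverage is evaluated pointwise
at bin starts (default 50 nt bins).

An exact molecule-level simulator realizes the same process (uniform spawn
times conditional on the Poisson count, exponential waiting times) and
serves as the internal oracle: the deterministic model and the simulator are
held to agree at Monte-Carlo precision across random genes and rate sets.
Because that check spans thousands of bins, it is applied familywise
(Bonferroni-corrected pointwise bound, ≥99% of bins within 3 SE, aggregate
z-mean within ±0.1) rather than as a naive 3-SE rule per bin, which a
perfect model would fail by the order statistics of thousands of standard
normals.

## Derived statistics

- **Time to transcribe** an intron: length / v.
- **Cleavage before splicing.** The splicing clock gets a head start of
  d = dist-to-TES / v minutes before the cleavage clock arms. The
  probability that cleavage wins, P(d + Exp(c) < Exp(s)), is
  exp(−s·d)·c/(c+s); s = 0 gives 1. A brute-force two-exponential
  simulation cross-checks the closed form. Both an analytic and a
  Monte-Carlo mode are exposed, since either could underlie a published
  pipeline.
- **Predicted cassette-exon Ψ.** Inclusion commits when either flanking
  intron splices; skipping (rate s_skip) competes from the moment the
  downstream 3′SS exists, Δt = (e3_down − e3_up)/v after the upstream clock
  starts. Closed form Ψ = 1 − exp(−s_up·Δt)·s_skip/(s_up+s_down+s_skip).
  Cleavage does not censor the race: splicing may complete
  post-transcriptionally, which is the phenomenon the downstream decay
  statistics quantify.

## Rate inference

`fit_rates` minimizes the sum of squared residuals between observed and
expected coverage over log-parameters with bounds σ ∈ [10⁻³,10³] min⁻¹,
v ∈ [10²,10⁵] nt/min, sᵢ ∈ [10⁻⁴,10²] min⁻¹, c ∈ [10⁻³,10²] min⁻¹
(scipy trust-region reflective least squares; multi-start with seeded
log-normal jitter, best loss wins, ties broken by the smaller parameter
norm). Least squares on raw coverage is the default loss deliberately — it
matches the fit target with minimal distributional commitment; counts enter
only through the synthetic noise model.

The elongation rate is initialized by regressing the coverage wavefront
position on time. The front is detected at a small fraction (2%) of the peak
coverage: the wave's leading edge tapers linearly, so detection at fraction
f biases the slope by (1−f), and bins beyond the true front are exactly zero
even under Poisson noise, making a small threshold safe. With fewer than two
detectable fronts the initializer falls back to a prior median of
1500 nt/min. σ is initialized from the linear ramp upstream of the wave;
bins the wave cannot have reached by the last time point are excluded from
the fit.

**Identifiability.** v is informed by the wave's motion across the sampling
window. A gene the wave crosses in much less than one sampling interval
(5 min) pins v only weakly; parameter-recovery guarantees are therefore
stated for gene populations in the assay's design regime (≥2 introns,
median intron ~4 kb, gene bodies ~10–20 kb — several minutes of travel).
On such genes the fit recovers all rates within 5% from noiseless 7-point
time courses, and within 10% (σ, v) / 25% (sᵢ, c; sᵢ ∈ [0.05, 2] min⁻¹)
under Poisson noise at bin means ≥ 50.

## Synthetic stated world

The generator emulates a three-condition study sampled every 5 min to
35 min post-release, with Poisson count/coverage noise and 2 replicates.
Priors are log-normal: σ median 1 min⁻¹, v median 1500 nt/min (typical
Pol II), sᵢ median 0.5 min⁻¹ (minutes-scale co-transcriptional splicing),
c median 0.5 min⁻¹, post-transcriptional intron decay k median
0.0025 min⁻¹ — chosen so a 60-min transcription block loses ≈20% of intron
signal (log₂ ≈ −0.22), the scale such experiments report.

A configurable fraction of introns (default 0.2) is planted as **detained**:
detention probability decays geometrically (ratio 0.4) from the last intron
— encoding TES proximity directly — and detained introns draw shorter
lengths (median 400 nt) and slower splicing rates (median 0.05 min⁻¹).

Ground-truth poly(A) retention is mechanistic rather than dialed:
Ψ = P(cleaved before spliced) × exp(−k·T_nuc) with a nuclear residence time
T_nuc = 60 min. Condition effects are multiplicative rate shifts chosen once:
the "slow" arm (type-II-inhibitor-like) has s×0.7 and k×0.5, raising
retention; the "fast" arm (type-I-inhibitor-like) has k×1.5, lowering it.
These magnitudes mirror the ≈0.5×/1.25–1.5× asymmetry of reported ActD
medians and make the planted directions recoverable at the stated study
size (≈300 introns, depth 10³).

What the generator does **not** model: mappability and GC structure, spike-in
normalization (coverage is generated depth-normalized), overdispersion beyond
Poisson, polymerase pausing within gene bodies, recursive splicing, isoform
mixtures beyond the declared cassette events, and read-level artifacts. A
green test therefore establishes correctness of the estimators on the stated
stochastic world, not robustness to those real-data features.

## Quantification and testing choices

- **Ψ**: length-normalized inclusion ratio with effective lengths l_I = 2,
  l_S = 1 (two exon–intron junctions vs one exon–exon junction). Replicates
  are pooled by count summation for variance stability; events with pooled
  I+S < 10 in a condition are excluded from the FDR family.
- **Differential retention**: two-proportion z-test on length-normalized
  pooled counts with BH correction. This deliberately replaces a
  hierarchical junction-count likelihood model and is not numerically
  equivalent to one; under Poisson counts the length normalization makes it
  conservative, and the null calibration suite verifies FDR ≤ nominal.
- **ActD decay**: pseudocount 0.5 on all four counts; the flanking-exon
  normalizer is the summed counts of both flanking exons (single-exon
  fallback allowed). Replicates pooled by summation. δ is antisymmetric
  under swapping the ±ActD labels and depth-scale invariant at counts ≥ 50
  up to pseudocount effects.
- **Overlap OR**: sample (cross-product) odds ratio with Haldane–Anscombe
  +0.5 on any zero cell and a two-sided Fisher exact p. A conditional-MLE
  OR (as some gene-overlap tools report) differs slightly; the sample OR is
  closed-form and oracle-checkable. The BH family for adjusted overlap p's
  is the pair list of a single call, and the universe is always an explicit
  argument.
- **Size-matched resampling**: draws without replacement, rank-sum per
  repetition, median p reported. For one fixed subset the repetition
  p-values are correlated (they share the subset), so uniformity of the
  procedure's p holds marginally over null subsets; the calibration test is
  formulated accordingly.
- **Proteomics enrichment**: log₂ transform, per-sample mean-centering
  ("average of the data distribution"; median-centering available), Welch
  t-test per protein, no imputation (non-positive or missing intensities
  flag the protein). Background subtraction works on the log₂ scale and
  drops proteins non-positive in every replicate after correction;
  unmatched proteins subtract the control matrix minimum as a
  limit-of-detection stand-in and are flagged.
- Splice-site profiles use windows −3..+6 (5′SS) and −20..+3 (3′SS) in the
  no-zero offset convention, unweighted by expression; ambiguous bases are
  excluded per column.

## Degenerate inputs and numerical conventions

Zero-count Ψ is undefined (flagged, not 0/0). All-tied rank-sum input yields
p = 1 with a warning. Zero-variance Welch comparisons yield p = 1 when means
agree and p = 0 otherwise. Row-standardization uses the sample SD (n−1);
zero-SD rows emit zeros and are flagged. Gene coordinates are 0-based,
half-open, transcript-relative with TSS = 0 and strand resolved at parse
time; one representative transcript (longest) is kept per gene. Pipeline
manifests hash inputs and outputs (SHA-256) and contain no timings, so a
rerun of the same config and seed is byte-identical.

## Known limitations

Single uniform elongation rate per gene; no pausing or piecewise rates. The
differential-retention test is a calibrated simplification, not a
reimplementation of hierarchical splicing-event models. Rate fitting at
desk scale covers tens of genes, not genome-wide inference. The decay
statistic assumes stable flanking exons by default (an exon-decay parameter
exists to probe that assumption).
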