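# splicewave

Co-transcriptional splicing kinetics and intron detention, as a tested,
reusable Python pipeline.

## The problem

In synchronized nascent-RNA experiments, transcription is stalled with DRB
and released, and chromatin-associated RNA is sequenced every 5 minutes up to
35 minutes. The shape of the resulting coverage wave along each gene encodes
four kinetic rates: the polymerase **spawn** rate σ (initiation +
pause-release, min⁻¹), the **elongation** rate v (nt/min), a per-intron
**splicing** rate sᵢ (min⁻¹), and the transcript **cleavage** rate c
(min⁻¹). From these rates one can ask why some introns escape
co-transcriptional splicing and end up retained in poly(A) RNA — and whether
a treatment changes retention by slowing splicing during transcription or by
changing how fast retained introns are removed *after* transcription.

`splicewave` implements, against a synthetic-data generator with known
ground truth:

- a forward model of the post-release coverage wave, with an exact
  molecule-level simulator as internal oracle;
- rate inference (σ, v, sᵢ, c) from a coverage time course by bounded
  multi-start least squares on log-rates;
- derived statistics: time to transcribe an intron (length/v), the
  competing-risks probability that the transcript is cleaved before an
  intron is spliced, `P = exp(−s·d)·c/(c+s)` with `d = dist-to-TES / v`,
  and a commitment-race prediction of poly(A) cassette-exon Ψ,
  `Ψ = 1 − exp(−s_up·Δt)·s_skip/(s_up+s_down+s_skip)`;
- percent-spliced-in quantification `Ψ = (I/l_I)/(I/l_I + S/l_S)` with a
  pooled two-proportion test and Benjamini–Hochberg FDR for differential
  retention;
- an actinomycin-D decay score
  `δ = log2[ (intron⁺/exon⁺) / (intron⁻/exon⁻) ]` (flanking-exon
  normalized, pseudocounted) that converges to `−k·t/ln 2` for first-order
  intron decay at rate k over a transcription block of t minutes;
- set statistics: Fisher-exact overlap odds ratios within a stated universe,
  ΔΨ rank concordance, size-matched resampled Wilcoxon tests (median p over
  1000 repetitions), and Welch-t differential enrichment for proteomics
  matrices, with background subtraction for affinity controls.

## Worked example

```python
import numpy as np
from splicewave.genome import GeneModel, Intron
from splicewave.kinetics import (RateSet, time_to_transcribe,
                                 cleavage_before_splicing_prob,
                                 predicted_cassette_psi)

L = 24000
gene = GeneModel(
    "DEMO", "+", L,
    exons=[(0, 2000), (8000, 10000), (16000, 18000), (22000, 24000)],
    introns=[Intron(0, 2000, 8000, L - 8000),
             Intron(1, 10000, 16000, L - 16000),
             Intron(2, 18000, 22000, L - 22000)],
)
rates = RateSet(sigma=2.0, v=1500.0, s=np.array([0.5, 0.15, 0.03]), c=0.4)

for intr in gene.introns:
    print(f"intron {intr.index}: s = {rates.s[intr.index]:.2f}/min, "
          f"time to transcribe = {time_to_transcribe(intr, rates):.1f} min, "
          f"P(cleaved before spliced) = "
          f"{100 * cleavage_before_splicing_prob(intr, rates):.1f}%")

print(f"predicted cassette-exon psi = "
      f"{predicted_cassette_psi(s_up=0.5, s_down=0.15, s_skip=0.1, dt=4.0):.3f}")
```

prints

```
intron 0: s = 0.50/min, time to transcribe = 4.0 min, P(cleaved before spliced) = 0.2%
intron 1: s = 0.15/min, time to transcribe = 4.0 min, P(cleaved before spliced) = 32.7%
intron 2: s = 0.03/min, time to transcribe = 2.7 min, P(cleaved before spliced) = 89.4%
predicted cassette-exon psi = 0.982
```

Intron 0 splices fast and sits 16 kb from the transcription end site, so it
is almost never still present when the transcript is cleaved. Intron 2
splices slowly and lies 2 kb from the TES: cleavage wins the race 89% of the
time, the signature of an intron whose removal must happen — if at all —
post-transcriptionally.

The same objects drive the end-to-end pipeline on synthetic data
(`splicewave run-all --seed 1 --outdir run/`): simulate a three-condition
study (control, a slow-splicing/slow-decay arm, a fast-decay arm), fit rates,
call differentially retained introns, score ActD decay, and compute overlap
and concordance statistics. On the default stated world the decay medians
order slow > control > fast and the two arms' ΔΨ values anticorrelate,
reproducing the qualitative asymmetry the pipeline is designed to detect.

## Command line

`splicewave` exposes subcommands `simulate`, `fit-rates`, `forward`,
`cleavage-prob`, `predict-psi`, `psi`, `call-ri`, `actd-decay`, `overlap`,
`concordance`, `subsample-test`, `ms-enrich`, and `run-all`. All stochastic
commands take `--seed`; `run-all` writes a content-hashed manifest and skips
stages that are up to date.

## Acceptance script

`python scripts/acceptance.py --seed <int> --out <path>` reruns the full
pipeline from scratch at that seed (simulation, rate fitting, kinetic
statistics, differential retention, decay scoring, set statistics) and
writes the summary JSON to `--out`; per-stage tables land next to it under
`acceptance_run/`.

## Layout

- `src/splicewave/genome.py` — gene models, GTF/BED12 I/O, intron features,
  splice-site nucleotide profiles
- `src/splicewave/kinetics.py` — forward model, molecule simulator, derived
  probabilities
- `src/splicewave/ratefit.py` — wavefront initializer and rate fitting
- `src/splicewave/simulate.py` — synthetic-data generator and ground truth
- `src/splicewave/psi.py` — Ψ/ΔΨ, retained-intron calling, z-scores
- `src/splicewave/decay.py` — ActD decay statistic, condition comparisons,
  fraction enrichment
- `src/splicewave/setstats.py` — overlap ORs, concordance, resampling tests,
  proteomics enrichment
- `src/splicewave/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
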