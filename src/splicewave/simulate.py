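"""Synthetic-data generator with known kinetic ground truth.

Emulates the statistical structure of a synchronized nascent-RNA study of
intron detention in a three-condition design: a vehicle control, a condition
that slows per-intron splicing and halves post-transcriptional intron decay
(the "slow" / type-II-inhibitor-like arm), and a condition that accelerates
post-transcriptional decay (the "fast" / type-I-inhibitor-like arm).  A
configurable fraction of introns is planted as "detained": shorter,
TES-proximal, and slow to splice — the feature profile of retained introns.

Ground-truth poly(A) percent-spliced-in per intron and condition is derived
mechanistically: the probability that the transcript is cleaved before the
intron is spliced co-transcriptionally, times exponential survival of
post-transcriptional decay over a fixed nuclear residence time,

    psi = P(cleave before splice | s, c, d) * exp(-k * T_nuc).

Everything downstream (time-course coverage, junction count tables, ActD
decay tables) is simulated from this truth with Poisson noise, so every
analysis stage can be checked against planted parameters.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as swio
from .genome import GeneModel, Intron, write_gtf
from .kinetics import (
    CoverageTimeCourse,
    RateSet,
    cleavage_before_splicing_prob,
    expected_timecourse,
)

DEFAULT_TIMES = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0)  # minutes post release


@dataclass(frozen=True)
class ConditionEffect:
    """Multiplicative shifts a condition applies to per-intron rates."""

    s_mult: float = 1.0  # splicing rate multiplier
    k_mult: float = 1.0  # post-transcriptional decay multiplier

    def __post_init__(self) -> None:
        if self.s_mult <= 0 or self.k_mult <= 0:
            raise ValueError("condition multipliers must be > 0")


def default_conditions() -> dict[str, ConditionEffect]:
    return {
        "control": ConditionEffect(1.0, 1.0),
        "slow": ConditionEffect(0.7, 0.5),  # type-II-inhibitor-like: more retention
        "fast": ConditionEffect(1.0, 1.5),  # type-I-inhibitor-like: less retention
    }


@dataclass
class SimConfig:
    """Stated world of the generator.  All rates in min^-1, lengths in nt.

    Rate priors are log-normal, parameterized by median and log-sd.  Default
    medians: elongation 1500 nt/min (typical Pol II), splicing 0.5/min
    (minutes-scale co-transcriptional half-life), cleavage 0.5/min, spawn
    1/min, post-transcriptional intron decay 0.0025/min (about a 20% loss
    over a 60-min transcription block, the scale seen in ActD experiments).
    """

    n_genes: int = 30
    seed: int = 0
    # gene structure
    intron_count_min: int = 1
    intron_count_max: int = 5
    exon_len_median: float = 150.0
    exon_len_log_sd: float = 0.4
    intron_len_median: float = 1500.0
    intron_len_log_sd: float = 0.6
    detained_len_median: float = 400.0
    detained_len_log_sd: float = 0.4
    min_exon_len: int = 30
    min_intron_len: int = 80
    ri_fraction: float = 0.2
    # kinetic rate priors (lognormal median, log-sd)
    sigma_median: float = 1.0
    sigma_log_sd: float = 0.7
    v_median: float = 1500.0
    v_log_sd: float = 0.3
    s_median: float = 0.5
    s_log_sd: float = 0.7
    s_detained_median: float = 0.05
    s_detained_log_sd: float = 0.5
    c_median: float = 0.5
    c_log_sd: float = 0.5
    k_median: float = 0.0025
    k_log_sd: float = 0.5
    nuclear_residence_min: float = 60.0
    # conditions
    conditions: dict[str, ConditionEffect] = field(default_factory=default_conditions)
    # sequencing / noise
    depth: float = 1.0  # time-course coverage scale
    polya_depth: float = 1000.0  # poly(A) junction-count scale per replicate
    actd_depth: float = 1000.0
    exon_level: float = 1.0  # flanking-exon abundance relative to depth
    exon_decay_rate: float = 0.0  # min^-1 during the transcription block
    actd_minutes: float = 60.0
    noise: str = "poisson"
    replicates: int = 2
    times: tuple[float, ...] = DEFAULT_TIMES
    bin_size: int = 50
    l_i: float = 2.0  # inclusion effective length (two exon-intron junctions)
    l_s: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sigma_median", "v_median", "s_median", "c_median", "k_median",
                     "s_detained_median", "depth", "polya_depth", "actd_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.ri_fraction <= 1.0:
            raise ValueError("ri_fraction must be in [0,1]")
        if self.noise not in ("poisson", "none"):
            raise ValueError("noise must be 'poisson' or 'none'")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if "control" not in self.conditions:
            raise ValueError("conditions must include 'control'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditions"] = {k: dataclasses.asdict(v) for k, v in self.conditions.items()}
        return d

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class GroundTruth:
    """Planted parameters: everything the downstream modules try to recover."""

    rates: dict[str, dict[str, RateSet]]  # condition -> gene_id -> RateSet
    psi: pd.DataFrame  # introns x conditions, true poly(A) percent-spliced-in
    k: pd.DataFrame  # introns x conditions, decay rate min^-1
    detained: pd.Series  # bool per intron_id
    config: SimConfig

    @property
    def conditions(self) -> list[str]:
        return list(self.psi.columns)

    def delta_psi(self, condition: str, control: str = "control") -> pd.Series:
        return self.psi[condition] - self.psi[control]


def _rng_for(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _lognormal(rng: np.random.Generator, median: float, log_sd: float, size=None):
    return np.exp(rng.normal(np.log(median), log_sd, size=size))


def sample_models_and_rates(config: SimConfig) -> tuple[list[GeneModel], GroundTruth]:
    """Draw gene structures and per-condition kinetic ground truth.

    Detained introns are planted with probability ``ri_fraction`` overall but
    weighted toward late ordinal positions, making them TES-proximal; their
    lengths and splicing rates come from the shorter/slower priors.
    """
    rng = _rng_for(config, 0)
    models: list[GeneModel] = []
    rates: dict[str, dict[str, RateSet]] = {c: {} for c in config.conditions}
    psi_rows, k_rows, detained_flags, intron_ids = [], [], [], []
    genomic_cursor = 0
    for g in range(config.n_genes):
        gene_id = f"g{g:04d}"
        n_introns = int(rng.integers(config.intron_count_min, config.intron_count_max + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        exon_lens = np.maximum(
            config.min_exon_len,
            _lognormal(rng, config.exon_len_median, config.exon_len_log_sd, n_introns + 1),
        ).astype(int)
        detained = np.zeros(n_introns, dtype=bool)
        intron_lens = np.empty(n_introns, dtype=int)
        s_control = np.empty(n_introns)
        # detention concentrates on TES-proximal introns: probability decays
        # geometrically with distance from the last intron, mean ri_fraction
        w = 0.4 ** np.arange(n_introns - 1, -1, -1, dtype=float)
        p_det = np.minimum(1.0, config.ri_fraction * n_introns * w / w.sum())
        for i in range(n_introns):
            detained[i] = rng.random() < p_det[i]
            if detained[i]:
                intron_lens[i] = max(
                    config.min_intron_len,
                    int(_lognormal(rng, config.detained_len_median, config.detained_len_log_sd)),
                )
                s_control[i] = _lognormal(rng, config.s_detained_median, config.s_detained_log_sd)
            else:
                intron_lens[i] = max(
                    config.min_intron_len,
                    int(_lognormal(rng, config.intron_len_median, config.intron_len_log_sd)),
                )
                s_control[i] = _lognormal(rng, config.s_median, config.s_log_sd)
        # assemble transcript-relative structure
        exons, introns = [], []
        pos = 0
        for i in range(n_introns + 1):
            exons.append((pos, pos + int(exon_lens[i])))
            pos += int(exon_lens[i])
            if i < n_introns:
                introns.append((pos, pos + int(intron_lens[i])))
                pos += int(intron_lens[i])
        length = pos
        intron_objs = [
            Intron(index=i, start=s, end=e, dist_to_tes=length - e)
            for i, (s, e) in enumerate(introns)
        ]
        model = GeneModel(
            gene_id=gene_id,
            strand=strand,
            length=length,
            exons=exons,
            introns=intron_objs,
            chrom="chrS",
            genomic_start=genomic_cursor,
            genomic_end=genomic_cursor + length,
        )
        genomic_cursor += length + 1000
        models.append(model)

        sigma = float(_lognormal(rng, config.sigma_median, config.sigma_log_sd))
        v = float(_lognormal(rng, config.v_median, config.v_log_sd))
        c = float(_lognormal(rng, config.c_median, config.c_log_sd))
        k_control = _lognormal(rng, config.k_median, config.k_log_sd, n_introns)

        for cond, eff in config.conditions.items():
            rs = RateSet(sigma=sigma, v=v, s=s_control * eff.s_mult, c=c)
            rates[cond][gene_id] = rs
            for intr in model.introns:
                p_cbs = cleavage_before_splicing_prob(intr, rs)
                k_cond = float(k_control[intr.index] * eff.k_mult)
                psi = p_cbs * np.exp(-k_cond * config.nuclear_residence_min)
                psi_rows.append((f"{gene_id}:{intr.index}", cond, psi))
                k_rows.append((f"{gene_id}:{intr.index}", cond, k_cond))
        for intr in model.introns:
            intron_ids.append(f"{gene_id}:{intr.index}")
            detained_flags.append(bool(detained[intr.index]))

    order = [c for c in config.conditions]
    if psi_rows:
        psi = pd.DataFrame(psi_rows, columns=["intron_id", "condition", "psi"]).pivot(
            index="intron_id", columns="condition", values="psi"
        ).loc[intron_ids, order]
        kdf = pd.DataFrame(k_rows, columns=["intron_id", "condition", "k"]).pivot(
            index="intron_id", columns="condition", values="k"
        ).loc[intron_ids, order]
    else:
        empty = pd.Index([], name="intron_id")
        psi = pd.DataFrame(index=empty, columns=order, dtype=float)
        kdf = pd.DataFrame(index=empty, columns=order, dtype=float)
    detained_series = pd.Series(detained_flags, index=pd.Index(intron_ids, name="intron_id"))
    truth = GroundTruth(rates=rates, psi=psi, k=kdf, detained=detained_series, config=config)
    return models, truth


# ---------------------------------------------------------------------------
# Sequences (for splice-site profile tests)
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _pwm(columns: dict[int, tuple[float, float, float, float]]) -> pd.DataFrame:
    df = pd.DataFrame(columns, index=list("ACGT"), dtype=float)
    return df / df.sum(axis=0)


# 5' splice-site position weight matrix (offsets -3..+6, no zero): CAG|GTAAGT
DEFAULT_5SS_PWM = _pwm({
    -3: (0.30, 0.40, 0.20, 0.10),
    -2: (0.60, 0.10, 0.15, 0.15),
    -1: (0.10, 0.05, 0.80, 0.05),
    +1: (0.00, 0.00, 1.00, 0.00),  # canonical G
    +2: (0.00, 0.00, 0.00, 1.00),  # canonical T
    +3: (0.60, 0.05, 0.30, 0.05),
    +4: (0.70, 0.05, 0.10, 0.15),
    +5: (0.10, 0.05, 0.80, 0.05),
    +6: (0.15, 0.15, 0.20, 0.50),
})

# 3' splice-site PWM (offsets -20..+3): polypyrimidine tract then NYAG|G
_PPT = (0.10, 0.30, 0.10, 0.50)
DEFAULT_3SS_PWM = _pwm(
    {o: _PPT for o in range(-20, -4)}
    | {
        -4: (0.10, 0.60, 0.05, 0.25),
        -3: (0.25, 0.30, 0.15, 0.30),
        -2: (1.00, 0.00, 0.00, 0.00),  # canonical A
        -1: (0.00, 0.00, 1.00, 0.00),  # canonical G
        +1: (0.25, 0.15, 0.50, 0.10),
        +2: (0.30, 0.20, 0.25, 0.25),
        +3: (0.25, 0.25, 0.25, 0.25),
    }
)


def sample_sequences(
    models: Sequence[GeneModel],
    seed: int | np.random.Generator = 0,
    pwm5: pd.DataFrame = DEFAULT_5SS_PWM,
    pwm3: pd.DataFrame = DEFAULT_3SS_PWM,
) -> dict[str, str]:
    """Pre-mRNA sequences: uniform background with PWM-sampled splice sites."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = {}
    for m in models:
        seq = rng.choice(_BASES, size=m.length)
        for intr in m.introns:
            for pwm, anchor in ((pwm5, intr.start), (pwm3, intr.end)):
                for off in pwm.columns:
                    idx = anchor + off - 1 if off > 0 else anchor + off
                    if 0 <= idx < m.length:
                        seq[idx] = rng.choice(_BASES, p=pwm[off].to_numpy())
        out[m.gene_id] = "".join(seq)
    return out


# ---------------------------------------------------------------------------
# Downstream observables
# ---------------------------------------------------------------------------

def simulate_timecourse(
    models: Sequence[GeneModel],
    truth: GroundTruth,
    times: Sequence[float] | None = None,
    config: SimConfig | None = None,
    condition: str = "control",
) -> dict[str, CoverageTimeCourse]:
    """Synchronized nascent-RNA coverage per gene: forward model x depth, Poisson noise."""
    config = config or truth.config
    times = np.asarray(times if times is not None else config.times, dtype=float)
    rng = _rng_for(config, 1)
    out = {}
    for m in models:
        tc = expected_timecourse(m, truth.rates[condition][m.gene_id], times, bin_size=config.bin_size)
        mean = tc.matrix * config.depth
        matrix = rng.poisson(mean).astype(float) if config.noise == "poisson" else mean
        out[m.gene_id] = CoverageTimeCourse(
            gene_id=m.gene_id, bin_size=config.bin_size,
            positions=tc.positions, times=times, matrix=matrix,
        )
    return out


def simulate_polya_counts(
    models: Sequence[GeneModel],
    truth: GroundTruth,
    depth: float | None = None,
    replicates: int | None = None,
    config: SimConfig | None = None,
) -> pd.DataFrame:
    """Poly(A)-RNA junction count table (long format, all conditions/replicates).

    Inclusion counts ~ Poisson(depth * psi * l_I), skip counts ~
    Poisson(depth * (1 - psi) * l_S), independently per replicate.
    """
    config = config or truth.config
    depth = depth if depth is not None else config.polya_depth
    replicates = replicates if replicates is not None else config.replicates
    rng = _rng_for(config, 2)
    rows = []
    for m in models:
        for intr in m.introns:
            iid = f"{m.gene_id}:{intr.index}"
            for cond in truth.conditions:
                psi = truth.psi.loc[iid, cond]
                mu_i = depth * psi * config.l_i
                mu_s = depth * (1.0 - psi) * config.l_s
                for rep in range(replicates):
                    if config.noise == "poisson":
                        I, S = int(rng.poisson(mu_i)), int(rng.poisson(mu_s))
                    else:
                        I, S = int(round(mu_i)), int(round(mu_s))
                    rows.append((iid, m.gene_id, intr.index, "RI", cond, rep, I, S, config.l_i, config.l_s))
    return pd.DataFrame(
        rows,
        columns=["event_id", "gene_id", "intron_index", "event_type",
                 "condition", "replicate", "I", "S", "l_I", "l_S"],
    )


def simulate_actd_counts(
    truth: GroundTruth,
    t_actd: float | None = None,
    depth: float | None = None,
    config: SimConfig | None = None,
) -> pd.DataFrame:
    """Paired (-ActD, +ActD) intron and flanking-exon counts per condition.

    Intron abundance decays as exp(-k_i * t) during the transcription block;
    flanking exons decay at ``config.exon_decay_rate`` (0 by default).
    """
    config = config or truth.config
    t = t_actd if t_actd is not None else config.actd_minutes
    depth = depth if depth is not None else config.actd_depth
    rng = _rng_for(config, 3)
    exon_mu_minus = depth * config.exon_level
    exon_mu_plus = exon_mu_minus * np.exp(-config.exon_decay_rate * t)
    rows = []
    for iid in truth.psi.index:
        for cond in truth.conditions:
            psi = truth.psi.loc[iid, cond]
            k = truth.k.loc[iid, cond]
            mu_minus = depth * psi
            mu_plus = mu_minus * np.exp(-k * t)
            for rep in range(config.replicates):
                if config.noise == "poisson":
                    vals = rng.poisson([mu_minus, mu_plus, exon_mu_minus, exon_mu_plus])
                else:
                    vals = np.round([mu_minus, mu_plus, exon_mu_minus, exon_mu_plus]).astype(int)
                rows.append((iid, cond, rep, *[int(x) for x in vals]))
    return pd.DataFrame(
        rows,
        columns=["intron_id", "condition", "replicate",
                 "intron_minus", "intron_plus", "exon_minus", "exon_plus"],
    )


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------

def write_fixture_bundle(
    outdir: str | Path,
    config: SimConfig,
    models: Sequence[GeneModel] | None = None,
    truth: GroundTruth | None = None,
    condition: str = "control",
) -> dict:
    """Write annotation, sequences, coverage tracks, count tables, and truth.

    Returns the manifest (also written as ``manifest.json``), keyed by the
    seed and a hash of the configuration.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if models is None or truth is None:
        models, truth = sample_models_and_rates(config)
    files: dict[str, str] = {}

    gtf = outdir / "genes.gtf"
    write_gtf(models, gtf)
    files["annotation"] = gtf.name

    seqs = sample_sequences(models, seed=_rng_for(config, 4))
    fa = outdir / "sequences.fa"
    swio.write_fasta(fa, seqs)
    files["sequences"] = fa.name

    tcs = simulate_timecourse(models, truth, config=config, condition=condition)
    if tcs:
        paths = swio.write_timecourses(outdir, tcs, prefix=f"coverage_{condition}")
        files["coverage"] = [p.name for p in paths]

    polya = simulate_polya_counts(models, truth, config=config)
    polya.to_csv(outdir / "polya_counts.tsv", sep="\t", index=False)
    files["polya_counts"] = "polya_counts.tsv"

    actd = simulate_actd_counts(truth, config=config)
    actd.to_csv(outdir / "actd_counts.tsv", sep="\t", index=False)
    files["actd_counts"] = "actd_counts.tsv"

    truth.psi.to_csv(outdir / "truth_psi.tsv", sep="\t")
    truth.k.to_csv(outdir / "truth_k.tsv", sep="\t")
    truth.detained.rename("detained").to_csv(outdir / "truth_detained.tsv", sep="\t")
    rate_rows = []
    for cond, per_gene in truth.rates.items():
        for gid, rs in per_gene.items():
            rate_rows.append(
                {"condition": cond, "gene_id": gid, "sigma": rs.sigma, "v": rs.v,
                 "c": rs.c, "s": ",".join(f"{x:g}" for x in rs.s)}
            )
    pd.DataFrame(rate_rows).to_csv(outdir / "truth_rates.tsv", sep="\t", index=False)
    files["truth"] = ["truth_psi.tsv", "truth_k.tsv", "truth_detained.tsv", "truth_rates.tsv"]

    manifest = {"seed": config.seed, "config_hash": config.hash(),
                "config": config.to_dict(), "files": files}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
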