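"""Forward kinetic model of synchronized nascent transcription.

After release from a DRB block, polymerases initiate ("spawn") as a Poisson
process with rate sigma (min^-1) and elongate at a constant speed v (nt/min).
Each intron i acquires an exponential splicing clock with rate s_i (min^-1)
once its 3' splice site is transcribed; the transcript acquires an exponential
cleavage clock with rate c (min^-1) once the TES is reached.  Spliced intron
RNA and cleaved transcripts leave the chromatin-associated fraction, so the
expected chromatin coverage at a position integrates the survival of those
two clocks over polymerase spawn times.

The module provides the deterministic forward model (`expected_coverage`),
an exact stochastic molecule simulator used as an internal oracle
(`simulate_molecules`, `monte_carlo_coverage`), and the derived per-intron
statistics: time to transcribe, the competing-risks probability of transcript
cleavage before co-transcriptional splicing, and the commitment-race
prediction of poly(A) cassette-exon percent-spliced-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import GeneModel, Intron

DEFAULT_QUAD_STEP = 0.05  # minutes; trapezoid step for the spawn-time integral
DEFAULT_BIN_SIZE = 50  # nt


@dataclass
class RateSet:
    """Per-gene kinetic parameters.

    sigma : spawn (initiation + pause-release) rate, events/min
    v     : elongation rate, nt/min
    s     : per-intron splicing rates, 1/min (order matches GeneModel.introns)
    c     : transcript cleavage rate, 1/min
    """

    sigma: float
    v: float
    s: np.ndarray
    c: float

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if not (self.sigma > 0 and self.v > 0 and self.c > 0):
            raise ValueError("sigma, v, c must be > 0")
        if (self.s < 0).any():
            raise ValueError("splicing rates must be >= 0")


@dataclass
class CoverageTimeCourse:
    """Nascent-RNA coverage on one gene, positions x times matrix."""

    gene_id: str
    bin_size: int
    positions: np.ndarray  # bin start coordinates, transcript-relative nt
    times: np.ndarray  # minutes post release
    matrix: np.ndarray  # shape (n_bins, n_times), non-negative

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions)
        self.times = np.asarray(self.times, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.positions), len(self.times)):
            raise ValueError("matrix shape inconsistent with positions/times")
        if (self.matrix < 0).any():
            raise ValueError("coverage must be non-negative")


@dataclass
class MoleculeState:
    """State of one nascent transcript at the observation time."""

    tau: float  # spawn time, min
    front: float  # polymerase position, nt (capped at L)
    intron_status: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    cleaved: bool = False

    UNTRANSCRIBED = 0
    PRESENT = 1
    SPLICED = 2


def _position_splicing_terms(model: GeneModel, rates: RateSet):
    """Per-intron (start, e3) arrays for mapping positions to splicing rates."""
    starts = np.array([i.start for i in model.introns], dtype=float)
    ends = np.array([i.end for i in model.introns], dtype=float)
    return starts, ends


def expected_coverage(
    model: GeneModel,
    rates: RateSet,
    t: float,
    bins: np.ndarray | None = None,
    bin_size: int = DEFAULT_BIN_SIZE,
    quad_step: float = DEFAULT_QUAD_STEP,
) -> np.ndarray:
    """Expected chromatin-associated coverage at time t after release.

    For a position x the coverage integrates sigma over spawn times
    tau in [0, t - x/v], weighted by the survival
    ``exp(-s_i * max(0, t - tau - e3_i/v))`` if x lies in intron i and by
    the cleavage survival ``exp(-c * max(0, t - tau - L/v))`` everywhere.
    The integral is evaluated by trapezoid quadrature with step <= quad_step.

    Parameters
    ----------
    bins : positions (nt) at which to evaluate; defaults to
        ``arange(0, L, bin_size)``.
    """
    if t <= 0:
        raise ValueError("t must be > 0")
    if rates.v <= 0:
        raise ValueError("v must be > 0")
    if len(rates.s) != model.n_introns:
        raise ValueError("rates.s length must match number of introns")
    x = np.arange(0, model.length, bin_size, dtype=float) if bins is None else np.asarray(bins, dtype=float)
    if x.size and (x.min() < 0 or x.max() >= model.length):
        raise ValueError("bins must lie within [0, L)")

    v, c, L = rates.v, rates.c, float(model.length)
    # per-position splicing rate and 3'SS arrival delay
    s_x = np.zeros_like(x)
    a_x = np.zeros_like(x)  # e3_i / v for intronic positions
    for intr, s_i in zip(model.introns, rates.s):
        mask = (x >= intr.start) & (x < intr.end)
        s_x[mask] = s_i
        a_x[mask] = intr.end / v

    T = np.maximum(0.0, t - x / v)  # upper integration limit per position
    Tmax = T.max(initial=0.0)
    if Tmax == 0.0:
        return np.zeros_like(x)
    n_tau = max(2, int(np.ceil(Tmax / quad_step)) + 1)
    u = np.linspace(0.0, 1.0, n_tau)  # shared relative grid
    tau = T[:, None] * u[None, :]  # (n_pos, n_tau)
    age = t - tau
    integrand = np.exp(
        -s_x[:, None] * np.maximum(0.0, age - a_x[:, None])
        - c * np.maximum(0.0, age - L / v)
    )
    cov = rates.sigma * np.trapezoid(integrand, x=tau, axis=1)
    cov[T == 0.0] = 0.0
    return cov


def expected_timecourse(
    model: GeneModel,
    rates: RateSet,
    times,
    bin_size: int = DEFAULT_BIN_SIZE,
    quad_step: float = DEFAULT_QUAD_STEP,
) -> CoverageTimeCourse:
    """Convenience wrapper: expected coverage at several times as a matrix."""
    times = np.asarray(times, dtype=float)
    positions = np.arange(0, model.length, bin_size)
    matrix = np.column_stack(
        [
            expected_coverage(model, rates, t, bins=positions, quad_step=quad_step)
            for t in times
        ]
    )
    return CoverageTimeCourse(
        gene_id=model.gene_id, bin_size=bin_size, positions=positions, times=times, matrix=matrix
    )


# ---------------------------------------------------------------------------
# Stochastic molecule simulator (internal oracle for the forward model)
# ---------------------------------------------------------------------------

def _simulate_arrays(
    model: GeneModel, rates: RateSet, t: float, n: int, rng: np.random.Generator
):
    """Vectorized molecule simulation; returns (tau, front, status, cleaved)."""
    tau = rng.uniform(0.0, t, size=n)
    front = np.minimum(rates.v * (t - tau), float(model.length))
    e3 = np.array([i.end for i in model.introns], dtype=float)
    starts = np.array([i.start for i in model.introns], dtype=float)
    # splicing clocks start when the 3'SS is transcribed
    status = np.full((n, model.n_introns), MoleculeState.PRESENT, dtype=np.int8)
    if model.n_introns:
        age_at_e3 = t - tau[:, None] - e3[None, :] / rates.v  # time since 3'SS made
        untr = front[:, None] <= starts[None, :]
        status[untr] = MoleculeState.UNTRANSCRIBED
        with np.errstate(divide="ignore"):
            scale = np.where(rates.s > 0, 1.0 / np.where(rates.s > 0, rates.s, 1.0), np.inf)
        wait = rng.exponential(1.0, size=(n, model.n_introns)) * scale[None, :]
        spliced = (age_at_e3 > 0) & (wait < age_at_e3) & ~untr
        status[spliced] = MoleculeState.SPLICED
    age_at_tes = t - tau - model.length / rates.v
    cleave_wait = rng.exponential(scale=1.0 / rates.c, size=n)
    cleaved = (age_at_tes > 0) & (cleave_wait < age_at_tes)
    return tau, front, status, cleaved


def simulate_molecules(
    model: GeneModel,
    rates: RateSet,
    t: float,
    n: int | None = None,
    seed: int | np.random.Generator = 0,
) -> list[MoleculeState]:
    """Exact stochastic realization of the forward model at time t.

    If ``n`` is None the number of molecules is drawn Poisson(sigma * t), the
    marginal of the spawn process; otherwise exactly ``n`` molecules are
    simulated with spawn times uniform on [0, t] (the conditional law of a
    homogeneous Poisson process given its count).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n is None:
        n = int(rng.poisson(rates.sigma * t))
    elif n < 1:
        raise ValueError("n must be >= 1")
    tau, front, status, cleaved = _simulate_arrays(model, rates, t, n, rng)
    return [
        MoleculeState(tau=tau[i], front=front[i], intron_status=status[i], cleaved=bool(cleaved[i]))
        for i in range(n)
    ]


def monte_carlo_coverage(
    model: GeneModel,
    rates: RateSet,
    t: float,
    bins: np.ndarray | None = None,
    bin_size: int = DEFAULT_BIN_SIZE,
    n: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo estimate (mean, standard error) of chromatin coverage.

    Simulates ``n`` molecules conditioned on the spawn count and rescales by
    the Poisson intensity sigma*t, giving an unbiased estimator of
    `expected_coverage` at each bin.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.arange(0, model.length, bin_size, dtype=float) if bins is None else np.asarray(bins, dtype=float)
    _, front, status, cleaved = _simulate_arrays(model, rates, t, n, rng)
    starts = np.array([i.start for i in model.introns], dtype=float)
    ends = np.array([i.end for i in model.introns], dtype=float)
    # molecule covers x iff transcribed past x, not cleaved, and (if x is
    # intronic) the intron not yet spliced out
    contrib = (front[:, None] > x[None, :]) & ~cleaved[:, None]
    for j in range(model.n_introns):
        in_intron = (x >= starts[j]) & (x < ends[j])
        if in_intron.any():
            removed = status[:, j] == MoleculeState.SPLICED
            contrib[:, in_intron] &= ~removed[:, None]
    weight = rates.sigma * t  # Poisson intensity on [0, t]
    frac = contrib.mean(axis=0)
    mean = weight * frac
    se = weight * np.sqrt(np.maximum(frac * (1 - frac), 0.0) / n)
    return mean, se


# ---------------------------------------------------------------------------
# Derived per-intron statistics
# ---------------------------------------------------------------------------

def time_to_transcribe(intron: Intron, rates: RateSet) -> float:
    """Minutes for the polymerase to traverse the intron: length / v."""
    if rates.v <= 0:
        raise ValueError("v must be > 0")
    return intron.length / rates.v


def cleavage_before_splicing_prob(intron: Intron, rates: RateSet) -> float:
    """Probability the transcript is cleaved before the intron is spliced.

    The splicing clock Exp(s_i) starts when the 3'SS is transcribed; the
    cleavage clock Exp(c) starts d = dist_to_TES / v minutes later, when the
    polymerase reaches the TES.  The probability that cleavage wins,
    P(d + Exp(c) < Exp(s)), has the closed form

        P = exp(-s * d) * c / (c + s)

    (the intron must survive the head start, then lose the memoryless race).
    """
    s = float(rates.s[intron.index])
    c = rates.c
    if s < 0 or c <= 0:
        raise ValueError("need s >= 0 and c > 0")
    d = intron.dist_to_tes / rates.v
    if s == 0:
        return 1.0
    return float(np.exp(-s * d) * c / (c + s))


def cleavage_prob_mc(
    s: float, c: float, d: float, n: int = 1_000_000, seed: int | np.random.Generator = 0
) -> tuple[float, float]:
    """Brute-force estimate of P(d + Exp(c) < Exp(s)) with its standard error."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if s == 0:
        return 1.0, 0.0
    x = rng.exponential(1.0 / s, size=n)
    y = rng.exponential(1.0 / c, size=n)
    p = float(np.mean(d + y < x))
    return p, float(np.sqrt(p * (1 - p) / n))


def predicted_cassette_psi(
    s_up: float,
    s_down: float,
    s_skip: float,
    dt: float,
    mode: str = "closed_form",
    n: int = 1_000_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Predicted poly(A)-RNA percent-spliced-in for a cassette exon.

    Inclusion is committed as soon as either flanking intron splices; the
    exon is skipped if the skip event (rate ``s_skip``) fires first.  The
    upstream intron's clock gets a head start of ``dt`` minutes — the time
    the polymerase needs to travel from the upstream 3'SS to the downstream
    3'SS — during which only upstream splicing can occur.  Closed form:

        psi = 1 - exp(-s_up * dt) * s_skip / (s_up + s_down + s_skip)

    Cleavage does not censor the race: splicing may finish
    post-transcriptionally.  ``mode='mc'`` simulates the race explicitly.
    """
    if min(s_up, s_down, s_skip) < 0:
        raise ValueError("rates must be >= 0")
    if s_up + s_down + s_skip == 0:
        raise ValueError("all three rates are zero; psi undefined")
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if mode == "closed_form":
        return float(1.0 - np.exp(-s_up * dt) * s_skip / (s_up + s_down + s_skip))
    if mode != "mc":
        raise ValueError("mode must be 'closed_form' or 'mc'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def draws(rate: float) -> np.ndarray:
        if rate == 0:
            return np.full(n, np.inf)
        return rng.exponential(1.0 / rate, size=n)

    t_up = draws(s_up)  # clock starts at 0
    t_down = dt + draws(s_down)  # clocks start at dt
    t_skip = dt + draws(s_skip)
    skipped = (t_skip < t_up) & (t_skip < t_down)
    return float(1.0 - skipped.mean())
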