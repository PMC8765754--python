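"""Recover kinetic rates from a synchronized nascent-RNA coverage time course.

The fit minimizes the sum of squared residuals between observed coverage and
the forward model over log-parameters (log sigma, log v, log s_i, log c) with
box constraints, using multi-start local optimization.  A wavefront regression
on the leading edge of the polymerase wave initializes the elongation rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genome import GeneModel
from .kinetics import CoverageTimeCourse, RateSet, expected_coverage

# log10 bounds on (sigma, v, s_i, c)
BOUNDS = {
    "sigma": (1e-3, 1e3),
    "v": (1e2, 1e5),
    "s": (1e-4, 1e2),
    "c": (1e-3, 1e2),
}
PRIOR_MEDIAN_V = 1500.0  # nt/min, wavefront fallback


@dataclass
class FitResult:
    rates: RateSet
    loss: float
    converged: bool
    n_restarts: int
    start_losses: list[float] = field(default_factory=list)
    gene_id: str = ""

    def __post_init__(self) -> None:
        if self.loss < 0:
            raise ValueError("loss must be >= 0")


def estimate_elongation_wavefront(
    tc: CoverageTimeCourse,
    threshold_frac: float = 0.02,
    fallback_v: float = PRIOR_MEDIAN_V,
) -> float:
    """Elongation-rate initializer from the leading edge of the coverage wave.

    For each time point the wavefront is the first bin whose coverage drops
    below ``threshold_frac`` times the maximum upstream coverage; the slope
    of the least-squares line of front position against time estimates v.
    The wave's leading edge tapers linearly, so detection at a fraction f of
    the peak biases the slope by (1 - f); the small default threshold keeps
    this below the initializer's accuracy needs while bins beyond the true
    front stay exactly zero even under Poisson noise.
    Falls back to ``fallback_v`` when fewer than two time points have a
    detectable front inside the gene.
    """
    fronts, times = [], []
    for j, t in enumerate(tc.times):
        col = tc.matrix[:, j]
        peak = col.max()
        if peak <= 0:
            continue
        covered = np.nonzero(col >= threshold_frac * peak)[0]
        front_idx = covered[-1]
        # require the front strictly inside the gene (wave not yet at the TES)
        if front_idx >= len(col) - 1:
            continue
        fronts.append(tc.positions[front_idx + 1])
        times.append(t)
    if len(fronts) < 2:
        warnings.warn("wavefront not detectable at >=2 time points; using prior median v")
        return float(fallback_v)
    slope, _, _, _, _ = stats.linregress(times, fronts)
    if slope <= 0:
        warnings.warn("non-positive wavefront slope; using prior median v")
        return float(fallback_v)
    return float(slope)


def _unpack(theta: np.ndarray, n_introns: int) -> RateSet:
    return RateSet(
        sigma=float(np.exp(theta[0])),
        v=float(np.exp(theta[1])),
        s=np.exp(theta[2 : 2 + n_introns]),
        c=float(np.exp(theta[-1])),
    )


def fit_rates(
    tc: CoverageTimeCourse,
    model: GeneModel,
    n_restarts: int = 5,
    seed: int = 0,
    quad_step: float = 0.05,
    jitter_sd: float = 0.5,
    depth: float = 1.0,
) -> FitResult:
    """Fit (sigma, v, s_i, c) to an observed coverage time course.

    Bins that no polymerase could have reached by the last time point (using
    the wavefront-estimated v) are excluded.  ``depth`` divides the observed
    coverage so the recovered sigma is on the forward-model scale; leave at 1
    to absorb sequencing depth into sigma.
    """
    if len(tc.times) < 3:
        raise ValueError("need at least 3 time points")
    if tc.matrix.max() <= 0:
        raise ValueError(f"gene {model.gene_id} not expressed (all-zero coverage)")
    obs = tc.matrix / depth
    n_introns = model.n_introns
    rng = np.random.default_rng(seed)

    v0 = estimate_elongation_wavefront(tc)
    t_last = float(tc.times.max())
    reachable = tc.positions < v0 * t_last
    if not reachable.any():
        reachable = np.ones(len(tc.positions), dtype=bool)
    positions = np.asarray(tc.positions, float)[reachable]
    obs = obs[reachable, :]

    # crude sigma initializer from the linear ramp upstream of the wave:
    # coverage ~ sigma * (t - x/v) at exonic, pre-TES-arrival bins
    with np.errstate(divide="ignore", invalid="ignore"):
        ramp = tc.times[None, :] - positions[:, None] / v0
        ratio = np.where(ramp > 0.5, obs / np.maximum(ramp, 1e-9), np.nan)
    sigma0 = np.nanmedian(ratio)
    if not np.isfinite(sigma0) or sigma0 <= 0:
        sigma0 = 1.0

    lo = np.log(np.concatenate(([BOUNDS["sigma"][0], BOUNDS["v"][0]],
                                np.full(n_introns, BOUNDS["s"][0]), [BOUNDS["c"][0]])))
    hi = np.log(np.concatenate(([BOUNDS["sigma"][1], BOUNDS["v"][1]],
                                np.full(n_introns, BOUNDS["s"][1]), [BOUNDS["c"][1]])))
    theta0 = np.log(np.concatenate(([sigma0, v0], np.full(n_introns, 0.5), [0.5])))
    theta0 = np.clip(theta0, lo, hi)

    def residuals(theta: np.ndarray) -> np.ndarray:
        rates = _unpack(theta, n_introns)
        pred = np.column_stack(
            [expected_coverage(model, rates, t, bins=positions, quad_step=quad_step)
             for t in tc.times]
        )
        return (pred - obs).ravel()

    best = None
    start_losses: list[float] = []
    any_converged = False
    for start in range(n_restarts):
        theta_start = theta0 if start == 0 else np.clip(
            theta0 + rng.normal(0.0, jitter_sd, size=theta0.size), lo, hi
        )
        try:
            sol = optimize.least_squares(
                residuals, theta_start, bounds=(lo, hi), method="trf",
                xtol=1e-10, ftol=1e-10,
            )
        except Exception:
            continue
        loss = float(np.sum(sol.fun**2))
        start_losses.append(loss)
        any_converged = any_converged or bool(sol.success)
        # best loss wins; ties broken by smallest parameter-vector norm
        key = (loss, float(np.linalg.norm(sol.x)))
        if best is None or key < best[0]:
            best = (key, sol)
    if best is None:
        raise RuntimeError(f"all optimizer starts failed for {model.gene_id}")
    if not any_converged:
        warnings.warn(f"{model.gene_id}: no optimizer start reported convergence")
    sol = best[1]
    return FitResult(
        rates=_unpack(sol.x, n_introns),
        loss=best[0][0],
        converged=any_converged,
        n_restarts=n_restarts,
        start_losses=start_losses,
        gene_id=model.gene_id,
    )


def fits_to_frame(fits: list[FitResult]) -> pd.DataFrame:
    rows = []
    for f in fits:
        rows.append({
            "gene_id": f.gene_id, "sigma": f.rates.sigma, "v": f.rates.v,
            "c": f.rates.c, "s": ",".join(f"{x:g}" for x in f.rates.s),
            "loss": f.loss, "converged": f.converged,
        })
    return pd.DataFrame(rows)


def spawn_expression_correlation(
    fits: list[FitResult], tpm: pd.Series | dict
) -> tuple[float, float]:
    """Spearman rank correlation between fitted spawn rates and expression.

    ``tpm`` maps gene_id to an expression value; at least 10 genes must be
    shared with the fits.
    """
    tpm = pd.Series(tpm)
    sigma = pd.Series({f.gene_id: f.rates.sigma for f in fits})
    common = sigma.index.intersection(tpm.index)
    if len(common) < 10:
        raise ValueError(f"need >=10 shared genes, have {len(common)}")
    a, b = sigma[common].to_numpy(), tpm[common].to_numpy(float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)
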