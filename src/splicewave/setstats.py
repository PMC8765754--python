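"""Cross-dataset set statistics: overlap odds ratios, delta-psi concordance,
size-matched resampling tests, and proteomics differential enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class OverlapResult:
    """Fisher-exact overlap of two gene/intron sets within a stated universe."""

    n_a: int
    n_b: int
    n_both: int
    n_universe: int
    table: np.ndarray  # [[both, a_only], [b_only, neither]]
    odds_ratio: float
    log2_odds_ratio: float
    p: float
    q: float | None = None  # BH-adjusted across the pairs of one call


def overlap_or(set_a, set_b, universe) -> OverlapResult:
    """Sample odds ratio and two-sided Fisher exact p for set overlap.

    The 2x2 table is [[|A∩B|, |A\\B|], [|B\\A|, |U\\(A∪B)|]].  The odds ratio
    is the sample (cross-product) estimator with a Haldane-Anscombe +0.5
    correction applied to every cell when any cell is zero; the p-value is
    the exact hypergeometric (Fisher) test.
    """
    A, B, U = set(set_a), set(set_b), set(universe)
    if not A <= U or not B <= U:
        raise ValueError("sets must be subsets of the universe")
    both = len(A & B)
    a_only = len(A - B)
    b_only = len(B - A)
    neither = len(U) - len(A | B)
    table = np.array([[both, a_only], [b_only, neither]])
    cells = table.astype(float)
    if (cells == 0).any():
        cells = cells + 0.5
    odds = (cells[0, 0] * cells[1, 1]) / (cells[0, 1] * cells[1, 0])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return OverlapResult(
        n_a=len(A), n_b=len(B), n_both=both, n_universe=len(U), table=table,
        odds_ratio=float(odds), log2_odds_ratio=float(np.log2(odds)), p=float(p),
    )


def overlap_or_many(pairs: dict[str, tuple], universe) -> pd.DataFrame:
    """Overlap ORs for several set pairs, BH-corrected within this call.

    ``pairs`` maps a label to an (A, B) tuple; the BH family is exactly the
    pair list of this call.
    """
    results = {name: overlap_or(a, b, universe) for name, (a, b) in pairs.items()}
    q = multipletests([r.p for r in results.values()], method="fdr_bh")[1]
    rows = []
    for qi, (name, r) in zip(q, results.items()):
        r.q = float(qi)
        rows.append({"pair": name, "n_a": r.n_a, "n_b": r.n_b, "n_both": r.n_both,
                     "odds_ratio": r.odds_ratio, "log2_odds_ratio": r.log2_odds_ratio,
                     "p": r.p, "q": r.q})
    return pd.DataFrame(rows).set_index("pair")


def delta_psi_concordance(
    delta_a: pd.Series, delta_b: pd.Series, min_common: int = 10
) -> dict:
    """Spearman correlation and sign agreement of delta-psi on common events."""
    a, b = pd.Series(delta_a).dropna(), pd.Series(delta_b).dropna()
    common = a.index.intersection(b.index)
    if len(common) < min_common:
        raise ValueError(f"need >= {min_common} common events, have {len(common)}")
    x, y = a[common].to_numpy(float), b[common].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant delta-psi vector: correlation undefined")
    rho, p = stats.spearmanr(x, y)
    sign_agree = float(np.mean(np.sign(x) == np.sign(y)))
    return {"rho": float(rho), "p": float(p), "sign_agreement": sign_agree,
            "n_common": int(len(common))}


def subsampled_wilcoxon(
    subset, global_values, n_rep: int = 1000, seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Size-matched resampled rank-sum test: median p over repetitions.

    Each repetition draws |subset| values without replacement from the global
    population and rank-sum-tests the subset against the draw; the median of
    the ``n_rep`` p-values is reported, removing the sensitivity of a single
    rank-sum p to the global/subset size imbalance.
    """
    subset = np.asarray(subset, dtype=float)
    pool = np.asarray(global_values, dtype=float)
    if subset.size < 3:
        raise ValueError("subset must have >= 3 values")
    if subset.size > pool.size:
        raise ValueError("subset larger than global population")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = np.random.default_rng(seed)
    ps = np.empty(n_rep)
    for r in range(n_rep):
        draw = rng.choice(pool, size=subset.size, replace=False)
        ps[r] = stats.mannwhitneyu(subset, draw, alternative="two-sided").pvalue
    return float(np.median(ps)), ps


def diff_enrichment(
    matrix: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    log2_transform: bool = True,
    normalize: bool = True,
) -> pd.DataFrame:
    """Per-protein Welch t-test on (optionally log2, mean-centered) abundances.

    ``matrix`` is proteins x samples.  With ``normalize`` each sample is
    centered by its own mean on the log2 scale ("normalized by the average of
    the data distribution").  log2FC is mean(group_a) - mean(group_b).
    Proteins with non-positive or missing intensities are flagged and get no
    p-value (no imputation).
    """
    for col in list(group_a) + list(group_b):
        if col not in matrix.columns:
            raise ValueError(f"sample {col!r} not in matrix")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 replicates per group")
    data = matrix[list(group_a) + list(group_b)].astype(float)
    bad = (data.isna() | (data <= 0)).any(axis=1) if log2_transform else data.isna().any(axis=1)
    vals = data.copy()
    if log2_transform:
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.log2(vals)
    if normalize:
        vals = vals - vals.mean(axis=0)
    rows = []
    for prot in matrix.index:
        if bad.loc[prot]:
            rows.append({"protein": prot, "log2fc": np.nan, "t": np.nan,
                         "df": np.nan, "p": np.nan, "flag": "nonpositive_or_missing"})
            continue
        a = vals.loc[prot, group_a].to_numpy()
        b = vals.loc[prot, group_b].to_numpy()
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            # degenerate Welch t: no within-group variance
            t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        na, nb = len(a), len(b)
        denom = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        dof = (va / na + vb / nb) ** 2 / denom if denom > 0 else np.nan
        rows.append({"protein": prot, "log2fc": float(a.mean() - b.mean()),
                     "t": float(t), "df": float(dof), "p": float(p), "flag": ""})
    return pd.DataFrame(rows).set_index("protein")


def background_subtract_polya(
    enriched: pd.DataFrame, control: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Subtract a competitor-control background on the log2 scale.

    Per protein, corrected = enriched - matched control (column-aligned by
    position if column names differ).  Proteins whose corrected abundance is
    <= 0 in every replicate are dropped.  Proteins absent from the control
    are kept, subtracting the control matrix's minimum as a
    limit-of-detection stand-in, and flagged.
    """
    ctrl = control.copy()
    ctrl.columns = enriched.columns[: ctrl.shape[1]]
    lod = float(np.nanmin(ctrl.to_numpy())) if ctrl.size else 0.0
    flags = pd.Series("", index=enriched.index, name="flag")
    corrected = enriched.copy().astype(float)
    matched = enriched.index.intersection(ctrl.index)
    unmatched = enriched.index.difference(ctrl.index)
    corrected.loc[matched] = enriched.loc[matched] - ctrl.loc[matched].to_numpy()
    corrected.loc[unmatched] = enriched.loc[unmatched] - lod
    flags.loc[unmatched] = "no_control_match"
    keep = (corrected > 0).any(axis=1)
    return corrected[keep], flags[keep]
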