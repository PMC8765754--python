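"""Post-transcriptional intron-decay statistics from a transcription block.

After blocking transcription (actinomycin D, default 60 min), the change in
intron abundance — normalized to the flanking exons to cancel transcript-level
decay and depth differences — measures post-transcriptional intron processing:

    delta = log2( ((intron+ + e) / (exon+ + e)) / ((intron- + e) / (exon- + e)) )

with a pseudocount e (default 0.5) for zero-count robustness.  For a true
first-order decay rate k and block duration t, delta converges to -k*t/ln(2)
as depth grows.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_PSEUDOCOUNT = 0.5


def actd_decay_stat(
    intron_minus, intron_plus, exon_minus, exon_plus,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
):
    """Flanking-exon-normalized log2 intron decay statistic (vectorized)."""
    arrs = [np.asarray(a, dtype=float) for a in (intron_minus, intron_plus, exon_minus, exon_plus)]
    if any((a < 0).any() for a in arrs):
        raise ValueError("counts must be non-negative")
    im, ip, em, ep = [a + pseudocount for a in arrs]
    delta = np.log2((ip / ep) / (im / em))
    return delta if delta.ndim else float(delta)


def decay_table(
    counts: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT, pool_replicates: bool = True
) -> pd.DataFrame:
    """Per-intron, per-condition decay statistics from a paired count table.

    ``counts`` needs columns intron_id, condition, intron_minus, intron_plus,
    exon_minus, exon_plus (and replicate, pooled by summation by default).
    All-zero rows are flagged; the pseudocount keeps delta defined.
    """
    need = ["intron_id", "condition", "intron_minus", "intron_plus", "exon_minus", "exon_plus"]
    missing = [c for c in need if c not in counts.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    if pool_replicates:
        counts = (
            counts.groupby(["intron_id", "condition"], as_index=False)[
                ["intron_minus", "intron_plus", "exon_minus", "exon_plus"]
            ].sum()
        )
    out = counts.copy()
    out["delta"] = actd_decay_stat(
        counts["intron_minus"], counts["intron_plus"],
        counts["exon_minus"], counts["exon_plus"], pseudocount,
    )
    out["flag"] = np.where(
        counts[["intron_minus", "intron_plus", "exon_minus", "exon_plus"]].sum(axis=1) == 0,
        "all_zero", "",
    )
    return out


def compare_decay(deltas: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Per-condition median decay and pairwise Wilcoxon rank-sum p-values.

    ``deltas`` is an introns x conditions matrix of decay statistics on the
    common intron set.  Pairs with fewer than 3 finite values per side have
    their p omitted (NaN).
    """
    if deltas.empty:
        raise ValueError("no common introns")
    medians = deltas.median()
    rows = []
    for a, b in combinations(deltas.columns, 2):
        x = deltas[a].dropna().to_numpy()
        y = deltas[b].dropna().to_numpy()
        if len(x) < 3 or len(y) < 3:
            p = np.nan
        else:
            p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        rows.append({"condition_a": a, "condition_b": b, "p": p,
                     "median_a": medians[a], "median_b": medians[b]})
    return medians, pd.DataFrame(rows)


def fraction_enrichment(
    counts: pd.DataFrame,
    nuclear_fractions: tuple[str, ...] = ("chromatin", "nucleoplasm"),
    cytoplasmic_fraction: str = "cytoplasm",
) -> dict:
    """Nuclear-vs-cytoplasmic enrichment of introns with a two-way ANOVA.

    ``counts`` is long format with columns intron_id, klass (e.g. "RI" vs
    "control"), fraction, replicate, abundance.  Reports the per-intron ratio
    of mean nuclear to mean cytoplasmic abundance, a two-factor
    (fraction x klass) ANOVA, and Tukey-adjusted pairwise comparisons of the
    fraction-by-klass groups.  Requires >= 2 replicates.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    need = ["intron_id", "klass", "fraction", "replicate", "abundance"]
    missing = [c for c in need if c not in counts.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    fractions = set(counts["fraction"].unique())
    if len(fractions) < 2:
        raise ValueError("need >= 2 fractions")
    if counts.groupby(["intron_id", "fraction"])["replicate"].nunique().min() < 2:
        raise ValueError("two-way ANOVA requires >= 2 replicates per cell")

    per = counts.groupby(["intron_id", "klass", "fraction"])["abundance"].mean().unstack("fraction")
    nuc_cols = [f for f in nuclear_fractions if f in per.columns]
    ratios = None
    if nuc_cols and cytoplasmic_fraction in per.columns:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = per[nuc_cols].mean(axis=1) / per[cytoplasmic_fraction]
        ratios = ratios.rename("nuclear_cytoplasmic_ratio").reset_index()
    else:
        warnings.warn("missing nuclear or cytoplasmic fraction; ratio contrast omitted")

    df = counts.copy()
    df["log_abundance"] = np.log2(df["abundance"].astype(float) + 0.5)
    fit = smf.ols("log_abundance ~ C(fraction) * C(klass)", data=df).fit()
    anova = sm.stats.anova_lm(fit, typ=2)
    group = df["fraction"].astype(str) + ":" + df["klass"].astype(str)
    tukey = pairwise_tukeyhsd(df["log_abundance"].to_numpy(), group.to_numpy())
    return {"ratios": ratios, "anova": anova, "tukey": tukey}
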