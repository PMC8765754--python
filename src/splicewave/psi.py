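"""Percent-spliced-in (psi) quantification, differential retention, and
feature-distribution comparisons.

Counts follow the rMATS-style convention: per splicing event, an inclusion
count I (reads supporting the retained form) and a skip count S, with
effective lengths l_I and l_S normalizing for the number of junctions each
form offers (defaults 2 and 1 for a retained intron).  The differential test
is a deliberate simplification of rMATS's hierarchical likelihood model: a
two-proportion z-test on length-normalized pooled counts with
Benjamini-Hochberg correction across events.  It is calibrated (conservative
under Poisson counts) but not numerically equivalent to rMATS.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

REQUIRED_COLUMNS = ["event_id", "condition", "replicate", "I", "S", "l_I", "l_S"]
DEFAULT_MIN_COUNT = 10  # pooled I+S below this -> event excluded


def validate_event_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    if (table[["I", "S"]] < 0).any().any():
        raise ValueError("counts must be non-negative")
    if (table[["l_I", "l_S"]] <= 0).any().any():
        raise ValueError("effective lengths must be positive")
    return table


def compute_psi(I, S, l_I: float = 2.0, l_S: float = 1.0):
    """Length-normalized inclusion level: (I/l_I) / (I/l_I + S/l_S).

    Vectorized; returns NaN where I + S == 0 (undefined).
    """
    I = np.asarray(I, dtype=float)
    S = np.asarray(S, dtype=float)
    ni, ns = I / l_I, S / l_S
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(ni + ns > 0, ni / (ni + ns), np.nan)
    return psi if psi.ndim else float(psi)


def delta_psi_test(
    table: pd.DataFrame,
    control: str,
    treatment: str,
    min_count: int = DEFAULT_MIN_COUNT,
) -> pd.DataFrame:
    """Per-event delta-psi with a pooled two-proportion test and BH correction.

    Counts are summed across replicates within each condition (count pooling,
    not psi averaging, for variance stability at low counts), length-
    normalized, and compared with a two-proportion z-test.  Events whose
    pooled I+S falls below ``min_count`` in either condition, or with zero
    total in one condition, are flagged and excluded from the FDR family.

    Returns a frame with psi_control, psi_treatment, delta_psi, p, q, flag.
    """
    validate_event_table(table)
    sub = table[table["condition"].isin([control, treatment])]
    pooled = (
        sub.groupby(["event_id", "condition"])
        .agg(I=("I", "sum"), S=("S", "sum"), l_I=("l_I", "first"), l_S=("l_S", "first"))
        .reset_index()
    )
    wide = pooled.pivot(index="event_id", columns="condition", values=["I", "S", "l_I", "l_S"])
    rows = []
    for event_id in wide.index:
        rec = {"event_id": event_id, "p": np.nan, "q": np.nan, "flag": ""}
        try:
            Ic, Sc = wide.loc[event_id, ("I", control)], wide.loc[event_id, ("S", control)]
            It, St = wide.loc[event_id, ("I", treatment)], wide.loc[event_id, ("S", treatment)]
            lI, lS = wide.loc[event_id, ("l_I", control)], wide.loc[event_id, ("l_S", control)]
        except KeyError:
            rec["flag"] = "missing_condition"
            rows.append(rec)
            continue
        if np.isnan([Ic, Sc, It, St]).any():
            rec["flag"] = "missing_condition"
            rows.append(rec)
            continue
        psi_c = compute_psi(Ic, Sc, lI, lS)
        psi_t = compute_psi(It, St, lI, lS)
        rec["psi_control"], rec["psi_treatment"] = psi_c, psi_t
        rec["delta_psi"] = psi_t - psi_c if not (np.isnan(psi_c) or np.isnan(psi_t)) else np.nan
        if Ic + Sc == 0 or It + St == 0:
            rec["flag"] = "zero_counts"
        elif Ic + Sc < min_count or It + St < min_count:
            rec["flag"] = "low_coverage"
        else:
            nc = np.array([Ic / lI, It / lI])
            nn = np.array([Ic / lI + Sc / lS, It / lI + St / lS])
            if psi_c == psi_t:
                rec["p"] = 1.0
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    _, p = proportions_ztest(nc, nn)
                rec["p"] = 1.0 if np.isnan(p) else float(p)
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("event_id")
    testable = out["p"].notna()
    if testable.any():
        out.loc[testable, "q"] = multipletests(out.loc[testable, "p"], method="fdr_bh")[1]
    return out


def call_ri(records: pd.DataFrame, fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Significant retained-intron calls partitioned by delta-psi sign.

    Returns the subset of ``records`` with q < threshold and a ``direction``
    column: "up" (more retained in treatment) or "down".
    """
    if "q" not in records.columns:
        raise ValueError("records must carry BH-adjusted q values (run delta_psi_test)")
    sig = records[(records["q"] < fdr_threshold) & records["q"].notna()].copy()
    sig["direction"] = np.where(sig["delta_psi"] > 0, "up", "down")
    return sig


def zscore_common_ri(delta_psi: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    """Row-standardize a (events x conditions) delta-psi matrix.

    Uses the sample SD (ddof=1).  Rows with zero SD are emitted as zeros and
    returned in the flagged list.  Requires >= 2 condition columns.
    """
    if delta_psi.shape[1] < 2:
        raise ValueError("need >=2 conditions to standardize")
    vals = delta_psi.to_numpy(float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    flagged = list(delta_psi.index[(sd == 0).ravel()])
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (vals - mean) / sd, 0.0)
    return pd.DataFrame(z, index=delta_psi.index, columns=delta_psi.columns), flagged


def compare_feature_distributions(sample_a, sample_b) -> dict:
    """Two-sided Wilcoxon rank-sum (exact where feasible) plus KS test.

    Used to compare retained-intron feature distributions (length, distance
    to the TES, splicing rate ...) against a background set.  All-tied input
    yields p = 1 with a warning.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if np.ptp(np.concatenate([a, b])) == 0:
        warnings.warn("all values tied; rank-sum p set to 1")
        return {"ranksum_stat": float(a.size * b.size / 2), "ranksum_p": 1.0,
                "ks_stat": 0.0, "ks_p": 1.0}
    mw = stats.mannwhitneyu(a, b, alternative="two-sided")
    ks = stats.ks_2samp(a, b)
    return {"ranksum_stat": float(mw.statistic), "ranksum_p": float(mw.pvalue),
            "ks_stat": float(ks.statistic), "ks_p": float(ks.pvalue)}


def delta_psi_matrix(
    table: pd.DataFrame, control: str, treatments: list[str] | None = None,
    min_count: int = DEFAULT_MIN_COUNT,
) -> pd.DataFrame:
    """Events x treatments delta-psi matrix (pooled counts), NaN where undefined."""
    validate_event_table(table)
    if treatments is None:
        treatments = [c for c in table["condition"].unique() if c != control]
    cols = {}
    for trt in treatments:
        res = delta_psi_test(table, control, trt, min_count=min_count)
        cols[trt] = res["delta_psi"]
    return pd.DataFrame(cols)
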