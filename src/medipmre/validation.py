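"""Wet-lab-style validation statistics.

Covers the arithmetic around methylation-specific PCR (MSP), qPCR
expression normalization against a housekeeping panel, standard-curve
amplification efficiency, and the two-tailed t-tests used for all pairwise
group comparisons.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


def percent_methylated(methylated, unmethylated):
    """% methylated DNA = M / (M + U) * 100; accepts scalars or arrays."""
    m = np.asarray(methylated, dtype=float)
    u = np.asarray(unmethylated, dtype=float)
    if np.any(m < 0) or np.any(u < 0):
        raise ValueError("quantities must be non-negative")
    total = m + u
    if np.any(total == 0):
        raise ValueError("methylated + unmethylated must be positive")
    out = 100.0 * m / total
    return float(out) if out.ndim == 0 else out


def normalize_expression(target_quantity, housekeeping_quantities):
    """Target quantity divided by the geometric mean of the housekeeping
    panel (three reference genes); scale-invariant under common rescaling."""
    hk = np.asarray(housekeeping_quantities, dtype=float)
    if np.any(hk <= 0):
        raise ValueError("housekeeping quantities must be positive")
    gm = float(np.exp(np.mean(np.log(hk), axis=-1)))
    return float(target_quantity) / gm


def qpcr_efficiency(slope: float) -> float:
    """Amplification efficiency (%) from a standard-curve slope:
    100 * (10^(-1/slope) - 1); a perfect doubling gives slope -1/log10(2)
    and 100%."""
    if slope >= 0:
        raise ValueError("standard-curve slope must be negative")
    return 100.0 * (10.0 ** (-1.0 / slope) - 1.0)


def two_tailed_t(group_a, group_b, equal_var: bool = False) -> tuple[float, float]:
    """Two-sample two-sided t-test (Welch by default, pooled via flag)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("zero variance in both groups")
    with warnings.catch_warnings():
        # zero variance in ONE group is legitimate (e.g. fully methylated
        # sites); scipy warns about precision loss there
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def msp_group_tests(msp: pd.DataFrame, equal_var: bool = False) -> pd.DataFrame:
    """Per-site group comparison of percent methylation, plus the comparison
    of per-animal means across sites (the per-site vs averaged views of the
    same validation panel).

    Expects columns site_id, group (1/2), animal_id, methylated_quantity,
    unmethylated_quantity.
    """
    df = msp.copy()
    df["pct"] = percent_methylated(
        df["methylated_quantity"].to_numpy(), df["unmethylated_quantity"].to_numpy()
    )
    rows = []
    for site, sub in df.groupby("site_id", sort=True):
        t, p = two_tailed_t(
            sub.loc[sub["group"] == 1, "pct"],
            sub.loc[sub["group"] == 2, "pct"],
            equal_var=equal_var,
        )
        rows.append({"site_id": site, "t": t, "p_value": p,
                     "mean_group1": sub.loc[sub["group"] == 1, "pct"].mean(),
                     "mean_group2": sub.loc[sub["group"] == 2, "pct"].mean()})
    per_animal = df.groupby(["group", "animal_id"], sort=True)["pct"].mean().reset_index()
    t, p = two_tailed_t(
        per_animal.loc[per_animal["group"] == 1, "pct"],
        per_animal.loc[per_animal["group"] == 2, "pct"],
        equal_var=equal_var,
    )
    rows.append({"site_id": "__across_sites__", "t": t, "p_value": p,
                 "mean_group1": per_animal.loc[per_animal["group"] == 1, "pct"].mean(),
                 "mean_group2": per_animal.loc[per_animal["group"] == 2, "pct"].mean()})
    return pd.DataFrame(rows)


def expression_group_tests(expression: pd.DataFrame, equal_var: bool = False) -> pd.DataFrame:
    """Per-gene group comparison of housekeeping-normalized expression.

    Expects columns gene_id, group (1/2), animal_id, target_quantity,
    hk1, hk2, hk3.
    """
    df = expression.copy()
    df["rel_expr"] = [
        normalize_expression(t, (h1, h2, h3))
        for t, h1, h2, h3 in zip(df["target_quantity"], df["hk1"], df["hk2"], df["hk3"])
    ]
    rows = []
    for gene, sub in df.groupby("gene_id", sort=True):
        t, p = two_tailed_t(
            sub.loc[sub["group"] == 1, "rel_expr"],
            sub.loc[sub["group"] == 2, "rel_expr"],
            equal_var=equal_var,
        )
        rows.append({"gene_id": gene, "t": t, "p_value": p,
                     "mean_group1": sub.loc[sub["group"] == 1, "rel_expr"].mean(),
                     "mean_group2": sub.loc[sub["group"] == 2, "rel_expr"].mean()})
    return pd.DataFrame(rows)
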