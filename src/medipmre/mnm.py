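"""Integrative MeDIP + MRE differential-methylation test ("MnM" test).

Model. For a bin with CpG content c and MRE-site content r, and samples
i in {1, 2} with per-assay library size factors s_i, raw counts are

    MeDIP:  X_i ~ Poisson(kappa * a_i * m_i),   a_i = c * s_i^medip
    MRE:    Y_i ~ Poisson(kappa * b_i * (1-m_i)), b_i = r * s_i^mre

where m_i in [0, 1] is the bin's methylation level in sample i and kappa a
common sequencing-scale constant. MeDIP coverage rises with methylation;
MRE coverage (cuts at unmethylated CpG sites) falls with it. Conditional on
the bin total T = X1+X2+Y1+Y2 the four counts are multinomial with cell
probabilities proportional to (a1*m1, a2*m2, b1*(1-m1), b2*(1-m2)); kappa
cancels, so the test never needs it.

Test. H0: m1 = m2. Reported per-sample estimates are the
normalized-coverage ratios m_hat_i = (X_i/a_i) / (X_i/a_i + Y_i/b_i). The
pooled H0 MLE has the closed form m_hat_0 = (X+/A) / (X+/A + Y+/B) with
X+ = X1+X2, Y+ = Y1+Y2, A = a1+a2, B = b1+b2 (the multinomial score
equation is linear in m: the quadratic coefficient carries the factor
T - X+ - Y+ = 0). The statistic is the conditional likelihood-ratio
2*(sup_{m1,m2} logL - logL(m_hat_0, m_hat_0)); the unrestricted maximizer
solves the coupled score equations X_i/m_i - Y_i/(1-m_i) = (T/S)(a_i - b_i)
(S the total rate), found by a fast fixed-point on T/S in which each update
is the root of a per-sample quadratic. The statistic is referred to
chi-square(1 df) when T is large and to exact enumeration of the
conditional multinomial (at m_hat_0) when T is small.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .binning import BinRecord
from .intervals import GenomicInterval

DEFAULT_EXACT_THRESHOLD = 20
DEFAULT_ALPHA = 0.05

MEDIP_COLS = ["medip_1", "medip_2"]
MRE_COLS = ["mre_1", "mre_2"]

DIRECTION_G1 = "group1-higher"
DIRECTION_G2 = "group2-higher"
DIRECTION_NONE = "none"


@dataclass(frozen=True)
class SizeFactors:
    """Per-sample, per-assay scale factors (sample total / mean of totals)."""

    medip: tuple[float, float]
    mre: tuple[float, float]

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.medip + self.mre):
            raise ValueError("size factors must be strictly positive")


@dataclass(frozen=True)
class MnMResult:
    """Per-bin test output."""

    bin: GenomicInterval
    m_hat: tuple[float, float]
    statistic: float
    p_value: float
    q_value: float
    direction: str
    tested: bool


def size_factors(counts: pd.DataFrame) -> SizeFactors:
    """Library-size factors from a bin count table.

    Factor = sample/assay total divided by the across-sample mean of totals
    for that assay, so that dividing raw counts by their factor equalizes
    expected genome-wide totals.
    """
    factors = []
    for cols in (MEDIP_COLS, MRE_COLS):
        totals = counts[cols].sum(axis=0).to_numpy(dtype=float)
        for col, tot in zip(cols, totals):
            if tot <= 0:
                raise ValueError(f"sample {col!r} has zero total counts")
        factors.append(tuple(totals / totals.mean()))
    return SizeFactors(medip=factors[0], mre=factors[1])


def _xlogy(n: np.ndarray, rate: np.ndarray) -> np.ndarray:
    """n * log(rate) with the 0*log(0) = 0 convention, -inf when impossible."""
    n = np.asarray(n, dtype=float)
    rate = np.asarray(rate, dtype=float)
    out = np.where((n > 0) & (rate <= 0), -np.inf, 0.0)
    ok = (n > 0) & (rate > 0)
    safe = np.where(ok, rate, 1.0)
    return out + np.where(ok, n * np.log(safe), 0.0)


def _cond_loglik(x1, x2, y1, y2, a1, a2, b1, b2, m1, m2):
    """Conditional multinomial log-likelihood up to an m-free constant."""
    total = np.asarray(x1 + x2 + y1 + y2, dtype=float)
    s = a1 * m1 + a2 * m2 + b1 * (1.0 - m1) + b2 * (1.0 - m2)
    with np.errstate(invalid="ignore"):
        ll = (
            _xlogy(x1, a1 * m1)
            + _xlogy(x2, a2 * m2)
            + _xlogy(y1, b1 * (1.0 - m1))
            + _xlogy(y2, b2 * (1.0 - m2))
            - _xlogy(total, s)
        )
    return ll


def _ratio_estimate(x, a, y, b, fallback):
    """(x/a) / (x/a + y/b), with ``fallback`` where the sample has no reads."""
    u = np.where(a > 0, x / np.where(a > 0, a, 1.0), 0.0)
    v = np.where(b > 0, y / np.where(b > 0, b, 1.0), 0.0)
    denom = u + v
    return np.where(denom > 0, u / np.where(denom > 0, denom, 1.0), fallback)


def _null_estimate(x1, x2, y1, y2, a1, a2, b1, b2):
    xs = np.asarray(x1 + x2, dtype=float)
    ys = np.asarray(y1 + y2, dtype=float)
    aa = a1 + a2
    bb = b1 + b2
    num = xs * bb
    den = xs * bb + ys * aa
    return np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.5)


def _coordinate_max(x, y, a, b, c_rest, r_rest, total, cur, m0):
    """Exact 1-D maximizer of the conditional log-likelihood in one sample's
    m, holding the other sample fixed.

    f(m) = x*log(m) + y*log(1-m) - T*log((a-b)*m + C) + const, with
    C = b + (other sample's rate contribution). Stationary points solve the
    quadratic D*R*m^2 + (x*D - C*(x+y) - T*D)*m + x*C = 0 where D = a-b and
    R is the other sample's read total; the maximizer is chosen among both
    roots and the endpoints by direct likelihood comparison.
    """
    d = a - b
    c0 = b + c_rest
    n = x + y
    a2c = d * r_rest
    a1c = x * d - c0 * n - total * d
    a0c = x * c0

    with np.errstate(divide="ignore", invalid="ignore"):
        # stable quadratic roots; degenerates to the linear solution when
        # the other sample carries no reads (a2c == 0)
        disc = np.sqrt(np.maximum(a1c * a1c - 4.0 * a2c * a0c, 0.0))
        qq = -0.5 * (a1c + np.sign(a1c + (a1c == 0)) * disc)
        root1 = np.where(np.abs(a2c) > 1e-300, qq / np.where(np.abs(a2c) > 1e-300, a2c, 1.0), np.nan)
        root2 = np.where(np.abs(qq) > 1e-300, a0c / np.where(np.abs(qq) > 1e-300, qq, 1.0), np.nan)
        linear = np.where(np.abs(a1c) > 1e-300, -a0c / np.where(np.abs(a1c) > 1e-300, a1c, 1.0), np.nan)
    root1 = np.where(np.abs(a2c) > 1e-300, root1, linear)

    def value(m):
        m = np.clip(m, 0.0, 1.0)
        s = d * m + c0
        bad = ~np.isfinite(m) | (s <= 0)
        m_safe = np.where(bad, 0.5, m)
        v = (
            _xlogy(x, m_safe)
            + _xlogy(y, 1.0 - m_safe)
            - _xlogy(total, d * m_safe + c0)
        )
        return np.where(bad, -np.inf, v), m_safe

    candidates = [root1, root2, np.zeros_like(cur), np.ones_like(cur)]
    best_val, best_m = value(candidates[0])
    for cand in candidates[1:]:
        val, m_c = value(cand)
        take = val > best_val
        best_val = np.where(take, val, best_val)
        best_m = np.where(take, m_c, best_m)
    # a sample with no reads contributes nothing: park it at the pooled value
    return np.where(n > 0, best_m, m0)


def _alt_mle(x1, x2, y1, y2, a1, a2, b1, b2, m0, max_sweeps=60, tol=1e-12):
    """Unrestricted conditional MLE of (m1, m2), vectorized.

    Coordinate ascent with exact per-coordinate maximization (closed-form
    quadratic roots compared by likelihood), started at the ratio
    estimates; each sweep is monotone in the likelihood, so convergence is
    guaranteed and boundary cases (zero cells) are handled by the endpoint
    candidates.
    """
    x1, x2, y1, y2 = (np.asarray(v, dtype=float) for v in (x1, x2, y1, y2))
    total = x1 + x2 + y1 + y2
    m1 = np.clip(_ratio_estimate(x1, a1, y1, b1, m0), 0.0, 1.0)
    m2 = np.clip(_ratio_estimate(x2, a2, y2, b2, m0), 0.0, 1.0)
    for _ in range(max_sweeps):
        new1 = _coordinate_max(
            x1, y1, a1, b1, a2 * m2 + b2 * (1.0 - m2), x2 + y2, total, m1, m0
        )
        new2 = _coordinate_max(
            x2, y2, a2, b2, a1 * new1 + b1 * (1.0 - new1), x1 + y1, total, m2, m0
        )
        delta = max(
            float(np.max(np.abs(new1 - m1), initial=0.0)),
            float(np.max(np.abs(new2 - m2), initial=0.0)),
        )
        m1, m2 = new1, new2
        if delta < tol:
            break
    return m1, m2


def _statistics(x1, x2, y1, y2, a1, a2, b1, b2):
    """Vectorized likelihood-ratio statistic plus reported estimates.

    The statistic uses the unrestricted conditional MLE; the returned
    (m1, m2) are the simpler normalized-coverage ratio estimates, which are
    what gets reported and what fixes the direction label.
    """
    m0 = _null_estimate(x1, x2, y1, y2, a1, a2, b1, b2)
    m1 = _ratio_estimate(x1, a1, y1, b1, m0)
    m2 = _ratio_estimate(x2, a2, y2, b2, m0)
    m1_mle, m2_mle = _alt_mle(x1, x2, y1, y2, a1, a2, b1, b2, m0)
    ll_alt = _cond_loglik(x1, x2, y1, y2, a1, a2, b1, b2, m1_mle, m2_mle)
    ll_null = _cond_loglik(x1, x2, y1, y2, a1, a2, b1, b2, m0, m0)
    with np.errstate(invalid="ignore"):
        stat = 2.0 * (ll_alt - ll_null)
    stat = np.where(np.isfinite(stat), np.maximum(stat, 0.0), 0.0)
    # exact-null bins (alt fit identical to pooled fit) carry rounding dust
    stat = np.where(stat < 1e-10, 0.0, stat)
    return stat, m1, m2, m0


def _compositions4(total: int) -> tuple[np.ndarray, ...]:
    """All non-negative integer 4-tuples summing to ``total``."""
    rng = np.arange(total + 1)
    x1, x2, y1 = np.meshgrid(rng, rng, rng, indexing="ij")
    x1, x2, y1 = x1.ravel(), x2.ravel(), y1.ravel()
    y2 = total - x1 - x2 - y1
    keep = y2 >= 0
    return x1[keep], x2[keep], y1[keep], y2[keep]


def _exact_pvalue(x1, x2, y1, y2, a1, a2, b1, b2) -> float:
    """Exact conditional p: total null probability of outcomes at least as
    extreme (statistic >= observed) under the multinomial at the pooled MLE."""
    total = int(x1 + x2 + y1 + y2)
    if total == 0:
        return 1.0
    obs_stat = float(_statistics(x1, x2, y1, y2, a1, a2, b1, b2)[0])
    m0 = float(_null_estimate(x1, x2, y1, y2, a1, a2, b1, b2))
    cell = np.array([a1 * m0, a2 * m0, b1 * (1.0 - m0), b2 * (1.0 - m0)])
    if cell.sum() <= 0:
        return 1.0
    p = cell / cell.sum()
    e1, e2, e3, e4 = _compositions4(total)
    stats_all = _statistics(e1, e2, e3, e4, a1, a2, b1, b2)[0]
    counts = np.column_stack([e1, e2, e3, e4])
    with np.errstate(divide="ignore", invalid="ignore"):
        logpmf = stats.multinomial.logpmf(counts, total, p)
    pmf = np.where(np.isfinite(logpmf), np.exp(logpmf), 0.0)
    return float(np.clip(pmf[stats_all >= obs_stat - 1e-9].sum(), 0.0, 1.0))


def _rates(cpg, mre_sites, factors: SizeFactors):
    a1 = cpg * factors.medip[0]
    a2 = cpg * factors.medip[1]
    b1 = mre_sites * factors.mre[0]
    b2 = mre_sites * factors.mre[1]
    return a1, a2, b1, b2


def mnm_test(
    bin_record: BinRecord,
    factors: SizeFactors,
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
) -> MnMResult:
    """Test one bin for differential methylation between two samples."""
    c, r = bin_record.cpg_count, bin_record.mre_site_count
    x1, x2 = bin_record.medip_counts
    y1, y2 = bin_record.mre_counts
    if min(x1, x2, y1, y2) < 0:
        raise ValueError("negative counts")
    tested = (c > 0 or r > 0)
    if c == 0 and (x1 > 0 or x2 > 0):
        tested = False  # MeDIP reads without any CpG: content/count contradiction
    if r == 0 and (y1 > 0 or y2 > 0):
        tested = False
    if not tested:
        return MnMResult(bin_record.interval, (np.nan, np.nan), 0.0, 1.0, 1.0,
                         DIRECTION_NONE, False)

    a1, a2, b1, b2 = _rates(float(c), float(r), factors)
    total = x1 + x2 + y1 + y2
    stat, m1, m2, m0 = _statistics(
        float(x1), float(x2), float(y1), float(y2), a1, a2, b1, b2
    )
    stat = float(stat)
    m1 = float(m1) if (x1 + y1) > 0 else np.nan
    m2 = float(m2) if (x2 + y2) > 0 else np.nan
    if total == 0:
        p = 1.0
    elif total > exact_threshold:
        p = float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
    else:
        p = _exact_pvalue(x1, x2, y1, y2, a1, a2, b1, b2)
    direction = DIRECTION_NONE
    if np.isfinite(m1) and np.isfinite(m2) and m1 != m2:
        direction = DIRECTION_G2 if m2 > m1 else DIRECTION_G1
    return MnMResult(bin_record.interval, (m1, m2), stat, p, np.nan, direction, True)


def test_bins(
    counts: pd.DataFrame,
    factors: SizeFactors | None = None,
    exact_threshold: int = DEFAULT_EXACT_THRESHOLD,
) -> pd.DataFrame:
    """Vectorized MnM test over a full bin count table.

    ``counts`` needs columns chrom/start/end, cpg_count, mre_site_count,
    medip_1, medip_2, mre_1, mre_2. Returns one row per bin with estimates,
    statistic, p_value, q_value (BH over tested bins only) and direction.
    Bins with no content, or with reads contradicting zero content, are
    flagged tested=False and excluded from the BH denominator.
    """
    if factors is None:
        factors = size_factors(counts)
    c = counts["cpg_count"].to_numpy(dtype=float)
    r = counts["mre_site_count"].to_numpy(dtype=float)
    x1 = counts["medip_1"].to_numpy(dtype=float)
    x2 = counts["medip_2"].to_numpy(dtype=float)
    y1 = counts["mre_1"].to_numpy(dtype=float)
    y2 = counts["mre_2"].to_numpy(dtype=float)
    if min(x1.min(initial=0), x2.min(initial=0), y1.min(initial=0), y2.min(initial=0)) < 0:
        raise ValueError("negative counts")

    tested = (c > 0) | (r > 0)
    tested &= ~((c == 0) & ((x1 > 0) | (x2 > 0)))
    tested &= ~((r == 0) & ((y1 > 0) | (y2 > 0)))

    a1, a2, b1, b2 = _rates(c, r, factors)
    total = x1 + x2 + y1 + y2
    stat, m1, m2, m0 = _statistics(x1, x2, y1, y2, a1, a2, b1, b2)
    m1 = np.where((x1 + y1) > 0, m1, np.nan)
    m2 = np.where((x2 + y2) > 0, m2, np.nan)

    p = np.ones(len(counts))
    asym = tested & (total > exact_threshold)
    p[asym] = stats.chi2.sf(stat[asym], df=1)
    p[asym & (stat <= 0)] = 1.0
    exact_idx = np.flatnonzero(tested & (total <= exact_threshold) & (total > 0))
    for i in exact_idx:
        p[i] = _exact_pvalue(
            int(x1[i]), int(x2[i]), int(y1[i]), int(y2[i]),
            a1[i], a2[i], b1[i], b2[i],
        )
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    q = np.full(len(counts), np.nan)
    if tested.any():
        q[tested] = bh_fdr(p[tested])

    direction = np.full(len(counts), DIRECTION_NONE, dtype=object)
    have_both = tested & np.isfinite(m1) & np.isfinite(m2)
    direction[have_both & (m2 > m1)] = DIRECTION_G2
    direction[have_both & (m1 > m2)] = DIRECTION_G1

    out = counts[["chrom", "start", "end"]].copy()
    out["m_hat_1"] = np.where(tested, m1, np.nan)
    out["m_hat_2"] = np.where(tested, m2, np.nan)
    out["statistic"] = np.where(tested, stat, 0.0)
    out["p_value"] = np.where(tested, p, 1.0)
    out["q_value"] = q
    out["direction"] = direction
    out["tested"] = tested
    return out


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return q


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (reporting convention for percentages)."""
    quant = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quant, rounding=ROUND_HALF_UP))


def summarize_directions(n_group1_higher: int, n_group2_higher: int) -> dict:
    """Direction summary: totals and one-decimal percentages."""
    total = n_group1_higher + n_group2_higher
    if total == 0:
        warnings.warn("empty DMR set; percentages reported as 0")
        return {
            "total": 0,
            "group1_higher": 0, "group2_higher": 0,
            "pct_group1_higher": 0.0, "pct_group2_higher": 0.0,
        }
    return {
        "total": total,
        "group1_higher": int(n_group1_higher),
        "group2_higher": int(n_group2_higher),
        "pct_group1_higher": round_half_up(100.0 * n_group1_higher / total),
        "pct_group2_higher": round_half_up(100.0 * n_group2_higher / total),
    }


def call_dmrs(
    results: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    merge_adjacent: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Call DMRs (tested bins with q < alpha) and summarize directions.

    With ``merge_adjacent`` on, touching significant bins with the same
    direction are merged into one region (multi-bin DMRs); default off, so a
    DMR is a single significant bin.
    """
    sig = results[(results["tested"]) & (results["q_value"] < alpha)].copy()
    sig = sig.sort_values(["chrom", "start"]).reset_index(drop=True)
    summary = summarize_directions(
        int((sig["direction"] == DIRECTION_G1).sum()),
        int((sig["direction"] == DIRECTION_G2).sum()),
    )
    if not merge_adjacent or sig.empty:
        return sig, summary
    merged_rows = []
    cur = None
    for row in sig.itertuples(index=False):
        if (
            cur is not None
            and row.chrom == cur["chrom"]
            and row.start <= cur["end"]
            and row.direction == cur["direction"]
        ):
            cur["end"] = max(cur["end"], row.end)
            cur["q_value"] = min(cur["q_value"], row.q_value)
            cur["n_bins"] += 1
        else:
            if cur is not None:
                merged_rows.append(cur)
            cur = {
                "chrom": row.chrom, "start": row.start, "end": row.end,
                "direction": row.direction, "q_value": row.q_value, "n_bins": 1,
            }
    if cur is not None:
        merged_rows.append(cur)
    merged = pd.DataFrame(
        merged_rows, columns=["chrom", "start", "end", "direction", "q_value", "n_bins"]
    )
    return merged, summary
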