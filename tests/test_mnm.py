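"""The conditional Poisson/multinomial differential-methylation test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from medipmre.binning import BinRecord
from medipmre.intervals import GenomicInterval
from medipmre.mnm import (
    SizeFactors,
    _exact_pvalue,
    _null_estimate,
    _statistics,
    bh_fdr,
    call_dmrs,
    mnm_test,
    size_factors,
)
from medipmre.mnm import test_bins as run_table_test  # avoid pytest collection

from conftest import simulate_counts

IV = GenomicInterval("chr1", 0, 500)
UNIT = SizeFactors((1.0, 1.0), (1.0, 1.0))


def _bin(medip, mre, cpg=5, sites=3):
    return BinRecord(IV, cpg, sites, medip, mre)


class TestSizeFactors:
    def test_equal_totals_give_unit_factors(self):
        df = pd.DataFrame({"medip_1": [10, 20], "medip_2": [15, 15],
                           "mre_1": [5, 5], "mre_2": [4, 6]})
        f = size_factors(df)
        assert f.medip == (1.0, 1.0) and f.mre == (1.0, 1.0)

    def test_two_to_one_totals(self):
        df = pd.DataFrame({"medip_1": [2_000_000], "medip_2": [1_000_000],
                           "mre_1": [1], "mre_2": [1]})
        f = size_factors(df)
        assert f.medip == pytest.approx((4 / 3, 2 / 3))

    def test_random_table_matches_hand_summation(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {c: rng.integers(1, 50, 200) for c in ["medip_1", "medip_2", "mre_1", "mre_2"]}
        )
        f = size_factors(df)
        tot1, tot2 = df["medip_1"].sum(), df["medip_2"].sum()
        assert f.medip[0] == pytest.approx(tot1 / ((tot1 + tot2) / 2))

    def test_all_zero_sample_named_in_error(self):
        df = pd.DataFrame({"medip_1": [1], "medip_2": [0], "mre_1": [1], "mre_2": [1]})
        with pytest.raises(ValueError, match="medip_2"):
            size_factors(df)


class TestMnMTest:
    def test_perfect_symmetry_gives_null(self):
        r = mnm_test(_bin((10, 10), (5, 5)), UNIT)
        assert r.statistic == 0.0 and r.p_value == 1.0 and r.direction == "none"

    def test_label_swap_flips_direction_keeps_pvalue(self):
        f = SizeFactors((1.0, 1.2), (1.1, 0.9))
        f_swapped = SizeFactors((1.2, 1.0), (0.9, 1.1))
        r = mnm_test(_bin((9, 2), (1, 6)), f)
        r_swapped = mnm_test(_bin((2, 9), (6, 1)), f_swapped)
        assert r.p_value == pytest.approx(r_swapped.p_value, abs=1e-12)
        assert {r.direction, r_swapped.direction} == {"group1-higher", "group2-higher"}

    def test_hypermethylated_pattern_direction(self):
        # MeDIP higher and MRE lower in group 2 -> group 2 more methylated
        r = mnm_test(_bin((2, 5), (7, 1)), UNIT)
        assert r.direction == "group2-higher"

    def test_hypomethylated_pattern_direction(self):
        # MeDIP higher and MRE lower in group 1 -> group 1 more methylated
        r = mnm_test(_bin((4, 3), (1, 2)), UNIT)
        assert r.direction == "group1-higher"

    def test_boundary_estimates(self):
        r = mnm_test(_bin((6, 0), (0, 6)), UNIT)
        assert r.m_hat == (1.0, 0.0)
        assert r.direction == "group1-higher"

    def test_zero_read_bin_tested_with_p_one(self):
        r = mnm_test(_bin((0, 0), (0, 0)), UNIT)
        assert r.tested and r.p_value == 1.0 and r.direction == "none"

    def test_no_content_bin_untested(self):
        r = mnm_test(BinRecord(IV, 0, 0, (3, 1), (0, 0)), UNIT)
        assert not r.tested

    def test_content_count_contradiction_flagged(self):
        r = mnm_test(BinRecord(IV, 0, 4, (3, 1), (2, 2)), UNIT)
        assert not r.tested

    def test_negative_counts_rejected(self):
        df = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [500], "cpg_count": [5],
             "mre_site_count": [3], "medip_1": [-1], "medip_2": [1],
             "mre_1": [1], "mre_2": [1]}
        )
        with pytest.raises(ValueError):
            run_table_test(df, UNIT)


def _oracle_stat(x1, x2, y1, y2, a1, a2, b1, b2):
    """Scalar brute-force LRT: grid + polish maximization of the conditional
    multinomial likelihood, independent of the package's fixed-point."""
    from scipy import optimize

    def ll(m1, m2):
        s = a1 * m1 + a2 * m2 + b1 * (1 - m1) + b2 * (1 - m2)
        tot = 0.0
        for n, r in ((x1, a1 * m1), (x2, a2 * m2), (y1, b1 * (1 - m1)), (y2, b2 * (1 - m2))):
            if n > 0:
                if r <= 0:
                    return -np.inf
                tot += n * np.log(r)
        return tot - (x1 + x2 + y1 + y2) * np.log(s)

    grid = np.linspace(1e-9, 1 - 1e-9, 41)
    best = max(((ll(u, v), u, v) for u in grid for v in grid), key=lambda t: t[0])
    res = optimize.minimize(
        lambda v: -ll(v[0], v[1]), [best[1], best[2]],
        bounds=[(1e-12, 1 - 1e-12)] * 2,
    )
    ll_alt = -res.fun
    null = optimize.minimize_scalar(
        lambda m: -ll(m, m), bounds=(1e-12, 1 - 1e-12), method="bounded"
    )
    return max(0.0, 2 * (ll_alt - (-null.fun)))


class TestExactBranch:
    def test_enumeration_equals_brute_force_small_totals(self):
        """For small bin totals the exact p equals an independent loop-based
        enumeration of the conditional multinomial."""
        from itertools import product
        from math import exp, lgamma, log

        rng = np.random.default_rng(5)
        for _ in range(12):
            a1, a2 = rng.uniform(1, 8, 2)
            b1, b2 = rng.uniform(0.5, 5, 2)
            total = int(rng.integers(1, 13))
            cnt = tuple(int(v) for v in rng.multinomial(total, [0.3, 0.3, 0.2, 0.2]))
            obs = float(_statistics(*map(float, cnt), a1, a2, b1, b2)[0])
            m0 = float(_null_estimate(*map(float, cnt), a1, a2, b1, b2))
            cells = [a1 * m0, a2 * m0, b1 * (1 - m0), b2 * (1 - m0)]
            s = sum(cells)
            probs = [c / s for c in cells]
            p_oracle = 0.0
            for e1, e2, e3 in product(range(total + 1), repeat=3):
                e4 = total - e1 - e2 - e3
                if e4 < 0:
                    continue
                st = float(_statistics(float(e1), float(e2), float(e3), float(e4),
                                       a1, a2, b1, b2)[0])
                if st >= obs - 1e-9:
                    lp = lgamma(total + 1) - sum(lgamma(e + 1) for e in (e1, e2, e3, e4))
                    skip = False
                    for n, pp in zip((e1, e2, e3, e4), probs):
                        if n > 0:
                            if pp <= 0:
                                skip = True
                                break
                            lp += n * log(pp)
                    if not skip:
                        p_oracle += exp(lp)
            p_pkg = _exact_pvalue(*cnt, a1, a2, b1, b2)
            assert p_pkg == pytest.approx(p_oracle, abs=1e-12)

    def test_statistic_matches_independent_optimizer(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            a1, a2 = rng.uniform(2, 8, 2)
            b1, b2 = rng.uniform(1, 5, 2)
            cnt = tuple(int(v) for v in rng.multinomial(40, [0.3, 0.3, 0.2, 0.2]))
            st = float(_statistics(*map(float, cnt), a1, a2, b1, b2)[0])
            assert st == pytest.approx(_oracle_stat(*cnt, a1, a2, b1, b2), abs=1e-6)

    def test_small_total_bins_use_enumeration(self):
        """Within the exact threshold, table p-values equal the per-bin
        exact computation (no chi-square leakage)."""
        counts, _, _, ls = simulate_counts(31, n_bins=400, dmr_frac=0.0, depth=2.0)
        f = SizeFactors(ls["medip"], ls["mre"])
        res = run_table_test(counts, f)
        total = (counts.medip_1 + counts.medip_2 + counts.mre_1 + counts.mre_2).to_numpy()
        small = np.flatnonzero((total > 0) & (total <= 20))[:15]
        for i in small:
            a1 = counts.cpg_count[i] * f.medip[0]
            a2 = counts.cpg_count[i] * f.medip[1]
            b1 = counts.mre_site_count[i] * f.mre[0]
            b2 = counts.mre_site_count[i] * f.mre[1]
            p = _exact_pvalue(int(counts.medip_1[i]), int(counts.medip_2[i]),
                              int(counts.mre_1[i]), int(counts.mre_2[i]),
                              a1, a2, b1, b2)
            assert res.p_value[i] == pytest.approx(p, abs=1e-12)


class TestBhFdr:
    def test_identical_ps_unchanged(self):
        assert bh_fdr([0.2, 0.2, 0.2]).tolist() == pytest.approx([0.2, 0.2, 0.2])

    def test_hand_computed_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]).tolist() == pytest.approx([0.04] * 4)

    def test_order_restored(self):
        p = [0.5, 0.001, 0.04]
        q = bh_fdr(p)
        assert q[1] == min(q) and q[0] == max(q)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(8)
        p = rng.uniform(1e-6, 1, 500)
        q = bh_fdr(p)
        q_ref = multipletests(p, method="fdr_bh")[1]
        assert np.max(np.abs(q - q_ref)) < 1e-12

    def test_q_at_least_p(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(1e-9, 1, 300)
        assert np.all(bh_fdr(p) >= p - 1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_fdr([1.5])


class TestCallDmrs:
    def _results(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "q_value", "direction", "tested"]
        )

    def test_threshold_and_summary(self):
        res = self._results([
            ("chr1", 0, 500, 0.01, "group1-higher", True),
            ("chr1", 500, 1000, 0.20, "group2-higher", True),
            ("chr1", 1000, 1500, 0.04, "group2-higher", True),
            ("chr1", 1500, 2000, 0.001, "group2-higher", False),
        ])
        dmrs, summary = call_dmrs(res)
        assert len(dmrs) == 2
        assert summary["total"] == 2
        assert summary["pct_group1_higher"] == 50.0

    def test_empty_call_set(self):
        res = self._results([("chr1", 0, 500, 0.9, "none", True)])
        with pytest.warns(UserWarning):
            dmrs, summary = call_dmrs(res)
        assert dmrs.empty and summary["total"] == 0

    def test_merge_adjacent_equals_brute_force_runs(self):
        rng = np.random.default_rng(12)
        rows = []
        for i in range(200):
            rows.append((
                "chr1", i * 500, (i + 1) * 500,
                float(rng.choice([0.01, 0.5])),
                str(rng.choice(["group1-higher", "group2-higher"])),
                True,
            ))
        res = self._results(rows)
        merged, _ = call_dmrs(res, merge_adjacent=True)
        # brute-force scan for maximal same-direction significant runs
        sig = [(r[1], r[2], r[4]) for r in rows if r[3] < 0.05]
        runs = []
        for s, e, d in sig:
            if runs and runs[-1][1] == s and runs[-1][2] == d:
                runs[-1][1] = e
            else:
                runs.append([s, e, d])
        assert [(r.start, r.end, r.direction) for r in merged.itertuples()] == [
            (s, e, d) for s, e, d in runs
        ]


class TestStatisticalProperties:
    def test_null_type_one_error_near_nominal(self):
        counts, _, _, _ = simulate_counts(100, n_bins=10_000, dmr_frac=0.0, depth=30.0)
        res = run_table_test(counts)
        rate = float((res.p_value[res.tested] < 0.05).mean())
        assert 0.03 <= rate <= 0.07

    def test_fdr_controlled_and_power_monotone(self):
        _, _, m, _ = simulate_counts(200, n_bins=2000)

        def run(delta, depth):
            counts, truth, _, _ = simulate_counts(
                200, n_bins=10_000, dmr_frac=0.1, delta=delta, depth=depth
            )
            res = run_table_test(counts)
            calls = (res.q_value < 0.05) & res.tested
            fdr = float((calls & ~truth).sum() / max(calls.sum(), 1))
            sens = float((calls & truth).sum() / truth.sum())
            return fdr, sens

        fdr_base, sens_base = run(0.5, 30.0)
        _, sens_low_delta = run(0.25, 30.0)
        _, sens_deep = run(0.5, 60.0)
        _, sens_shallow = run(0.5, 15.0)
        assert fdr_base <= 0.10
        assert sens_base >= sens_low_delta
        assert sens_deep >= sens_shallow

    def test_parameter_recovery_at_high_depth(self):
        counts, _, m, ls = simulate_counts(300, n_bins=3000, delta=0.4, depth=500.0)
        res = run_table_test(counts, SizeFactors(ls["medip"], ls["mre"]))
        err = np.abs(np.column_stack([res.m_hat_1, res.m_hat_2]) - m)
        assert float(np.nanmean(err)) < 0.05

    def test_chi_square_close_to_enumeration_moderate_totals(self):
        counts, _, _, ls = simulate_counts(400, n_bins=3000, dmr_frac=0.0, depth=12.0)
        f = SizeFactors(ls["medip"], ls["mre"])
        total = (counts.medip_1 + counts.medip_2 + counts.mre_1 + counts.mre_2).to_numpy()
        sel = np.flatnonzero((total >= 30) & (total <= 100))[:60]
        diffs = []
        for i in sel:
            a1 = counts.cpg_count[i] * f.medip[0]
            a2 = counts.cpg_count[i] * f.medip[1]
            b1 = counts.mre_site_count[i] * f.mre[0]
            b2 = counts.mre_site_count[i] * f.mre[1]
            cnt = (int(counts.medip_1[i]), int(counts.medip_2[i]),
                   int(counts.mre_1[i]), int(counts.mre_2[i]))
            st = float(_statistics(*map(float, cnt), a1, a2, b1, b2)[0])
            p_chi = float(ss.chi2.sf(st, 1))
            p_enum = _exact_pvalue(*cnt, a1, a2, b1, b2)
            diffs.append(abs(p_chi - p_enum))
        assert float(np.mean(diffs)) <= 0.02
        assert max(diffs) <= 0.05
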