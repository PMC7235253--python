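"""Cohort-level statistics: exactness, calibration and recovery checks."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hippotheta import cohortstats as cs


class TestBinomialPrevalence:
    def test_matches_pmf_enumeration_and_scipy(self):
        for k, n in [(13, 19), (7, 19), (1, 20), (0, 19), (5, 25), (25, 25)]:
            got = cs.binomial_prevalence_test(k, n)
            brute = sum(
                math.comb(n, i) * 0.05**i * 0.95 ** (n - i)
                for i in range(k, n + 1)
            )
            assert got == pytest.approx(brute, abs=1e-15)
            assert got == pytest.approx(stats.binom.sf(k - 1, n, 0.05), rel=1e-12)

    def test_thirteen_of_nineteen_below_1e5(self):
        p = cs.binomial_prevalence_test(13, 19)
        assert p < 1e-5

    def test_zero_successes_probability_one(self):
        assert cs.binomial_prevalence_test(0, 19) == pytest.approx(1.0)

    def test_one_of_twenty_closed_form(self):
        assert cs.binomial_prevalence_test(1, 20) == pytest.approx(
            1 - 0.95**20, abs=1e-12
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cs.binomial_prevalence_test(1, 0)
        with pytest.raises(ValueError):
            cs.binomial_prevalence_test(5, 3)


class TestProportionZ:
    def test_equal_proportions(self):
        res = cs.proportion_z_test(5, 20, 5, 20)
        assert res["z"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(0.5)

    def test_closed_form_oracle(self):
        k1, n1, k2, n2 = 13, 19, 5, 20
        res = cs.proportion_z_test(k1, n1, k2, n2)
        p1, p2 = k1 / n1, k2 / n2
        pool = (k1 + k2) / (n1 + n2)
        z = (p1 - p2) / math.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
        assert res["z"] == pytest.approx(z, abs=1e-12)
        assert res["p"] == pytest.approx(stats.norm.sf(z), rel=1e-12)

    def test_degenerate_pooled_flagged(self):
        res = cs.proportion_z_test(0, 10, 0, 10)
        assert res["flag"] == "degenerate_pooled_proportion"


class TestLogistic:
    def _cohort(self, beta1, n, seed):
        rng = np.random.default_rng(seed)
        ap = rng.uniform(0.1, 0.9, n)
        p = 1 / (1 + np.exp(-(-1.5 + beta1 * ap)))
        y = rng.random(n) < p
        return ap, np.where(y, "single", "dual")

    def test_positive_slope_recovered(self):
        hits = 0
        for seed in range(30):
            ap, y = self._cohort(5.0, 60, seed)
            if len(set(y)) < 2:
                continue
            res = cs.oscillator_logistic(ap, y)
            hits += res["flag"] is None and res["beta1"] > 0 and res["p"] < 0.05
        assert hits >= 24

    def test_null_slope_calibrated(self):
        hits = trials = 0
        for seed in range(200):
            ap, y = self._cohort(0.0, 60, seed)
            if len(set(y)) < 2:
                continue
            res = cs.oscillator_logistic(ap, y)
            if res["flag"] is None:
                trials += 1
                hits += res["p"] < 0.05
        assert trials > 150
        assert hits / trials == pytest.approx(0.05, abs=0.04)

    def test_single_class_rejected(self):
        ap = np.linspace(0.1, 0.9, 20)
        with pytest.raises(ValueError, match="class"):
            cs.oscillator_logistic(ap, np.array(["single"] * 20))

    def test_perfect_separation_flagged(self):
        ap = np.linspace(0.1, 0.9, 20)
        y = np.where(ap > 0.5, "single", "dual")
        res = cs.oscillator_logistic(ap, y)
        assert res["flag"] == "perfect_separation"
        assert np.isnan(res["p"])


class TestGradient:
    def test_exact_linear_relation(self):
        ap = np.linspace(0.1, 0.9, 20)
        table = pd.DataFrame({
            "ap_fraction": ap, "peak_hz": 5 + 4 * ap,
            "hemisphere": ["L", "R"] * 10,
        })
        res = cs.gradient_correlation(table)
        assert res["r"] == pytest.approx(1.0)

    def test_small_stratum_skipped(self):
        table = pd.DataFrame({
            "ap_fraction": [0.1, 0.5], "peak_hz": [6.0, 8.0],
            "hemisphere": ["L", "L"],
        })
        res = cs.gradient_correlation(table, by="R")
        assert res["flag"] == "insufficient_n"


class TestHemisphere:
    def _table(self, l_shift=0.0, seed=0, n=15):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(2 * n):
            hemi = "L" if i < n else "R"
            f = rng.normal(7.0 + (l_shift if hemi == "L" else 0.0), 0.5)
            rows.append({
                "electrode_id": f"e{i}", "hemisphere": hemi,
                "ap_fraction": rng.uniform(0.1, 0.9),
                "peak_hz": f, "subregion": rng.choice(["CA1", "DG", "SUB"]),
                "oscillator_class": "single", "label": "high",
            })
        return pd.DataFrame(rows)

    def test_identical_hemisphere_samples(self):
        t = self._table()
        t2 = t.copy()
        t2["hemisphere"] = np.where(t["hemisphere"] == "L", "R", "L")
        both = pd.concat([t, t2], ignore_index=True)
        both["electrode_id"] = [f"e{i}" for i in range(len(both))]
        res = cs.hemisphere_tests(both)
        assert res["freq_t"]["t"] == pytest.approx(0.0, abs=1e-9)

    def test_shifted_hemisphere_detected(self):
        hits = 0
        for seed in range(20):
            res = cs.hemisphere_tests(self._table(l_shift=2.0, seed=seed))
            hits += res["freq_t"]["p"] < 1e-4
        assert hits >= 19

    def test_null_subregion_anova_p_uniform(self):
        ps = []
        for seed in range(200):
            res = cs.hemisphere_tests(self._table(seed=seed))
            p = res["subregion_anova"]["p"]
            if np.isfinite(p):
                ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestSpeedfreqAnova:
    def _cells(self, means, sd, n_subj, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(n_subj):
            for (region, band), mu in means.items():
                rows.append({
                    "subject_id": f"S{s}", "region": region, "label": band,
                    "value": rng.normal(mu, sd),
                })
        return pd.DataFrame(rows)

    def test_balanced_design_matches_closed_form(self):
        means = {("anterior", "low"): 0.2, ("anterior", "high"): 0.4,
                 ("posterior", "low"): 0.3, ("posterior", "high"): 0.9}
        cells = self._cells(means, 0.1, 8, seed=1)
        res = cs.speedfreq_anova(cells)
        # closed-form balanced two-way ANOVA
        y = cells.pivot_table(index="subject_id", columns=["region", "label"],
                              values="value")
        n = len(y)
        a = y.values.reshape(n, 2, 2)  # subjects x region x band
        grand = a.mean()
        region_means = a.mean(axis=(0, 2))
        band_means = a.mean(axis=(0, 1))
        cell_means = a.mean(axis=0)
        ss_region = 2 * n * np.sum((region_means - grand) ** 2)
        ss_band = 2 * n * np.sum((band_means - grand) ** 2)
        ss_cells = n * np.sum((cell_means - grand) ** 2)
        ss_inter = ss_cells - ss_region - ss_band
        ss_err = np.sum((a - cell_means) ** 2)
        df_err = 4 * (n - 1)
        for name, ss, df in [("region", ss_region, 1), ("band", ss_band, 1),
                             ("interaction", ss_inter, 1)]:
            f_expected = (ss / df) / (ss_err / df_err)
            assert res[name]["F"] == pytest.approx(f_expected, abs=1e-6)

    def test_pure_interaction_pattern(self):
        d = 0.4
        means = {("anterior", "low"): 0.5 + d, ("anterior", "high"): 0.5 - d,
                 ("posterior", "low"): 0.5 - d, ("posterior", "high"): 0.5 + d}
        inter_hits = main_null = 0
        for seed in range(20):
            res = cs.speedfreq_anova(self._cells(means, 0.05, 8, seed))
            inter_hits += res["interaction"]["p"] < 0.01
            # main effects are null here; non-significance holds ~90% jointly
            main_null += (res["region"]["p"] > 0.05 and res["band"]["p"] > 0.05)
        assert inter_hits == 20
        assert main_null >= 16

    def test_degenerate_identical_values(self):
        means = {("anterior", "low"): 0.5, ("anterior", "high"): 0.5,
                 ("posterior", "low"): 0.5, ("posterior", "high"): 0.5}
        cells = self._cells(means, 0.0, 4, seed=0)
        assert cs.speedfreq_anova(cells)["flag"] == "degenerate"


class TestHarmonicPermutation:
    def test_exact_harmonic_rejected(self):
        rng = np.random.default_rng(0)
        f_low = rng.uniform(2.5, 3.5, 20)
        res = cs.harmonic_permutation_test(f_low, 2 * f_low, n_perm=10_000, rng=1)
        assert res["p"] <= 0.001
        assert res["r"] == pytest.approx(1.0)

    def test_independent_frequencies_uniform_p(self):
        ps = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            res = cs.harmonic_permutation_test(
                rng.uniform(2.5, 3.5, 12), rng.uniform(6, 9, 12),
                n_perm=200, rng=seed,
            )
            ps.append(res["p"])
        assert 0.45 <= np.mean(ps) <= 0.55

    def test_permutation_p_floor(self):
        res = cs.harmonic_permutation_test(
            np.arange(5.0), 2 * np.arange(5.0), n_perm=100, rng=0
        )
        assert res["p"] >= 1 / 101

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            cs.harmonic_permutation_test([1.0, 2.0], [2.0, 4.0])


class TestCooccurrence:
    def test_independent_masks_near_zero(self):
        rng = np.random.default_rng(0)
        pairs = [
            (rng.random(100_000) < 0.3, rng.random(100_000) < 0.4)
            for _ in range(6)
        ]
        res = cs.cooccurrence_test(pairs)
        for s in res["statistics"]:
            assert abs(s) < 0.01

    def test_identical_masks_statistic(self):
        rng = np.random.default_rng(1)
        m = rng.random(100_000) < 0.3
        res = cs.cooccurrence_test([(m, m)] * 5)
        q = m.mean()
        for s in res["statistics"]:
            assert s == pytest.approx(q - q * q, abs=1e-12)

    def test_positive_statistics_significant(self):
        rng = np.random.default_rng(2)
        pairs = []
        for _ in range(10):
            base = rng.random(50_000) < 0.3
            noisy = base & (rng.random(50_000) < 0.9)
            pairs.append((base, noisy))
        res = cs.cooccurrence_test(pairs)
        assert all(s > 0 for s in res["statistics"])
        assert res["p"] < 0.05

    def test_zero_presence_excluded_with_warning(self):
        rng = np.random.default_rng(3)
        good = [(rng.random(1000) < 0.3, rng.random(1000) < 0.4)
                for _ in range(5)]
        bad = (np.zeros(1000, bool), rng.random(1000) < 0.4)
        with pytest.warns(UserWarning, match="zero presence"):
            res = cs.cooccurrence_test(good + [bad])
        assert res["n_excluded"] == 1
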