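"""delta-f subsets, informativeness, resampling test, f3, shared elevation."""

import itertools
import math

import numpy as np
import pytest

from flaxpop.geneflow import (
    delta_f_subsets,
    f3_statistic,
    informativeness_ia,
    informativeness_per_locus,
    shared_elevation_fraction,
    subset_fst_resample_test,
)
from flaxpop.synthetic import balding_nichols_panel, geneflow_scenario


def oracle_informativeness(freq_table):
    """Literal term-by-term summation of Rosenberg's I_n for biallelic loci."""
    total = []
    for row in np.atleast_2d(freq_table):
        k = len(row)
        val = 0.0
        for allele_freqs in (row, 1.0 - row):
            pbar = sum(allele_freqs) / k
            val += -(pbar * math.log(pbar)) if pbar > 0 else 0.0
            for p in allele_freqs:
                val += (p * math.log(p)) / k if p > 0 else 0.0
        total.append(val)
    return total


class TestDeltaFSubsets:
    def test_no_difference_all_empty(self):
        f = np.linspace(0.1, 0.9, 20)
        subsets = delta_f_subsets(f, f.copy())
        assert all(len(s) == 0 for s in subsets)

    def test_threshold_bookkeeping(self):
        f_n = np.array([0.5, 0.9])
        f_s = np.array([0.05, 0.9])  # locus 0 has delta f = 0.45
        s05, s04, s03 = delta_f_subsets(f_n, f_s, loci=["a", "b"])
        assert s05.loci == ()
        assert s04.loci == ("a",) and s03.loci == ("a",)

    def test_membership_brute_force_and_nesting(self, rng):
        f_n = rng.random(500)
        f_s = rng.random(500)
        subsets = delta_f_subsets(f_n, f_s)
        for sub in subsets:
            expected = {i for i in range(500) if f_n[i] - f_s[i] > sub.threshold}
            assert set(sub.loci) == expected
        assert set(subsets[0].loci) <= set(subsets[1].loci) <= set(subsets[2].loci)

    def test_missing_frequency_excluded(self):
        f_n = np.array([0.9, np.nan])
        f_s = np.array([0.1, 0.1])
        subsets = delta_f_subsets(f_n, f_s)
        assert subsets[2].loci == (0,)

    def test_no_shared_loci_error(self):
        with pytest.raises(ValueError):
            delta_f_subsets(np.array([]), np.array([]), loci=[])


class TestInformativeness:
    def test_identical_populations_zero(self):
        freqs = np.tile(np.linspace(0.1, 0.9, 9)[:, None], (1, 3))
        assert informativeness_ia(freqs) == pytest.approx(0.0, abs=1e-15)

    def test_fixed_difference_is_ln2(self):
        assert informativeness_ia(np.array([[1.0, 0.0]])) == pytest.approx(
            math.log(2), abs=1e-12
        )

    def test_matches_brute_force_oracle(self, rng):
        freqs = rng.random((50, 4))
        got = informativeness_per_locus(freqs)
        want = oracle_informativeness(freqs)
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_permutation_invariance_and_additivity(self, rng):
        freqs = rng.random((30, 3))
        base = informativeness_ia(freqs)
        for perm in itertools.permutations(range(3)):
            assert informativeness_ia(freqs[:, perm]) == pytest.approx(base)
        per_locus = informativeness_per_locus(freqs)
        assert base == pytest.approx(per_locus.mean())

    def test_invalid_frequency_rejected(self):
        with pytest.raises(ValueError):
            informativeness_ia(np.array([[1.2, 0.0]]))


class TestResampleTest:
    def test_maximal_divergence_hits_floor(self, rng):
        n_loci = 400
        x_n = rng.integers(20, 80, size=n_loci)
        x_s = rng.integers(20, 80, size=n_loci)
        idx = np.arange(10)
        x_n[idx] = 100
        x_s[idx] = 0
        res = subset_fst_resample_test(
            idx, x_n, np.full(n_loci, 100), x_s, np.full(n_loci, 100),
            n_resamples=999, seed=5,
        )
        assert res.p_value == pytest.approx(1.0 / 1000.0)

    def test_random_subset_p_roughly_uniform(self, rng):
        panel, _ = balding_nichols_panel(
            600, 0.05, 2, [100, 100], seed=21, pop_names=["cultN", "cultS"]
        )
        ps = []
        for _ in range(60):
            idx = rng.choice(600, size=30, replace=False)
            res = subset_fst_resample_test(
                idx,
                panel.x["cultN"].values, panel.n["cultN"].values,
                panel.x["cultS"].values, panel.n["cultS"].values,
                n_resamples=500, seed=int(rng.integers(2**31)),
            )
            ps.append(res.p_value)
        from scipy import stats

        assert stats.kstest(ps, "uniform").statistic < 0.15

    def test_p_floor_and_reproducibility(self, rng):
        panel, _ = balding_nichols_panel(
            300, 0.05, 2, [100, 100], seed=22, pop_names=["cultN", "cultS"]
        )
        args = (
            np.arange(12),
            panel.x["cultN"].values, panel.n["cultN"].values,
            panel.x["cultS"].values, panel.n["cultS"].values,
        )
        r1 = subset_fst_resample_test(*args, n_resamples=1000, seed=9)
        r2 = subset_fst_resample_test(*args, n_resamples=1000, seed=9)
        assert r1.p_value == r2.p_value
        assert r1.p_value >= 1.0 / 1001.0

    def test_oversized_subset_warns(self, rng):
        panel, _ = balding_nichols_panel(
            100, 0.05, 2, [100, 100], seed=23, pop_names=["cultN", "cultS"]
        )
        with pytest.warns(UserWarning, match="half"):
            subset_fst_resample_test(
                np.arange(60),
                panel.x["cultN"].values, panel.n["cultN"].values,
                panel.x["cultS"].values, panel.n["cultS"].values,
                n_resamples=100, seed=1,
            )


class TestF3:
    def test_target_equal_to_source_a_zero(self):
        x = np.full(50, 30)
        n = np.full(50, 100)
        xb = np.linspace(10, 90, 50).astype(int)
        f3, _ = f3_statistic(x, n, x, n, xb, n, bias_correction=False)
        assert f3 == pytest.approx(0.0, abs=1e-15)

    def test_admixed_target_negative(self, rng):
        # target is a 50/50 mix of two strongly diverged sources
        n_loci = 2000
        pa = rng.uniform(0.05, 0.95, n_loci)
        pb = np.clip(pa + rng.choice([-1, 1], n_loci) * 0.45, 0.01, 0.99)
        pt = 0.5 * (pa + pb)
        n = 200
        f3, z = f3_statistic(
            rng.binomial(n, pt), np.full(n_loci, n),
            rng.binomial(n, pa), np.full(n_loci, n),
            rng.binomial(n, pb), np.full(n_loci, n),
        )
        assert f3 < 0 and z < -3

    def test_drifted_target_positive(self, rng):
        n_loci = 2000
        ratio = (1 - 0.05) / 0.05
        p = rng.uniform(0.1, 0.9, n_loci)
        pt = rng.beta(p * ratio, (1 - p) * ratio)
        pa = rng.beta(p * ratio, (1 - p) * ratio)
        pb = rng.beta(p * ratio, (1 - p) * ratio)
        n = 200
        f3, z = f3_statistic(
            rng.binomial(n, pt), np.full(n_loci, n),
            rng.binomial(n, pa), np.full(n_loci, n),
            rng.binomial(n, pb), np.full(n_loci, n),
        )
        assert f3 > 0 and z > 3

    def test_too_few_loci_refused(self):
        x = np.full(10, 5)
        n = np.full(10, 20)
        with pytest.raises(ValueError, match="30"):
            f3_statistic(x, n, x, n, x, n)


class TestSharedElevation:
    def test_tie_rule(self):
        f_n = np.array([0.5, 0.6, 0.3])
        f_s = np.array([0.5, 0.4, 0.5])
        # locus 0 ties (excluded); 1 elevated; 2 not
        assert shared_elevation_fraction(f_n, f_s, [0, 1, 2]) == pytest.approx(0.5)

    def test_all_ties_undefined(self):
        f = np.array([0.5, 0.2])
        assert math.isnan(shared_elevation_fraction(f, f.copy(), [0, 1]))

    def test_empty_subset_undefined(self):
        assert math.isnan(shared_elevation_fraction(np.array([0.5]), np.array([0.4]), []))


class TestScenarioIntegration:
    def test_gene_flow_elevates_sharing_and_informativeness(self):
        sc = geneflow_scenario(3000, 0.05, 0.1, 20, 3, seed=31)
        f = sc.freq
        subsets = delta_f_subsets(f["wildN"].values, f["wildS"].values)
        idx = np.asarray(subsets[1].loci, dtype=int)  # delta f > 0.4
        assert len(idx) >= 5
        frac = shared_elevation_fraction(f["cultN"].values, f["cultS"].values, idx)
        assert frac > 0.7
        wild = f[["wildN", "wildS"]].values
        assert informativeness_ia(wild[idx]) > informativeness_ia(wild)

    def test_no_gene_flow_sharing_near_half(self):
        fracs = []
        for seed in (41, 42, 43, 44):
            sc = geneflow_scenario(3000, 0.05, 0.0, 20, 0, seed=seed)
            f = sc.freq
            subsets = delta_f_subsets(f["wildN"].values, f["wildS"].values)
            idx = np.asarray(subsets[2].loci, dtype=int)  # delta f > 0.3
            fracs.append(
                shared_elevation_fraction(f["cultN"].values, f["cultS"].values, idx)
            )
        assert 0.3 < np.nanmean(fracs) < 0.7
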