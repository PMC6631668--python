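"""Informativeness, marker equivalence, Mantel tests, supervised admixture."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import radpanel as rp
from radpanel.evaluate import RegressionFit, classify_ancestry
from radpanel.popgen import AlleleFrequencyTable, SampleSizeError


def table_from_freqs(by_locus_pop):
    """Build an AlleleFrequencyTable from {locus: {pop: {allele: f}}}."""
    copies = {l: {p: 100 for p in by_pop} for l, by_pop in by_locus_pop.items()}
    return AlleleFrequencyTable(by_locus_pop, copies)


def brute_force_in(by_pop):
    """Term-by-term evaluation of the informativeness definition."""
    pops = list(by_pop)
    K = len(pops)
    alleles = sorted({a for f in by_pop.values() for a in f})
    total = 0.0
    for j in alleles:
        pbar = sum(by_pop[p].get(j, 0.0) for p in pops) / K
        term = -(pbar * math.log(pbar)) if pbar > 0 else 0.0
        for p in pops:
            pij = by_pop[p].get(j, 0.0)
            if pij > 0:
                term += (pij / K) * math.log(pij)
        total += term
    return total


class TestInformativeness:
    def test_identical_frequencies_zero(self):
        f = {"A": 0.7, "G": 0.3}
        t = table_from_freqs({"l": {"p1": f, "p2": f, "p3": f}})
        assert rp.informativeness_for_assignment(t) == pytest.approx(0.0, abs=1e-12)

    def test_fixed_difference_is_ln2(self):
        t = table_from_freqs({"l": {"p1": {"A": 1.0}, "p2": {"G": 1.0}}})
        assert rp.informativeness_for_assignment(t) == pytest.approx(math.log(2))

    def test_two_population_07_03_matches_direct_evaluation(self):
        by_pop = {"p1": {"A": 0.7, "G": 0.3}, "p2": {"A": 0.3, "G": 0.7}}
        expected = brute_force_in(by_pop)  # = 0.7*ln(1.4)/... evaluated directly
        assert rp.locus_informativeness(by_pop) == pytest.approx(expected)
        # frozen value from the independent evaluation above
        assert expected == pytest.approx(0.0822828, abs=1e-6)

    def test_single_population_rejected(self):
        t = table_from_freqs({"l": {"p1": {"A": 1.0}}})
        with pytest.raises(rp.ConfigurationError):
            rp.informativeness_for_assignment(t)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10 ** 6))
    def test_additive_nonnegative_and_order_invariant(self, seed):
        rng = np.random.default_rng(seed)
        n_loci = int(rng.integers(2, 6))
        k = int(rng.integers(2, 5))
        by_locus = {}
        for l in range(n_loci):
            by_locus[f"l{l}"] = {
                f"p{i}": dict(zip("AG", rng.dirichlet([1, 1])))
                for i in range(k)}
        t = table_from_freqs(by_locus)
        total = rp.informativeness_for_assignment(t)
        parts = [rp.locus_informativeness(by_locus[l]) for l in by_locus]
        assert total == pytest.approx(sum(parts))
        assert total >= -1e-12
        assert all(p >= -1e-12 for p in parts)
        # population order must not matter
        shuffled = {l: dict(reversed(list(by_pop.items())))
                    for l, by_pop in by_locus.items()}
        assert rp.informativeness_for_assignment(
            table_from_freqs(shuffled)) == pytest.approx(total)

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            by_pop = {f"p{i}": dict(zip("ACGT", rng.dirichlet([1] * 4)))
                      for i in range(int(rng.integers(2, 6)))}
            assert rp.locus_informativeness(by_pop) == pytest.approx(
                brute_force_in(by_pop))


class TestInformativenessCurve:
    def test_full_panel_size_exact_and_deterministic(self, two_pop_small):
        m, pops, _ = two_pop_small
        loci = [l for l in m.locus_ids if len(m.alleles_at(l)) >= 2]
        full = rp.informativeness_for_assignment(
            rp.allele_frequencies(m, pops, loci=loci))
        curve = rp.informativeness_curve(m, pops, [10, 20, len(loci)],
                                         replicates=20, seed=5)
        assert curve.means[-1] == pytest.approx(full)
        assert curve.sds[-1] == 0.0
        again = rp.informativeness_curve(m, pops, [10, 20, len(loci)],
                                         replicates=20, seed=5)
        assert curve.means == again.means

    def test_mean_scales_with_subset_size(self, two_pop_small):
        m, pops, _ = two_pop_small
        loci = [l for l in m.locus_ids if len(m.alleles_at(l)) >= 2]
        freqs = rp.allele_frequencies(m, pops, loci=loci)
        per_locus = np.array([rp.locus_informativeness(freqs.freqs[l])
                              for l in loci])
        size = 20
        curve = rp.informativeness_curve(m, pops, [size], replicates=300, seed=2)
        expected = size * per_locus.mean()
        se = curve.sds[0] / math.sqrt(curve.replicates)
        assert abs(curve.means[0] - expected) < 3 * se + 1e-9

    def test_oversize_subset_rejected(self, two_pop_small):
        m, pops, _ = two_pop_small
        with pytest.raises(SampleSizeError):
            rp.informativeness_curve(m, pops, [m.n_loci + 1], 5, 0)


class TestRegressionAndEquivalence:
    def test_exact_linear_curve_recovered(self):
        curve = rp.InformativenessCurve(
            sizes=[10, 20, 40, 80], means=[0.5, 1.0, 2.0, 4.0],
            sds=[0] * 4, replicates=1, seed=0)
        fit = rp.fit_informativeness_regression(curve)
        assert fit.slope == pytest.approx(0.05, abs=1e-9)
        assert fit.intercept == pytest.approx(0.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_curve_zero_slope(self):
        curve = rp.InformativenessCurve([1, 2, 3], [0.7, 0.7, 0.7],
                                        [0] * 3, 1, 0)
        assert rp.fit_informativeness_regression(curve).slope == pytest.approx(0.0)

    def test_planted_coefficients_recovered_through_noise(self):
        rng = np.random.default_rng(77)
        sizes = [10, 20, 40, 60, 80, 92]
        a, b = 0.023, 0.0038
        means = [a * n + b + rng.normal(0, 0.01) for n in sizes]
        fit = rp.fit_informativeness_regression(
            rp.InformativenessCurve(sizes, means, [0.01] * 6, 50, 0))
        assert fit.slope == pytest.approx(a, abs=0.002)
        assert fit.intercept == pytest.approx(b, abs=0.05)
        assert fit.r_squared > 0.95

    def test_reference_equation_inverts_to_108(self):
        fit = RegressionFit(slope=0.023, intercept=0.0038, r_squared=0.98)
        assert rp.equivalent_marker_count(fit, 2.48) == 108

    def test_target_at_intercept_needs_zero_markers(self):
        fit = RegressionFit(0.023, 0.0038, 1.0)
        assert rp.equivalent_marker_count(fit, 0.0038) == 0

    def test_matches_brute_force_integer_search(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            a = rng.uniform(0.001, 0.1)
            b = rng.uniform(-0.5, 0.5)
            target = rng.uniform(0, 5)
            got = rp.equivalent_marker_count(RegressionFit(a, b, 1.0), target)
            n = 0
            while a * n + b < target - 1e-12:
                n += 1
            assert got == n

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(rp.ConfigurationError):
            rp.equivalent_marker_count(RegressionFit(-0.01, 0.0, 1.0), 1.0)


class TestMantel:
    def test_proportional_matrices_perfect_correlation(self):
        geo, fst, _ = rp.simulate_site_network(seed=1, noise_sd=0.0)
        res = rp.mantel_test(fst, geo, n_perm=199, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value <= 0.05

    def test_observed_r_matches_hand_computation(self):
        # 4 sites, 6 lower-triangle pairs, Pearson by hand
        g = np.array([[0, 1, 2, 3], [1, 0, 1.5, 2.5],
                      [2, 1.5, 0, 1.2], [3, 2.5, 1.2, 0]], dtype=float)
        f = np.array([[0, .02, .05, .09], [.02, 0, .01, .06],
                      [.05, .01, 0, .03], [.09, .06, .03, 0]])
        x = [1, 2, 3, 1.5, 2.5, 1.2]
        y = [.02, .05, .09, .01, .06, .03]
        r_hand = np.corrcoef(x, y)[0, 1]
        res = rp.mantel_test(rp.DistanceMatrix(list("abcd"), f),
                             rp.DistanceMatrix(list("abcd"), g),
                             n_perm=99, seed=0)
        assert res.r == pytest.approx(r_hand)

    def test_p_invariant_to_joint_relabeling(self):
        geo, fst, _ = rp.simulate_site_network(seed=3)
        perm = ["site3", "site1", "site4", "site2", "site6", "site5",
                "site8", "site7"]
        res1 = rp.mantel_test(fst, geo, n_perm=499, seed=9)
        res2 = rp.mantel_test(fst.reordered(perm), geo.reordered(perm),
                              n_perm=499, seed=9)
        assert res1.r == pytest.approx(res2.r)
        # permuted-r samples are conjugated, not identical, so the p
        # estimate matches up to Monte-Carlo resolution
        assert res1.p_value == pytest.approx(res2.p_value, abs=0.02)

    def test_label_mismatch_rejected(self):
        geo, fst, _ = rp.simulate_site_network(seed=4)
        other = rp.DistanceMatrix(["x"] * 0 + [f"s{k}" for k in range(8)],
                                  geo.values)
        with pytest.raises(rp.ValidationError):
            rp.mantel_test(fst, other)


def reference_tables(truth, n_copies=200):
    """AlleleFrequencyTables for the two simulated source pools."""
    def tab(freqs, pop):
        f = {f"snp{j:04d}": {pop: {"G": float(freqs[j]),
                                   "A": 1.0 - float(freqs[j])}}
             for j in range(len(freqs))}
        c = {l: {pop: n_copies} for l in f}
        return AlleleFrequencyTable(f, c)
    pools = list(truth.pop_freqs)
    return tab(truth.pop_freqs[pools[0]], "captive"), \
        tab(truth.pop_freqs[pools[1]], "wild")


class TestSupervisedAdmixture:
    def test_pure_captive_individual_scores_near_one(self):
        m, pops, truth = rp.simulate_two_lineage_genotypes(
            n_pops=2, n_per_pop=20, n_loci=90, divergence_F=0.5, seed=31)
        cap, wild = reference_tables(truth)
        res = rp.supervised_admixture(m, cap, wild)
        q1 = res.q[pops.members("pop1")]
        assert q1.mean() > 0.9
        assert (res.labels[pops.members("pop1")] == "captive-bred").mean() > 0.8

    def test_f1_hybrids_score_near_half(self):
        n = 40
        q_true = [0.5] * n + [0.5] * n
        m, pops, truth = rp.simulate_two_lineage_genotypes(
            n_pops=2, n_per_pop=n, n_loci=90, divergence_F=0.5,
            admixture_spec=q_true, seed=32)
        cap, wild = reference_tables(truth)
        res = rp.supervised_admixture(m, cap, wild)
        assert res.q.between(0.3, 0.7).mean() > 0.9
        assert (res.labels == "admixed").mean() > 0.8

    def test_threshold_rule_is_strict(self):
        assert classify_ancestry(0.7, 0.7) == "admixed"
        assert classify_ancestry(0.3, 0.7) == "admixed"
        assert classify_ancestry(0.7 + 1e-9, 0.7) == "captive-bred"
        assert classify_ancestry(0.3 - 1e-9, 0.7) == "wild"
        assert classify_ancestry(float("nan"), 0.7) == "missing"

    def test_individual_with_no_scorable_loci_reported_missing(self):
        m, _, truth = rp.simulate_two_lineage_genotypes(
            n_pops=2, n_per_pop=2, n_loci=30, divergence_F=0.5, seed=33)
        calls = m.calls.copy()
        calls[0, :] = None
        m2 = rp.GenotypeMatrix(m.individual_ids, m.locus_ids, calls)
        cap, wild = reference_tables(truth)
        res = rp.supervised_admixture(m2, cap, wild)
        first = m.individual_ids[0]
        assert math.isnan(res.q[first])
        assert res.labels[first] == "missing"
        assert res.metadata["estimator"].startswith("supervised")


class TestAncestryConcordance:
    def test_identity_and_reversal(self):
        q = pd.Series(np.linspace(0, 1, 20),
                      index=[f"i{k}" for k in range(20)])
        rho, _ = rp.ancestry_concordance(q, q)
        assert rho == pytest.approx(1.0)
        rho2, _ = rp.ancestry_concordance(q, 1 - q)
        assert rho2 == pytest.approx(-1.0)

    def test_matches_manual_midrank_formula(self):
        rng = np.random.default_rng(8)
        idx = [f"i{k}" for k in range(30)]
        a = pd.Series(rng.random(30), index=idx)
        b = pd.Series(np.round(rng.random(30), 1), index=idx)  # ties
        rho, _ = rp.ancestry_concordance(a, b)
        ra, rb = a.rank(), b.rank()
        manual = np.corrcoef(ra, rb)[0, 1]
        assert rho == pytest.approx(manual)

    def test_too_few_pairs_rejected(self):
        q = pd.Series([0.1, 0.2], index=["a", "b"])
        with pytest.raises(SampleSizeError):
            rp.ancestry_concordance(q, q)
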