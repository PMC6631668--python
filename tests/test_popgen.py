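"""Frequencies, heterozygosity, Fst, rarefaction, QC, outlier scan."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import radpanel as rp
from radpanel.popgen import SampleSizeError, _copy_counts

from conftest import random_calls


def matrix_from_columns(cols, n, prefix="i", classes=None):
    loci = list(cols)
    calls = [[cols[l][i] for l in loci] for i in range(n)]
    return rp.GenotypeMatrix([f"{prefix}{k}" for k in range(n)], loci, calls,
                             classes)


class TestAlleleFrequencies:
    def test_two_individual_example(self):
        m = matrix_from_columns({"l": [("A", "A"), ("A", "G")]}, 2)
        pops = rp.PopulationAssignment({"i0": "p", "i1": "p"})
        t = rp.allele_frequencies(m, pops)
        assert t.frequency("l", "p", "A") == pytest.approx(0.75)
        assert t.frequency("l", "p", "G") == pytest.approx(0.25)

    def test_all_missing_in_one_population_errors(self):
        m = matrix_from_columns({"l": [("A", "A"), None]}, 2)
        pops = rp.PopulationAssignment({"i0": "p1", "i1": "p2"})
        with pytest.raises(rp.UndefinedValueError, match="p2"):
            rp.allele_frequencies(m, pops)

    def test_haploid_counts_one_copy_per_individual(self):
        m = matrix_from_columns({"mt": [("A", "A"), ("A", "A"), ("G", "G")]},
                                3, classes={"mt": "mitochondrial"})
        pops = rp.PopulationAssignment({f"i{k}": "p" for k in range(3)})
        t = rp.allele_frequencies(m, pops)
        assert t.frequency("mt", "p", "G") == pytest.approx(1 / 3)
        assert t.copies["mt"]["p"] == 3

    def test_matches_brute_force_copy_counting(self):
        rng = np.random.default_rng(3)
        cols = {f"l{k}": random_calls(rng, 30, rng.uniform(0.1, 0.9),
                                      missing_rate=0.1) for k in range(15)}
        m = matrix_from_columns(cols, 30)
        pops = rp.PopulationAssignment(
            {f"i{k}": ("p1" if k < 15 else "p2") for k in range(30)})
        t = rp.allele_frequencies(m, pops)
        for l in m.locus_ids:
            for p, rows in (("p1", range(15)), ("p2", range(15, 30))):
                copies = [a for i in rows if cols[l][i] is not None
                          for a in cols[l][i]]
                for allele in set(copies):
                    assert t.frequency(l, p, allele) == pytest.approx(
                        copies.count(allele) / len(copies))


class TestHeterozygosity:
    def test_biallelic_half(self):
        assert rp.expected_heterozygosity({"A": 0.5, "G": 0.5}) == pytest.approx(0.5)

    def test_four_equifrequent_alleles(self):
        assert rp.expected_heterozygosity(
            {a: 0.25 for a in "abcd"}) == pytest.approx(0.75)

    def test_observed_fraction(self):
        calls = [("A", "G"), ("A", "A"), None, ("A", "G")]
        assert rp.observed_heterozygosity(calls) == pytest.approx(2 / 3)

    def test_fis_zero_under_hardy_weinberg(self):
        rng = np.random.default_rng(8)
        cols = {f"l{k}": random_calls(rng, 500, rng.uniform(0.2, 0.8))
                for k in range(30)}
        m = matrix_from_columns(cols, 500)
        fis_vals = []
        for l in m.locus_ids:
            freqs = {a: c / 1000 for a, c in _copy_counts(m.column(l), False).items()}
            fis_vals.append(rp.fis(rp.expected_heterozygosity(freqs),
                                   rp.observed_heterozygosity(m.column(l))))
        assert abs(np.mean(fis_vals)) < 0.05

    def test_fis_undefined_for_monomorphic(self):
        assert math.isnan(rp.fis(0.0, 0.0))


class TestSiteUniquenessFst:
    def test_equal_diversity_is_zero(self):
        assert rp.site_uniqueness_fst(0.2, 0.2) == 0.0

    def test_direct_arithmetic(self):
        assert rp.site_uniqueness_fst(0.18, 0.20) == pytest.approx(0.10)

    def test_zero_total_undefined(self):
        with pytest.raises(rp.UndefinedValueError):
            rp.site_uniqueness_fst(0.1, 0.0)

    def test_per_site_table_matches_independent_recomputation(self, two_pop_small):
        m, pops, _ = two_pop_small
        table = rp.per_site_stats(m, pops).set_index("site")
        loci = [l for l in m.locus_ids if len(m.alleles_at(l)) >= 2]
        all_pop = rp.PopulationAssignment({i: "all" for i in m.individual_ids})
        t_all = rp.allele_frequencies(m.subset(loci=loci), all_pop)
        he_tot = np.mean([rp.expected_heterozygosity(t_all.freqs[l]["all"])
                          for l in loci])
        for p in pops.populations():
            sub = m.subset(individuals=pops.members(p), loci=loci)
            he_site = np.mean([rp.expected_heterozygosity(
                {a: c / sum(_copy_counts(sub.column(l), False).values())
                 for a, c in _copy_counts(sub.column(l), False).items()})
                for l in loci])
            assert table.loc[p, "Fst"] == pytest.approx(1 - he_site / he_tot)


class TestPairwiseFst:
    def test_identical_populations_zero(self):
        col = [("A", "A"), ("A", "G"), ("G", "G")] * 2
        m = matrix_from_columns({"l": col}, 6)
        pops = rp.PopulationAssignment(
            {f"i{k}": ("p1" if k < 3 else "p2") for k in range(6)})
        # same genotype multiset in both demes
        assert rp.pairwise_fst(m, pops, ("p1", "p2")) == pytest.approx(0.0)

    def test_fixed_difference_is_one(self):
        col = [("A", "A")] * 3 + [("G", "G")] * 3
        m = matrix_from_columns({"l": col}, 6)
        pops = rp.PopulationAssignment(
            {f"i{k}": ("p1" if k < 3 else "p2") for k in range(6)})
        assert rp.pairwise_fst(m, pops, ("p1", "p2")) == pytest.approx(1.0)

    def test_symmetric_and_relabel_invariant(self, two_pop_small):
        m, pops, _ = two_pop_small
        a = rp.pairwise_fst(m, pops, ("pop1", "pop2"))
        b = rp.pairwise_fst(m, pops, ("pop2", "pop1"))
        assert a == pytest.approx(b)
        # swap allele labels at every locus
        swapped = np.empty_like(m.calls)
        relabel = {"A": "G", "G": "A"}
        for i in range(m.calls.shape[0]):
            for j in range(m.calls.shape[1]):
                c = m.calls[i, j]
                swapped[i, j] = None if c is None else rp.call(relabel[c[0]],
                                                               relabel[c[1]])
        m2 = rp.GenotypeMatrix(m.individual_ids, m.locus_ids, swapped)
        assert rp.pairwise_fst(m2, pops, ("pop1", "pop2")) == pytest.approx(a)

    def test_monomorphic_pair_undefined(self):
        m = matrix_from_columns({"l": [("A", "A")] * 4}, 4)
        pops = rp.PopulationAssignment(
            {f"i{k}": ("p1" if k < 2 else "p2") for k in range(4)})
        with pytest.raises(rp.UndefinedValueError):
            rp.pairwise_fst(m, pops, ("p1", "p2"))

    def test_matrix_is_symmetric_distance_object(self, two_pop_small):
        m, pops, _ = two_pop_small
        dm = rp.pairwise_fst_matrix(m, pops)
        assert dm.labels == ["pop1", "pop2"]
        assert dm.values[0, 1] == dm.values[1, 0] > 0


class TestAllelicRichness:
    def test_full_depth_equals_observed_allele_count(self):
        counts = {"a": 3, "b": 2, "c": 1}
        assert rp.rarefied_allele_count(counts, 6) == pytest.approx(3.0)

    def test_monomorphic_is_one(self):
        for n in (2, 5, 9):
            assert rp.rarefied_allele_count({"a": 10}, n) == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        counts = {"a": 3, "b": 2, "c": 1}
        pool = ["a"] * 3 + ["b"] * 2 + ["c"]
        n = 4
        subs = list(itertools.combinations(range(6), n))
        expected = np.mean([len({pool[i] for i in s}) for s in subs])
        assert rp.rarefied_allele_count(counts, n) == pytest.approx(expected)

    def test_nondecreasing_in_subsample_size(self):
        counts = {"a": 6, "b": 3, "c": 1}
        vals = [rp.rarefied_allele_count(counts, n) for n in range(2, 11)]
        assert all(x <= y + 1e-12 for x, y in zip(vals, vals[1:]))

    def test_subsample_size_limits(self):
        with pytest.raises(rp.ConfigurationError):
            rp.rarefied_allele_count({"a": 4}, 1)
        with pytest.raises(SampleSizeError):
            rp.rarefied_allele_count({"a": 4}, 5)


class TestGenotypingQC:
    def test_complete_matrix(self, two_pop_small):
        m, _, _ = two_pop_small
        qc = rp.genotyping_qc(m)
        assert (qc.per_individual["n_missing"] == 0).all()
        assert qc.summary["max_missing_per_individual"] == 0

    def test_single_missing_call_proportion(self):
        rng = np.random.default_rng(2)
        cols = {f"l{k}": random_calls(rng, 3, 0.5) for k in range(162)}
        cols["l0"][1] = None
        m = matrix_from_columns(cols, 3)
        qc = rp.genotyping_qc(m)
        row = qc.per_individual.set_index("individual_id").loc["i1"]
        assert row["prop_missing"] == pytest.approx(1 / 162)

    def test_planted_missingness_rate_recovered(self):
        m, _, truth = rp.simulate_two_lineage_genotypes(
            n_pops=2, n_per_pop=50, n_loci=200, divergence_F=0.1,
            missing_rate=0.01, seed=6)
        qc = rp.genotyping_qc(m)
        observed = qc.per_individual["prop_missing"].mean()
        n_calls = m.n_individuals * m.n_loci
        se = math.sqrt(0.01 * 0.99 / n_calls)
        assert abs(observed - 0.01) < 3 * se

    def test_polymorphic_count(self):
        cols = {"poly": [("A", "G"), ("A", "A")], "mono": [("C", "C")] * 2}
        m = matrix_from_columns(cols, 2)
        assert rp.genotyping_qc(m).n_polymorphic == 1


class TestDropHighMissing:
    def test_individual_over_one_third_removed(self):
        rng = np.random.default_rng(4)
        n_loci = 100
        cols = {f"l{k}": random_calls(rng, 2, 0.5) for k in range(n_loci)}
        for k in range(34):
            cols[f"l{k}"][0] = None
        m = matrix_from_columns(cols, 2)
        kept = rp.drop_high_missing_individuals(m, 1 / 3)
        assert kept.individual_ids == ["i1"]

    def test_exactly_one_third_kept(self):
        cols = {f"l{k}": [("A", "G")] for k in range(3)}
        cols["l0"][0] = None
        m = matrix_from_columns(cols, 1)
        assert rp.drop_high_missing_individuals(m, 1 / 3).individual_ids == ["i0"]

    def test_matches_brute_force_rule(self):
        m, _, _ = rp.simulate_two_lineage_genotypes(
            n_pops=2, n_per_pop=40, n_loci=60, divergence_F=0.1,
            missing_rate=0.3, seed=9)
        kept = set(rp.drop_high_missing_individuals(m, 1 / 3).individual_ids)
        miss = m.missing_mask()
        expected = {ind for r, ind in enumerate(m.individual_ids)
                    if miss[r].mean() <= 1 / 3}
        assert kept == expected


class TestOutlierScan:
    def test_too_few_loci_rejected(self):
        m, pops, _ = rp.simulate_two_lineage_genotypes(
            n_pops=2, n_per_pop=20, n_loci=10, divergence_F=0.1, seed=1)
        with pytest.raises(SampleSizeError):
            rp.fst_outlier_scan(m, pops)

    def test_engineered_fixed_difference_flagged(self):
        m, pops, _ = rp.simulate_two_lineage_genotypes(
            n_pops=2, n_per_pop=40, n_loci=120, divergence_F=0.02, seed=3)
        calls = m.calls.copy()
        j = m.locus_index("snp0000")
        for r, ind in enumerate(m.individual_ids):
            allele = "A" if pops.assignments[ind] == "pop1" else "G"
            calls[r, j] = (allele, allele)
        m2 = rp.GenotypeMatrix(m.individual_ids, m.locus_ids, calls)
        scan = rp.fst_outlier_scan(m2, pops)
        assert "snp0000" in scan.flagged

    def test_envelope_ordering_and_flag_definition(self):
        m, pops, _ = rp.simulate_two_lineage_genotypes(
            n_pops=2, n_per_pop=40, n_loci=200, divergence_F=0.05, seed=4)
        scan = rp.fst_outlier_scan(m, pops)
        assert (scan.envelope["lower"] <= scan.envelope["upper"] + 1e-12).all()
        flagged = set(scan.flagged)
        assert flagged == set(
            scan.per_locus.loc[scan.per_locus["flagged"], "locus_id"])


def test_statistics_invariant_to_individual_order(two_pop_small):
    m, pops, _ = two_pop_small
    order = list(reversed(m.individual_ids))
    m2 = m.subset(individuals=order)
    assert rp.pairwise_fst(m, pops, ("pop1", "pop2")) == pytest.approx(
        rp.pairwise_fst(m2, pops, ("pop1", "pop2")))
    loci = m.locus_ids[:10]
    assert rp.allelic_richness(m.subset(loci=loci), 10) == pytest.approx(
        rp.allelic_richness(m2.subset(loci=loci), 10))
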