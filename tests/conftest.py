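import numpy as np
import pytest

import radpanel as rp


@pytest.fixture
def trio_matrix():
    """Three individuals, two SNP loci, one missing call."""
    calls = [
        [("A", "A"), ("C", "T")],
        [("A", "G"), ("C", "C")],
        [None, ("T", "T")],
    ]
    return rp.GenotypeMatrix(["i1", "i2", "i3"], ["l1", "l2"], calls)


@pytest.fixture
def two_pop_small():
    """Two demes, 60 loci, no missing data; moderate divergence."""
    return rp.simulate_two_lineage_genotypes(
        n_pops=2, n_per_pop=25, n_loci=60, divergence_F=0.15, seed=11)


@pytest.fixture
def clean_tags():
    """200 single-SNP mapped tags that pass every filter."""
    lmap = rp.simulate_linkage_map(seed=21)
    tags, labels = rp.simulate_rad_tags(
        lmap, 200, snp_count_probs={1: 1.0}, seed=21)
    return lmap, tags, labels


def random_calls(rng, n, p, missing_rate=0.0):
    """Random biallelic calls at one locus (helper for brute-force oracles)."""
    out = []
    for _ in range(n):
        if rng.random() < missing_rate:
            out.append(None)
        else:
            g = rng.binomial(2, p)
            out.append(rp.call(*(["A"] * (2 - g) + ["G"] * g)))
    return out
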