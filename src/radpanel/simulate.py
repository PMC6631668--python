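"""Synthetic-data generators for every input the toolkit consumes.

These emulate a two-lineage salmonid setting: a ~1453 cM linkage map in
40 groups, RAD tags with within-tag SNPs, diploid genotypes for demes
diverging under a Balding-Nichols model, hatchery admixture, wide
microsatellite tables and along-river site networks with an
isolation-by-distance signal.  Every generator is a deterministic
function of (parameters, seed) and each emits a SimulationTruth record
sufficient to verify downstream estimates.

Divergence model.  Population allele frequencies are Beta-distributed
around an ancestral frequency p with variance c*p*(1-p).  The
``divergence_F`` parameter is calibrated so that it equals the expected
pairwise Fst ((Ht-Hs)/Ht) between two demes rather than the per-deme
variance coefficient: two demes drawn independently with coefficient c
show expected pairwise Fst (c/2)/(1 - c/2), so we draw with
c = 2F/(1+F), which makes the planted parameter directly recoverable by
the estimator it is meant to exercise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    ConfigurationError,
    DistanceMatrix,
    GenotypeMatrix,
    LinkageMap,
    PopulationAssignment,
    RadTag,
    call,
)

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationTruth:
    """Ground truth behind one simulated dataset."""

    seed: int
    ancestral_freqs: np.ndarray | None = None
    pop_freqs: dict[str, np.ndarray] = field(default_factory=dict)
    q: pd.Series | None = None
    outlier_loci: list[str] = field(default_factory=list)
    missing_rate: float = 0.0
    divergence_F: float | None = None
    tag_labels: pd.DataFrame | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Linkage map
# ---------------------------------------------------------------------------

def simulate_linkage_map(n_groups: int = 40, total_cM: float = 1453.0,
                         concentration: float = 5.0, seed: int = 0) -> LinkageMap:
    """Empty linkage map whose group lengths split ``total_cM`` Dirichlet-style."""
    if n_groups < 1 or total_cM <= 0:
        raise ConfigurationError("need n_groups >= 1 and total_cM > 0")
    rng = np.random.default_rng(seed)
    if n_groups == 1:
        lengths = np.array([total_cM])
    else:
        lengths = rng.dirichlet([concentration] * n_groups) * total_cM
    return LinkageMap(groups={g + 1: [] for g in range(n_groups)},
                      total_length_cM=float(total_cM),
                      group_lengths={g + 1: float(L) for g, L in enumerate(lengths)})


# ---------------------------------------------------------------------------
# RAD tags with planted filter violations
# ---------------------------------------------------------------------------

def simulate_rad_tags(lmap: LinkageMap, n_tags: int, tag_length: int = 230,
                      snp_count_probs: Mapping[int, float] | None = None,
                      edge_violation_rate: float = 0.0,
                      primer_violation_rate: float = 0.0,
                      n_rate: float = 0.0, unmapped_rate: float = 0.0,
                      excess_snp_rate: float = 0.0,
                      edge_bp: int = 30, primer_zone_bp: int = 50,
                      seed: int = 0) -> tuple[list[RadTag], pd.DataFrame]:
    """RAD tags whose truth labels record the filter each is built to violate.

    Violation classes are drawn independently per tag: ``excess_snps``
    (3 SNPs), ``edge`` (a SNP inside the first/last ``edge_bp``),
    ``primer_zone`` (single SNP inside the primer zones but outside the
    edge windows), ``has_n`` (an N base), ``unmapped`` (no map position).
    All-zero rates with single-SNP tags produce tags passing every filter.
    """
    for r in (edge_violation_rate, primer_violation_rate, n_rate,
              unmapped_rate, excess_snp_rate):
        if not 0 <= r <= 1:
            raise ConfigurationError("violation rates must lie in [0, 1]")
    if tag_length <= 2 * primer_zone_bp:
        raise ConfigurationError(
            f"tag_length {tag_length} too short for {primer_zone_bp} bp zones")
    probs = dict(snp_count_probs or {1: 0.8, 2: 0.2})
    counts = sorted(probs)
    pvec = np.array([probs[c] for c in counts], dtype=float)
    pvec = pvec / pvec.sum()
    rng = np.random.default_rng(seed)
    group_labels = sorted(lmap.groups)
    lengths = lmap.group_lengths or {g: lmap.total_length_cM / len(group_labels)
                                     for g in group_labels}
    tags: list[RadTag] = []
    rows = []
    for k in range(n_tags):
        tid = f"tag{k:06d}"
        seq = rng.choice(_BASES, size=tag_length)
        excess = rng.random() < excess_snp_rate
        n_snps = 3 if excess else int(rng.choice(counts, p=pvec))
        edge_v = rng.random() < edge_violation_rate
        primer_v = (not edge_v) and n_snps == 1 and rng.random() < primer_violation_rate
        has_n = rng.random() < n_rate
        unmapped = rng.random() < unmapped_rate

        interior = np.arange(primer_zone_bp, tag_length - primer_zone_bp)
        offsets = sorted(rng.choice(interior, size=n_snps, replace=False).tolist())
        if edge_v:
            side = rng.random() < 0.5
            bad = int(rng.integers(0, edge_bp))
            offsets[0] = bad if side else tag_length - 1 - bad
            offsets = sorted(set(offsets))
            while len(offsets) < n_snps:  # collision repair, keeps count fixed
                extra = int(rng.choice(interior))
                if extra not in offsets:
                    offsets = sorted(offsets + [extra])
        if primer_v:
            side = rng.random() < 0.5
            o = int(rng.integers(edge_bp, primer_zone_bp))
            offsets = [o if side else tag_length - 1 - o]
        alleles = []
        for o in offsets:
            ref = seq[o]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            alleles.append((str(ref), str(alt)))
        if has_n:
            free = [i for i in range(tag_length) if i not in offsets]
            seq[int(rng.choice(free))] = "N"
        if unmapped:
            lg, pos = None, None
        else:
            lg = int(rng.choice(group_labels))
            pos = float(rng.uniform(0, lengths[lg]))
        tags.append(RadTag(tag_id=tid, sequence="".join(seq),
                           snp_offsets=offsets, snp_alleles=alleles,
                           linkage_group=lg, position_cM=pos))
        n_eff = len(offsets)
        rows.append({
            "tag_id": tid,
            "violates_max_snps": n_eff > 2,
            "violates_edge": any(o < edge_bp or o >= tag_length - edge_bp
                                 for o in offsets),
            "violates_primer_zone": not (
                n_eff == 1 and all(primer_zone_bp <= o < tag_length - primer_zone_bp
                                   for o in offsets)),
            "has_n": has_n,
            "unmapped": unmapped,
        })
    return tags, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Two-lineage genotypes
# ---------------------------------------------------------------------------

def _bn_concentration(divergence_F: float) -> float:
    return 2 * divergence_F / (1 + divergence_F)


def simulate_two_lineage_genotypes(
        n_pops: int = 2, n_per_pop: int = 100, n_loci: int = 100,
        divergence_F: float = 0.1,
        admixture_spec: Sequence[float] | Mapping[str, float] | None = None,
        missing_rate: float = 0.0,
        outlier_spec: Mapping[str, float] | None = None,
        seed: int = 0,
) -> tuple[GenotypeMatrix, PopulationAssignment, SimulationTruth]:
    """Biallelic SNP genotypes for demes under the calibrated BN model.

    Each deme's allele frequency is Beta-drawn around a shared ancestral
    frequency ~ Uniform(0.05, 0.95); genotypes are Binomial(2, f).  With
    ``admixture_spec`` (a per-individual q vector or {individual: q}),
    individual genotypes instead use q*f_pop1 + (1-q)*f_pop2, emulating
    hatchery introgression between the first two frequency sets.
    ``outlier_spec`` = {"n_outliers": k, "divergence_F": F'} replants k
    loci at an inflated divergence.  Missing calls are Bernoulli per
    call.  Alleles are "A" (ancestral-counted) and "G".
    """
    if not 0 < divergence_F < 1:
        raise ConfigurationError("divergence_F must lie in (0, 1)")
    if not 0 <= missing_rate < 1:
        raise ConfigurationError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    c = _bn_concentration(divergence_F)
    p = rng.uniform(0.05, 0.95, n_loci)
    a, b = p * (1 - c) / c, (1 - p) * (1 - c) / c
    pops = [f"pop{i + 1}" for i in range(n_pops)]
    pop_freqs = {pn: rng.beta(a, b) for pn in pops}

    outliers: list[int] = []
    if outlier_spec:
        k = int(outlier_spec.get("n_outliers", 0))
        f_out = float(outlier_spec.get("divergence_F", 0.8))
        c_out = _bn_concentration(f_out)
        outliers = list(rng.choice(n_loci, size=k, replace=False))
        for j in outliers:
            aa, bb = p[j] * (1 - c_out) / c_out, (1 - p[j]) * (1 - c_out) / c_out
            for pn in pops:
                pop_freqs[pn][j] = rng.beta(aa, bb)

    locus_ids = [f"snp{j:04d}" for j in range(n_loci)]
    ind_ids, assign = [], {}
    for pn in pops:
        for i in range(n_per_pop):
            iid = f"{pn}_ind{i:03d}"
            ind_ids.append(iid)
            assign[iid] = pn
    if admixture_spec is None:
        q_ser = None
    else:
        if isinstance(admixture_spec, Mapping):
            q_ser = pd.Series({i: float(admixture_spec[i]) for i in ind_ids})
        else:
            q_ser = pd.Series(np.asarray(admixture_spec, dtype=float), index=ind_ids)

    calls = np.empty((len(ind_ids), n_loci), dtype=object)
    for r, iid in enumerate(ind_ids):
        if q_ser is None:
            f = pop_freqs[assign[iid]]
        else:
            q = q_ser[iid]
            f = q * pop_freqs[pops[0]] + (1 - q) * pop_freqs[pops[1]]
        g = rng.binomial(2, f)
        miss = rng.random(n_loci) < missing_rate
        for j in range(n_loci):
            if miss[j]:
                calls[r, j] = None
            else:
                calls[r, j] = call(*(["A"] * (2 - g[j]) + ["G"] * g[j]))
    matrix = GenotypeMatrix(ind_ids, locus_ids, calls)
    truth = SimulationTruth(
        seed=seed, ancestral_freqs=p,
        pop_freqs={pn: f.copy() for pn, f in pop_freqs.items()},
        q=q_ser, outlier_loci=[locus_ids[j] for j in outliers],
        missing_rate=missing_rate, divergence_F=divergence_F,
        extras={"allele_counted": "G", "bn_concentration": c})
    return matrix, PopulationAssignment(assign), truth


# ---------------------------------------------------------------------------
# Microsatellites
# ---------------------------------------------------------------------------

def simulate_microsatellites(n_loci: int = 13,
                             alleles_per_locus: tuple[int, int] = (6, 10),
                             n_pops: int = 2, n_per_pop: int = 30,
                             divergence_F: float = 0.05,
                             seed: int = 0) -> tuple[GenotypeMatrix,
                                                      PopulationAssignment,
                                                      SimulationTruth]:
    """Multiallelic genotypes; allele ids resemble fragment sizes (step 2).

    Ancestral frequencies are symmetric-Dirichlet; each population's
    frequencies are Dirichlet-perturbed around them with concentration
    (1-c)/c (the multiallelic analogue of the Balding-Nichols draw).
    """
    lo, hi = alleles_per_locus
    if lo < 1:
        raise ConfigurationError("alleles_per_locus must be >= 1")
    rng = np.random.default_rng(seed)
    c = _bn_concentration(divergence_F)
    pops = [f"pop{i + 1}" for i in range(n_pops)]
    locus_ids = [f"ms{j:02d}" for j in range(n_loci)]
    allele_ids: list[list[str]] = []
    anc: list[np.ndarray] = []
    pop_f: dict[str, list[np.ndarray]] = {pn: [] for pn in pops}
    for j in range(n_loci):
        k = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(120, 240))
        allele_ids.append([str(start + 2 * t) for t in range(k)])
        base = rng.dirichlet([1.5] * k) if k > 1 else np.array([1.0])
        anc.append(base)
        for pn in pops:
            pop_f[pn].append(rng.dirichlet(base * (1 - c) / c)
                             if k > 1 else np.array([1.0]))
    ind_ids, assign = [], {}
    for pn in pops:
        for i in range(n_per_pop):
            iid = f"{pn}_ms{i:03d}"
            ind_ids.append(iid)
            assign[iid] = pn
    calls = np.empty((len(ind_ids), n_loci), dtype=object)
    for r, iid in enumerate(ind_ids):
        for j in range(n_loci):
            f = pop_f[assign[iid]][j]
            picks = rng.choice(len(f), size=2, p=f)
            calls[r, j] = call(allele_ids[j][picks[0]], allele_ids[j][picks[1]])
    matrix = GenotypeMatrix(ind_ids, locus_ids, calls,
                            {l: "microsatellite" for l in locus_ids})
    truth = SimulationTruth(seed=seed, divergence_F=divergence_F,
                            extras={"ancestral": anc, "pop_freqs": pop_f,
                                    "allele_ids": allele_ids})
    return matrix, PopulationAssignment(assign), truth


# ---------------------------------------------------------------------------
# Site network with isolation-by-distance
# ---------------------------------------------------------------------------

def simulate_site_network(n_sites: int = 8, river_length_m: float = 15000.0,
                          fst_intercept: float = 0.01,
                          fst_slope_per_m: float = 2e-6,
                          noise_sd: float = 0.008,
                          seed: int = 0) -> tuple[DistanceMatrix, DistanceMatrix,
                                                   SimulationTruth]:
    """Sites on a river line; pairwise Fst rises with riparian distance.

    Returns (riparian distances in meters, genetic Fst matrix, truth).
    Defaults give a mean Mantel r around 0.75, emulating a clearly
    detectable IBD pattern; set ``noise_sd=0`` for a perfect gradient.
    """
    if n_sites < 4:
        raise ConfigurationError("need at least 4 sites")
    rng = np.random.default_rng(seed)
    pos = np.sort(rng.uniform(0, river_length_m, n_sites))
    labels = [f"site{k + 1}" for k in range(n_sites)]
    d = np.abs(pos[:, None] - pos[None, :])
    eps = rng.normal(0, noise_sd, (n_sites, n_sites)) if noise_sd > 0 else \
        np.zeros((n_sites, n_sites))
    eps = (eps + eps.T) / 2
    fst = np.clip(fst_intercept + fst_slope_per_m * d + eps, 0.0, None)
    np.fill_diagonal(fst, 0.0)
    truth = SimulationTruth(seed=seed,
                            extras={"positions_m": pos,
                                    "slope": fst_slope_per_m,
                                    "intercept": fst_intercept,
                                    "noise_sd": noise_sd})
    return (DistanceMatrix(labels, d), DistanceMatrix(labels, fst), truth)


# ---------------------------------------------------------------------------
# Full-study bundle
# ---------------------------------------------------------------------------

@dataclass
class StudyBundle:
    """A small-river study in one object: genotypes, references, map, distances."""

    snps: GenotypeMatrix
    snp_populations: PopulationAssignment
    microsats: GenotypeMatrix
    linkage_map: LinkageMap
    riparian_distances: DistanceMatrix
    truth: SimulationTruth


def simulate_full_study(n_sites: int = 7, n_wild_per_site: int = 27,
                        n_hatchery: int = 30, n_snps: int = 92,
                        n_microsats: int = 13, divergence_F: float = 0.4,
                        admixed_fraction: float = 0.15,
                        missing_rate: float = 0.005,
                        seed: int = 0) -> StudyBundle:
    """Seven-site wild river plus a hatchery strain, SNPs and microsatellites.

    Wild individuals carry true hatchery ancestry q = 0 except for a
    planted ``admixed_fraction`` with q drawn from {0.25, 0.5, 0.75};
    hatchery individuals have q = 1.  Site structure on top of the
    wild/hatchery contrast is kept mild (demes share the wild pool).
    """
    rng = np.random.default_rng(seed)
    n_wild = n_sites * n_wild_per_site
    ids_q = []
    for i in range(n_wild):
        if rng.random() < admixed_fraction:
            ids_q.append(float(rng.choice([0.25, 0.5, 0.75])))
        else:
            ids_q.append(0.0)
    q = np.array([1.0] * n_hatchery + ids_q)  # pop1 = hatchery reference pool
    matrix, pops, truth = simulate_two_lineage_genotypes(
        n_pops=2, n_per_pop=max(n_hatchery, n_wild), n_loci=n_snps,
        divergence_F=divergence_F, seed=int(rng.integers(2**31)))
    # rebuild with explicit individuals: hatchery from pool 1, wild sites from pool 2
    f_h, f_w = truth.pop_freqs["pop1"], truth.pop_freqs["pop2"]
    locus_ids = matrix.locus_ids
    ind_ids, assign, qs = [], {}, {}
    for i in range(n_hatchery):
        iid = f"hatchery_{i:03d}"
        ind_ids.append(iid)
        assign[iid] = "hatchery"
        qs[iid] = 1.0
    for s in range(n_sites):
        for i in range(n_wild_per_site):
            iid = f"site{s + 1}_{i:03d}"
            ind_ids.append(iid)
            assign[iid] = f"site{s + 1}"
            qs[iid] = ids_q[s * n_wild_per_site + i]
    calls = np.empty((len(ind_ids), n_snps), dtype=object)
    for r, iid in enumerate(ind_ids):
        f = qs[iid] * f_h + (1 - qs[iid]) * f_w
        g = rng.binomial(2, f)
        miss = rng.random(n_snps) < missing_rate
        for j in range(n_snps):
            calls[r, j] = None if miss[j] else \
                call(*(["A"] * (2 - g[j]) + ["G"] * g[j]))
    snps = GenotypeMatrix(ind_ids, locus_ids, calls)
    snp_pops = PopulationAssignment(assign)

    ms, _, _ = simulate_microsatellites(
        n_loci=n_microsats, n_pops=1, n_per_pop=len(ind_ids),
        seed=int(rng.integers(2**31)))
    ms = GenotypeMatrix(ind_ids, ms.locus_ids,
                        ms.calls[:len(ind_ids)], ms.marker_class)
    lmap = simulate_linkage_map(seed=int(rng.integers(2**31)))
    geo, fstm, _ = simulate_site_network(n_sites=max(n_sites, 4),
                                         seed=int(rng.integers(2**31)))
    geo = DistanceMatrix([f"site{k + 1}" for k in range(len(geo.labels))],
                         geo.values)
    truth_full = SimulationTruth(
        seed=seed, pop_freqs={"hatchery": f_h, "wild": f_w},
        q=pd.Series(qs), missing_rate=missing_rate, divergence_F=divergence_F)
    return StudyBundle(snps, snp_pops, ms, lmap, geo, truth_full)
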