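"""Per-locus and per-population genetic statistics.

Conventions used throughout (standard for the downstream R packages this
workflow mirrors):

* frequencies come from non-missing gene copies; haploid mitochondrial
  calls contribute one copy per individual;
* He = 1 - sum_j p_j^2 (Nei's gene diversity), Ho = fraction of
  non-missing diploid calls that are heterozygous, Fis = 1 - Ho/He;
* multilocus He/Ho/Fis are means of per-locus values over polymorphic
  loci, while pairwise Fst = (Ht - Hs)/Ht uses ratio-of-sums across loci
  with Hs the sample-size-weighted mean within-population diversity and
  Ht the diversity of the pooled pair;
* allelic richness uses hypergeometric rarefaction to a fixed number of
  gene copies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    ConfigurationError,
    GenotypeMatrix,
    PopulationAssignment,
    RadPanelError,
    UndefinedValueError,
)


class SampleSizeError(RadPanelError):
    pass


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------

class AlleleFrequencyTable:
    """Locus x population allele frequencies with gene-copy sample sizes.

    ``freqs[locus][pop]`` maps allele -> relative frequency;
    ``copies[locus][pop]`` is the number of non-missing gene copies the
    frequencies were estimated from.  The pooled mean frequency of an
    allele is the unweighted mean of its per-population frequencies.
    """

    def __init__(self, freqs: dict[str, dict[str, dict[str, float]]],
                 copies: dict[str, dict[str, int]]) -> None:
        self.freqs = freqs
        self.copies = copies
        self.loci = list(freqs)
        first = next(iter(freqs.values()), {})
        self.populations = list(first)
        for locus, by_pop in freqs.items():
            for pop, f in by_pop.items():
                s = sum(f.values())
                if abs(s - 1.0) > 1e-9:
                    raise UndefinedValueError(
                        f"frequencies at ({locus}, {pop}) sum to {s}")

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    def alleles(self, locus: str) -> list[str]:
        seen: set[str] = set()
        for f in self.freqs[locus].values():
            seen.update(f)
        return sorted(seen)

    def frequency(self, locus: str, pop: str, allele: str) -> float:
        return self.freqs[locus][pop].get(allele, 0.0)

    def mean_frequency(self, locus: str, allele: str) -> float:
        """Unweighted mean of the allele's frequency across populations."""
        return sum(self.frequency(locus, p, allele)
                   for p in self.populations) / self.n_populations

    def subset(self, loci: Sequence[str]) -> "AlleleFrequencyTable":
        return AlleleFrequencyTable(
            {l: self.freqs[l] for l in loci},
            {l: self.copies[l] for l in loci})


def _copy_counts(calls: Sequence[tuple[str, str] | None],
                 haploid: bool) -> dict[str, int]:
    counts: dict[str, int] = {}
    for c in calls:
        if c is None:
            continue
        alleles = (c[0],) if haploid else c
        for a in alleles:
            counts[a] = counts.get(a, 0) + 1
    return counts


def allele_frequencies(matrix: GenotypeMatrix,
                       populations: PopulationAssignment,
                       loci: Sequence[str] | None = None) -> AlleleFrequencyTable:
    """Estimate per-population allele frequencies from non-missing copies."""
    populations.require_complete(matrix)
    loci = list(loci) if loci is not None else matrix.locus_ids
    pops = populations.populations()
    rows_by_pop = {p: [matrix._ind_index[i] for i in populations.members(p)
                       if i in matrix._ind_index] for p in pops}
    freqs: dict[str, dict[str, dict[str, float]]] = {}
    copies: dict[str, dict[str, int]] = {}
    for locus in loci:
        col = matrix.column(locus)
        hap = matrix.is_haploid(locus)
        freqs[locus] = {}
        copies[locus] = {}
        for p in pops:
            counts = _copy_counts([col[i] for i in rows_by_pop[p]], hap)
            total = sum(counts.values())
            if total == 0:
                raise UndefinedValueError(
                    f"no non-missing calls at locus {locus} in population {p}")
            freqs[locus][p] = {a: n / total for a, n in counts.items()}
            copies[locus][p] = total
    return AlleleFrequencyTable(freqs, copies)


# ---------------------------------------------------------------------------
# Heterozygosity and F-statistics
# ---------------------------------------------------------------------------

def expected_heterozygosity(freqs: Mapping[str, float]) -> float:
    """Nei's gene diversity He = 1 - sum p_j^2."""
    if not freqs:
        raise UndefinedValueError("no alleles: He undefined")
    return 1.0 - sum(p * p for p in freqs.values())


def observed_heterozygosity(calls: Sequence[tuple[str, str] | None]) -> float:
    """Fraction of non-missing diploid calls that are heterozygous."""
    non_missing = [c for c in calls if c is not None]
    if not non_missing:
        raise UndefinedValueError("all calls missing: Ho undefined")
    return sum(c[0] != c[1] for c in non_missing) / len(non_missing)


def fis(he: float, ho: float) -> float:
    """Fis = 1 - Ho/He; NaN when He = 0 (monomorphic)."""
    if he == 0:
        return math.nan
    return 1.0 - ho / he


def site_uniqueness_fst(he_site: float, he_total: float) -> float:
    """Site-level uniqueness Fst = 1 - He_site / He_total."""
    if he_total <= 0:
        raise UndefinedValueError("He_total must be positive")
    return 1.0 - he_site / he_total


def per_site_stats(matrix: GenotypeMatrix, populations: PopulationAssignment,
                   polymorphic_only: bool = True,
                   rarefaction_copies: int | None = None) -> pd.DataFrame:
    """Per-site summary table: N, Ho, He (multilocus means +/- SD), Fis, Fst, Ar.

    He/Ho/Fis are means of per-locus values over the analysed loci
    (polymorphic loci by default); the site Fst column is the uniqueness
    index 1 - mean He_site / mean He_total computed as a ratio of
    multilocus means, with He_total taken over all individuals pooled.
    """
    pops = populations.populations()
    loci = matrix.locus_ids
    if polymorphic_only:
        loci = [l for l in loci if len(matrix.alleles_at(l)) >= 2]
    diploid = [l for l in loci if not matrix.is_haploid(l)]
    total_freqs = allele_frequencies(
        matrix.subset(loci=loci),
        PopulationAssignment({i: "all" for i in matrix.individual_ids}))
    he_total = float(np.mean([expected_heterozygosity(total_freqs.freqs[l]["all"])
                              for l in loci]))
    if rarefaction_copies is None:
        rarefaction_copies = _min_copies(matrix, populations, diploid)
    rows = []
    for p in pops:
        members = populations.members(p)
        sub = matrix.subset(individuals=members, loci=loci)
        he = [expected_heterozygosity(
            {a: f for a, f in _norm(_copy_counts(sub.column(l), sub.is_haploid(l))).items()})
            for l in loci]
        ho = [observed_heterozygosity(sub.column(l)) for l in diploid]
        he_arr, ho_arr = np.array(he), np.array(ho)
        he_dip = [expected_heterozygosity(_norm(_copy_counts(sub.column(l), False)))
                  for l in diploid]
        fis_site = fis(float(np.mean(he_dip)), float(np.mean(ho_arr))) if diploid else math.nan
        ar = allelic_richness(sub, rarefaction_copies, loci=diploid) if diploid else math.nan
        rows.append({
            "site": p, "N": len(members),
            "Ho": float(np.mean(ho_arr)) if diploid else math.nan,
            "Ho_sd": float(np.std(ho_arr, ddof=1)) if len(ho_arr) > 1 else math.nan,
            "He": float(np.mean(he_arr)),
            "He_sd": float(np.std(he_arr, ddof=1)) if len(he_arr) > 1 else math.nan,
            "Fis": fis_site,
            "Fst": site_uniqueness_fst(float(np.mean(he_arr)), he_total),
            "Ar": ar,
        })
    return pd.DataFrame(rows)


def _norm(counts: dict[str, int]) -> dict[str, float]:
    total = sum(counts.values())
    if total == 0:
        raise UndefinedValueError("zero gene copies")
    return {a: n / total for a, n in counts.items()}


def _min_copies(matrix: GenotypeMatrix, populations: PopulationAssignment,
                loci: Sequence[str]) -> int:
    least = math.inf
    for p in populations.populations():
        sub = matrix.subset(individuals=populations.members(p), loci=loci)
        for l in loci:
            n = sum(v for v in _copy_counts(sub.column(l), sub.is_haploid(l)).values())
            least = min(least, n)
    return max(2, int(least))


def pairwise_fst(matrix: GenotypeMatrix, populations: PopulationAssignment,
                 pair: tuple[str, str],
                 loci: Sequence[str] | None = None) -> float:
    """Nei-style pairwise Fst = (Ht - Hs)/Ht, summed over loci before the ratio.

    Hs is the gene-copy-weighted mean within-population He; Ht the He of
    the two populations pooled.  Estimates may be slightly negative by
    sampling noise and are returned as computed.
    """
    a, b = pair
    loci = list(loci) if loci is not None else matrix.locus_ids
    members = populations.members(a) + populations.members(b)
    if not populations.members(a) or not populations.members(b):
        raise UndefinedValueError(f"empty population in pair {pair}")
    hs_sum = ht_sum = 0.0
    for locus in loci:
        hap = matrix.is_haploid(locus)
        col = matrix.column(locus)
        cnt = {}
        he = {}
        for p in (a, b):
            idx = [matrix._ind_index[i] for i in populations.members(p)]
            counts = _copy_counts([col[i] for i in idx], hap)
            n = sum(counts.values())
            if n == 0:
                continue
            cnt[p] = (counts, n)
            he[p] = expected_heterozygosity(_norm(counts))
        if len(cnt) < 2:
            continue
        n_a, n_b = cnt[a][1], cnt[b][1]
        hs = (n_a * he[a] + n_b * he[b]) / (n_a + n_b)
        pooled: dict[str, int] = {}
        for counts, _ in cnt.values():
            for al, c in counts.items():
                pooled[al] = pooled.get(al, 0) + c
        ht = expected_heterozygosity(_norm(pooled))
        hs_sum += hs
        ht_sum += ht
    if ht_sum == 0:
        raise UndefinedValueError(f"pair {pair} monomorphic at every locus")
    return (ht_sum - hs_sum) / ht_sum


def pairwise_fst_matrix(matrix: GenotypeMatrix,
                        populations: PopulationAssignment,
                        loci: Sequence[str] | None = None):
    """All pairwise Fst values as a DistanceMatrix-shaped symmetric array."""
    from .containers import DistanceMatrix

    pops = populations.populations()
    n = len(pops)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pairwise_fst(matrix, populations,
                                                 (pops[i], pops[j]), loci)
    # negative sampling-noise estimates would violate the distance
    # contract; clip only for the matrix container, keeping pair values raw
    return DistanceMatrix(pops, np.clip(out, 0.0, None))


# ---------------------------------------------------------------------------
# Allelic richness (rarefaction)
# ---------------------------------------------------------------------------

def rarefied_allele_count(counts: Mapping[str, int], n: int) -> float:
    """Expected allele count in a subsample of ``n`` gene copies.

    Ar = sum_j [1 - C(N - c_j, n)/C(N, n)] where c_j is allele j's copy
    count and N the total; the hypergeometric probability that allele j
    is absent from the subsample.
    """
    if n < 2:
        raise ConfigurationError("rarefaction needs n >= 2 gene copies")
    total = sum(counts.values())
    if n > total:
        raise SampleSizeError(f"rarefaction size {n} exceeds {total} copies")
    denom = math.comb(total, n)
    return sum(1.0 - math.comb(total - c, n) / denom for c in counts.values())


def allelic_richness(matrix: GenotypeMatrix, n: int,
                     loci: Sequence[str] | None = None) -> float:
    """Mean rarefied allele count over loci for one population's matrix."""
    loci = list(loci) if loci is not None else matrix.locus_ids
    vals = [rarefied_allele_count(
        _copy_counts(matrix.column(l), matrix.is_haploid(l)), n) for l in loci]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Genotyping QC
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    per_individual: pd.DataFrame  # individual_id, n_missing, prop_missing
    per_locus: pd.DataFrame       # locus_id, n_missing, prop_missing
    n_polymorphic: int
    summary: dict = field(default_factory=dict)


def genotyping_qc(matrix: GenotypeMatrix) -> QCReport:
    """Missingness per individual and per locus, plus polymorphic-locus count."""
    miss = matrix.missing_mask()
    n_i, n_l = matrix.calls.shape
    ind = pd.DataFrame({
        "individual_id": matrix.individual_ids,
        "n_missing": miss.sum(axis=1),
        "prop_missing": miss.sum(axis=1) / max(n_l, 1),
    })
    loc = pd.DataFrame({
        "locus_id": matrix.locus_ids,
        "n_missing": miss.sum(axis=0),
        "prop_missing": miss.sum(axis=0) / max(n_i, 1),
    })
    poly = sum(len(matrix.alleles_at(l)) >= 2 for l in matrix.locus_ids)
    counts = ind["n_missing"].to_numpy()
    summary = {
        "mean_missing_per_individual": float(counts.mean()) if n_i else math.nan,
        "sd_missing_per_individual": float(counts.std(ddof=1)) if n_i > 1 else math.nan,
        "min_missing_per_individual": int(counts.min()) if n_i else 0,
        "max_missing_per_individual": int(counts.max()) if n_i else 0,
    }
    return QCReport(ind, loc, poly, summary)


def drop_high_missing_individuals(matrix: GenotypeMatrix,
                                  max_fraction: float = 1 / 3) -> GenotypeMatrix:
    """Keep individuals whose missing fraction is <= ``max_fraction``."""
    if not 0 < max_fraction <= 1:
        raise ConfigurationError("max_fraction must lie in (0, 1]")
    qc = genotyping_qc(matrix)
    keep = qc.per_individual.loc[
        qc.per_individual["prop_missing"] <= max_fraction + 1e-12, "individual_id"]
    return matrix.subset(individuals=list(keep))


# ---------------------------------------------------------------------------
# Fst-vs-heterozygosity outlier scan
# ---------------------------------------------------------------------------

@dataclass
class OutlierScan:
    per_locus: pd.DataFrame      # locus_id, he, fst, flagged
    envelope: pd.DataFrame       # bin midpoints with lower/upper quantiles
    envelope_level: float
    n_bins: int

    @property
    def flagged(self) -> list[str]:
        return list(self.per_locus.loc[self.per_locus["flagged"], "locus_id"])


def _global_fst_per_locus(matrix, populations, locus) -> tuple[float, float] | None:
    """(total He, Nei Fst across all populations) for one locus, or None."""
    col = matrix.column(locus)
    hap = matrix.is_haploid(locus)
    hs_parts, weights = [], []
    pooled: dict[str, int] = {}
    for p in populations.populations():
        idx = [matrix._ind_index[i] for i in populations.members(p)]
        counts = _copy_counts([col[i] for i in idx], hap)
        n = sum(counts.values())
        if n == 0:
            continue
        hs_parts.append(expected_heterozygosity(_norm(counts)))
        weights.append(n)
        for a, c in counts.items():
            pooled[a] = pooled.get(a, 0) + c
    if not pooled or len(pooled) < 2:
        return None
    ht = expected_heterozygosity(_norm(pooled))
    hs = float(np.average(hs_parts, weights=weights))
    if ht == 0:
        return None
    return ht, (ht - hs) / ht


def fst_outlier_scan(matrix: GenotypeMatrix, populations: PopulationAssignment,
                     envelope: float = 0.95, n_bins: int = 10) -> OutlierScan:
    """Flag loci whose Fst falls outside a binned-quantile neutral envelope.

    Per-locus global Fst is plotted against total He; loci are split into
    ``n_bins`` equal-count He bins, empirical (1-envelope)/2 and
    1-(1-envelope)/2 Fst quantiles are taken per bin, and the envelope is
    linearly interpolated across bin midpoints.
    """
    rows = []
    for l in matrix.locus_ids:
        r = _global_fst_per_locus(matrix, populations, l)
        if r is not None:
            rows.append((l, r[0], r[1]))
    if len(rows) < 50:
        raise SampleSizeError(
            f"outlier scan needs >= 50 polymorphic loci, got {len(rows)}")
    df = pd.DataFrame(rows, columns=["locus_id", "he", "fst"])
    order = df["he"].rank(method="first").to_numpy() - 1
    bins = np.floor(order * n_bins / len(df)).astype(int)
    lo_q, hi_q = (1 - envelope) / 2, 1 - (1 - envelope) / 2
    mids, los, his = [], [], []
    for b in range(n_bins):
        sel = df.loc[bins == b]
        if sel.empty:
            continue
        mids.append(float(sel["he"].mean()))
        los.append(float(sel["fst"].quantile(lo_q)))
        his.append(float(sel["fst"].quantile(hi_q)))
    lower = np.interp(df["he"], mids, los)
    upper = np.interp(df["he"], mids, his)
    df["flagged"] = (df["fst"] < lower - 1e-12) | (df["fst"] > upper + 1e-12)
    env = pd.DataFrame({"he_mid": mids, "lower": los, "upper": his})
    return OutlierScan(df, env, envelope, n_bins)
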