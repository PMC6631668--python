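"""Panel-level performance analyses.

* Informativeness for assignment (In): an entropy-based measure of how
  much a marker set tells an assignment method about population origin.
  Per locus, with K populations, alleles j, per-population frequencies
  P_ij and unweighted mean frequency Pbar_j,

      In = sum_j ( -Pbar_j * ln(Pbar_j) + sum_i (P_ij / K) * ln(P_ij) )

  (0*ln 0 = 0; natural logarithm, so a locus fixed for opposite alleles
  in two populations scores ln 2).  Multi-locus In is the sum over loci,
  which makes the near-linear informativeness-vs-panel-size relation
  meaningful and supports marker-equivalence extrapolation.

* Mantel test for isolation-by-distance: Pearson correlation of the
  off-diagonal vectors of a pairwise-Fst matrix and a riparian-distance
  matrix, with a one-tailed permutation p-value.

* Supervised admixture: a deterministic maximum-likelihood hybrid-index
  estimator that stands in for MCMC clustering runs.  Given wild and
  captive reference allele frequencies, each individual's ancestry
  proportion q maximises a binomial likelihood over loci; individuals
  are classified wild / admixed / captive-bred by a strict q-threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    ConfigurationError,
    DistanceMatrix,
    GenotypeMatrix,
    PopulationAssignment,
    RadPanelError,
    ValidationError,
)
from .popgen import AlleleFrequencyTable, SampleSizeError, allele_frequencies


# ---------------------------------------------------------------------------
# Informativeness for assignment
# ---------------------------------------------------------------------------

def _xlnx(x: float) -> float:
    return 0.0 if x <= 0.0 else x * math.log(x)


def locus_informativeness(freqs_by_pop: Mapping[str, Mapping[str, float]]) -> float:
    """Single-locus In from a {population: {allele: frequency}} mapping."""
    pops = list(freqs_by_pop)
    k = len(pops)
    if k < 2:
        raise ConfigurationError("informativeness needs K >= 2 populations")
    alleles = sorted({a for f in freqs_by_pop.values() for a in f})
    total = 0.0
    for a in alleles:
        pbar = sum(freqs_by_pop[p].get(a, 0.0) for p in pops) / k
        total += -_xlnx(pbar) + sum(_xlnx(freqs_by_pop[p].get(a, 0.0)) / k
                                    for p in pops)
    return total


def informativeness_for_assignment(freqs: AlleleFrequencyTable,
                                   loci: Sequence[str] | None = None) -> float:
    """Multi-locus In: sum of single-locus values over the chosen loci."""
    if freqs.n_populations < 2:
        raise ConfigurationError("informativeness needs K >= 2 populations")
    loci = list(loci) if loci is not None else freqs.loci
    return sum(locus_informativeness(freqs.freqs[l]) for l in loci)


@dataclass
class InformativenessCurve:
    sizes: list[int]
    means: list[float]
    sds: list[float]
    replicates: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n_markers": self.sizes, "mean_In": self.means,
                             "sd_In": self.sds})


def informativeness_curve(matrix: GenotypeMatrix,
                          populations: PopulationAssignment,
                          sizes: Sequence[int], replicates: int = 100,
                          seed: int = 0,
                          loci: Sequence[str] | None = None) -> InformativenessCurve:
    """Mean In of random locus subsets of each size (polymorphic loci only)."""
    if loci is None:
        loci = [l for l in matrix.locus_ids if len(matrix.alleles_at(l)) >= 2]
    loci = list(loci)
    sizes = sorted(int(s) for s in sizes)
    if sizes and sizes[-1] > len(loci):
        raise SampleSizeError(
            f"subset size {sizes[-1]} exceeds {len(loci)} polymorphic loci")
    freqs = allele_frequencies(matrix, populations, loci=loci)
    per_locus = np.array([locus_informativeness(freqs.freqs[l]) for l in loci])
    rng = np.random.default_rng(seed)
    means, sds = [], []
    for m in sizes:
        if m == len(loci):
            vals = np.full(replicates, per_locus.sum())
        else:
            vals = np.array([
                per_locus[rng.choice(len(loci), size=m, replace=False)].sum()
                for _ in range(replicates)])
        means.append(float(vals.mean()))
        sds.append(float(vals.std(ddof=1)) if replicates > 1 else 0.0)
    return InformativenessCurve(sizes, means, sds, replicates, seed)


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float


def fit_informativeness_regression(curve: InformativenessCurve) -> RegressionFit:
    """Ordinary least squares of mean In on panel size: I = a*N + b."""
    if len(curve.sizes) < 3:
        raise SampleSizeError("regression needs >= 3 subset sizes")
    if len(set(curve.sizes)) == 1:
        raise ValidationError("all subset sizes identical; regression degenerate")
    res = stats.linregress(curve.sizes, curve.means)
    return RegressionFit(float(res.slope), float(res.intercept),
                         float(res.rvalue) ** 2)


def equivalent_marker_count(fit: RegressionFit,
                            target_informativeness: float) -> int:
    """Smallest integer N with slope*N + intercept >= target (extrapolation)."""
    if fit.slope <= 0:
        raise ConfigurationError("extrapolation needs a positive slope")
    n = math.ceil((target_informativeness - fit.intercept) / fit.slope - 1e-12)
    return max(n, 0)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    seed: int


def mantel_test(genetic: DistanceMatrix, geographic: DistanceMatrix,
                n_perm: int = 1000, seed: int = 0) -> MantelResult:
    """One-tailed Mantel test: is genetic distance correlated with geographic?

    r is the Pearson correlation of the off-diagonal vectors; the p-value
    is (1 + #{permuted r >= observed r}) / (n_perm + 1), permuting the
    site labels of one matrix.
    """
    if set(genetic.labels) != set(geographic.labels):
        raise ValidationError("matrices carry different site labels")
    if n_perm < 99:
        raise ConfigurationError("use at least 99 permutations")
    geo = geographic.reordered(genetic.labels)
    n = len(genetic.labels)
    iu = np.triu_indices(n, 1)
    x = genetic.values[iu]
    rng = np.random.default_rng(seed)
    r_obs = float(np.corrcoef(x, geo.values[iu])[0, 1])
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        y = geo.values[np.ix_(perm, perm)][iu]
        if np.corrcoef(x, y)[0, 1] >= r_obs - 1e-12:
            exceed += 1
    return MantelResult(r_obs, (1 + exceed) / (n_perm + 1), n_perm, seed)


# ---------------------------------------------------------------------------
# Supervised admixture (maximum-likelihood hybrid index)
# ---------------------------------------------------------------------------

@dataclass
class AdmixtureResult:
    q: pd.Series                 # per-individual captive-bred ancestry
    labels: pd.Series            # wild / admixed / captive-bred
    threshold: float
    n_loci_used: pd.Series
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"q_captive": self.q, "class": self.labels,
                             "n_loci": self.n_loci_used})


def classify_ancestry(q: float, threshold: float = 0.7) -> str:
    """Strict threshold rule: captive-bred iff q > t, wild iff 1-q > t, else admixed."""
    if math.isnan(q):
        return "missing"
    if q > threshold:
        return "captive-bred"
    if 1 - q > threshold:
        return "wild"
    return "admixed"


def _reference_frequencies(freqs: AlleleFrequencyTable, allele_of: dict[str, str],
                           floor: float | None) -> dict[str, float]:
    pop = freqs.populations[0]
    out = {}
    for locus, a in allele_of.items():
        if locus not in freqs.freqs:
            continue
        f = freqs.frequency(locus, pop, a)
        n = freqs.copies[locus][pop]
        eps = floor if floor is not None else 1.0 / (n + 1)
        out[locus] = min(max(f, eps), 1.0 - eps)
    return out


def supervised_admixture(matrix: GenotypeMatrix,
                         captive_freqs: AlleleFrequencyTable,
                         wild_freqs: AlleleFrequencyTable,
                         threshold: float = 0.7,
                         grid_points: int = 1001,
                         floor: float | None = None) -> AdmixtureResult:
    """Maximum-likelihood ancestry proportion toward the captive-bred pool.

    For each individual, q in [0, 1] maximises
    sum_loci log Binom(g | 2, q*f_captive + (1-q)*f_wild) where g counts
    the designated allele.  The maximisation is a deterministic dense
    grid search (default resolution 1e-3).  Reference frequencies are
    floored at 1/(2n+1) (n reference individuals) to avoid infinite
    log-likelihoods from alleles unseen in one reference.

    The classification rule is strict: captive-bred iff q > threshold,
    wild iff 1 - q > threshold, otherwise admixed.  This estimator is an
    explicit stand-in for Bayesian MCMC clustering (recorded in
    ``metadata``).
    """
    loci = [l for l in matrix.locus_ids
            if l in captive_freqs.freqs and l in wild_freqs.freqs
            and not matrix.is_haploid(l)]
    # the designated allele per locus: alphabetically first of the union
    allele_of = {}
    for l in loci:
        alleles = sorted(set(captive_freqs.alleles(l)) | set(wild_freqs.alleles(l)))
        if len(alleles) < 2:
            continue
        allele_of[l] = alleles[0]
    f_c = _reference_frequencies(captive_freqs, allele_of, floor)
    f_w = _reference_frequencies(wild_freqs, allele_of, floor)
    loci = [l for l in allele_of if l in f_c and l in f_w]

    qs = np.linspace(0.0, 1.0, grid_points)
    fc = np.array([f_c[l] for l in loci])
    fw = np.array([f_w[l] for l in loci])
    fq = qs[:, None] * fc[None, :] + (1 - qs)[:, None] * fw[None, :]  # grid x loci
    log_f, log_1mf = np.log(fq), np.log1p(-fq)

    q_hat, labels, n_used = {}, {}, {}
    for ind in matrix.individual_ids:
        row = matrix.calls[matrix._ind_index[ind]]
        g = np.full(len(loci), -1, dtype=int)
        for k, l in enumerate(loci):
            c = row[matrix._loc_index[l]]
            if c is not None:
                g[k] = (c[0] == allele_of[l]) + (c[1] == allele_of[l])
        use = g >= 0
        n_used[ind] = int(use.sum())
        if not use.any():
            q_hat[ind] = math.nan
            labels[ind] = "missing"
            continue
        ll = log_f[:, use] @ g[use] + log_1mf[:, use] @ (2 - g[use])
        q = float(qs[int(np.argmax(ll))])
        q_hat[ind] = q
        labels[ind] = classify_ancestry(q, threshold)
    idx = list(matrix.individual_ids)
    return AdmixtureResult(
        q=pd.Series(q_hat).reindex(idx),
        labels=pd.Series(labels).reindex(idx),
        threshold=threshold,
        n_loci_used=pd.Series(n_used).reindex(idx),
        metadata={
            "estimator": "supervised maximum-likelihood hybrid index",
            "note": ("deterministic grid-search ML stand-in for Bayesian "
                     "MCMC clustering; q is ancestry toward the captive "
                     "reference pool"),
            "grid_points": grid_points,
        })


def ancestry_concordance(q_a: pd.Series | Mapping[str, float],
                         q_b: pd.Series | Mapping[str, float]) -> tuple[float, float]:
    """Spearman rank correlation (rho, p) of two paired ancestry vectors."""
    a, b = pd.Series(q_a).dropna(), pd.Series(q_b).dropna()
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise SampleSizeError("concordance needs >= 3 paired individuals")
    rho, p = stats.spearmanr(a.loc[shared], b.loc[shared])
    return float(rho), float(p)
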