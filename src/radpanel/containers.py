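"""Core in-memory containers shared by every stage of the toolkit.

A genotype call is an unordered pair of allele identifiers (strings),
stored as a sorted 2-tuple, or ``None`` for missing.  The same shape is
used for biallelic SNPs, multiallelic microsatellites (allele sizes as
strings) and haploid mitochondrial markers (stored as a homozygous pair
but counted as a single gene copy downstream).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: sentinel for a missing genotype call
MISSING = None

#: IUPAC ambiguity codes -> the set of bases each covers
IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}

MARKER_CLASSES = ("snp", "microsatellite", "mitochondrial")


def call(a: str, b: str) -> tuple[str, str]:
    """Normalise an allele pair into the canonical (sorted) call tuple."""
    a, b = str(a), str(b)
    return (a, b) if a <= b else (b, a)


class RadPanelError(Exception):
    """Base class for toolkit errors."""


class InputError(RadPanelError):
    """A file could not be read or contained no usable records."""


class ValidationError(RadPanelError):
    """An object violates one of its structural invariants."""


class UndefinedValueError(RadPanelError):
    """A statistic is undefined for the given data (e.g. zero gene copies)."""


class ConfigurationError(RadPanelError):
    """A parameter combination is unusable."""


@dataclass
class RadTag:
    """One RAD locus: a reference sequence plus its within-tag SNPs.

    Offsets are 0-based positions into ``sequence``; ``snp_alleles`` holds
    one (ref, alt) base pair per offset.  Map information is optional —
    unmapped tags are removed by the mapping filter.
    """

    tag_id: str
    sequence: str
    snp_offsets: list[int] = field(default_factory=list)
    snp_alleles: list[tuple[str, str]] = field(default_factory=list)
    linkage_group: int | None = None
    position_cM: float | None = None
    local_recomb_rate: float | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        n = len(self.sequence)
        if len(self.snp_offsets) != len(self.snp_alleles):
            raise ValidationError(
                f"{self.tag_id}: {len(self.snp_offsets)} offsets vs "
                f"{len(self.snp_alleles)} allele pairs")
        last = -1
        for off, (ref, alt) in zip(self.snp_offsets, self.snp_alleles):
            if not 0 <= off < n:
                raise ValidationError(f"{self.tag_id}: offset {off} outside [0, {n})")
            if off <= last:
                raise ValidationError(f"{self.tag_id}: offsets not strictly increasing")
            last = off
            if ref == alt:
                raise ValidationError(f"{self.tag_id}: ref == alt ({ref}) at {off}")
            base = self.sequence[off]
            covered = IUPAC.get(base, set())
            if base != ref and not {ref, alt} <= covered:
                raise ValidationError(
                    f"{self.tag_id}: base {base!r} at {off} matches neither ref "
                    f"{ref!r} nor an ambiguity code covering {{ref, alt}}")
        if self.position_cM is not None and self.position_cM < 0:
            raise ValidationError(f"{self.tag_id}: negative cM position")

    @property
    def mapped(self) -> bool:
        return self.linkage_group is not None and self.position_cM is not None

    @property
    def n_snps(self) -> int:
        return len(self.snp_offsets)

    def snp_ids(self) -> list[str]:
        """Locus identifiers for the SNPs on this tag (``tagid:offset``)."""
        return [f"{self.tag_id}:{o}" for o in self.snp_offsets]


class GenotypeMatrix:
    """Individuals x loci matrix of unordered allele-pair calls.

    Calls live in a 2-D object array; ``None`` marks missing.  Marker
    classes distinguish diploid SNPs, microsatellites and haploid
    mitochondrial markers (stored homozygous, counted once).
    """

    def __init__(
        self,
        individual_ids: Sequence[str],
        locus_ids: Sequence[str],
        calls: np.ndarray | Sequence[Sequence[tuple | None]],
        marker_class: Mapping[str, str] | None = None,
    ) -> None:
        self.individual_ids = list(individual_ids)
        self.locus_ids = list(locus_ids)
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValidationError("duplicate individual ids")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValidationError("duplicate locus ids")
        arr = np.empty((len(self.individual_ids), len(self.locus_ids)), dtype=object)
        if isinstance(calls, np.ndarray) and calls.dtype == object and calls.shape == arr.shape:
            arr[:, :] = calls
        else:
            # element-wise fill: tuples must stay scalar cells, never a 3rd axis
            for i, row in enumerate(calls):
                row = list(row)
                if len(row) != arr.shape[1]:
                    raise ValidationError("ragged call rows")
                for j, c in enumerate(row):
                    arr[i, j] = None if c is None else call(*c)
        self.calls = arr
        self.marker_class = {l: "snp" for l in self.locus_ids}
        if marker_class:
            for l, c in marker_class.items():
                if c not in MARKER_CLASSES:
                    raise ValidationError(f"unknown marker class {c!r} for {l}")
                if l in self.marker_class:
                    self.marker_class[l] = c
        self._loc_index = {l: j for j, l in enumerate(self.locus_ids)}
        self._ind_index = {i: j for j, i in enumerate(self.individual_ids)}
        self._validate_mito()

    def _validate_mito(self) -> None:
        for l, cls in self.marker_class.items():
            if cls != "mitochondrial":
                continue
            col = self.calls[:, self._loc_index[l]]
            for c in col:
                if c is not None and c[0] != c[1]:
                    raise ValidationError(
                        f"mitochondrial locus {l} has a heterozygous call {c}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def locus_index(self, locus: str) -> int:
        return self._loc_index[locus]

    def column(self, locus: str) -> np.ndarray:
        return self.calls[:, self._loc_index[locus]]

    def is_haploid(self, locus: str) -> bool:
        return self.marker_class[locus] == "mitochondrial"

    def missing_mask(self) -> np.ndarray:
        return np.vectorize(lambda c: c is None, otypes=[bool])(self.calls) \
            if self.calls.size else np.zeros(self.calls.shape, dtype=bool)

    def alleles_at(self, locus: str) -> list[str]:
        """Sorted distinct alleles observed at a locus (haploid counted once)."""
        seen: set[str] = set()
        for c in self.column(locus):
            if c is not None:
                seen.update(c)
        return sorted(seen)

    def subset(self, individuals: Iterable[str] | None = None,
               loci: Iterable[str] | None = None) -> "GenotypeMatrix":
        inds = list(individuals) if individuals is not None else self.individual_ids
        locs = list(loci) if loci is not None else self.locus_ids
        ri = [self._ind_index[i] for i in inds]
        ci = [self._loc_index[l] for l in locs]
        sub = self.calls[np.ix_(ri, ci)] if ri and ci else np.empty((len(ri), len(ci)), dtype=object)
        return GenotypeMatrix(inds, locs, sub,
                              {l: self.marker_class[l] for l in locs})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (self.individual_ids == other.individual_ids
                and self.locus_ids == other.locus_ids
                and self.marker_class == other.marker_class
                and all((a is None and b is None) or a == b
                        for a, b in zip(self.calls.ravel(), other.calls.ravel())))


@dataclass
class LinkageMap:
    """Ordered cM positions per linkage group.

    ``groups`` maps a group label to the position-sorted ``(marker_id,
    position_cM)`` list; ``group_lengths`` (optional) carries the nominal
    length of each group, used by the simulators to place markers.
    """

    groups: dict[int, list[tuple[str, float]]]
    total_length_cM: float
    group_lengths: dict[int, float] | None = None

    def __post_init__(self) -> None:
        if self.total_length_cM <= 0:
            raise ValidationError("total map length must be positive")
        for g, entries in self.groups.items():
            pos = [p for _, p in entries]
            if any(p < 0 for p in pos):
                raise ValidationError(f"group {g}: negative cM position")
            if pos != sorted(pos):
                raise ValidationError(f"group {g}: positions not nondecreasing")
        maxpos = max((p for e in self.groups.values() for _, p in e), default=0.0)
        if self.total_length_cM + 1e-9 < maxpos:
            raise ValidationError("total_length_cM smaller than a marker position")
        self._positions = {m: (g, p) for g, e in self.groups.items() for m, p in e}

    def position_of(self, marker_id: str) -> tuple[int, float] | None:
        return self._positions.get(marker_id)

    @property
    def n_markers(self) -> int:
        return len(self._positions)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LinkageMap):
            return NotImplemented
        if set(self.groups) != set(other.groups):
            return False
        for g in self.groups:
            a, b = self.groups[g], other.groups[g]
            if len(a) != len(b):
                return False
            if any(m1 != m2 or abs(p1 - p2) > 1e-9
                   for (m1, p1), (m2, p2) in zip(a, b)):
                return False
        return abs(self.total_length_cM - other.total_length_cM) <= 1e-9


@dataclass
class PopulationAssignment:
    """individual id -> population label, with optional per-population lineage."""

    assignments: dict[str, str]
    lineages: dict[str, str] = field(default_factory=dict)

    def populations(self) -> list[str]:
        seen: list[str] = []
        for p in self.assignments.values():
            if p not in seen:
                seen.append(p)
        return seen

    def members(self, population: str) -> list[str]:
        return [i for i, p in self.assignments.items() if p == population]

    def require_complete(self, matrix: GenotypeMatrix) -> None:
        missing = [i for i in matrix.individual_ids if i not in self.assignments]
        if missing:
            raise ValidationError(
                f"{len(missing)} individuals lack a population label "
                f"(first: {missing[0]})")


class DistanceMatrix:
    """Symmetric nonnegative matrix of pairwise distances between sites."""

    def __init__(self, labels: Sequence[str], values: np.ndarray) -> None:
        self.labels = list(labels)
        v = np.asarray(values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("distance matrix shape does not match labels")
        if np.any(np.abs(np.diag(v)) > 1e-9):
            raise ValidationError("nonzero diagonal")
        if np.any(np.abs(v - v.T) > 1e-9):
            raise ValidationError("matrix not symmetric within 1e-9")
        self.values = (v + v.T) / 2.0

    def condensed(self) -> np.ndarray:
        """Upper-triangle (i<j) vector in row-major label order."""
        iu = np.triu_indices(len(self.labels), 1)
        return self.values[iu]

    def reordered(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DistanceMatrix):
            return NotImplemented
        return (self.labels == other.labels
                and np.allclose(self.values, other.values, atol=1e-9))


@dataclass
class FilterStep:
    name: str
    n_in: int
    n_out: int
    removed: list[str]


@dataclass
class FilterReport:
    """Ordered record of a filtering cascade; counts telescope."""

    steps: list[FilterStep] = field(default_factory=list)
    final_ids: list[str] = field(default_factory=list)

    def add(self, name: str, ids_in: Sequence[str], ids_out: Sequence[str]) -> None:
        removed = sorted(set(ids_in) - set(ids_out))
        if self.steps and self.steps[-1].n_out != len(ids_in):
            raise ValidationError("filter report counts do not telescope")
        self.steps.append(FilterStep(name, len(ids_in), len(ids_out), removed))
        self.final_ids = list(ids_out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.name, s.n_in, s.n_out, len(s.removed)) for s in self.steps],
            columns=["filter", "n_in", "n_out", "n_removed"])


@dataclass
class PanelSelection:
    """An ordered marker subset with spacing provenance.

    ``table`` has columns marker_id, linkage_group, position_cM (NaN for
    unmapped add-ons) and optionally maf; row order is (LG, cM, id) for
    mapped markers followed by add-ons in the order given.
    """

    table: pd.DataFrame
    min_spacing_cM: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.table["marker_id"].duplicated().any():
            raise ValidationError("duplicate marker ids in panel")

    @property
    def marker_ids(self) -> list[str]:
        return list(self.table["marker_id"])

    @property
    def size(self) -> int:
        return len(self.table)

    def per_lg_counts(self) -> dict[int, int]:
        mapped = self.table.dropna(subset=["linkage_group"])
        return {int(g): int(c) for g, c in
                mapped.groupby("linkage_group").size().items()}

    def check_spacing(self) -> list[tuple[str, str, float]]:
        """Return consecutive same-LG pairs closer than ``min_spacing_cM``."""
        bad = []
        mapped = self.table.dropna(subset=["linkage_group", "position_cM"])
        for _, grp in mapped.groupby("linkage_group"):
            grp = grp.sort_values(["position_cM", "marker_id"])
            ids = list(grp["marker_id"])
            pos = list(grp["position_cM"])
            for k in range(1, len(pos)):
                gap = pos[k] - pos[k - 1]
                if gap < self.min_spacing_cM - 1e-9:
                    bad.append((ids[k - 1], ids[k], gap))
        return bad
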