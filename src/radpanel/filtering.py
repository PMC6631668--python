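"""The candidate-locus filtering cascade.

Raw RAD/SNP sets are reduced to assay-ready candidates by four rules:
a minor-allele-frequency cut over all pooled individuals, a per-tag SNP
count limit, an edge window keeping SNPs away from the tag extremities,
exclusion of tags containing undetermined (N) bases, and a mapping
requirement.  A stricter primer-zone rule prepares tags for KASP-style
assay design (exactly one SNP, outside the two 50-bp primer zones).

Conventions: SNP offsets are 0-based; the "first or last ``edge_bp``"
windows are the offset sets {0..edge_bp-1} and {len-edge_bp..len-1}, so
offset ``edge_bp`` itself is allowed.  A locus is retained by the MAF
filter iff MAF >= threshold (boundary inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .containers import (
    ConfigurationError,
    FilterReport,
    GenotypeMatrix,
    RadTag,
    UndefinedValueError,
    ValidationError,
)


def minor_allele_frequency(calls: Sequence[tuple[str, str] | None],
                           haploid: bool = False) -> float:
    """MAF = min(p, 1-p) over non-missing gene copies at one locus.

    Haploid (mitochondrial) calls contribute one copy each.  Raises
    :class:`UndefinedValueError` when every call is missing.
    """
    counts: dict[str, int] = {}
    for c in calls:
        if c is None:
            continue
        if haploid:
            counts[c[0]] = counts.get(c[0], 0) + 1
        else:
            for a in c:
                counts[a] = counts.get(a, 0) + 1
    total = sum(counts.values())
    if total == 0:
        raise UndefinedValueError("all calls missing; MAF undefined")
    if len(counts) > 2:
        raise ValidationError("MAF defined for biallelic loci only")
    return 1.0 - max(counts.values()) / total


def filter_by_maf(matrix: GenotypeMatrix, threshold: float = 0.05) -> list[str]:
    """Locus ids retained at ``MAF >= threshold`` over pooled individuals.

    All-missing loci are removed (they carry no frequency information).
    """
    if not 0.0 <= threshold <= 0.5:
        raise ConfigurationError("MAF threshold must lie in [0, 0.5]")
    kept = []
    for locus in matrix.locus_ids:
        try:
            maf = minor_allele_frequency(matrix.column(locus),
                                         haploid=matrix.is_haploid(locus))
        except UndefinedValueError:
            continue
        if maf >= threshold:
            kept.append(locus)
    return kept


def _edge_ok(tag: RadTag, edge_bp: int) -> bool:
    n = len(tag.sequence)
    return all(edge_bp <= o < n - edge_bp for o in tag.snp_offsets)


def filter_rad_tags(tags: Iterable[RadTag], max_snps: int = 2, edge_bp: int = 30,
                    forbid_undetermined: bool = True, require_mapped: bool = True,
                    ) -> tuple[list[str], FilterReport]:
    """Apply the tag-level cleanliness filters; returns (kept ids, report).

    A tag survives iff it has at most ``max_snps`` SNPs, every SNP lies
    outside the first/last ``edge_bp`` bases, the sequence contains no N
    (when forbidden) and it carries a linkage-map position (when required).
    """
    tags = list(tags)
    for t in tags:
        if 2 * edge_bp >= len(t.sequence):
            raise ConfigurationError(
                f"edge windows (2x{edge_bp} bp) cover tag {t.tag_id} "
                f"({len(t.sequence)} bp) entirely")
    report = FilterReport()
    ids = [t.tag_id for t in tags]
    by_id = {t.tag_id: t for t in tags}

    step = [i for i in ids if by_id[i].n_snps <= max_snps]
    report.add(f"max_snps<={max_snps}", ids, step)
    prev, step = step, [i for i in step if _edge_ok(by_id[i], edge_bp)]
    report.add(f"edge>={edge_bp}bp", prev, step)
    if forbid_undetermined:
        prev, step = step, [i for i in step if "N" not in by_id[i].sequence]
        report.add("no_N", prev, step)
    if require_mapped:
        prev, step = step, [i for i in step if by_id[i].mapped]
        report.add("mapped", prev, step)
    return step, report


def filter_for_assay(tags: Iterable[RadTag], primer_zone_bp: int = 50) -> list[str]:
    """Tags ready for assay design: exactly one SNP, outside the primer zones."""
    kept = []
    for t in tags:
        if 2 * primer_zone_bp >= len(t.sequence):
            raise ConfigurationError(
                f"primer zones (2x{primer_zone_bp} bp) cover tag {t.tag_id} entirely")
        if t.n_snps == 1 and _edge_ok(t, primer_zone_bp):
            kept.append(t.tag_id)
    return kept


@dataclass
class FilterConfig:
    maf_threshold: float = 0.05
    max_snps: int = 2
    edge_bp: int = 30
    forbid_undetermined: bool = True
    require_mapped: bool = True
    assay: bool = False
    primer_zone_bp: int = 50


def run_filter_cascade(matrix: GenotypeMatrix, tags: Sequence[RadTag],
                       config: FilterConfig | None = None) -> FilterReport:
    """Run MAF then tag filters (then optionally the assay filter); SNP-level report.

    Locus ids must have the form ``tagid:offset`` so SNPs and tags can be
    cross-referenced.  The MAF step removes individual SNPs; surviving
    SNP counts per tag feed the ``max_snps`` rule, mirroring a workflow
    where the frequency cut runs upstream of the sequence checks.
    """
    config = config or FilterConfig()
    by_tag = {t.tag_id: t for t in tags}
    orphans = [l for l in matrix.locus_ids if l.rsplit(":", 1)[0] not in by_tag]
    if orphans:
        raise ValidationError(
            f"{len(orphans)} matrix loci lack a RAD tag (first: {orphans[0]})")

    report = FilterReport()
    loci = list(matrix.locus_ids)
    kept_maf = filter_by_maf(matrix, config.maf_threshold)
    kept_maf = [l for l in loci if l in set(kept_maf)]
    report.add(f"maf>={config.maf_threshold}", loci, kept_maf)

    # prune each tag to its surviving SNPs before the sequence-level rules
    pruned: list[RadTag] = []
    snps_by_tag: dict[str, list[str]] = {}
    for l in kept_maf:
        snps_by_tag.setdefault(l.rsplit(":", 1)[0], []).append(l)
    for tid, snp_ids in snps_by_tag.items():
        t = by_tag[tid]
        keep_offsets = {int(s.rsplit(":", 1)[1]) for s in snp_ids}
        sel = [k for k, o in enumerate(t.snp_offsets) if o in keep_offsets]
        pruned.append(RadTag(
            tag_id=t.tag_id, sequence=t.sequence,
            snp_offsets=[t.snp_offsets[k] for k in sel],
            snp_alleles=[t.snp_alleles[k] for k in sel],
            linkage_group=t.linkage_group, position_cM=t.position_cM,
            local_recomb_rate=t.local_recomb_rate))

    kept_ids, tag_report = filter_rad_tags(
        pruned, config.max_snps, config.edge_bp,
        config.forbid_undetermined, config.require_mapped)
    kept_set = set(kept_ids)
    # translate each tag-level step into SNP-level counts
    current = kept_maf
    surviving = {t.tag_id for t in pruned}
    for s in tag_report.steps:
        surviving -= set(s.removed)
        nxt = [l for l in current if l.rsplit(":", 1)[0] in surviving]
        report.add(s.name, current, nxt)
        current = nxt
    if config.assay:
        assay_tags = [t for t in pruned if t.tag_id in kept_set]
        assay_kept = set(filter_for_assay(assay_tags, config.primer_zone_bp))
        nxt = [l for l in current if l.rsplit(":", 1)[0] in assay_kept]
        report.add(f"assay_zone>={config.primer_zone_bp}bp", current, nxt)
    return report
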