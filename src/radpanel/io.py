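"""Readers and writers for every external format the toolkit touches.

VCF parsing is delegated to :mod:`cyvcf2`; FASTA to Biopython; delimited
tables to pandas.  All writers emit a header row and terminate lines with
``\\n`` so that write-then-read round-trips are exact.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import (
    MISSING,
    DistanceMatrix,
    GenotypeMatrix,
    InputError,
    LinkageMap,
    PanelSelection,
    PopulationAssignment,
    RadPanelError,
    RadTag,
    ValidationError,
    call,
)

log = logging.getLogger("radpanel")


class ExportError(RadPanelError):
    pass


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_variants(path: str | Path) -> tuple[GenotypeMatrix, dict[str, tuple[str, str]]]:
    """Read biallelic SNP records from a VCF into a GenotypeMatrix.

    Multiallelic and non-SNP records are skipped (count logged).  Missing
    genotypes map to the missing sentinel; phasing is discarded.  Returns
    the matrix plus a per-locus (ref, alt) table.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise InputError(f"cannot read VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    locus_ids: list[str] = []
    ref_alt: dict[str, tuple[str, str]] = {}
    columns: list[list[tuple[str, str] | None]] = []
    skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            skipped += 1
            continue
        lid = v.ID if v.ID not in (None, ".", "") else f"{v.CHROM}:{v.POS}"
        ref, alt = v.REF, v.ALT[0]
        col: list[tuple[str, str] | None] = []
        for g in v.genotypes:
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                col.append(MISSING)
            else:
                alleles = (ref, alt)
                col.append(call(alleles[a], alleles[b]))
        locus_ids.append(lid)
        ref_alt[lid] = (ref, alt)
        columns.append(col)
    if skipped:
        log.info("read_variants: skipped %d non-biallelic/non-SNP records", skipped)
    if not locus_ids:
        raise InputError(f"no usable biallelic SNP records in {path}")
    calls = np.empty((len(samples), len(locus_ids)), dtype=object)
    for j, col in enumerate(columns):
        for i, c in enumerate(col):
            calls[i, j] = c
    matrix = GenotypeMatrix(samples, locus_ids, calls)
    matrix.n_skipped_records = skipped  # type: ignore[attr-defined]
    return matrix, ref_alt


def write_variants(path: str | Path, matrix: GenotypeMatrix,
                   ref_alt: dict[str, tuple[str, str]],
                   contig: str = "1") -> None:
    """Write a GenotypeMatrix of biallelic SNPs as a minimal VCF 4.2 file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"##contig=<ID={contig}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.individual_ids) + "\n")
        for pos, locus in enumerate(matrix.locus_ids, start=1):
            ref, alt = ref_alt[locus]
            code = {call(ref, ref): "0/0", call(ref, alt): "0/1",
                    call(alt, alt): "1/1"}
            gts = []
            for c in matrix.column(locus):
                gts.append("./." if c is None else code[c])
            fh.write(f"{contig}\t{pos}\t{locus}\t{ref}\t{alt}\t.\t.\t.\tGT\t"
                     + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# Linkage map
# ---------------------------------------------------------------------------

_MAP_COLS = {"marker_id", "linkage_group", "position_cM"}


def read_linkage_map(path: str | Path, total_length_cM: float | None = None) -> LinkageMap:
    """Read a delimited linkage-map table (marker_id, linkage_group, position_cM).

    An optional ``recomb_rate`` column is kept; unknown columns are ignored
    with a warning.  Rows are position-sorted within each group.
    """
    df = _read_table(path)
    missing = _MAP_COLS - set(df.columns)
    if missing:
        raise InputError(f"linkage map missing columns: {sorted(missing)}")
    unknown = set(df.columns) - _MAP_COLS - {"recomb_rate"}
    if unknown:
        log.warning("read_linkage_map: ignoring columns %s", sorted(unknown))
    if df["marker_id"].duplicated().any():
        dup = df.loc[df["marker_id"].duplicated(), "marker_id"].iloc[0]
        raise ValidationError(f"duplicate marker id in map: {dup}")
    if (df["position_cM"] < 0).any():
        raise ValidationError("negative cM position in linkage map")
    groups: dict[int, list[tuple[str, float]]] = {}
    for g, grp in df.groupby("linkage_group"):
        grp = grp.sort_values(["position_cM", "marker_id"])
        groups[int(g)] = list(zip(grp["marker_id"], grp["position_cM"].astype(float)))
    maxpos = float(df["position_cM"].max()) if len(df) else 0.0
    total = total_length_cM if total_length_cM is not None else max(maxpos, 1e-9)
    return LinkageMap(groups=groups, total_length_cM=float(total))


def write_linkage_map(path: str | Path, lmap: LinkageMap) -> None:
    rows = [(m, g, p) for g in sorted(lmap.groups) for m, p in lmap.groups[g]]
    pd.DataFrame(rows, columns=["marker_id", "linkage_group", "position_cM"]) \
        .to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Population assignments & distance matrices
# ---------------------------------------------------------------------------

def read_populations(path: str | Path) -> PopulationAssignment:
    df = _read_table(path)
    if not {"individual_id", "population"} <= set(df.columns):
        raise InputError("population table needs individual_id and population columns")
    lineages = {}
    if "lineage" in df.columns:
        lineages = {str(r.population): str(r.lineage)
                    for r in df.itertuples() if not _isna(r.lineage)}
    return PopulationAssignment(
        assignments={str(r.individual_id): str(r.population) for r in df.itertuples()},
        lineages=lineages)


def write_populations(path: str | Path, pops: PopulationAssignment) -> None:
    rows = [(i, p, pops.lineages.get(p, "")) for i, p in pops.assignments.items()]
    pd.DataFrame(rows, columns=["individual_id", "population", "lineage"]) \
        .to_csv(path, index=False, lineterminator="\n")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    labels = [str(l) for l in df.index]
    if labels != [str(c) for c in df.columns]:
        raise InputError("distance matrix rows and columns disagree")
    return DistanceMatrix(labels, df.to_numpy(dtype=float))


def write_distance_matrix(path: str | Path, dm: DistanceMatrix) -> None:
    pd.DataFrame(dm.values, index=dm.labels, columns=dm.labels) \
        .to_csv(path, lineterminator="\n")


# ---------------------------------------------------------------------------
# Wide genotype tables (KASP result files, microsatellite allele sizes)
# ---------------------------------------------------------------------------

def read_genotype_table(path: str | Path, marker_class: str = "snp",
                        missing: str = "NA") -> GenotypeMatrix:
    """Read a wide genotype table into a GenotypeMatrix.

    Two dialects are accepted: two columns per locus (``L.1``/``L.2`` or
    ``L_1``/``L_2``) or one combined column per locus with ``A/B`` cells.
    Allele identifiers (microsatellite sizes included) become strings.
    """
    df = _read_table(path, dtype=str)
    first = df.columns[0]
    inds = [str(x) for x in df[first]]
    cols = list(df.columns[1:])
    combined = not any(c.endswith((".1", "_1")) for c in cols)
    loci: list[str] = []
    columns: list[list[tuple[str, str] | None]] = []
    if combined:
        for c in cols:
            loci.append(c)
            col = []
            for v in df[c]:
                if _isna(v) or str(v) == missing:
                    col.append(MISSING)
                    continue
                parts = str(v).split("/")
                if len(parts) != 2:
                    raise InputError(f"malformed call {v!r} at locus {c}")
                if missing in parts:
                    col.append(MISSING)
                else:
                    col.append(call(*parts))
            columns.append(col)
    else:
        if len(cols) % 2:
            raise InputError("two-column dialect needs an even number of allele columns")
        for k in range(0, len(cols), 2):
            c1, c2 = cols[k], cols[k + 1]
            base = c1[:-2]
            if c2[:-2] != base:
                raise InputError(f"allele columns {c1!r}/{c2!r} do not pair up")
            loci.append(base)
            col = []
            for a, b in zip(df[c1], df[c2]):
                if _isna(a) or _isna(b) or missing in (str(a), str(b)):
                    col.append(MISSING)
                else:
                    col.append(call(str(a), str(b)))
            columns.append(col)
    calls = np.empty((len(inds), len(loci)), dtype=object)
    for j, col in enumerate(columns):
        for i, c in enumerate(col):
            calls[i, j] = c
    return GenotypeMatrix(inds, loci, calls, {l: marker_class for l in loci})


def write_genotype_table(path: str | Path, matrix: GenotypeMatrix,
                         missing: str = "NA") -> None:
    """Write a GenotypeMatrix as a combined-column ("A/B") wide CSV."""
    data = {"individual_id": matrix.individual_ids}
    for locus in matrix.locus_ids:
        data[locus] = [missing if c is None else f"{c[0]}/{c[1]}"
                       for c in matrix.column(locus)]
    pd.DataFrame(data).to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# RAD tags (FASTA + offsets sidecar)
# ---------------------------------------------------------------------------

def write_rad_tags(fasta_path: str | Path, table_path: str | Path,
                   tags: list[RadTag]) -> None:
    """Write tag sequences as FASTA and SNP/map metadata as a CSV sidecar."""
    records = [SeqRecord(Seq(t.sequence), id=t.tag_id, description="") for t in tags]
    with open(fasta_path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    rows = []
    for t in tags:
        for off, (ref, alt) in zip(t.snp_offsets, t.snp_alleles):
            rows.append((t.tag_id, off, ref, alt,
                         "" if t.linkage_group is None else t.linkage_group,
                         "" if t.position_cM is None else t.position_cM,
                         "" if t.local_recomb_rate is None else t.local_recomb_rate))
    pd.DataFrame(rows, columns=["tag_id", "offset", "ref", "alt",
                                "linkage_group", "position_cM", "recomb_rate"]) \
        .to_csv(table_path, index=False, lineterminator="\n")


def read_rad_tags(fasta_path: str | Path, table_path: str | Path) -> list[RadTag]:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    df = _read_table(table_path, dtype={"tag_id": str, "ref": str, "alt": str})
    tags: list[RadTag] = []
    for tag_id, grp in df.groupby("tag_id", sort=False):
        if tag_id not in seqs:
            raise InputError(f"tag {tag_id} present in table but not FASTA")
        grp = grp.sort_values("offset")
        lg = grp["linkage_group"].iloc[0]
        pos = grp["position_cM"].iloc[0]
        rr = grp["recomb_rate"].iloc[0] if "recomb_rate" in grp else float("nan")
        tags.append(RadTag(
            tag_id=str(tag_id),
            sequence=seqs[tag_id],
            snp_offsets=[int(o) for o in grp["offset"]],
            snp_alleles=list(zip(grp["ref"], grp["alt"])),
            linkage_group=None if _isna(lg) else int(lg),
            position_cM=None if _isna(pos) else float(pos),
            local_recomb_rate=None if _isna(rr) else float(rr),
        ))
    # tags with no SNPs exist only in the FASTA
    for tid, seq in seqs.items():
        if tid not in set(df["tag_id"].astype(str)):
            tags.append(RadTag(tag_id=tid, sequence=seq))
    return tags


# ---------------------------------------------------------------------------
# Assay export (KASP-style flanking-sequence submission)
# ---------------------------------------------------------------------------

def write_panel_export(path: str | Path, panel: PanelSelection,
                       rads: list[RadTag], flank_bp: int = 50) -> pd.DataFrame:
    """Write the assay design file: one ``left[REF/ALT]right`` row per marker.

    Flanks are truncated at tag boundaries.  Rows are ordered by
    (linkage group, cM, marker id); unmapped markers sort last.  Each panel
    marker must resolve to a tag with exactly one target SNP.
    """
    by_snp: dict[str, tuple[RadTag, int]] = {}
    for t in rads:
        for k, off in enumerate(t.snp_offsets):
            by_snp[f"{t.tag_id}:{off}"] = (t, k)
        by_snp.setdefault(t.tag_id, (t, 0))
    rows = []
    for r in panel.table.itertuples():
        mid = r.marker_id
        if mid not in by_snp:
            raise ExportError(f"marker {mid} has no sequence context")
        tag, k = by_snp[mid]
        if tag.n_snps != 1 and ":" not in mid:
            raise ExportError(f"marker {mid}: tag has {tag.n_snps} SNPs, need exactly one")
        off = tag.snp_offsets[k]
        ref, alt = tag.snp_alleles[k]
        left = tag.sequence[max(0, off - flank_bp):off]
        right = tag.sequence[off + 1:off + 1 + flank_bp]
        lg = np.nan if r.linkage_group is None or _isna(r.linkage_group) else float(r.linkage_group)
        pos = np.nan if r.position_cM is None or _isna(r.position_cM) else float(r.position_cM)
        rows.append((mid, lg, pos, f"{left}[{ref}/{alt}]{right}"))
    df = pd.DataFrame(rows, columns=["marker_id", "linkage_group", "position_cM", "sequence"])
    df = df.sort_values(["linkage_group", "position_cM", "marker_id"],
                        na_position="last").reset_index(drop=True)
    out = df.copy()
    out["linkage_group"] = [("" if math.isnan(v) else str(int(v))) for v in df["linkage_group"]]
    out.to_csv(path, index=False, lineterminator="\n")
    return df


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a comma- or tab-delimited table, sniffing the separator."""
    try:
        return pd.read_csv(path, sep=None, engine="python", **kwargs)
    except FileNotFoundError:
        raise InputError(f"no such file: {path}") from None
    except Exception as exc:
        raise InputError(f"cannot parse table {path}: {exc}") from exc


def _isna(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and math.isnan(v):
        return True
    return isinstance(v, str) and v.strip() == ""
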