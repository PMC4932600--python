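"""Readers and writers for the external file formats, plus alignment filtering.

SAM/BAM and VCF go through pysam, GFF3 through gffutils, coverage tables
through pandas.  The coverage-table dialect is fixed: a ``#seq<TAB>pos<TAB>A
<TAB>C<TAB>G<TAB>T`` header line followed by one row per covered position,
1-based coordinates.
"""

from __future__ import annotations

import logging
import os
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import gffutils
import numpy as np
import pandas as pd
import pysam

from .types import (
    BASES,
    BASE_INDEX,
    AlignedFragment,
    CoverageTable,
    DiploidProfile,
    GeneInterval,
    GenomicPosition,
    HSPRecord,
    SBSRecord,
    SubgenomeCallTable,
)

logger = logging.getLogger(__name__)

# Single-character diploid codes (tab output) <-> VCF INFO tokens.
_DIP_TO_TOKEN = {"0": "0", "<": "LOW", "*": "AMB", "?": "MIS"}
_TOKEN_TO_DIP = {v: k for k, v in _DIP_TO_TOKEN.items()}


class VcfFormatError(ValueError):
    pass


def _first_gt(record: "pysam.VariantRecord") -> Optional[Tuple[Optional[int], ...]]:
    """GT of the first sample, or None when the VCF carries no genotype."""
    if not record.samples:
        return None
    sample = record.samples[next(iter(record.samples))]
    gt = sample.get("GT")
    if gt is None or all(a is None for a in gt):
        return None
    return gt


def _is_snv(record: "pysam.VariantRecord") -> bool:
    if record.ref is None or len(record.ref) != 1 or record.ref.upper() not in BASE_INDEX:
        return False
    alts = record.alts or ()
    if not alts:
        return False
    return all(len(a) == 1 and a.upper() in BASE_INDEX for a in alts)


def read_hsp_vcf(path: str, genotype_rule: bool = True) -> List[HSPRecord]:
    """Read candidate HSPs from a VCF (v4.0+).

    ``observed_bases`` is the set of ALT alleles; the REF base is added when
    ``genotype_rule`` is on and the genotype includes allele 0 (or no
    genotype is present).  Non-SNV rows are skipped with a count in the log.
    """
    records: List[HSPRecord] = []
    skipped = 0
    try:
        vcf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise VcfFormatError(f"{path}: not a parseable VCF: {exc}") from exc
    with vcf:
        for rec in vcf:
            if not _is_snv(rec):
                skipped += 1
                continue
            ref = rec.ref.upper()
            observed = {a.upper() for a in rec.alts}
            if genotype_rule:
                gt = _first_gt(rec)
                if gt is None or 0 in gt:
                    observed.add(ref)
            records.append(
                HSPRecord(GenomicPosition(rec.chrom, rec.pos), ref, observed)
            )
    if skipped:
        logger.info("%s: skipped %d non-SNV rows", path, skipped)
    return records


def read_sbs_vcf(path: str) -> List[SBSRecord]:
    """Read one diploid progenitor's single-base substitutions from a VCF.

    Only biallelic SNV rows with a homozygous-ALT (or absent) genotype are
    kept; heterozygous/ambiguous diploid calls are ignored.
    """
    records: List[SBSRecord] = []
    skipped = 0
    try:
        vcf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise VcfFormatError(f"{path}: not a parseable VCF: {exc}") from exc
    with vcf:
        for rec in vcf:
            if not _is_snv(rec) or len(rec.alts) != 1:
                skipped += 1
                continue
            gt = _first_gt(rec)
            if gt is not None and (0 in gt or len(set(a for a in gt if a is not None)) > 1):
                skipped += 1  # heterozygous / reference-bearing: not a clean substitution
                continue
            records.append(
                SBSRecord(
                    GenomicPosition(rec.chrom, rec.pos),
                    rec.ref.upper(),
                    rec.alts[0].upper(),
                )
            )
    if skipped:
        logger.info("%s: ignored %d non-SNV or heterozygous rows", path, skipped)
    return records


def read_gene_intervals(path: str) -> List[GeneInterval]:
    """Gene/contig intervals from a GFF3 file; only rows of type ``gene``."""
    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    out: List[GeneInterval] = []
    for feat in db.features_of_type("gene"):
        ids = feat.attributes.get("ID")
        if ids:
            gene_id = ids[0]
        else:
            gene_id = f"{feat.seqid}:{feat.start}-{feat.end}"
            logger.warning("gene row without ID attribute; using %s", gene_id)
        out.append(GeneInterval(gene_id, feat.seqid, feat.start, feat.end))
    out.sort(key=lambda g: (g.seq_name, g.start))
    return out


_COVERAGE_COLUMNS = ["seq", "pos", "A", "C", "G", "T"]


def read_coverage_table(path: str) -> CoverageTable:
    table = CoverageTable()
    try:
        df = pd.read_csv(path, sep="\t", comment="#", names=_COVERAGE_COLUMNS, dtype=str)
    except pd.errors.EmptyDataError:
        return table
    if df.empty:
        return table
    try:
        pos = df["pos"].astype(np.int64)
        counts = df[["A", "C", "G", "T"]].astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-integer position or count: {exc}") from exc
    if (counts.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative count")
    seen = set()
    for seq, p, row in zip(df["seq"], pos, counts.to_numpy()):
        key = GenomicPosition(seq, int(p))
        if key in seen:
            raise ValueError(f"{path}: duplicate position {seq}:{p}")
        seen.add(key)
        table.set_counts(key, row)
    return table


def write_coverage_table(table: CoverageTable, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#seq\tpos\tA\tC\tG\tT\n")
        for position in table.positions():
            c = table.counts(position)
            fh.write(
                f"{position.seq_name}\t{position.pos}\t{c['A']}\t{c['C']}\t{c['G']}\t{c['T']}\n"
            )


@dataclass
class GeneIndex:
    """Sorted interval lookup: position -> containing gene (intervals must
    not overlap within a sequence)."""

    genes: Sequence[GeneInterval]
    _by_seq: Dict[str, Tuple[List[int], List[GeneInterval]]] = field(init=False)

    def __post_init__(self) -> None:
        self._by_seq = {}
        by_seq: Dict[str, List[GeneInterval]] = {}
        for g in self.genes:
            by_seq.setdefault(g.seq_name, []).append(g)
        for seq, gs in by_seq.items():
            gs.sort(key=lambda g: g.start)
            for a, b in zip(gs, gs[1:]):
                if b.start <= a.end:
                    raise ValueError(f"overlapping gene intervals {a.gene_id}/{b.gene_id}")
            self._by_seq[seq] = ([g.start for g in gs], gs)

    def find(self, seq_name: str, pos: int) -> Optional[GeneInterval]:
        entry = self._by_seq.get(seq_name)
        if entry is None:
            return None
        starts, gs = entry
        i = bisect_right(starts, pos) - 1
        if i >= 0 and pos <= gs[i].end:
            return gs[i]
        return None


@dataclass
class FilterStats:
    reads_seen: int = 0
    dropped_unmapped: int = 0
    dropped_mapq: int = 0
    dropped_no_gene: int = 0
    dropped_orphan: int = 0
    dropped_cross_gene: int = 0
    fragments_out: int = 0


def _read_bases(read: "pysam.AlignedSegment", quality_min: int) -> Dict[int, str]:
    """Reference position (1-based) -> base for one aligned read, per CIGAR.

    Insertions contribute nothing; deletions/skips leave positions uncovered;
    non-ACGT query bases contribute nothing.
    """
    seq = read.query_sequence
    if seq is None:
        return {}
    quals = read.query_qualities
    out: Dict[int, str] = {}
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        base = seq[qpos].upper()
        if base not in BASE_INDEX:
            continue
        if quality_min > 0 and quals is not None and quals[qpos] < quality_min:
            continue
        out[rpos + 1] = base
    return out


def _fuse_mates(bases1: Dict[int, str], bases2: Dict[int, str]) -> Dict[int, str]:
    """Union of the two mates' bases; disagreeing overlap positions dropped."""
    fused = dict(bases1)
    for pos, base in bases2.items():
        other = fused.get(pos)
        if other is None:
            fused[pos] = base
        elif other != base:
            fused[pos] = None  # mark conflict
    return {p: b for p, b in fused.items() if b is not None}


def filter_alignments(
    alignments: "str | pysam.AlignmentFile",
    genes: Sequence[GeneInterval],
    mapq_min: int = 20,
    base_quality_min: int = 0,
    stats: Optional[FilterStats] = None,
) -> Iterator[AlignedFragment]:
    """Stream filtered fragments from a position-sorted SAM/BAM.

    Filters: reads with MAPQ <= ``mapq_min``; reads overlapping no gene
    interval; for paired data, orphans (mate unmapped or absent) and pairs
    whose mates fall in different genes.  Surviving mates are fused into one
    fragment covering both reads' aligned positions.
    """
    if stats is None:
        stats = FilterStats()
    index = GeneIndex(genes)
    opened = isinstance(alignments, str)
    af = pysam.AlignmentFile(alignments, check_sq=False) if opened else alignments

    # qname -> (gene, bases) awaiting the mate
    pending: Dict[str, Tuple[GeneInterval, Dict[int, str], int]] = {}
    try:
        for read in af:
            if read.is_secondary or read.is_supplementary:
                continue
            stats.reads_seen += 1
            if read.is_unmapped:
                stats.dropped_unmapped += 1
                continue
            if read.mapping_quality <= mapq_min:
                stats.dropped_mapq += 1
                continue
            gene = index.find(read.reference_name, read.reference_start + 1)
            if gene is None:
                gene = index.find(read.reference_name, read.reference_end or 0)
            if gene is None or gene.seq_name != read.reference_name:
                stats.dropped_no_gene += 1
                continue
            bases = {
                p: b for p, b in _read_bases(read, base_quality_min).items() if p in gene
            }
            if not read.is_paired:
                stats.fragments_out += 1
                yield AlignedFragment.from_bases(
                    read.query_name, gene.gene_id, gene.seq_name, bases, read.mapping_quality
                )
                continue
            if read.mate_is_unmapped:
                stats.dropped_orphan += 1
                continue
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = (gene, bases, read.mapping_quality)
                continue
            mate_gene, mate_bases, mate_mapq = mate
            if mate_gene.gene_id != gene.gene_id:
                stats.dropped_cross_gene += 2
                continue
            stats.fragments_out += 1
            yield AlignedFragment.from_bases(
                read.query_name,
                gene.gene_id,
                gene.seq_name,
                _fuse_mates(mate_bases, bases),
                min(mate_mapq, read.mapping_quality),
            )
        # mates never seen (filtered away or missing): orphans
        stats.dropped_orphan += len(pending)
    finally:
        if opened:
            af.close()


def _build_vcf_header(
    subgenome: str, contig_lengths: Mapping[str, int]
) -> "pysam.VariantHeader":
    header = pysam.VariantHeader()
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    header.info.add("AB", 1, "String", "Assigned subgenome base (. when unassigned)")
    header.info.add("FC", 1, "String", "Position fully characterized across subgenomes (yes/no)")
    header.info.add(
        "DIP", 1, "String",
        "Diploid progenitor state: base, 0=no coverage, LOW=low coverage, "
        "AMB=ambiguous/heterozygous, MIS=missing diploid",
    )
    header.add_meta("source", f"homeocall subgenome={subgenome}")
    return header


def write_outputs(
    calls: SubgenomeCallTable,
    profiles: Mapping[str, DiploidProfile],
    contig_lengths: Mapping[str, int],
    out_dir: str,
    fmt: str = "both",
    header: bool = False,
) -> Dict[str, List[str]]:
    """Write one VCF and/or tab file per subgenome.

    Every position where at least one subgenome has an assigned base is
    reported in every subgenome's file; the assigned-base column is '.' for
    a subgenome without a call there.  Returns the written paths keyed by
    subgenome label.
    """
    if fmt not in ("vcf", "tab", "both"):
        raise ValueError(f"unknown output format {fmt!r}")
    os.makedirs(out_dir, exist_ok=True)
    reported = calls.reported_positions()
    written: Dict[str, List[str]] = {s: [] for s in calls.subgenomes}
    for sub in calls.subgenomes:
        profile = profiles[sub]
        if fmt in ("tab", "both"):
            path = os.path.join(out_dir, f"{sub}.tab")
            with open(path, "w") as fh:
                if header:
                    fh.write("#seq\tpos\tref\tdiploid\tassigned\tfully_characterized\n")
                for position in reported:
                    row = calls[position]
                    assigned = row.calls[sub] or "."
                    fc = "yes" if row.fully_characterized() else "no"
                    fh.write(
                        f"{position.seq_name}\t{position.pos}\t{row.ref_base}\t"
                        f"{profile.state(position)}\t{assigned}\t{fc}\n"
                    )
            written[sub].append(path)
        if fmt in ("vcf", "both"):
            path = os.path.join(out_dir, f"{sub}.vcf")
            vcf_header = _build_vcf_header(sub, contig_lengths)
            with pysam.VariantFile(path, "w", header=vcf_header) as vf:
                for position in reported:
                    row = calls[position]
                    assigned = row.calls[sub]
                    rec = vf.new_record(
                        contig=position.seq_name,
                        start=position.pos - 1,
                        stop=position.pos,
                        alleles=(
                            (row.ref_base, assigned)
                            if assigned is not None and assigned != row.ref_base
                            else (row.ref_base, ".")
                        ),
                    )
                    rec.info["AB"] = assigned or "."
                    rec.info["FC"] = "yes" if row.fully_characterized() else "no"
                    state = profile.state(position)
                    rec.info["DIP"] = _DIP_TO_TOKEN.get(state, state)
                    vf.write(rec)
            written[sub].append(path)
    return written


def read_subgenome_tabs(paths: Mapping[str, str]) -> SubgenomeCallTable:
    """Rebuild a call table from per-subgenome tab files (inverse of
    ``write_outputs`` for the tab-recoverable content)."""
    subgenomes = tuple(paths)
    table = SubgenomeCallTable(subgenomes)
    for sub, path in paths.items():
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                seq, pos_s, ref, _dip, assigned, _fc = line.rstrip("\n").split("\t")
                position = GenomicPosition(seq, int(pos_s))
                if position not in table:
                    table.add_position(position, ref, set(BASES))
                if assigned != ".":
                    table.assign(position, sub, assigned)
    return table
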