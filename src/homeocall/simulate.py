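"""Deterministic allopolyploid transcriptome simulator with known truth.

The generative model mirrors how homeolog-specific polymorphisms arise: an
ancestral transcriptome (one sequence per gene, uniform ACGT) is copied
once per subgenome, and every site of every subgenome copy mutates
independently with probability ``hsp_rate`` to a uniformly chosen different
base.  A site where the resulting subgenome bases are not all identical is
a true HSP.  Each extant diploid progenitor is a further copy of its
subgenome with per-site divergence ``diploid_divergence``.  Reads (paired
or single-end) are sampled uniformly within genes at the requested
per-subgenome coverage, with an independent per-base sequencing error.

Reads are emitted as a position-sorted SAM at their true coordinates on the
concatenated reference, so the pipeline's own alignment reader and filters
are exercised without an external aligner.  The HSP and SBS input VCFs are
derived from the simulated pileups with naive threshold rules — not copied
from truth — so validation and discovery run on realistic, slightly noisy
candidate lists.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pysam

from .coverage import compute_base_coverage
from .io import write_coverage_table
from .reference import ReferenceBuild, build_reference, write_reference
from .types import (
    BASES,
    AlignedFragment,
    CoverageTable,
    GenomicPosition,
    SBSRecord,
)

_CODE_TO_BASE = np.array(list(BASES))


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    Defaults reflect a typical plant RNA-seq experiment: 1 kb transcripts,
    2x100 bp pairs with a 300+-30 bp insert, 30x coverage per subgenome,
    0.2% base error, ~1% per-subgenome divergence from the ancestor and
    0.3% diploid-vs-subgenome divergence.
    """

    n_genes: int = 50
    gene_length: int = 1000
    n_subgenomes: int = 2
    hsp_rate: float = 0.01
    diploid_divergence: float = 0.003
    read_length: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    coverage: float = 30.0
    base_error_rate: float = 0.002
    paired: bool = True
    seed: int = 0
    gap_length: int = 200

    def __post_init__(self) -> None:
        for name in ("hsp_rate", "diploid_divergence", "base_error_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not 2 <= self.n_subgenomes <= 10:
            raise ValueError("n_subgenomes must be between 2 and 10")
        if self.gene_length < 2 * self.read_length:
            raise ValueError("gene_length must hold at least one read pair")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    @property
    def labels(self) -> List[str]:
        return [f"D{i + 1}" for i in range(self.n_subgenomes)]


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    subgenome_sequences: Dict[str, List[str]]  # label -> per-gene sequence
    hsp_bases: Dict[GenomicPosition, Dict[str, str]]  # true HSPs only
    diploid_sbs: Dict[str, List[SBSRecord]]

    def accuracy_map(self) -> Dict[Tuple[GenomicPosition, str], str]:
        """Truth in the shape the accuracy evaluator consumes."""
        return {
            (position, label): base
            for position, per in self.hsp_bases.items()
            for label, base in per.items()
        }


@dataclass
class SimResult:
    reference: ReferenceBuild
    truth: SimTruth
    paths: Dict[str, str] = field(default_factory=dict)  # file role -> path
    sbs_paths: Dict[str, str] = field(default_factory=dict)  # label -> SBS VCF
    diploid_coverage_paths: Dict[str, str] = field(default_factory=dict)


@dataclass
class _Read:
    name: str
    start0: int  # 0-based global reference start
    seq: str
    paired: bool
    first: bool
    mate_start0: int
    insert: int  # signed template length


def _mutate(rng: np.random.Generator, codes: np.ndarray, rate: float) -> np.ndarray:
    """Mutate each site with the given probability to a distinct base."""
    out = codes.copy()
    if rate > 0:
        mask = rng.random(codes.shape) < rate
        shift = rng.integers(1, 4, size=int(mask.sum()))
        out[mask] = (out[mask] + shift) % 4
    return out


def _apply_errors(rng: np.random.Generator, codes: np.ndarray, rate: float) -> np.ndarray:
    return _mutate(rng, codes, rate)


def simulate_allopolyploid(cfg: SimConfig, out_dir: str) -> SimResult:
    """Generate the full input file set plus truth tables under ``out_dir``.

    Emits: reference FASTA + GFF3, position-sorted polyploid SAM, polyploid
    HSP VCF, one SBS VCF and one coverage table per diploid, the polyploid
    coverage table, and a truth TSV.  Byte-identical for identical configs.
    """
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    labels = cfg.labels

    ancestral = [
        rng.integers(0, 4, size=cfg.gene_length).astype(np.int8)
        for _ in range(cfg.n_genes)
    ]
    subgenomes = {
        label: [_mutate(rng, gene, cfg.hsp_rate) for gene in ancestral] for label in labels
    }
    diploids = {
        label: [_mutate(rng, gene, cfg.diploid_divergence) for gene in subgenomes[label]]
        for label in labels
    }

    ref = build_reference(
        [(f"g{i + 1}", _codes_to_str(gene)) for i, gene in enumerate(ancestral)],
        gap_length=cfg.gap_length,
    )
    ref_name = ref.name

    truth = _build_truth(cfg, ref_name, ref, ancestral, subgenomes, diploids)

    # --- polyploid reads (all subgenomes pooled), written as SAM ---
    poly_reads: List[_Read] = []
    poly_fragments: List[AlignedFragment] = []
    for label in labels:
        _sample_reads(
            rng, cfg, label, subgenomes[label], ref, poly_reads, poly_fragments
        )
    poly_cov = compute_base_coverage(poly_fragments)

    # --- diploid reads: only their derived products are kept ---
    dip_cov: Dict[str, CoverageTable] = {}
    for label in labels:
        dip_fragments: List[AlignedFragment] = []
        _sample_reads(rng, cfg, label, diploids[label], ref, [], dip_fragments)
        dip_cov[label] = compute_base_coverage(dip_fragments)

    result = SimResult(reference=ref, truth=truth)
    fasta, gff = write_reference(ref, os.path.join(out_dir, "reference"))
    result.paths["fasta"] = fasta
    result.paths["gff"] = gff

    sam_path = os.path.join(out_dir, "polyploid.sam")
    _write_sam(sam_path, ref_name, len(ref.sequence), poly_reads, cfg.paired)
    result.paths["sam"] = sam_path

    poly_cov_path = os.path.join(out_dir, "polyploid_coverage.tsv")
    write_coverage_table(poly_cov, poly_cov_path)
    result.paths["polyploid_coverage"] = poly_cov_path

    hsp_path = os.path.join(out_dir, "polyploid_hsps.vcf")
    _write_hsp_vcf(hsp_path, ref, poly_cov, min_total=3, min_frac=0.05)
    result.paths["hsp_vcf"] = hsp_path

    for label in labels:
        cov_path = os.path.join(out_dir, f"{label}_coverage.tsv")
        write_coverage_table(dip_cov[label], cov_path)
        result.diploid_coverage_paths[label] = cov_path
        sbs_path = os.path.join(out_dir, f"{label}_sbs.vcf")
        _write_sbs_vcf(sbs_path, ref, dip_cov[label], min_total=3, min_major=0.8)
        result.sbs_paths[label] = sbs_path

    truth_path = os.path.join(out_dir, "truth_hsps.tsv")
    with open(truth_path, "w") as fh:
        fh.write("#seq\tpos\tref\t" + "\t".join(labels) + "\n")
        for position in sorted(truth.hsp_bases):
            per = truth.hsp_bases[position]
            ref_base = ref.sequence[position.pos - 1]
            fh.write(
                f"{position.seq_name}\t{position.pos}\t{ref_base}\t"
                + "\t".join(per[label] for label in labels)
                + "\n"
            )
    result.paths["truth"] = truth_path
    return result


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(_CODE_TO_BASE[codes])


def _build_truth(
    cfg: SimConfig,
    ref_name: str,
    ref: ReferenceBuild,
    ancestral: Sequence[np.ndarray],
    subgenomes: Dict[str, List[np.ndarray]],
    diploids: Dict[str, List[np.ndarray]],
) -> SimTruth:
    labels = cfg.labels
    hsp_bases: Dict[GenomicPosition, Dict[str, str]] = {}
    diploid_sbs: Dict[str, List[SBSRecord]] = {label: [] for label in labels}
    for gi, gene in enumerate(ancestral):
        offset = ref.genes[gi].start  # 1-based start of the gene
        stack = np.stack([subgenomes[label][gi] for label in labels])
        hsp_sites = np.where((stack != stack[0]).any(axis=0))[0]
        for site in hsp_sites.tolist():
            position = GenomicPosition(ref_name, offset + site)
            hsp_bases[position] = {
                label: BASES[int(stack[k, site])] for k, label in enumerate(labels)
            }
        for label in labels:
            dip = diploids[label][gi]
            sbs_sites = np.where(dip != gene)[0]
            for site in sbs_sites.tolist():
                diploid_sbs[label].append(
                    SBSRecord(
                        GenomicPosition(ref_name, offset + site),
                        BASES[int(gene[site])],
                        BASES[int(dip[site])],
                    )
                )
    sequences = {
        label: [_codes_to_str(g) for g in subgenomes[label]] for label in labels
    }
    return SimTruth(sequences, hsp_bases, diploid_sbs)


def _sample_reads(
    rng: np.random.Generator,
    cfg: SimConfig,
    label: str,
    gene_seqs: Sequence[np.ndarray],
    ref: ReferenceBuild,
    reads_out: List[_Read],
    fragments_out: List[AlignedFragment],
) -> None:
    """Sample reads for one genome copy; append SAM-ready reads and fused
    fragments (positions with conflicting mate bases dropped)."""
    R = cfg.read_length
    L = cfg.gene_length
    n_per_gene = max(1, int(round(cfg.coverage * L / (2 * R if cfg.paired else R))))
    for gi, codes in enumerate(gene_seqs):
        offset0 = ref.genes[gi].start - 1  # 0-based global offset of the gene
        for k in range(n_per_gene):
            name = f"{label}_g{gi + 1}_{k}"
            if cfg.paired:
                insert = int(np.clip(rng.normal(cfg.insert_mean, cfg.insert_sd), R, L))
                start = int(rng.integers(0, L - insert + 1))
                s2 = start + insert - R
                r1 = _apply_errors(rng, codes[start : start + R], cfg.base_error_rate)
                r2 = _apply_errors(rng, codes[s2 : s2 + R], cfg.base_error_rate)
                reads_out.append(
                    _Read(name, offset0 + start, _codes_to_str(r1), True, True, offset0 + s2, insert)
                )
                reads_out.append(
                    _Read(name, offset0 + s2, _codes_to_str(r2), True, False, offset0 + start, -insert)
                )
                fragments_out.append(
                    _fuse_pair(name, f"g{gi + 1}", ref.name, offset0, start, r1, s2, r2)
                )
            else:
                start = int(rng.integers(0, L - R + 1))
                r1 = _apply_errors(rng, codes[start : start + R], cfg.base_error_rate)
                reads_out.append(
                    _Read(name, offset0 + start, _codes_to_str(r1), False, True, 0, 0)
                )
                positions = np.arange(offset0 + start + 1, offset0 + start + R + 1)
                fragments_out.append(
                    AlignedFragment(name, f"g{gi + 1}", ref.name, positions, r1.astype(np.uint8), 60)
                )


def _fuse_pair(
    name: str,
    gene_id: str,
    seq_name: str,
    offset0: int,
    start1: int,
    codes1: np.ndarray,
    start2: int,
    codes2: np.ndarray,
) -> AlignedFragment:
    R = len(codes1)
    pos1 = np.arange(start1, start1 + R)
    pos2 = np.arange(start2, start2 + R)
    all_pos = np.concatenate([pos1, pos2])
    all_codes = np.concatenate([codes1, codes2])
    order = np.argsort(all_pos, kind="stable")
    p = all_pos[order]
    c = all_codes[order]
    # collapse mate-overlap duplicates: agreeing -> one entry, disagreeing -> dropped
    n = len(p)
    dup_next = np.zeros(n, dtype=bool)
    dup_next[:-1] = p[1:] == p[:-1]
    dup_prev = np.zeros(n, dtype=bool)
    dup_prev[1:] = dup_next[:-1]
    eq_next = np.zeros(n, dtype=bool)
    eq_next[:-1] = dup_next[:-1] & (c[1:] == c[:-1])
    keep = ~dup_prev & (~dup_next | eq_next)
    positions = (p[keep] + offset0 + 1).astype(np.int64)
    return AlignedFragment(name, gene_id, seq_name, positions, c[keep].astype(np.uint8), 60)


def _write_sam(
    path: str, ref_name: str, ref_length: int, reads: List[_Read], paired: bool
) -> None:
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": ref_name, "LN": ref_length}],
        }
    )
    reads = sorted(reads, key=lambda r: (r.start0, r.name, not r.first))
    with pysam.AlignmentFile(path, "w", header=header) as sam:
        for read in reads:
            seg = pysam.AlignedSegment(header)
            seg.query_name = read.name
            seg.query_sequence = read.seq
            seg.reference_id = 0
            seg.reference_start = read.start0
            seg.mapping_quality = 60
            seg.cigarstring = f"{len(read.seq)}M"
            seg.query_qualities = pysam.qualitystring_to_array("I" * len(read.seq))
            if read.paired:
                seg.is_paired = True
                seg.is_proper_pair = True
                seg.is_read1 = read.first
                seg.is_read2 = not read.first
                seg.is_reverse = not read.first
                seg.mate_is_reverse = read.first
                seg.next_reference_id = 0
                seg.next_reference_start = read.mate_start0
                seg.template_length = read.insert
            sam.write(seg)


def _variant_header(ref: ReferenceBuild, sample: str) -> "pysam.VariantHeader":
    header = pysam.VariantHeader()
    header.contigs.add(ref.name, length=len(ref.sequence))
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample(sample)
    return header


def _write_hsp_vcf(
    path: str, ref: ReferenceBuild, cov: CoverageTable, min_total: int, min_frac: float
) -> None:
    """Naive HSP caller on the polyploid pileup: a position with >= min_total
    fragments where >= 2 bases each reach min_frac of them."""
    header = _variant_header(ref, "POLY")
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for position in cov.positions():
            counts = cov.counts(position)
            total = sum(counts.values())
            if total < min_total:
                continue
            passing = [b for b in BASES if counts[b] >= min_frac * total and counts[b] > 0]
            if len(passing) < 2:
                continue
            ref_base = ref.sequence[position.pos - 1]
            alts = [b for b in passing if b != ref_base]
            if not alts:
                continue
            alleles = [ref_base] + alts
            gt = tuple(
                alleles.index(b) for b in passing
            )
            rec = vcf.new_record(
                contig=position.seq_name,
                start=position.pos - 1,
                stop=position.pos,
                alleles=tuple(alleles),
            )
            rec.samples["POLY"]["GT"] = gt
            vcf.write(rec)


def _write_sbs_vcf(
    path: str, ref: ReferenceBuild, cov: CoverageTable, min_total: int, min_major: float
) -> None:
    """Naive homozygous-substitution caller on a diploid pileup: the majority
    base must hold >= min_major of the reads and differ from the reference;
    anything less clean is treated as ambiguous and not reported."""
    header = _variant_header(ref, "DIPLOID")
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for position in cov.positions():
            counts = cov.counts(position)
            total = sum(counts.values())
            if total < min_total:
                continue
            major = max(BASES, key=lambda b: counts[b])
            if counts[major] < min_major * total:
                continue
            ref_base = ref.sequence[position.pos - 1]
            if major == ref_base:
                continue
            rec = vcf.new_record(
                contig=position.seq_name,
                start=position.pos - 1,
                stop=position.pos,
                alleles=(ref_base, major),
            )
            rec.samples["DIPLOID"]["GT"] = (1, 1)
            vcf.write(rec)


# ---------------------------------------------------------------------------
# Worked fixture: a tiny dataset whose six-step outcome is hand-derivable


@dataclass
class WorkedFixture:
    """One gene of 20 bp with HSPs at positions 5 and 12, six single-end
    reads, two subgenomes D1 and D2.

    Subgenome haplotypes: D1 carries A5/T12 (reference-like), D2 carries
    G5/C12.  Three reads span both HSPs with the D1 haplotype; two short D2
    reads cover only position 5 (base G); one D2 read covers only position
    12 (base C).  Diploid D1 has coverage at both HSPs (A, T) and an empty
    substitution list; diploid D2 has a validated G substitution and
    coverage at position 5 but no data at position 12.

    Hand trace: the A5-T12 pattern matches D1 at 100% -> subgenome D1 gets
    A and T.  The lone-G pattern matches D2 at 100% -> D2 gets G at 5.  The
    lone-C pattern matches neither diploid (D2 is uninformative at 12), so
    position 12 stays half-called until finalization, where C — the only
    unassigned observed base — is eliminated onto D2, the only uncalled
    subgenome.  Both positions end fully characterized; with finalization
    off, position 12 does not.  Withholding D2 entirely (missing diploid)
    routes both unplaced patterns to D2 and yields the same calls without
    needing finalization.
    """

    out_dir: str
    labels: Tuple[str, str]
    paths: Dict[str, str]
    sbs_paths: Dict[str, str]
    diploid_coverage_paths: Dict[str, str]
    expected_calls: Dict[Tuple[GenomicPosition, str], str]
    ref_name: str = "reference"


def make_worked_fixture(out_dir: str) -> WorkedFixture:
    os.makedirs(out_dir, exist_ok=True)
    ref_seq = "ACGTACGTACGTACGTACGT"  # positions 1..20, gene g1
    build = build_reference([("g1", ref_seq)], gap_length=10)
    fasta, gff = write_reference(build, os.path.join(out_dir, "reference"))
    name = build.name

    def hap(start: int, end: int, subs: Dict[int, str]) -> str:
        return "".join(subs.get(p, ref_seq[p - 1]) for p in range(start, end + 1))

    # (read name, 1-based start, sequence)
    reads = [
        ("r1", 3, hap(3, 16, {})),
        ("r2", 3, hap(3, 16, {})),
        ("r3", 3, hap(3, 16, {})),
        ("r4", 1, hap(1, 8, {5: "G"})),
        ("r5", 1, hap(1, 8, {5: "G"})),
        ("r6", 10, hap(10, 18, {12: "C"})),
    ]
    sam_reads = [
        _Read(rname, start - 1, seq, False, True, 0, 0) for rname, start, seq in reads
    ]
    sam_path = os.path.join(out_dir, "polyploid.sam")
    _write_sam(sam_path, name, len(build.sequence), sam_reads, paired=False)

    fragments = [
        AlignedFragment.from_bases(
            rname, "g1", name, {start + i: b for i, b in enumerate(seq)}
        )
        for rname, start, seq in reads
    ]
    poly_cov = compute_base_coverage(fragments)
    poly_cov_path = os.path.join(out_dir, "polyploid_coverage.tsv")
    write_coverage_table(poly_cov, poly_cov_path)

    header = _variant_header(build, "POLY")
    hsp_path = os.path.join(out_dir, "polyploid_hsps.vcf")
    with pysam.VariantFile(hsp_path, "w", header=header) as vcf:
        for pos, ref_base, alt in ((5, "A", "G"), (12, "T", "C")):
            rec = vcf.new_record(
                contig=name, start=pos - 1, stop=pos, alleles=(ref_base, alt)
            )
            rec.samples["POLY"]["GT"] = (0, 1)
            vcf.write(rec)

    sbs_paths: Dict[str, str] = {}
    d1_path = os.path.join(out_dir, "D1_sbs.vcf")
    with pysam.VariantFile(d1_path, "w", header=_variant_header(build, "DIPLOID")):
        pass  # D1 is reference-like: empty body
    sbs_paths["D1"] = d1_path
    d2_path = os.path.join(out_dir, "D2_sbs.vcf")
    with pysam.VariantFile(d2_path, "w", header=_variant_header(build, "DIPLOID")) as vcf:
        rec = vcf.new_record(contig=name, start=4, stop=5, alleles=("A", "G"))
        rec.samples["DIPLOID"]["GT"] = (1, 1)
        vcf.write(rec)
    sbs_paths["D2"] = d2_path

    dip_cov_paths: Dict[str, str] = {}
    d1_cov = CoverageTable()
    d1_cov.set_counts(GenomicPosition(name, 5), [6, 0, 0, 0])  # A
    d1_cov.set_counts(GenomicPosition(name, 12), [0, 0, 0, 6])  # T
    d1_cov_path = os.path.join(out_dir, "D1_coverage.tsv")
    write_coverage_table(d1_cov, d1_cov_path)
    dip_cov_paths["D1"] = d1_cov_path
    d2_cov = CoverageTable()
    d2_cov.set_counts(GenomicPosition(name, 5), [0, 0, 5, 0])  # G
    d2_cov_path = os.path.join(out_dir, "D2_coverage.tsv")
    write_coverage_table(d2_cov, d2_cov_path)
    dip_cov_paths["D2"] = d2_cov_path

    expected = {
        (GenomicPosition(name, 5), "D1"): "A",
        (GenomicPosition(name, 5), "D2"): "G",
        (GenomicPosition(name, 12), "D1"): "T",
        (GenomicPosition(name, 12), "D2"): "C",
    }
    return WorkedFixture(
        out_dir=out_dir,
        labels=("D1", "D2"),
        paths={
            "fasta": fasta,
            "gff": gff,
            "sam": sam_path,
            "polyploid_coverage": poly_cov_path,
            "hsp_vcf": hsp_path,
        },
        sbs_paths=sbs_paths,
        diploid_coverage_paths=dip_cov_paths,
        expected_calls=expected,
        ref_name=name,
    )
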