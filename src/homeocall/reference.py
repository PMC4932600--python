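"""In-silico transcriptomic reference construction.

Unigene/cDNA sequences are concatenated into a single reference sequence
with a block of N separator bases after every input sequence (``gap_length``
Ns, default 200), and a GFF3 file records each gene's interval on the
concatenation.  The N blocks prevent reads from aligning across gene
boundaries; one block follows every sequence, including the last, so the
total number of separator bases is ``n_sequences * gap_length``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import List, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import GeneInterval

logger = logging.getLogger(__name__)

_NON_ACGTN = re.compile(r"[^ACGTN]")


@dataclass
class ReferenceBuild:
    sequence: str
    genes: List[GeneInterval]
    gap_length: int
    n_total: int
    name: str = "reference"

    def __len__(self) -> int:
        return len(self.sequence)


def build_reference(
    sequences: Sequence[Tuple[str, str]],
    gap_length: int = 200,
    name: str = "reference",
) -> ReferenceBuild:
    """Concatenate ``(name, sequence)`` pairs into one reference.

    Layout: seq1, gap, seq2, gap, ..., seqN, gap.  Input is case-folded to
    upper case; letters outside ACGTN are replaced with N (with a warning).
    Duplicate sequence names and empty inputs are errors.
    """
    if gap_length < 0:
        raise ValueError("gap_length must be >= 0")
    if not sequences:
        raise ValueError("no input sequences")
    names = [n for n, _ in sequences]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate sequence names: {dupes}")

    parts: List[str] = []
    genes: List[GeneInterval] = []
    gap = "N" * gap_length
    offset = 0
    replaced = 0
    for seq_name, raw in sequences:
        if not raw:
            raise ValueError(f"empty sequence {seq_name!r}")
        seq = raw.upper()
        cleaned = _NON_ACGTN.sub("N", seq)
        replaced += sum(1 for a, b in zip(seq, cleaned) if a != b)
        genes.append(GeneInterval(seq_name, name, offset + 1, offset + len(cleaned)))
        parts.append(cleaned)
        parts.append(gap)
        offset += len(cleaned) + gap_length
    if replaced:
        logger.warning("replaced %d non-ACGTN letters with N", replaced)
    return ReferenceBuild(
        sequence="".join(parts),
        genes=genes,
        gap_length=gap_length,
        n_total=len(sequences) * gap_length,
        name=name,
    )


def write_reference(build: ReferenceBuild, out_prefix: str, line_width: int = 60) -> Tuple[str, str]:
    """Write ``PREFIX.fa`` (single record) and ``PREFIX.gff3``."""
    fasta_path = f"{out_prefix}.fa"
    gff_path = f"{out_prefix}.gff3"
    record = SeqRecord(Seq(build.sequence), id=build.name, description="")
    with open(fasta_path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file([record])
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {build.name} 1 {len(build.sequence)}\n")
        for gene in build.genes:
            fh.write(
                f"{build.name}\thomeocall\tgene\t{gene.start}\t{gene.end}\t.\t+\t.\t"
                f"ID={gene.gene_id}\n"
            )
    return fasta_path, gff_path


def seq2ref(fasta_path: str, out_prefix: str, gap_length: int = 200) -> ReferenceBuild:
    """Read a multi-FASTA of unigenes/cDNAs, build the concatenated
    reference, and write PREFIX.fa + PREFIX.gff3."""
    sequences = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fasta_path, "fasta")]
    build = build_reference(sequences, gap_length=gap_length)
    write_reference(build, out_prefix)
    return build
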