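"""Domain containers shared across the pipeline.

Coordinates are 1-based and inclusive throughout, matching VCF/GFF
conventions.  A *subgenome* is identified by the label of its diploid
progenitor; at most one progenitor may be declared missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, NamedTuple, Optional, Set, Tuple

import numpy as np

BASES = ("A", "C", "G", "T")
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# Diploid-state codes used in the tab output.
NO_COVERAGE = "0"
LOW_COVERAGE = "<"
AMBIGUOUS = "*"
MISSING = "?"
NON_BASE_CODES = frozenset({NO_COVERAGE, LOW_COVERAGE, AMBIGUOUS, MISSING})


class GenomicPosition(NamedTuple):
    """Reference sequence name plus 1-based coordinate."""

    seq_name: str
    pos: int


@dataclass(frozen=True)
class GeneInterval:
    """A gene/contig interval on the reference (1-based, inclusive)."""

    gene_id: str
    seq_name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")
        if self.start < 1:
            raise ValueError(f"gene {self.gene_id}: start must be >= 1")

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class HSPRecord:
    """A candidate homeolog-specific polymorphism: a reference position where
    the polyploid subgenomes carry (at least) two different bases."""

    position: GenomicPosition
    ref_base: str
    observed_bases: Set[str]

    def __post_init__(self) -> None:
        if self.ref_base not in BASES:
            raise ValueError(f"invalid reference base {self.ref_base!r}")
        bad = self.observed_bases - set(BASES)
        if bad:
            raise ValueError(f"invalid observed bases {bad}")


@dataclass(frozen=True)
class SBSRecord:
    """A single-base substitution of one diploid progenitor vs. the reference."""

    position: GenomicPosition
    ref_base: str
    diploid_base: str

    def __post_init__(self) -> None:
        if self.diploid_base == self.ref_base:
            raise ValueError("SBS base equals reference base")
        if self.ref_base not in BASES or self.diploid_base not in BASES:
            raise ValueError("SBS bases must be A/C/G/T")


class CoverageTable:
    """Per-position, per-base read(-fragment) counts.

    Positions absent from the table have zero coverage.  Counts are stored as
    a 4-vector in A, C, G, T order.
    """

    def __init__(self) -> None:
        self._counts: Dict[GenomicPosition, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, position: GenomicPosition) -> bool:
        return position in self._counts

    def __iter__(self) -> Iterator[GenomicPosition]:
        return iter(self._counts)

    def add(self, position: GenomicPosition, base: str, count: int = 1) -> None:
        vec = self._counts.get(position)
        if vec is None:
            vec = np.zeros(4, dtype=np.int64)
            self._counts[position] = vec
        vec[BASE_INDEX[base]] += count

    def set_counts(self, position: GenomicPosition, counts) -> None:
        vec = np.asarray(counts, dtype=np.int64)
        if vec.shape != (4,) or (vec < 0).any():
            raise ValueError("counts must be four non-negative integers")
        self._counts[position] = vec

    def counts(self, position: GenomicPosition) -> Dict[str, int]:
        vec = self._counts.get(position)
        if vec is None:
            return {b: 0 for b in BASES}
        return {b: int(vec[i]) for i, b in enumerate(BASES)}

    def count(self, position: GenomicPosition, base: str) -> int:
        vec = self._counts.get(position)
        return 0 if vec is None else int(vec[BASE_INDEX[base]])

    def total(self, position: GenomicPosition) -> int:
        vec = self._counts.get(position)
        return 0 if vec is None else int(vec.sum())

    def positions(self) -> List[GenomicPosition]:
        return sorted(self._counts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoverageTable):
            return NotImplemented
        if set(self._counts) != set(other._counts):
            return False
        return all((self._counts[p] == other._counts[p]).all() for p in self._counts)


class AlignedFragment:
    """One sequencing unit after filtering: a single-end read or a fused
    read pair.  Bases are stored per covered reference position; positions
    where the two mates disagree are omitted (treated as uncovered)."""

    __slots__ = ("fragment_id", "gene_id", "seq_name", "positions", "base_codes", "mapq")

    def __init__(
        self,
        fragment_id: str,
        gene_id: str,
        seq_name: str,
        positions: np.ndarray,
        base_codes: np.ndarray,
        mapq: int,
    ) -> None:
        self.fragment_id = fragment_id
        self.gene_id = gene_id
        self.seq_name = seq_name
        self.positions = positions  # sorted 1-based coordinates
        self.base_codes = base_codes  # uint8 indices into BASES
        self.mapq = mapq

    @classmethod
    def from_bases(
        cls, fragment_id: str, gene_id: str, seq_name: str, bases: Dict[int, str], mapq: int = 60
    ) -> "AlignedFragment":
        items = sorted((p, b) for p, b in bases.items() if b in BASE_INDEX)
        pos = np.array([p for p, _ in items], dtype=np.int64)
        codes = np.array([BASE_INDEX[b] for _, b in items], dtype=np.uint8)
        return cls(fragment_id, gene_id, seq_name, pos, codes, mapq)

    def to_dict(self) -> Dict[int, str]:
        return {int(p): BASES[c] for p, c in zip(self.positions, self.base_codes)}

    def base_at(self, pos: int) -> Optional[str]:
        i = np.searchsorted(self.positions, pos)
        if i < len(self.positions) and self.positions[i] == pos:
            return BASES[self.base_codes[i]]
        return None

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class DiploidProfile:
    """Per-progenitor base state at each HSP position.

    ``base_at`` maps positions to A/C/G/T or one of the state codes:
    '0' no coverage, '<' low coverage, '*' ambiguous/heterozygous,
    '?' missing progenitor.
    """

    subgenome_label: str
    base_at: Dict[GenomicPosition, str] = field(default_factory=dict)
    is_missing: bool = False

    def state(self, position: GenomicPosition) -> str:
        if self.is_missing:
            return MISSING
        return self.base_at.get(position, NO_COVERAGE)

    def concrete_base(self, position: GenomicPosition) -> Optional[str]:
        s = self.state(position)
        return s if s in BASE_INDEX else None


@dataclass
class PositionCall:
    """Per-position slice of the call table."""

    ref_base: str
    observed_bases: Set[str]
    calls: Dict[str, Optional[str]]  # subgenome label -> base or None

    def fully_characterized(self) -> bool:
        return all(b is not None for b in self.calls.values())


class SubgenomeCallTable:
    """Assigned base per HSP position per subgenome."""

    def __init__(self, subgenomes: Tuple[str, ...]) -> None:
        if not subgenomes:
            raise ValueError("at least one subgenome label required")
        self.subgenomes = tuple(subgenomes)
        self._rows: Dict[GenomicPosition, PositionCall] = {}

    def add_position(
        self, position: GenomicPosition, ref_base: str, observed_bases: Set[str]
    ) -> PositionCall:
        row = PositionCall(ref_base, set(observed_bases), {s: None for s in self.subgenomes})
        self._rows[position] = row
        return row

    def __contains__(self, position: GenomicPosition) -> bool:
        return position in self._rows

    def __getitem__(self, position: GenomicPosition) -> PositionCall:
        return self._rows[position]

    def __len__(self) -> int:
        return len(self._rows)

    def positions(self) -> List[GenomicPosition]:
        return sorted(self._rows)

    def assign(self, position: GenomicPosition, subgenome: str, base: str) -> None:
        row = self._rows[position]
        if base not in row.observed_bases:
            raise ValueError(
                f"base {base} not among observed bases {sorted(row.observed_bases)} at {position}"
            )
        row.calls[subgenome] = base

    def call(self, position: GenomicPosition, subgenome: str) -> Optional[str]:
        row = self._rows.get(position)
        return None if row is None else row.calls.get(subgenome)

    def reported_positions(self) -> List[GenomicPosition]:
        """Positions where at least one subgenome has an assigned base."""
        return sorted(
            p for p, row in self._rows.items() if any(b is not None for b in row.calls.values())
        )

    def n_fully_characterized(self) -> int:
        return sum(1 for row in self._rows.values() if row.fully_characterized())

    def calls_equal(self, other: "SubgenomeCallTable") -> bool:
        """Equality on the reportable content: positions, reference bases and
        per-subgenome calls (observed-base sets are not compared)."""
        if self.subgenomes != other.subgenomes:
            return False
        a = {p: r for p, r in self._rows.items() if any(v is not None for v in r.calls.values())}
        b = {p: r for p, r in other._rows.items() if any(v is not None for v in r.calls.values())}
        if set(a) != set(b):
            return False
        return all(
            a[p].ref_base == b[p].ref_base and a[p].calls == b[p].calls for p in a
        )
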