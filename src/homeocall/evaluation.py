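"""Accuracy evaluation against known truth and comparison of call sets.

The comparison counts mirror the shared-position / shared-base numbers used
to relate like subgenomes of different polyploids (or a subgenome to its
diploid progenitor): the number of positions called with a concrete base in
both sets, and how many of those agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple, Union

from .types import DiploidProfile, GenomicPosition, SubgenomeCallTable

CallSet = Union[SubgenomeCallTable, DiploidProfile]


@dataclass
class ComparisonSummary:
    shared_positions: int
    same_base: int
    per_subgenome: Dict[Tuple[str, str], Tuple[int, int]] = field(default_factory=dict)

    @property
    def fraction_same(self) -> Optional[float]:
        if self.shared_positions == 0:
            return None
        return self.same_base / self.shared_positions


def _concrete_calls(calls: CallSet) -> Dict[str, Dict[GenomicPosition, str]]:
    """label -> position -> concrete base."""
    if isinstance(calls, DiploidProfile):
        out = {
            calls.subgenome_label: {
                p: b for p in calls.base_at if (b := calls.concrete_base(p)) is not None
            }
        }
        return out
    result: Dict[str, Dict[GenomicPosition, str]] = {s: {} for s in calls.subgenomes}
    for position in calls.positions():
        for sub, base in calls[position].calls.items():
            if base is not None:
                result[sub][position] = base
    return result


def compare_call_sets(
    a: CallSet,
    b: CallSet,
    pairing: Optional[Mapping[str, str]] = None,
) -> ComparisonSummary:
    """Count positions called in both sets and those with identical bases.

    ``pairing`` maps labels of ``a`` onto labels of ``b`` (identity when
    omitted).  Both sets must live on the same reference coordinates; fully
    disjoint reference names are rejected as a likely coordinate mismatch.
    """
    calls_a = _concrete_calls(a)
    calls_b = _concrete_calls(b)
    if pairing is None:
        common = set(calls_a) & set(calls_b)
        pairing = {s: s for s in sorted(common)}
    seqs_a = {p.seq_name for per in calls_a.values() for p in per}
    seqs_b = {p.seq_name for per in calls_b.values() for p in per}
    if seqs_a and seqs_b and not (seqs_a & seqs_b):
        raise ValueError(
            f"no reference sequence in common between call sets ({sorted(seqs_a)[:3]} vs "
            f"{sorted(seqs_b)[:3]})"
        )

    per_subgenome: Dict[Tuple[str, str], Tuple[int, int]] = {}
    shared = same = 0
    for label_a, label_b in pairing.items():
        side_a = calls_a.get(label_a, {})
        side_b = calls_b.get(label_b, {})
        positions = set(side_a) & set(side_b)
        agree = sum(1 for p in positions if side_a[p] == side_b[p])
        per_subgenome[(label_a, label_b)] = (len(positions), agree)
        shared += len(positions)
        same += agree
    return ComparisonSummary(shared, same, per_subgenome)


@dataclass
class AccuracyResult:
    correct: int
    evaluated: int
    per_subgenome: Dict[str, Tuple[int, int]] = field(default_factory=dict)

    @property
    def accuracy(self) -> Optional[float]:
        """Fraction correct, or None when nothing was evaluable."""
        if self.evaluated == 0:
            return None
        return self.correct / self.evaluated


def evaluate_accuracy(
    calls: SubgenomeCallTable,
    truth: Mapping[Tuple[GenomicPosition, str], str],
    fully_characterized_only: bool = True,
) -> AccuracyResult:
    """Fraction of assigned bases matching truth.

    Each (position, subgenome) assignment with a truth entry counts once; a
    fully characterized position therefore contributes one comparison per
    subgenome.  With ``fully_characterized_only`` (the default) only
    positions where every subgenome received a base are scored.
    """
    correct = evaluated = 0
    per_subgenome: Dict[str, Tuple[int, int]] = {s: (0, 0) for s in calls.subgenomes}
    for position in calls.positions():
        row = calls[position]
        if fully_characterized_only and not row.fully_characterized():
            continue
        for sub, base in row.calls.items():
            if base is None:
                continue
            expected = truth.get((position, sub))
            if expected is None:
                continue
            evaluated += 1
            ok, n = per_subgenome[sub]
            hit = int(base == expected)
            correct += hit
            per_subgenome[sub] = (ok + hit, n + 1)
    return AccuracyResult(correct, evaluated, per_subgenome)
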