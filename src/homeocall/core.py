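"""The six-step homoeallelic base-characterization algorithm.

Starting from filtered read(-pair) fragments and a validated HSP list, the
algorithm:

1. extracts *base patterns* — the ordered (HSP position, base) pairs seen in
   each fragment, deduplicated with read support counts;
2. removes noise: patterns containing a rare base combination at two
   consecutive HSP positions, and patterns embedded in a larger pattern;
3. optionally merges overlapping, agreeing patterns into longer ones
   (greedy, longest overlap first) — the key step when a diploid
   progenitor is missing, since longer patterns are easier to place;
4. assigns each pattern to every subgenome whose diploid progenitor it
   matches at >= 50% of informative positions; a pattern matching no
   progenitor falls to the missing subgenome, when one is declared;
5. elects one base per position per subgenome from the assigned patterns
   (maximum-identity or additive-identity mode; exact ties elect nothing),
   then removes patterns that conflict with the elected bases and repeats
   until stable;
6. finalizes: a lone unassigned base at a position is given to the lone
   uncalled subgenome, and leftover patterns are rechecked against the
   assigned bases to fill remaining gaps.

All threshold comparisons and scores use exact rational arithmetic so ties
are detected exactly and runs are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .types import (
    AlignedFragment,
    BASES,
    DiploidProfile,
    GeneInterval,
    GenomicPosition,
    HSPRecord,
    SubgenomeCallTable,
)

logger = logging.getLogger(__name__)

Pair = Tuple[int, str]  # (1-based position, base) within one reference sequence


@dataclass
class BasePattern:
    """A deduplicated (position, base) sequence over the HSP sites covered by
    one or more identical fragments, with its read support."""

    gene_id: str
    seq_name: str
    pairs: Tuple[Pair, ...]
    support: int
    identity: Dict[str, Optional[Fraction]] = field(default_factory=dict)  # % in [0,100]
    assigned_to: Set[str] = field(default_factory=set)
    state: str = "active"

    @property
    def start(self) -> int:
        return self.pairs[0][0]

    def positions(self) -> Tuple[int, ...]:
        return tuple(p for p, _ in self.pairs)

    def base_string(self) -> str:
        return "".join(b for _, b in self.pairs)

    def base_at(self) -> Dict[int, str]:
        return dict(self.pairs)


@dataclass
class CoreConfig:
    """Tunables of the six-step algorithm (defaults follow the published
    parameterization: 5% base-pair noise floor, 50% identity, maximum mode).

    merge_enabled: None means "on exactly when a diploid progenitor is
    missing" (the recommended default); True/False force it.
    """

    basepair_min_frac: float = 0.05
    identity_min: float = 0.50
    mode: str = "max"  # or "additive"
    merge_enabled: Optional[bool] = None
    finalize_enabled: bool = True
    min_overlap: int = 1
    max_iterations: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.basepair_min_frac < 1:
            raise ValueError("basepair_min_frac must be in (0, 1)")
        if not 0 < self.identity_min < 1:
            raise ValueError("identity_min must be in (0, 1)")
        if self.mode not in ("max", "additive"):
            raise ValueError(f"mode must be 'max' or 'additive', got {self.mode!r}")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")

    def merging(self, missing: Optional[str]) -> bool:
        if self.merge_enabled is None:
            return missing is not None
        return self.merge_enabled


# ---------------------------------------------------------------------------
# Step 1: base patterns


def extract_base_patterns(
    fragments: Iterable[AlignedFragment],
    hsps_by_gene: Mapping[str, Sequence[HSPRecord]],
) -> List[BasePattern]:
    """Collect the (HSP position, base) pairs of every fragment; identical
    patterns within a gene collapse with summed support."""
    hsp_arrays: Dict[str, Tuple[str, np.ndarray]] = {}
    for gene_id, records in hsps_by_gene.items():
        if not records:
            continue
        pos = np.array(sorted(h.position.pos for h in records), dtype=np.int64)
        hsp_arrays[gene_id] = (records[0].position.seq_name, pos)

    counts: Dict[Tuple[str, Tuple[Pair, ...]], int] = {}
    seqs: Dict[str, str] = {}
    for frag in fragments:
        entry = hsp_arrays.get(frag.gene_id)
        if entry is None or len(frag.positions) == 0:
            continue
        seq_name, hsp_pos = entry
        _, f_idx, _ = np.intersect1d(
            frag.positions, hsp_pos, assume_unique=True, return_indices=True
        )
        if len(f_idx) == 0:
            continue
        pairs = tuple(
            (int(frag.positions[i]), BASES[frag.base_codes[i]]) for i in sorted(f_idx)
        )
        counts[(frag.gene_id, pairs)] = counts.get((frag.gene_id, pairs), 0) + 1
        seqs[frag.gene_id] = seq_name
    return [
        BasePattern(gene_id, seqs[gene_id], pairs, support)
        for (gene_id, pairs), support in sorted(counts.items())
    ]


# ---------------------------------------------------------------------------
# Step 2: noise filtering


def filter_rare_basepairs(
    patterns: Sequence[BasePattern],
    hsps_by_gene: Mapping[str, Sequence[HSPRecord]],
    cfg: CoreConfig,
) -> List[BasePattern]:
    """Remove patterns containing a base combination at two consecutive HSP
    positions that is supported by < basepair_min_frac of the reads covering
    that position pair.

    "Consecutive" means adjacent in the gene's validated HSP list, whatever
    the genomic distance between them.  Single-position patterns have no
    pairs and are never removed here.
    """
    min_frac = Fraction(str(cfg.basepair_min_frac))
    by_gene: Dict[str, List[BasePattern]] = {}
    for p in patterns:
        by_gene.setdefault(p.gene_id, []).append(p)

    keep: List[BasePattern] = []
    for gene_id, gene_patterns in by_gene.items():
        ordered = sorted(h.position.pos for h in hsps_by_gene.get(gene_id, ()))
        consecutive = list(zip(ordered, ordered[1:]))
        # tally combination support per consecutive position pair
        combo_support: Dict[Tuple[int, int, str, str], int] = {}
        pair_total: Dict[Tuple[int, int], int] = {}
        pattern_combos: List[List[Tuple[int, int, str, str]]] = []
        for pat in gene_patterns:
            base_at = pat.base_at()
            combos = []
            for p1, p2 in consecutive:
                b1, b2 = base_at.get(p1), base_at.get(p2)
                if b1 is None or b2 is None:
                    continue
                key = (p1, p2, b1, b2)
                combos.append(key)
                combo_support[key] = combo_support.get(key, 0) + pat.support
                pair_total[(p1, p2)] = pair_total.get((p1, p2), 0) + pat.support
            pattern_combos.append(combos)
        for pat, combos in zip(gene_patterns, pattern_combos):
            rare = any(
                Fraction(combo_support[k]) < min_frac * pair_total[(k[0], k[1])]
                for k in combos
            )
            if not rare:
                keep.append(pat)
    return keep


def remove_embedded_patterns(patterns: Sequence[BasePattern]) -> List[BasePattern]:
    """Drop any pattern whose (position, base) pairs are a subset of another
    pattern's in the same gene; the containing pattern's support is left
    unchanged."""
    by_gene: Dict[str, List[BasePattern]] = {}
    for p in patterns:
        by_gene.setdefault(p.gene_id, []).append(p)
    keep: List[BasePattern] = []
    for gene_patterns in by_gene.values():
        sets = [frozenset(p.pairs) for p in gene_patterns]
        for i, pat in enumerate(gene_patterns):
            embedded = any(
                i != j and sets[i] <= sets[j] and sets[i] != sets[j]
                or (i != j and sets[i] == sets[j] and i > j)
                for j in range(len(gene_patterns))
            )
            if not embedded:
                keep.append(pat)
    return keep


# ---------------------------------------------------------------------------
# Step 3: iterative merging


def _overlap(a: BasePattern, b: BasePattern, min_overlap: int) -> int:
    """Number of shared positions when the two patterns agree at every
    shared position and share at least min_overlap; else 0 (not mergeable)."""
    small, large = (a, b) if len(a.pairs) <= len(b.pairs) else (b, a)
    large_at = large.base_at()
    shared = 0
    for pos, base in small.pairs:
        other = large_at.get(pos)
        if other is None:
            continue
        if other != base:
            return 0
        shared += 1
    return shared if shared >= min_overlap else 0


def _pair_key(ov: int, a: BasePattern, b: BasePattern):
    # largest overlap first; then smaller leftmost start; then the
    # lexicographically smaller combined base string; then full pair content
    first, second = sorted((a, b), key=lambda p: (p.start, p.base_string(), p.pairs))
    return (
        -ov,
        min(a.start, b.start),
        first.base_string() + "|" + second.base_string(),
        first.pairs,
        second.pairs,
    )


def merge_overlapping_patterns(
    patterns: Sequence[BasePattern], cfg: CoreConfig
) -> List[BasePattern]:
    """Greedily merge same-gene patterns, longest overlap first.

    Two patterns are mergeable when they share >= min_overlap positions and
    agree at every shared position; the merge is the union of their pairs
    with summed support.  Ties on overlap length are broken
    deterministically (leftmost start, then base string)."""
    by_gene: Dict[str, List[BasePattern]] = {}
    for p in patterns:
        by_gene.setdefault(p.gene_id, []).append(p)

    merged_all: List[BasePattern] = []
    for gene_id, gene_patterns in by_gene.items():
        pool: Dict[int, BasePattern] = {i: p for i, p in enumerate(gene_patterns)}
        next_id = len(gene_patterns)
        overlaps: Dict[Tuple[int, int], int] = {}
        ids = sorted(pool)
        for ii, i in enumerate(ids):
            for j in ids[ii + 1 :]:
                ov = _overlap(pool[i], pool[j], cfg.min_overlap)
                if ov:
                    overlaps[(i, j)] = ov
        while overlaps:
            (i, j), ov = min(
                overlaps.items(), key=lambda kv: _pair_key(kv[1], pool[kv[0][0]], pool[kv[0][1]])
            )
            a, b = pool.pop(i), pool.pop(j)
            union = dict(a.pairs)
            union.update(b.pairs)
            merged = BasePattern(
                gene_id, a.seq_name, tuple(sorted(union.items())), a.support + b.support
            )
            overlaps = {k: v for k, v in overlaps.items() if i not in k and j not in k}
            mid = next_id
            next_id += 1
            for k, other in pool.items():
                ov2 = _overlap(merged, other, cfg.min_overlap)
                if ov2:
                    overlaps[(min(k, mid), max(k, mid))] = ov2
            pool[mid] = merged
        merged_all.extend(pool[k] for k in sorted(pool))
    return merged_all


# ---------------------------------------------------------------------------
# Step 4: pattern-to-subgenome assignment


def assign_patterns_to_subgenomes(
    patterns: Sequence[BasePattern],
    profiles: Mapping[str, DiploidProfile],
    missing: Optional[str],
    cfg: CoreConfig,
) -> List[BasePattern]:
    """Score every pattern against every diploid profile and assign it to
    each subgenome reaching >= identity_min; unplaced patterns fall to the
    missing subgenome when one is declared.

    Identity is 100 * matches / informative over the pattern's positions
    where the profile has a concrete base (positions coded 0/</*/? are not
    informative); it is undefined (None) when nothing is informative.
    """
    identity_min = Fraction(str(cfg.identity_min))
    for pat in patterns:
        pat.identity = {}
        pat.assigned_to = set()
        for label, profile in profiles.items():
            if profile.is_missing:
                pat.identity[label] = None
                continue
            informative = 0
            matches = 0
            for pos, base in pat.pairs:
                ref = profile.concrete_base(GenomicPosition(pat.seq_name, pos))
                if ref is None:
                    continue
                informative += 1
                if ref == base:
                    matches += 1
            if informative == 0:
                pat.identity[label] = None
            else:
                pat.identity[label] = Fraction(100 * matches, informative)
                if Fraction(matches, informative) >= identity_min:
                    pat.assigned_to.add(label)
        if missing is not None and not pat.assigned_to:
            pat.assigned_to.add(missing)
    return list(patterns)


# ---------------------------------------------------------------------------
# Step 5: base election


def _pattern_score(
    pat: BasePattern, subgenome: str, missing: Optional[str]
) -> Optional[Tuple[int, Fraction]]:
    """Election score of a pattern for one subgenome, as (tier, value).

    For a subgenome with a present diploid the score is the diploid identity
    (tier 1).  For the missing subgenome no identity exists, so the score is
    100 minus the best identity against any present diploid — "least like
    every known progenitor" (tier 1); when every identity is undefined the
    pattern's read support is used instead (tier 0, outranked by any
    identity-based score)."""
    if subgenome != missing:
        ident = pat.identity.get(subgenome)
        return None if ident is None else (1, ident)
    present = [v for k, v in pat.identity.items() if k != missing and v is not None]
    if present:
        return (1, Fraction(100) - max(present))
    return (0, Fraction(pat.support))


def assign_bases_to_subgenomes(
    patterns: Sequence[BasePattern],
    hsps: Sequence[HSPRecord],
    cfg: CoreConfig,
    missing: Optional[str] = None,
    subgenomes: Optional[Sequence[str]] = None,
) -> SubgenomeCallTable:
    """Elect one base per HSP position per subgenome from the assigned
    patterns, then iteratively remove patterns conflicting with the elected
    bases until the call table is stable.

    In maximum mode the base of the best-scoring pattern wins; in additive
    mode the base with the largest score sum over patterns carrying it wins.
    An exact tie between different bases elects nothing.  Candidate bases
    outside the position's validated observed set are never electable.
    """
    if subgenomes is None:
        labels: List[str] = sorted({s for p in patterns for s in p.assigned_to})
        if missing is not None and missing not in labels:
            labels.append(missing)
        subgenomes = labels
    table = SubgenomeCallTable(tuple(subgenomes))
    for hsp in hsps:
        table.add_position(hsp.position, hsp.ref_base, hsp.observed_bases)
    observed_at = {h.position: h.observed_bases for h in hsps}

    previous: Optional[Dict[Tuple[GenomicPosition, str], Optional[str]]] = None
    for _ in range(cfg.max_iterations):
        elected = _elect(patterns, observed_at, cfg, missing, subgenomes)
        if elected == previous:
            break
        previous = elected
        # consistency: drop active patterns conflicting with elected bases
        for pat in patterns:
            if pat.state != "active":
                continue
            for sub in pat.assigned_to:
                conflict = False
                for pos, base in pat.pairs:
                    e = elected.get((GenomicPosition(pat.seq_name, pos), sub))
                    if e is not None and e != base:
                        conflict = True
                        break
                if conflict:
                    pat.state = "removed"
                    break
    else:
        raise RuntimeError(
            f"base election did not stabilize within {cfg.max_iterations} passes"
        )

    for (position, sub), base in previous.items():
        if base is not None:
            table.assign(position, sub, base)
    return table


def _elect(
    patterns: Sequence[BasePattern],
    observed_at: Mapping[GenomicPosition, Set[str]],
    cfg: CoreConfig,
    missing: Optional[str],
    subgenomes: Sequence[str],
) -> Dict[Tuple[GenomicPosition, str], Optional[str]]:
    candidates: Dict[Tuple[GenomicPosition, str], Dict[str, List[Tuple[int, Fraction]]]] = {}
    for pat in patterns:
        if pat.state != "active" or not pat.assigned_to:
            continue
        for sub in pat.assigned_to:
            score = _pattern_score(pat, sub, missing)
            if score is None:
                continue
            for pos, base in pat.pairs:
                position = GenomicPosition(pat.seq_name, pos)
                observed = observed_at.get(position)
                if observed is None or base not in observed:
                    continue
                candidates.setdefault((position, sub), {}).setdefault(base, []).append(score)

    elected: Dict[Tuple[GenomicPosition, str], Optional[str]] = {
        (position, sub): None for position in observed_at for sub in subgenomes
    }
    for key, per_base in candidates.items():
        # identity-derived scores outrank support-derived fallbacks
        top_tier = max(t for scores in per_base.values() for t, _ in scores)
        if cfg.mode == "max":
            best: Dict[str, Fraction] = {
                b: max(v for t, v in scores if t == top_tier)
                for b, scores in per_base.items()
                if any(t == top_tier for t, _ in scores)
            }
        else:  # additive
            best = {
                b: sum((v for t, v in scores if t == top_tier), Fraction(0))
                for b, scores in per_base.items()
                if any(t == top_tier for t, _ in scores)
            }
        top = max(best.values())
        winners = [b for b, v in best.items() if v == top]
        elected[key] = winners[0] if len(winners) == 1 else None
    return elected


# ---------------------------------------------------------------------------
# Step 6: finalization


def finalize_assignments(
    calls: SubgenomeCallTable,
    patterns: Sequence[BasePattern],
    cfg: CoreConfig,
    missing: Optional[str] = None,
) -> SubgenomeCallTable:
    """Fill remaining gaps using the structure of HSPs themselves.

    (a) Elimination: when exactly one observed base at a position is
    unassigned and exactly one subgenome lacks a call, the base goes to that
    subgenome.  (b) Recheck: patterns left unassigned or removed earlier are
    scored against the assigned bases (identity over called positions) and,
    at >= identity_min, their bases compete for still-empty slots under the
    usual election rules.  Existing calls are never retracted.  Disabled
    entirely when cfg.finalize_enabled is off (heterozygous species).
    """
    if not cfg.finalize_enabled:
        return calls
    identity_min = Fraction(str(cfg.identity_min))
    leftovers = [p for p in patterns if p.state == "removed" or not p.assigned_to]

    changed = True
    iterations = 0
    while changed:
        iterations += 1
        if iterations > cfg.max_iterations:
            raise RuntimeError("finalization did not reach a fixed point")
        changed = False
        # (a) elimination
        for position in calls.positions():
            row = calls[position]
            assigned = {b for b in row.calls.values() if b is not None}
            unassigned_bases = row.observed_bases - assigned
            empty_subs = [s for s, b in row.calls.items() if b is None]
            if len(unassigned_bases) == 1 and len(empty_subs) == 1:
                calls.assign(position, empty_subs[0], next(iter(unassigned_bases)))
                changed = True
        # (b) recheck leftover patterns against the assigned bases
        candidates: Dict[Tuple[GenomicPosition, str], Dict[str, List[Tuple[int, Fraction]]]] = {}
        for pat in leftovers:
            for sub in calls.subgenomes:
                informative = 0
                matches = 0
                for pos, base in pat.pairs:
                    call = calls.call(GenomicPosition(pat.seq_name, pos), sub)
                    if call is None:
                        continue
                    informative += 1
                    if call == base:
                        matches += 1
                if informative == 0 or Fraction(matches, informative) < identity_min:
                    continue
                score = (1, Fraction(100 * matches, informative))
                for pos, base in pat.pairs:
                    position = GenomicPosition(pat.seq_name, pos)
                    if position not in calls:
                        continue
                    row = calls[position]
                    if row.calls[sub] is not None or base not in row.observed_bases:
                        continue
                    candidates.setdefault((position, sub), {}).setdefault(base, []).append(score)
        for (position, sub), per_base in candidates.items():
            if calls.call(position, sub) is not None:
                continue
            if cfg.mode == "max":
                best = {b: max(v for _, v in scores) for b, scores in per_base.items()}
            else:
                best = {b: sum((v for _, v in scores), Fraction(0)) for b, scores in per_base.items()}
            top = max(best.values())
            winners = [b for b, v in best.items() if v == top]
            if len(winners) == 1:
                calls.assign(position, sub, winners[0])
                changed = True
    return calls


# ---------------------------------------------------------------------------
# Orchestration of steps 1-6 on in-memory objects


def group_hsps_by_gene(
    hsps: Sequence[HSPRecord], genes: Sequence["GeneInterval"]
) -> Dict[str, List[HSPRecord]]:
    """Assign each HSP to its containing gene interval; HSPs outside every
    gene (e.g. in an N separator block) are dropped with a warning."""
    from .io import GeneIndex  # local import: io pulls heavier deps

    index = GeneIndex(genes)
    by_gene: Dict[str, List[HSPRecord]] = {}
    orphaned = 0
    for hsp in hsps:
        gene = index.find(hsp.position.seq_name, hsp.position.pos)
        if gene is None:
            orphaned += 1
            continue
        by_gene.setdefault(gene.gene_id, []).append(hsp)
    if orphaned:
        logger.warning("%d HSP positions fall outside every gene interval", orphaned)
    for records in by_gene.values():
        records.sort(key=lambda h: h.position.pos)
    return by_gene


def characterize(
    fragments: Iterable[AlignedFragment],
    hsps: Sequence[HSPRecord],
    genes: Sequence["GeneInterval"],
    profiles: Mapping[str, DiploidProfile],
    cfg: CoreConfig,
    missing: Optional[str] = None,
    counters: Optional[Dict[str, int]] = None,
) -> SubgenomeCallTable:
    """Run steps 1-6 and return the call table.

    ``hsps`` must already be validated; ``profiles`` must cover every HSP
    position for every subgenome (the missing one included)."""
    if counters is None:
        counters = {}
    by_gene = group_hsps_by_gene(hsps, genes)
    hsps = [h for records in by_gene.values() for h in records]
    patterns = extract_base_patterns(fragments, by_gene)
    counters["patterns_initial"] = len(patterns)
    patterns = filter_rare_basepairs(patterns, by_gene, cfg)
    patterns = remove_embedded_patterns(patterns)
    counters["patterns_after_filter"] = len(patterns)
    if cfg.merging(missing):
        patterns = merge_overlapping_patterns(patterns, cfg)
    counters["patterns_after_merge"] = len(patterns)
    patterns = assign_patterns_to_subgenomes(patterns, profiles, missing, cfg)
    counters["patterns_assigned"] = sum(1 for p in patterns if p.assigned_to)
    calls = assign_bases_to_subgenomes(
        patterns, hsps, cfg, missing=missing, subgenomes=sorted(profiles)
    )
    calls = finalize_assignments(calls, patterns, cfg, missing=missing)
    counters["positions_reported"] = len(calls.reported_positions())
    counters["positions_fully_characterized"] = calls.n_fully_characterized()
    return calls
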