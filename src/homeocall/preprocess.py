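"""Optional validation of HSP/SBS lists against base coverage, discovery of
additional HSPs at diploid substitution (and user-supplied) positions, and
construction of per-progenitor base profiles.

Thresholds are "at least X%" rules compared exactly: a base with count c at
a position with ACGT total t passes a fraction f iff c >= f * t, evaluated
with rational arithmetic so boundary cases (e.g. exactly 5%) are stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

from .types import (
    AMBIGUOUS,
    BASES,
    LOW_COVERAGE,
    MISSING,
    NO_COVERAGE,
    CoverageTable,
    DiploidProfile,
    GenomicPosition,
    HSPRecord,
    SBSRecord,
)

logger = logging.getLogger(__name__)


def _as_fraction(x: float) -> Fraction:
    # via the decimal string so 0.05 means exactly 5/100
    return Fraction(str(x))


@dataclass
class PreprocessConfig:
    """User-driven validation thresholds.

    hsp_min_frac: minimum fraction of reads supporting a base for it to be a
        valid subgenome base at an HSP position (default 0.05).
    sbs_min_frac: minimum fraction of reads supporting the diploid base for a
        substitution to be kept (default 0.30).
    min_diploid_coverage: reads required for a confident diploid base;
        below this the position is flagged low-coverage (default 3).
    ambiguous_min_frac: a diploid position is called ambiguous/heterozygous
        when at least two bases each reach this fraction (default 0.20).
    """

    hsp_min_frac: float = 0.05
    sbs_min_frac: float = 0.30
    min_diploid_coverage: int = 3
    ambiguous_min_frac: float = 0.20

    def __post_init__(self) -> None:
        for name in ("hsp_min_frac", "sbs_min_frac", "ambiguous_min_frac"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.min_diploid_coverage < 0:
            raise ValueError("min_diploid_coverage must be >= 0")


def _passing_bases(counts: Mapping[str, int], min_frac: Fraction) -> Set[str]:
    total = sum(counts.values())
    if total == 0:
        return set()
    threshold = min_frac * total
    return {b for b in BASES if counts[b] > 0 and Fraction(counts[b]) >= threshold}


def validate_hsps(
    hsps: Sequence[HSPRecord],
    cov: Optional[CoverageTable],
    cfg: PreprocessConfig,
) -> List[HSPRecord]:
    """Keep only bases supported by >= hsp_min_frac of the reads at each HSP
    position; drop positions left with fewer than two valid bases.

    Without a coverage table the records pass through unchanged (validation
    is optional).
    """
    if cov is None:
        return list(hsps)
    frac = _as_fraction(cfg.hsp_min_frac)
    out: List[HSPRecord] = []
    dropped = 0
    for hsp in hsps:
        if hsp.position not in cov:
            dropped += 1
            continue
        valid = hsp.observed_bases & _passing_bases(cov.counts(hsp.position), frac)
        if len(valid) >= 2:
            out.append(HSPRecord(hsp.position, hsp.ref_base, valid))
        else:
            dropped += 1
    if dropped:
        logger.info("HSP validation dropped %d of %d positions", dropped, len(hsps))
    return out


def validate_sbss(
    sbss: Sequence[SBSRecord],
    cov: Optional[CoverageTable],
    cfg: PreprocessConfig,
) -> List[SBSRecord]:
    """Keep a substitution only when >= sbs_min_frac of that diploid's reads
    at the position support the substituted base."""
    if cov is None:
        return list(sbss)
    frac = _as_fraction(cfg.sbs_min_frac)
    out: List[SBSRecord] = []
    dropped = 0
    for sbs in sbss:
        total = cov.total(sbs.position)
        if total == 0:
            dropped += 1
            continue
        if Fraction(cov.count(sbs.position, sbs.diploid_base)) >= frac * total:
            out.append(sbs)
        else:
            dropped += 1
    if dropped:
        logger.info("SBS validation dropped %d of %d records", dropped, len(sbss))
    return out


def discover_additional_hsps(
    sbs_by_diploid: Mapping[str, Sequence[SBSRecord]],
    extra_positions: Optional[Sequence[Tuple[GenomicPosition, str]]],
    polyploid_cov: CoverageTable,
    existing: Sequence[HSPRecord],
    cfg: PreprocessConfig,
) -> List[HSPRecord]:
    """Check diploid-substitution positions (and any user-supplied extra
    positions) for HSPs missed by the polyploid variant caller.

    A candidate becomes an HSP when at least two bases each reach
    hsp_min_frac of the polyploid reads there.  Returns existing + new,
    deduplicated by position.
    """
    known = {h.position for h in existing}
    candidates: Dict[GenomicPosition, str] = {}
    for records in sbs_by_diploid.values():
        for sbs in records:
            candidates.setdefault(sbs.position, sbs.ref_base)
    for position, ref_base in extra_positions or ():
        candidates.setdefault(position, ref_base)

    frac = _as_fraction(cfg.hsp_min_frac)
    added: List[HSPRecord] = []
    for position in sorted(set(candidates) - known):
        if polyploid_cov.total(position) == 0:
            continue
        valid = _passing_bases(polyploid_cov.counts(position), frac)
        if len(valid) >= 2:
            added.append(HSPRecord(position, candidates[position], valid))
    if added:
        logger.info("discovered %d additional HSPs at candidate positions", len(added))
    return list(existing) + added


def read_extra_positions(path: str) -> List[Tuple[GenomicPosition, str]]:
    """Tab-delimited seq_name, position, reference base."""
    out: List[Tuple[GenomicPosition, str]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            seq, pos_s, ref = line.split()[:3]
            out.append((GenomicPosition(seq, int(pos_s)), ref.upper()))
    return out


def build_diploid_profiles(
    sbs_by_diploid: Mapping[str, Sequence[SBSRecord]],
    coverage_by_diploid: Mapping[str, Optional[CoverageTable]],
    hsps: Sequence[HSPRecord],
    missing: Optional[str],
    cfg: PreprocessConfig,
) -> Dict[str, DiploidProfile]:
    """Base state of every diploid progenitor at every HSP position.

    Precedence at a position: '?' for the missing progenitor; the validated
    substitution base when one exists; otherwise, with a coverage table,
    '0' (no reads), '<' (fewer than min_diploid_coverage reads), '*'
    (ambiguous: two or more bases above ambiguous_min_frac) or the majority
    base; without a coverage table, the reference base (the diploid is
    assumed reference-like wherever it reported no substitution).
    """
    labels = list(sbs_by_diploid)
    if missing is not None:
        if missing in labels:
            raise ValueError(f"missing progenitor {missing!r} also has an SBS list")
        labels.append(missing)

    amb_frac = _as_fraction(cfg.ambiguous_min_frac)
    profiles: Dict[str, DiploidProfile] = {}
    for label in labels:
        if label == missing:
            profiles[label] = DiploidProfile(
                label, {h.position: MISSING for h in hsps}, is_missing=True
            )
            continue
        sbs_at = {s.position: s.diploid_base for s in sbs_by_diploid[label]}
        cov = coverage_by_diploid.get(label)
        base_at: Dict[GenomicPosition, str] = {}
        for hsp in hsps:
            position = hsp.position
            sbs_base = sbs_at.get(position)
            if sbs_base is not None:
                base_at[position] = sbs_base
            elif cov is not None:
                counts = cov.counts(position)
                total = sum(counts.values())
                if total == 0:
                    base_at[position] = NO_COVERAGE
                elif total < cfg.min_diploid_coverage:
                    base_at[position] = LOW_COVERAGE
                else:
                    high = [b for b in BASES if Fraction(counts[b]) >= amb_frac * total]
                    if len(high) >= 2:
                        base_at[position] = AMBIGUOUS
                    else:
                        base_at[position] = max(BASES, key=lambda b: counts[b])
            else:
                base_at[position] = hsp.ref_base
        profiles[label] = DiploidProfile(label, base_at)
    return profiles
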