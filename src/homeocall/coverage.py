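"""Per-position, per-base coverage counting from filtered fragments.

Counting is fragment-level: a fused read pair contributes at most one count
per position, and positions where the two mates disagreed contribute
nothing (they were dropped during fragment fusion).  This keeps the
denominators used for HSP/SBS validation in the same unit as base-pattern
support.
"""

from __future__ import annotations

from typing import Dict, Iterable, Optional, Set

import numpy as np

from .types import AlignedFragment, CoverageTable, GenomicPosition


def compute_base_coverage(
    fragments: Iterable[AlignedFragment],
    restrict_to: Optional[Set[GenomicPosition]] = None,
) -> CoverageTable:
    """Tally fragment bases per position.

    ``restrict_to`` limits the output to the requested positions (a position
    requested but never covered is simply absent, i.e. zero coverage).
    """
    # dense per-sequence accumulation keyed by (seq, pos) extent
    acc: Dict[str, Dict[int, np.ndarray]] = {}
    for frag in fragments:
        per_seq = acc.setdefault(frag.seq_name, {})
        for pos, code in zip(frag.positions.tolist(), frag.base_codes.tolist()):
            vec = per_seq.get(pos)
            if vec is None:
                vec = np.zeros(4, dtype=np.int64)
                per_seq[pos] = vec
            vec[code] += 1
    table = CoverageTable()
    for seq_name, per_seq in acc.items():
        for pos, vec in per_seq.items():
            key = GenomicPosition(seq_name, pos)
            if restrict_to is not None and key not in restrict_to:
                continue
            table.set_counts(key, vec)
    return table
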