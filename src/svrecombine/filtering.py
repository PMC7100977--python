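"""Coverage-calibrated support thresholds and the disjointness filter.

Fixed support cutoffs behave badly across coverages, so the minimum number
of supporting fragments is derived from the dataset's fold-coverage by
piecewise-linear interpolation over a pinned anchor table (calibrated so
that 25x coverage yields the (PE, SR, mixed) triple (4, 4, 4), monotone in
coverage, floored at 3).

The disjointness filter then performs a greedy set cover over variant maps:
the variant with the most *unique* (unshared) supporting fragments is
accepted when that unique count meets its class threshold, its fragments
are struck from every remaining map, and the process repeats. Thresholds
apply to integrated variant blocks, never to individual clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .consolidation import IntegratedVariant

#: coverage -> support threshold anchors; interpolated linearly in between
DEFAULT_ANCHOR_TABLE: dict[float, int] = {5: 3, 10: 3, 25: 4, 50: 5, 100: 6}
DEFAULT_SUPPORT_FLOOR = 3


@dataclass(frozen=True)
class SupportThresholds:
    pe: int
    sr: int
    mixed: int
    coverage: float

    def for_class(self, support: str) -> int:
        return {"PE": self.pe, "SR": self.sr, "mixed": self.mixed}[support]


def support_threshold(coverage: float,
                      anchor_table: Mapping[float, int] | None = None,
                      floor: int = DEFAULT_SUPPORT_FLOOR) -> SupportThresholds:
    """Dynamic (PE, SR, mixed) support thresholds at the given coverage."""
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    table = dict(anchor_table or DEFAULT_ANCHOR_TABLE)
    xs = sorted(table)
    ys = [table[x] for x in xs]
    val = float(np.interp(coverage, xs, ys))
    t = max(int(np.floor(val + 0.5)), floor)
    return SupportThresholds(pe=t, sr=t, mixed=t, coverage=coverage)


def disjointness_filter(variants: Iterable[IntegratedVariant],
                        thresholds: SupportThresholds
                        ) -> tuple[list[IntegratedVariant], list[IntegratedVariant]]:
    """Greedy disjoint set cover over variant maps.

    Returns ``(passing, rejected)``. Passing variants have pairwise disjoint
    variant maps; output is independent of input order (ties break on unique
    support count, then leading coordinate, then type).
    """
    candidates = sorted(variants, key=lambda v: v.sort_key())
    passing: list[IntegratedVariant] = []
    rejected: list[IntegratedVariant] = []

    while candidates:
        uniques = []
        for v in candidates:
            others: set[str] = set()
            for o in candidates:
                if o is not v:
                    others |= o.variant_map
            uniques.append(len(v.variant_map - others))
        # highest unique count wins; ties break to the earliest coordinate
        best_i = min(range(len(candidates)),
                     key=lambda i: (-uniques[i], candidates[i].sort_key()))
        v = candidates.pop(best_i)
        if uniques[best_i] >= thresholds.for_class(v.support):
            passing.append(v)
            for o in candidates:
                o.variant_map -= v.variant_map
        else:
            rejected.append(v)
    passing.sort(key=lambda v: v.sort_key())
    rejected.sort(key=lambda v: v.sort_key())
    return passing, rejected
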