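"""Interval overlap semantics, Venn counts, and the full-overlap tier.

Two features overlap iff they share at least one base (same chromosome,
``max(starts) < min(ends)``); strand is always ignored, as histone peaks are
unstranded. Overlap counting is per source interval, never per merged region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome import GenomicInterval

logger = logging.getLogger(__name__)


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff a and b share >= 1 base. Strand is ignored."""
    return a.chrom == b.chrom and max(a.start, b.start) < min(a.end, b.end)


def intersection_length(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


class _ChromIndex:
    """Sorted-array overlap index for one chromosome.

    ``starts`` sorted ascending with a running maximum of ``ends`` allows an
    O(log n) any-overlap query; retrieval scans the candidate slice.
    """

    def __init__(self, intervals: Sequence[GenomicInterval]):
        order = sorted(range(len(intervals)), key=lambda i: intervals[i].start)
        self.intervals = [intervals[i] for i in order]
        self.starts = np.array([iv.start for iv in self.intervals], dtype=np.int64)
        ends = np.array([iv.end for iv in self.intervals], dtype=np.int64)
        self.ends = ends
        self.prefix_max_end = np.maximum.accumulate(ends) if len(ends) else ends

    def any_overlap(self, start: int, end: int) -> bool:
        idx = int(np.searchsorted(self.starts, end, side="left"))
        if idx == 0:
            return False
        return bool(self.prefix_max_end[idx - 1] > start)

    def query(self, start: int, end: int) -> list[GenomicInterval]:
        idx = int(np.searchsorted(self.starts, end, side="left"))
        return [iv for iv in self.intervals[:idx] if iv.end > start]


@dataclass
class FeatureSet:
    """A labelled set of intervals (one histone mark's peaks, CpG islands...).

    Intervals are stored as given (no silent merging), sorted by
    (chrom, start, end).
    """

    label: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(
            self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        self._index: dict[str, _ChromIndex] = {}
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            self._index[chrom] = _ChromIndex(ivs)

    def __len__(self) -> int:
        return len(self.intervals)

    def overlaps_region(self, region: GenomicInterval) -> bool:
        idx = self._index.get(region.chrom)
        return idx.any_overlap(region.start, region.end) if idx else False

    def overlapping(self, region: GenomicInterval) -> list[GenomicInterval]:
        idx = self._index.get(region.chrom)
        return idx.query(region.start, region.end) if idx else []


def count_overlapping(a_set: FeatureSet, b_set: FeatureSet) -> tuple[int, int]:
    """Count a-intervals overlapping >=1 b-interval, with a rounded percent.

    Returns ``(count, percent)`` where percent = round(100 * count / |A|) for
    reporting; an empty A yields (0, 0) with a warning.
    """
    if len(a_set) == 0:
        logger.warning("count_overlapping: empty query set %r", a_set.label)
        return 0, 0
    count = sum(1 for iv in a_set.intervals if b_set.overlaps_region(iv))
    percent = int(round_half_away(100.0 * count / len(a_set)))
    return count, percent


def round_half_away(x: float) -> float:
    """Round to nearest integer, ties away from zero (reporting convention)."""
    return float(np.floor(abs(x) + 0.5) * np.sign(x)) if x else 0.0


def cooccurs_at(
    region: GenomicInterval, sets: Sequence[FeatureSet]
) -> dict[str, bool]:
    """Per-set boolean: does the region overlap >=1 interval of that set."""
    return {s.label: s.overlaps_region(region) for s in sets}


def full_overlap_tier(region: GenomicInterval, sets: Sequence[FeatureSet]) -> bool:
    """Strict co-occurrence: the selected peaks fully nest at this region.

    For each set, select the peak whose intersection with the region is
    longest. Returns True iff the shortest selected peak is contained in every
    other selected peak — equivalently, the length of the selected peaks'
    common intersection equals the shortest selected peak's length. Returns
    False when any set has no overlapping peak.
    """
    selected: list[GenomicInterval] = []
    for s in sets:
        hits = s.overlapping(region)
        if not hits:
            return False
        best = max(hits, key=lambda iv: (intersection_length(iv, region), -len(iv)))
        selected.append(best)
    lo = max(iv.start for iv in selected)
    hi = min(iv.end for iv in selected)
    shortest = min(len(iv) for iv in selected)
    return max(0, hi - lo) == shortest


@dataclass
class VennCounts:
    """Per-set totals, ordered pairwise overlap counts, and triple counts.

    ``pairwise[(A, B)]`` is the number of A-intervals overlapping >= 1
    B-interval (counts of source intervals, not merged regions);
    ``triple[A]`` is the number of A-intervals overlapping >= 1 interval of
    each of the other two sets.
    """

    totals: dict[str, int]
    pairwise: dict[tuple[str, str], int]
    triple: dict[str, int]

    def to_json_dict(self) -> dict:
        return {
            "totals": self.totals,
            "pairwise": {f"{a}|{b}": v for (a, b), v in self.pairwise.items()},
            "triple": self.triple,
        }


def venn_counts(sets: Sequence[FeatureSet]) -> VennCounts:
    """All ordered pairwise and per-set triple co-occurrence counts."""
    if len(sets) != 3:
        raise ValueError("venn_counts requires exactly 3 feature sets")
    totals = {s.label: len(s) for s in sets}
    pairwise: dict[tuple[str, str], int] = {}
    triple: dict[str, int] = {}
    for a in sets:
        others = [s for s in sets if s is not a]
        for b in others:
            pairwise[(a.label, b.label)], _ = count_overlapping(a, b)
        triple[a.label] = sum(
            1
            for iv in a.intervals
            if all(o.overlaps_region(iv) for o in others)
        )
    return VennCounts(totals=totals, pairwise=pairwise, triple=triple)
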