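"""Shared primitives: genomic intervals, reciprocal overlap, seeded RNG streams.

All coordinates are 0-based half-open internally; conversion to 1-based
happens only at VCF boundaries (see :mod:`svharmonize.io`).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

SV_TYPES = ("DEL", "INS", "DUP", "INV")


def derive_rng(seed: int, label: str) -> np.random.Generator:
    """Labeled RNG substream: independent of call order across modules.

    The stream is keyed by (seed, crc32(label)) so two generators with the
    same seed but different labels never share state.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), zlib.crc32(label.encode())]))


@dataclass
class SVCall:
    """One structural variant as a half-open interval on a chromosome.

    ``length`` is the positive magnitude of the event; for insertions the
    interval is a point anchor (start == end) and ``length`` carries the
    inserted size. ``truth_id`` retains planted-truth linkage for scoring on
    synthetic data and is never consulted by the method itself.
    """

    chrom: str
    start: int
    end: int
    svtype: str
    source: str = ""
    genotype: str | None = None
    length: int | None = None
    id: str | None = None
    truth_id: str | None = None
    haplotype: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise ValueError(f"unknown SV type {self.svtype!r}")
        if self.end < self.start:
            raise ValueError("end < start")
        if self.length is None:
            self.length = self.end - self.start

    @property
    def span(self) -> int:
        return self.end - self.start

    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


def overlap_len(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def reciprocal_overlap(a: tuple[str, int, int], b: tuple[str, int, int]) -> tuple[float, float]:
    """Fraction of each interval covered by the intersection.

    Returns (|a∩b|/|a|, |a∩b|/|b|); (0, 0) for different chromosomes.
    A pair "passes RO t" when min of the two fractions exceeds t.
    """
    if a[0] != b[0]:
        return (0.0, 0.0)
    inter = overlap_len(a[1], a[2], b[1], b[2])
    la, lb = a[2] - a[1], b[2] - b[1]
    if la <= 0 or lb <= 0:
        return (0.0, 0.0)
    return (inter / la, inter / lb)


def ro_pass(a: tuple[str, int, int], b: tuple[str, int, int], ro_min: float, strict: bool = True) -> bool:
    fa, fb = reciprocal_overlap(a, b)
    m = min(fa, fb)
    return m > ro_min if strict else m >= ro_min


class UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra

    def groups(self) -> list[list[int]]:
        out: dict[int, list[int]] = {}
        for i in range(len(self.parent)):
            out.setdefault(self.find(i), []).append(i)
        return list(out.values())


def chain_by_ro(intervals: Sequence[tuple[str, int, int]], ro_min: float = 0.5, strict: bool = True) -> list[list[int]]:
    """Single-linkage clusters over the reciprocal-overlap graph.

    Sweep over start-sorted intervals per chromosome; since an RO partner at
    threshold > 0 must overlap, only overlapping pairs are examined.
    """
    n = len(intervals)
    uf = UnionFind(n)
    order = sorted(range(n), key=lambda i: (intervals[i][0], intervals[i][1]))
    active: list[int] = []
    for idx in order:
        chrom, start, _ = intervals[idx]
        active = [j for j in active if intervals[j][0] == chrom and intervals[j][2] > start]
        for j in active:
            if ro_pass(intervals[idx], intervals[j], ro_min, strict=strict):
                uf.union(idx, j)
        active.append(idx)
    return uf.groups()


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort and merge overlapping/adjacent half-open intervals."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def interval_distance(a: tuple[str, int, int], b: tuple[str, int, int]) -> float:
    """Gap between two half-open intervals; 0 when they touch or overlap."""
    if a[0] != b[0]:
        return float("inf")
    if a[1] < b[2] and b[1] < a[2]:
        return 0.0
    return float(max(a[1], b[1]) - min(a[2], b[2]))


def covered_bases(interval: tuple[int, int], track: Sequence[tuple[int, int]]) -> int:
    """Bases of ``interval`` covered by a sorted, merged track."""
    s, e = interval
    return sum(overlap_len(s, e, ts, te) for ts, te in track if te > s and ts < e)
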