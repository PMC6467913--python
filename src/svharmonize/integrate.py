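"""Cross-platform inversion unification.

Five discovery callsets (Illumina WGS, long-insert WGS, PacBio, Bionano
optical maps, Strand-seq) see different slices of the inversion size
spectrum. Calls become *supported* in one of three ways: a >50% reciprocal
overlap with a call from an independent platform (intersection test),
re-genotyping in the Strand-seq composite file, or — Strand-seq only —
phase-data classification. Supported calls merge into non-redundant unified
loci carrying an outer interval (InvR, the outermost bounds), inner
breakpoints (the consensus region covered by at least half of the
overlapping predictions), a majority consensus genotype, and a simple /
complex class; pericentric loci and loci almost fully inside tandem repeats
are removed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .core import chain_by_ro, merge_intervals, overlap_len, reciprocal_overlap
from .strandseq import (
    EmptyLocusError,
    GenotypedInversion,
    SegmentationParams,
    compute_read_ratio,
    genotype_locus,
)

__all__ = [
    "PlatformCall",
    "UnifiedInversion",
    "reciprocal_overlap",
    "intersection_test",
    "regenotype_test",
    "sts_phase_support",
    "tandem_repeat_fraction",
    "unify_inversions",
]

PLATFORMS = ("IL", "PB", "liWGS", "BNG", "StS")


@dataclass
class PlatformCall:
    platform: str
    chrom: str
    start: int
    end: int
    genotype: str | None = None  # het | hom
    cls: str | None = None  # simple | complex (Strand-seq classification)
    phase: str | None = None
    cn_flag: bool = False  # external copy-number flag (complex evidence)
    id: str | None = None

    def __post_init__(self) -> None:
        if self.end - self.start <= 0:
            raise ValueError("interval length must be > 0")

    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class SupportedCall:
    call: PlatformCall
    source: str  # intersection | sts_genotype | sts_phase
    partners: list[PlatformCall] = field(default_factory=list)


@dataclass
class UnifiedInversion:
    chrom: str
    invr_start: int
    invr_end: int
    inner_start: int
    inner_end: int
    support_sources: frozenset
    platforms: frozenset
    consensus_genotype: str  # het | hom | ambiguous
    cls: str  # simple | complex

    def __post_init__(self) -> None:
        if not (self.invr_start <= self.inner_start <= self.inner_end <= self.invr_end):
            raise ValueError("inner breakpoints must lie within InvR")
        if not self.support_sources:
            raise ValueError("support_sources must be non-empty")

    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.invr_start, self.invr_end)


def intersection_test(
    callsets: dict[str, list[PlatformCall]], ro_min: float = 0.5
) -> list[SupportedCall]:
    """Calls supported by >ro_min reciprocal overlap across two platforms.

    A call is supported iff some call from a *different* platform reciprocally
    overlaps it (both fractions above the threshold); partners are recorded.
    """
    if len(callsets) < 2:
        raise ValueError("intersection test needs >= 2 platforms")
    pool = [c for calls in callsets.values() for c in calls]
    out: list[SupportedCall] = []
    for c in pool:
        partners = [
            o
            for o in pool
            if o.platform != c.platform
            and min(*reciprocal_overlap(c.interval(), o.interval())) > ro_min
        ]
        if partners:
            out.append(SupportedCall(c, "intersection", partners))
    return out


def regenotype_test(
    calls: list[PlatformCall],
    composite: pd.DataFrame,
    params: SegmentationParams | None = None,
    min_reads: int = 25,
) -> tuple[list[SupportedCall], list[PlatformCall], list[PlatformCall]]:
    """Re-genotype platform calls in a Strand-seq composite file.

    Each locus is genotyped with the exact-binomial model comparison at a
    reduced ``min_reads`` threshold; calls genotyped het or hom_inv are
    supported, hom_ref refuted, and loci with too few reads ungenotyped
    (neither supported nor refuted, recorded separately).
    """
    params = params or SegmentationParams()
    supported: list[SupportedCall] = []
    refuted: list[PlatformCall] = []
    ungenotyped: list[PlatformCall] = []
    for call in calls:
        try:
            locus = compute_read_ratio(composite, call.chrom, call.start, call.end)
        except EmptyLocusError:
            ungenotyped.append(call)
            continue
        g = genotype_locus(locus.n_ref, locus.n_nonref, params, min_reads=min_reads)
        if g.genotype in ("het", "hom_inv"):
            supported.append(SupportedCall(call, "sts_genotype"))
        elif g.genotype == "hom_ref":
            refuted.append(call)
        else:
            ungenotyped.append(call)
    return supported, refuted, ungenotyped


def sts_phase_support(inversions: list[GenotypedInversion]) -> list[SupportedCall]:
    """Strand-seq inversions whose phase data classified them (simple/complex)."""
    out: list[SupportedCall] = []
    for inv in inversions:
        if inv.cls == "unclassified":
            continue
        chrom, start, end = inv.interval()
        call = PlatformCall(
            "StS",
            chrom,
            start,
            end,
            genotype="hom" if inv.genotype == "hom_inv" else "het",
            cls="complex" if inv.cls == "complex" else "simple",
            phase=inv.phase,
        )
        out.append(SupportedCall(call, "sts_phase"))
    return out


def tandem_repeat_fraction(
    interval: tuple[str, int, int], tr_track: dict[str, list[tuple[int, int]]] | list[tuple[int, int]]
) -> float:
    """Fraction of an interval's bases covered by the tandem-repeat track."""
    chrom, start, end = interval
    if end <= start:
        raise ValueError("interval must be non-empty")
    track = tr_track.get(chrom, []) if isinstance(tr_track, dict) else tr_track
    track = merge_intervals(track)
    covered = sum(overlap_len(start, end, s, e) for s, e in track)
    return covered / (end - start)


def _consensus_region(preds: list[tuple[int, int]]) -> tuple[int, int]:
    """Bounding span of bases covered by at least half of the predictions."""
    m = len(preds)
    events: list[tuple[int, int]] = []
    for s, e in preds:
        events.append((s, 1))
        events.append((e, -1))
    events.sort()
    depth = 0
    lo, hi = None, None
    for i, (x, d) in enumerate(events):
        depth += d
        nxt = events[i + 1][0] if i + 1 < len(events) else x
        if 2 * depth >= m and nxt > x:
            if lo is None:
                lo = x
            hi = nxt
    if lo is None:  # cannot happen for non-empty predictions, kept defensive
        return min(s for s, _ in preds), max(e for _, e in preds)
    return lo, hi


def unify_inversions(
    intersection_supported: list[SupportedCall],
    regenotype_supported: list[SupportedCall],
    sts_phase_supported: list[SupportedCall],
    genome=None,
    ro_min: float = 0.5,
    tr_max: float = 0.9,
) -> list[UnifiedInversion]:
    """Merge the three supported inversion lists into a non-redundant set.

    Events chain into loci by >ro_min reciprocal overlap (single linkage).
    InvR spans the outermost bounds; with more than one distinct prediction
    the inner breakpoints bound the region covered by at least half of the
    overlapping predictions, otherwise they match InvR. The consensus
    genotype is the strict majority over discovery platforms (each platform
    one vote), else "ambiguous". Loci overlapping a centromere (pericentric)
    or with tandem-repeat fraction > tr_max are removed; a locus is complex
    when a supporting Strand-seq call is complex or a copy-number flag is
    set. The result is independent of input list order.
    """
    entries = list(intersection_supported) + list(regenotype_supported) + list(sts_phase_supported)
    if not entries:
        return []
    entries.sort(key=lambda s: (s.call.chrom, s.call.start, s.call.end, s.call.platform, s.source))
    groups = chain_by_ro([s.call.interval() for s in entries], ro_min, strict=True)
    out: list[UnifiedInversion] = []
    for grp in groups:
        members = [entries[i] for i in grp]
        chrom = members[0].call.chrom
        invr = (min(m.call.start for m in members), max(m.call.end for m in members))
        preds = sorted({(m.call.start, m.call.end) for m in members})
        if len(preds) > 1:
            inner = _consensus_region(preds)
        else:
            inner = invr
        sources = frozenset(m.source for m in members)
        platforms = frozenset(m.call.platform for m in members)
        votes: list[str] = []
        for platform in sorted(platforms):
            gts = [m.call.genotype for m in members if m.call.platform == platform and m.call.genotype]
            if not gts:
                continue
            counts = Counter(gts)
            top = counts.most_common()
            if len(top) > 1 and top[0][1] == top[1][1]:
                continue  # platform-internal tie contributes no vote
            votes.append(top[0][0])
        if votes:
            counts = Counter(votes)
            top = counts.most_common()
            consensus = "ambiguous" if len(top) > 1 and top[0][1] == top[1][1] else top[0][0]
        else:
            consensus = "ambiguous"
        cls = "complex" if any(
            m.call.cls == "complex" or m.call.cn_flag for m in members
        ) else "simple"
        if genome is not None:
            cen = genome.centromere_intervals.get(chrom)
            if cen and overlap_len(invr[0], invr[1], cen[0], cen[1]) > 0:
                continue
            tr = genome.tandem_repeat_track.get(chrom, [])
            if tandem_repeat_fraction((chrom, invr[0], invr[1]), tr) > tr_max:
                continue
        out.append(
            UnifiedInversion(chrom, invr[0], invr[1], inner[0], inner[1], sources, platforms, consensus, cls)
        )
    out.sort(key=lambda u: (u.chrom, u.invr_start, u.invr_end))
    return out
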