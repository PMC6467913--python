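"""Long-read-side SV calculus: haplotype assignment, contig merging,
read-support / optical-map / depth validation, haplotype and cross-method
merging, and three-way (IL/PB/BNG) integration.

All per-read alignment is abstracted away: this module consumes support
counts, optical-map lengths and coverage profiles (see SupportEvidence) and
applies the decision rules; the synthetic module produces the evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import networkx as nx
import numpy as np

from .core import SVCall, interval_distance, merge_intervals, overlap_len, reciprocal_overlap
from .consensus import length_concordance


@dataclass
class ReadObservation:
    """SNV incidences of one read: (snv position, matches H1?, error prob q)."""

    read_id: str
    observations: list[tuple[int, bool, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for _, _, q in self.observations:
            if not 0.0 < q < 1.0:
                raise ValueError("base error probability must lie in (0, 1)")


@dataclass
class LocalAssembly:
    id: str
    chrom: str
    start: int
    end: int
    haplotype: str = "H1"  # H1 | H2 | autozygous

    def __post_init__(self) -> None:
        if self.end - self.start <= 0:
            raise ValueError("assembly interval length must be > 0")

    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass
class SupportEvidence:
    """Evidence for one call: alt-supporting reads (alignments >= 1.5 kb only),
    an optical-map event length when matched, and a coverage profile over the
    call's interval plus flanks (``profile_start`` anchors the array)."""

    call_id: str
    alt_support_reads: int = 0
    bng_length: int | None = None
    depth_profile: np.ndarray | None = None
    profile_start: int = 0

    def __post_init__(self) -> None:
        if self.alt_support_reads < 0:
            raise ValueError("support count must be >= 0")


@dataclass
class PanSVRecord:
    representative: SVCall
    provenance: frozenset
    members: list[SVCall]
    validation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValueError("provenance must be non-empty")


def assign_read_haplotype(obs: ReadObservation, qv_threshold: float = 10.0) -> str:
    """Assign a read to H1/H2 from its SNV incidences, or call it ambiguous.

    Haplotype scores are products over SNVs of (1 - q_i) for a matching base
    and q_i for a mismatching base, computed in log10 space. The read goes to
    the higher-scoring haplotype iff the phred-scaled gap 10*|log10 S1/S2|
    exceeds ``qv_threshold``; reads spanning no SNV are ambiguous.
    """
    if not obs.observations:
        return "ambiguous"
    s1 = 0.0
    s2 = 0.0
    for _, matches_h1, q in obs.observations:
        if matches_h1:
            s1 += math.log10(1.0 - q)
            s2 += math.log10(q)
        else:
            s1 += math.log10(q)
            s2 += math.log10(1.0 - q)
    gap = 10.0 * abs(s1 - s2)
    if gap <= qv_threshold:
        return "ambiguous"
    return "H1" if s1 > s2 else "H2"


def merge_local_assemblies(
    assemblies: Sequence[LocalAssembly],
    max_gap: int = 100_000,
    min_overlap: int = 10_000,
    overlaps: dict[tuple[str, str], int] | None = None,
) -> list[list[LocalAssembly]]:
    """Merge tiled local assemblies into contig paths via a genomic-order DAG.

    Vertices are local assemblies; an edge connects u -> v when v follows u in
    genomic order, their regions are separated by at most ``max_gap`` bp, and
    their overlap alignment is at least ``min_overlap`` bp. Overlap defaults
    to the genomic interval overlap; an explicit alignment-overlap map keyed
    by (u.id, v.id) overrides it. Per weakly connected component, the contig
    is the path maximizing total spanned (union) length.
    """
    n = len(assemblies)
    order = sorted(range(n), key=lambda i: (assemblies[i].chrom, assemblies[i].start, assemblies[i].end, assemblies[i].id))
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    for ii, i in enumerate(order):
        a = assemblies[i]
        for j in order[ii + 1 :]:
            b = assemblies[j]
            if b.chrom != a.chrom:
                break
            if b.start - a.end > max_gap:
                break  # sorted by start: every later assembly is even further away
            ov = overlap_len(a.start, a.end, b.start, b.end)
            if overlaps is not None and (a.id, b.id) in overlaps:
                ov = overlaps[(a.id, b.id)]
            if b.start - a.end <= max_gap and ov >= min_overlap:
                g.add_edge(i, j)
    if not nx.is_directed_acyclic_graph(g):
        raise RuntimeError("assembly graph has a cycle despite genomic-order edges")
    contigs: list[list[LocalAssembly]] = []
    for comp in nx.weakly_connected_components(g):
        sub = g.subgraph(comp)
        topo = list(nx.topological_sort(sub))
        best: dict[int, float] = {}
        pred: dict[int, int | None] = {}
        for v in topo:
            best[v] = float(assemblies[v].end - assemblies[v].start)
            pred[v] = None
            for u in sub.predecessors(v):
                ov = overlap_len(assemblies[u].start, assemblies[u].end, assemblies[v].start, assemblies[v].end)
                cand = best[u] + (assemblies[v].end - assemblies[v].start) - ov
                if cand > best[v] + 1e-9:
                    best[v] = cand
                    pred[v] = u
        tail = max(topo, key=lambda v: (best[v], -assemblies[v].start))
        path: list[int] = []
        cur: int | None = tail
        while cur is not None:
            path.append(cur)
            cur = pred[cur]
        path.reverse()
        contigs.append([assemblies[i] for i in path])
    contigs.sort(key=lambda p: (p[0].chrom, p[0].start))
    return contigs


@dataclass
class SVCluster:
    calls: list[SVCall]
    chrom: str
    eval_start: int
    eval_end: int


def cluster_svs_by_window(calls: Sequence[SVCall], window: int = 250, flank: int = 1000) -> list[SVCluster]:
    """Cluster SVs whose boundaries lie within ``window`` bp of each other.

    Single-linkage chaining on sorted calls; a link requires both start-start
    and end-end distances within the window. The cluster's evaluation interval
    runs from 1 kb upstream of the first variant to 1 kb downstream of the
    last variant's endpoint (deletions) or start point (insertions).
    """
    by_chrom: dict[str, list[SVCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    out: list[SVCluster] = []
    for chrom in sorted(by_chrom):
        cs = sorted(by_chrom[chrom], key=lambda c: (c.start, c.end))
        group: list[SVCall] = []
        for c in cs:
            if group and abs(c.start - group[-1].start) <= window and abs(c.end - group[-1].end) <= window:
                group.append(c)
            else:
                if group:
                    out.append(_finish_cluster(group, chrom, flank))
                group = [c]
        if group:
            out.append(_finish_cluster(group, chrom, flank))
    return out


def _finish_cluster(group: list[SVCall], chrom: str, flank: int) -> SVCluster:
    first = min(group, key=lambda c: c.start)
    last = max(group, key=lambda c: (c.start, c.end))
    end_anchor = last.end if last.svtype == "DEL" else last.start
    return SVCluster(list(group), chrom, max(0, first.start - flank), end_anchor + flank)


def pbrc_validate(evidence: SupportEvidence | None, min_support: int = 5) -> bool:
    """Read-support validation: more than ``min_support - 1`` alt-supporting
    alignments (default: > 4 reads). Missing evidence never validates."""
    if evidence is None:
        return False
    return evidence.alt_support_reads >= min_support


def fbn_match(
    pb_candidates: Sequence[SVCall],
    bng_length: int,
    f_max: float = 0.1,
    svtype: str | None = None,
) -> tuple[SVCall | None, float | None, bool]:
    """Optical-map length concordance: pick the single candidate minimizing
    f_BN = |L_BN - L_PB| / L_BN; validated iff f_BN < f_max (strict).

    Lengths are compared as magnitudes after type matching (the optical-map
    sign convention encodes insertion/deletion; pass ``svtype`` to restrict).
    """
    if bng_length <= 0:
        raise ValueError("L_BN must be > 0")
    cands = [c for c in pb_candidates if svtype is None or c.svtype == svtype]
    if not cands:
        return (None, None, False)
    fs = [abs(bng_length - abs(c.length)) / bng_length for c in cands]
    i = int(np.argmin(fs))
    return (cands[i], fs[i], fs[i] < f_max)


def depth_validate_deletion(
    depth_profile: np.ndarray, sv_len: int, max_min_cov: float = 30.0
) -> bool:
    """Depth validation of a deletion against a coverage profile.

    The genomic interval is scanned with a sliding window of the SV length;
    the candidate coverage is the minimum window mean; validated iff that
    minimum is strictly below ``max_min_cov``.
    """
    profile = np.asarray(depth_profile, dtype=float)
    if sv_len <= 0:
        raise ValueError("sv_len must be > 0")
    if len(profile) < sv_len:
        raise ValueError("depth profile shorter than the SV length")
    c = np.concatenate([[0.0], np.cumsum(profile)])
    means = (c[sv_len:] - c[:-sv_len]) / sv_len
    return bool(means.min() < max_min_cov)


def _gather_targets(query: SVCall, targets: Sequence[SVCall], max_dist: int = 1000) -> list[SVCall]:
    return [
        t
        for t in targets
        if t.svtype == query.svtype and interval_distance(query.interval(), t.interval()) <= max_dist
    ]


def max_concordance(query: SVCall, targets: Sequence[SVCall], max_dist: int = 1000) -> float:
    """Max length concordance over same-type targets within 1 kb of the query."""
    cands = _gather_targets(query, targets, max_dist)
    return max((length_concordance(query, t) for t in cands), default=0.0)


def il_concordance_filter(
    il_call: SVCall,
    pb_assembly_calls: Sequence[SVCall] = (),
    pb_read_calls: Sequence[SVCall] = (),
    pb_unfiltered_calls: Sequence[SVCall] = (),
    bng_calls: Sequence[SVCall] = (),
    depth_profile: SupportEvidence | None = None,
    dotplot_predicate: Callable[[SVCall], bool] | None = None,
    min_concordance: float = 0.5,
    read_concordance: float = 0.7,
    min_reads: int = 3,
    max_depth: float = 25.0,
    max_dist: int = 1000,
) -> bool:
    """A short-read call is concordant if any orthogonal condition holds:

    1. maximal length concordance with a PB assembly/unfiltered or BNG target
       is at least ``min_concordance`` (BNG targets match by interval overlap,
       since optical maps give position intervals rather than breakpoints);
    2. at least ``min_reads`` read-level PB calls reach ``read_concordance``;
    3. the call is a deletion and mean PB depth over its interval < ``max_depth``;
    4. a pluggable raw-read predicate (defaults to never-supported).
    """
    conds = il_concordance_conditions(
        il_call, pb_assembly_calls, pb_read_calls, pb_unfiltered_calls, bng_calls,
        depth_profile, dotplot_predicate, min_concordance, read_concordance,
        min_reads, max_depth, max_dist,
    )
    return any(conds.values())


def il_concordance_conditions(
    il_call: SVCall,
    pb_assembly_calls: Sequence[SVCall] = (),
    pb_read_calls: Sequence[SVCall] = (),
    pb_unfiltered_calls: Sequence[SVCall] = (),
    bng_calls: Sequence[SVCall] = (),
    depth_profile: SupportEvidence | None = None,
    dotplot_predicate: Callable[[SVCall], bool] | None = None,
    min_concordance: float = 0.5,
    read_concordance: float = 0.7,
    min_reads: int = 3,
    max_depth: float = 25.0,
    max_dist: int = 1000,
) -> dict[str, bool]:
    seq_targets = list(pb_assembly_calls) + list(pb_unfiltered_calls)
    c1 = max_concordance(il_call, seq_targets, max_dist) >= min_concordance
    if not c1:
        bng_over = [
            t
            for t in bng_calls
            if t.svtype == il_call.svtype
            and t.chrom == il_call.chrom
            and overlap_len(il_call.start, max(il_call.end, il_call.start + 1), t.start, max(t.end, t.start + 1)) > 0
        ]
        c1 = max((length_concordance(il_call, t) for t in bng_over), default=0.0) >= min_concordance
    reads = _gather_targets(il_call, pb_read_calls, max_dist)
    c2 = sum(1 for r in reads if length_concordance(il_call, r) >= read_concordance) >= min_reads
    c3 = False
    if il_call.svtype == "DEL" and depth_profile is not None and depth_profile.depth_profile is not None:
        s = il_call.start - depth_profile.profile_start
        e = il_call.end - depth_profile.profile_start
        if 0 <= s < e <= len(depth_profile.depth_profile):
            c3 = float(np.mean(depth_profile.depth_profile[s:e])) < max_depth
    c4 = bool(dotplot_predicate(il_call)) if dotplot_predicate is not None else False
    return {"concordance": c1, "read_support": c2, "depth": c3, "dotplot": c4}


@dataclass
class HaplotypeMergeResult:
    diploid_calls: list[SVCall]
    removed_loci: list[tuple[str, int, int]]
    removed_calls: list[SVCall]


def merge_haplotypes(
    h1_calls: Sequence[SVCall],
    h2_calls: Sequence[SVCall],
    tr_track: dict[str, list[tuple[int, int]]],
    ro_non_tr: float = 0.10,
    ro_tr: float = 0.50,
    max_cluster: int = 5,
    tr_pad: int = 20,
) -> HaplotypeMergeResult:
    """Merge per-haplotype callsets into diploid calls with genotypes.

    Tandem-repeat loci (padded by ``tr_pad`` bp to absorb under-annotation)
    hosting more than ``max_cluster`` SVs on either haplotype are set aside:
    their calls are removed from both haplotypes and the locus recorded.
    Remaining cross-haplotype pairs merge as homozygous (1/1) at a TR-aware
    reciprocal overlap threshold — a loose 0.10 outside tandem repeats, 0.50
    inside (breakpoints are well defined outside TRs but degenerate inside).
    Unmatched calls stay heterozygous (1/0 on H1, 0/1 on H2).
    """
    padded: dict[str, list[tuple[int, int]]] = {
        chrom: merge_intervals([(max(0, s - tr_pad), e + tr_pad) for s, e in ivs])
        for chrom, ivs in tr_track.items()
    }

    def in_tr(call: SVCall) -> bool:
        track = padded.get(call.chrom, [])
        s, e = call.start, max(call.end, call.start + 1)
        return any(overlap_len(s, e, ts, te) > 0 for ts, te in track)

    def tr_locus(call: SVCall) -> tuple[str, int, int] | None:
        for ts, te in padded.get(call.chrom, []):
            if overlap_len(call.start, max(call.end, call.start + 1), ts, te) > 0:
                return (call.chrom, ts, te)
        return None

    removed_loci: set[tuple[str, int, int]] = set()
    per_locus: dict[tuple[str, int, int], dict[str, int]] = {}
    for hap, calls in (("H1", h1_calls), ("H2", h2_calls)):
        for c in calls:
            loc = tr_locus(c)
            if loc is not None:
                per_locus.setdefault(loc, {"H1": 0, "H2": 0})[hap] += 1
    for loc, counts in per_locus.items():
        if counts["H1"] > max_cluster or counts["H2"] > max_cluster:
            removed_loci.add(loc)

    removed: list[SVCall] = []
    keep1: list[SVCall] = []
    keep2: list[SVCall] = []
    for hap, calls, keep in (("H1", h1_calls, keep1), ("H2", h2_calls, keep2)):
        for c in calls:
            loc = tr_locus(c)
            if loc is not None and loc in removed_loci:
                removed.append(c)
            else:
                keep.append(c)

    pairs: list[tuple[float, tuple, int, int]] = []
    for i, a in enumerate(keep1):
        for j, b in enumerate(keep2):
            if a.chrom != b.chrom or a.svtype != b.svtype:
                continue
            if a.svtype == "INS":
                # point anchors: pair insertions within the TR-aware window
                thr = ro_tr if (in_tr(a) or in_tr(b)) else ro_non_tr
                dist = abs(a.start - b.start)
                window = 250
                if dist > window:
                    continue
                lc = length_concordance(a, b)
                if lc < thr:
                    continue
                ro = lc
            else:
                fa, fb = reciprocal_overlap(a.interval(), b.interval())
                ro = min(fa, fb)
                thr = ro_tr if (in_tr(a) or in_tr(b)) else ro_non_tr
                if ro < thr:
                    continue
            key = (a.chrom, min(a.start, b.start), max(a.start, b.start), min(a.end, b.end), max(a.end, b.end))
            pairs.append((ro, key, i, j))
    pairs.sort(key=lambda p: (-p[0], p[1]))
    used1: set[int] = set()
    used2: set[int] = set()
    hom_pairs: list[tuple[int, int]] = []
    for ro, _, i, j in pairs:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        hom_pairs.append((i, j))

    diploid: list[SVCall] = []
    for i, j in hom_pairs:
        a, b = keep1[i], keep2[j]
        rep = SVCall(a.chrom, min(a.start, b.start), max(a.end, b.end), a.svtype, source=a.source,
                     genotype="1/1", length=max(a.length, b.length), id=a.id,
                     truth_id=a.truth_id or b.truth_id, meta={"partner": b.id})
        diploid.append(rep)
    for i, c in enumerate(keep1):
        if i not in used1:
            diploid.append(SVCall(c.chrom, c.start, c.end, c.svtype, source=c.source, genotype="1/0",
                                  length=c.length, id=c.id, truth_id=c.truth_id, haplotype="H1"))
    for j, c in enumerate(keep2):
        if j not in used2:
            diploid.append(SVCall(c.chrom, c.start, c.end, c.svtype, source=c.source, genotype="0/1",
                                  length=c.length, id=c.id, truth_id=c.truth_id, haplotype="H2"))
    diploid.sort(key=lambda c: (c.chrom, c.start, c.end))
    return HaplotypeMergeResult(diploid, sorted(removed_loci), removed)


def _same_window(a: SVCall, b: SVCall, window: int = 250) -> bool:
    return a.chrom == b.chrom and abs(a.start - b.start) <= window and abs(a.end - b.end) <= window


def unify_pb(
    phased_sv_calls: Sequence[SVCall],
    mspac_calls: Sequence[SVCall],
    evidence: dict[str, SupportEvidence],
    bng_events: Sequence[SVCall] = (),
    pbrc_min: int = 3,
    f_max: float = 0.1,
    mspac_min_dist: int = 10_000,
    dedup_window: int = 250,
) -> list[SVCall]:
    """Unified long-read callset from two assembly methods plus optical maps.

    Ordered inclusion: (a) optical-map-validated representatives — for each
    BNG event, the single Phased-SV or MS-PAC candidate minimizing f_BN is
    included when f_BN < ``f_max``, regardless of read support; (b) remaining
    Phased-SV calls with read support > ``pbrc_min``; (c) MS-PAC calls at
    least ``mspac_min_dist`` bp from any Phased-SV call. Calls landing in the
    same ``dedup_window`` bp boundary window as an already-included call are
    dropped; tier precedence is (a) > (b) > (c). Provenance is recorded in
    each call's ``meta``.
    """
    included: list[SVCall] = []

    def is_dup(c: SVCall) -> bool:
        return any(_same_window(c, x, dedup_window) for x in included)

    all_pb = list(phased_sv_calls) + list(mspac_calls)
    for bng in bng_events:
        cands = [
            c
            for c in all_pb
            if c.chrom == bng.chrom
            and overlap_len(c.start, max(c.end, c.start + 1), bng.start, max(bng.end, bng.start + 1)) > 0
        ]
        best, f, ok = fbn_match(cands, abs(bng.length), f_max=f_max, svtype=bng.svtype)
        if ok and best is not None and not is_dup(best):
            best.meta.update({"tier": "bng", "f_bn": f})
            included.append(best)
    for c in phased_sv_calls:
        ev = evidence.get(c.id)
        if ev is not None and ev.alt_support_reads > pbrc_min and not is_dup(c):
            c.meta.setdefault("tier", "phased_sv_pbrc")
            included.append(c)
    for c in mspac_calls:
        if c.meta.get("tier"):
            continue
        near = min(
            (interval_distance(c.interval(), p.interval()) for p in phased_sv_calls if p.chrom == c.chrom),
            default=float("inf"),
        )
        if near >= mspac_min_dist and not is_dup(c):
            c.meta.setdefault("tier", "mspac_distal")
            included.append(c)
    return sorted(included, key=lambda c: (c.chrom, c.start, c.end))


def build_pan_sv(
    il_filtered: Sequence[SVCall],
    bng_filtered: Sequence[SVCall],
    pb_unified: Sequence[SVCall],
    max_dist: int = 1000,
    min_concordance: float = 0.5,
) -> list[PanSVRecord]:
    """Three-way integration into a partition of provenance-tagged records.

    Concordant matches link calls across platforms (sequence callsets by
    breakpoint distance + length concordance; optical-map calls by interval
    overlap + length concordance). Connected components of the match graph
    become records; the representative is the PB variant when available, then
    IL, then BNG.
    """
    tagged: list[tuple[str, SVCall]] = (
        [("PB", c) for c in pb_unified] + [("IL", c) for c in il_filtered] + [("BNG", c) for c in bng_filtered]
    )
    g = nx.Graph()
    g.add_nodes_from(range(len(tagged)))
    for i in range(len(tagged)):
        pi, a = tagged[i]
        for j in range(i + 1, len(tagged)):
            pj, b = tagged[j]
            if pi == pj or a.svtype != b.svtype or a.chrom != b.chrom:
                continue
            if "BNG" in (pi, pj) and a.svtype != "INS":
                # optical maps give position intervals, not breakpoints
                if overlap_len(a.start, max(a.end, a.start + 1), b.start, max(b.end, b.start + 1)) <= 0:
                    continue
            elif interval_distance(a.interval(), b.interval()) > max_dist:
                continue
            if length_concordance(a, b) >= min_concordance:
                g.add_edge(i, j)
    pref = {"PB": 0, "IL": 1, "BNG": 2}
    records: list[PanSVRecord] = []
    for comp in nx.connected_components(g):
        members = sorted(comp, key=lambda k: (pref[tagged[k][0]], tagged[k][1].chrom, tagged[k][1].start))
        platforms = frozenset(tagged[k][0] for k in members)
        rep = tagged[members[0]][1]
        records.append(PanSVRecord(rep, platforms, [tagged[k][1] for k in members]))
    records.sort(key=lambda r: (r.representative.chrom, r.representative.start, r.representative.end))
    return records


def summarize_pan_sv(records: Sequence[PanSVRecord]):
    """Counts and mean lengths per provenance class and SV type (table-style)."""
    import pandas as pd

    rows = []
    for r in records:
        rows.append(
            {
                "svtype": r.representative.svtype,
                "provenance": ",".join(sorted(r.provenance)) if len(r.provenance) < 3 else "All",
                "length": r.representative.length,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    return (
        df.groupby(["svtype", "provenance"])
        .agg(count=("length", "size"), mean_length=("length", "mean"))
        .reset_index()
    )
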