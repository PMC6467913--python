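"""Breakpoint CI estimation/clustering and NCR combinations vs brute force."""

import numpy as np
import pytest

from svharmonize import consensus as cns
from svharmonize import synthetic as syn
from svharmonize.consensus import BreakpointCI
from svharmonize.core import SVCall


def bp(point, lo, hi, caller="c", side="left"):
    return BreakpointCI(caller, side, point, lo, hi)


class TestEstimateCI:
    def _gold(self, n=60, size=2000, gap=10_000):
        return [SVCall("chr1", i * gap, i * gap + size, "DEL", source="gold") for i in range(n)]

    def test_perfect_caller_has_zero_ci(self):
        gold = self._gold()
        calls = [SVCall(c.chrom, c.start, c.end, "DEL", source="x") for c in gold]
        ci = cns.estimate_breakpoint_ci({"x": calls}, gold)
        assert ci[("x", "left")] == (0, 0) and ci[("x", "right")] == (0, 0)

    def test_symmetric_offsets_recovered(self):
        gold = self._gold(n=90)
        offs = [-10, 0, 10] * 30
        calls = [
            SVCall(g.chrom, g.start + o, g.end + o, "DEL", source="x")
            for g, o in zip(gold, offs)
        ]
        ci = cns.estimate_breakpoint_ci({"x": calls}, gold)
        lo, hi = ci[("x", "left")]
        assert lo == pytest.approx(-10, abs=2) and hi == pytest.approx(10, abs=2)

    def test_gaussian_jitter_quantiles(self):
        # 10-90% band of N(0, 20) has half-width 1.2816 * 20 = 25.6
        rng = np.random.default_rng(42)
        gold = self._gold(n=500)
        calls = [
            SVCall(g.chrom, g.start + int(round(rng.normal(0, 20))), g.end + int(round(rng.normal(0, 20))),
                   "DEL", source="x")
            for g in gold
        ]
        ci = cns.estimate_breakpoint_ci({"x": calls}, gold)
        for side in ("left", "right"):
            lo, hi = ci[("x", side)]
            half = (hi - lo) / 2
            assert abs(half - 25.6) / 25.6 < 0.15

    def test_too_few_matches_falls_back_to_default(self):
        gold = self._gold(n=5)
        calls = [SVCall(g.chrom, g.start, g.end, "DEL", source="x") for g in gold]
        with pytest.warns(UserWarning, match="default CI"):
            ci = cns.estimate_breakpoint_ci({"x": calls}, gold, min_matches=30, default_ci=(-500, 500))
        assert ci[("x", "left")] == (-500, 500)


def oracle_cluster(bps):
    """Brute-force CI clustering: pairwise-overlap components, then per-bp
    coverage stacking with peak + right-neighbor candidate CIs."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(bps)))
    for i in range(len(bps)):
        for j in range(i + 1, len(bps)):
            if bps[i].lo <= bps[j].hi and bps[j].lo <= bps[i].hi:
                g.add_edge(i, j)
    clusters = []
    for comp in nx.connected_components(g):
        members = [bps[i] for i in sorted(comp)]
        lo = max(m.lo for m in members)
        hi = min(m.hi for m in members)
        if lo <= hi:
            clusters.append((members, (lo, hi)))
            continue
        xmin = min(m.lo for m in members)
        xmax = max(m.hi for m in members)
        cov = np.zeros(xmax - xmin + 1, dtype=int)
        for m in members:
            cov[m.lo - xmin : m.hi - xmin + 1] += 1
        # plateau runs of the per-bp coverage
        runs = []
        s = 0
        for x in range(1, len(cov) + 1):
            if x == len(cov) or cov[x] != cov[s]:
                runs.append((s + xmin, x - 1 + xmin, int(cov[s])))
                s = x
        peaks = []
        for i, (rs, re, rc) in enumerate(runs):
            lc = runs[i - 1][2] if i > 0 else -1
            rc2 = runs[i + 1][2] if i + 1 < len(runs) else -1
            if rc > lc and rc > rc2:
                peaks.append((rs, runs[i + 1][1] if i + 1 < len(runs) else re))
        sub = {k: [] for k in range(len(peaks))}
        for m in members:
            d = [max(pk[0] - m.point, m.point - pk[1], 0) for pk in peaks]
            sub[int(np.argmin(d))].append(m)
        for k, mem in sub.items():
            if not mem:
                continue
            slo = max(x.lo for x in mem)
            shi = min(x.hi for x in mem)
            clusters.append((mem, (slo, shi) if slo <= shi else peaks[k]))
    return clusters


def as_key(members):
    return sorted((m.caller, m.side, m.point, m.lo, m.hi) for m in members)


class TestClusterByCI:
    def test_common_intersection(self):
        clusters = cns.cluster_by_ci([bp(5, 0, 10), bp(10, 5, 15)])
        assert len(clusters) == 1
        assert clusters[0].ci == (5, 10)

    def test_singleton_cluster_keeps_own_ci(self):
        (c,) = cns.cluster_by_ci([bp(7, 2, 12)])
        assert c.ci == (2, 12) and c.consensus == 7

    def test_stacking_fallback_splits_group(self):
        bps = [bp(5, 0, 10), bp(14, 8, 20), bp(25, 18, 30)]
        clusters = cns.cluster_by_ci(bps)
        assert len(clusters) >= 2
        got = sorted(as_key(c.members) for c in clusters)
        want = sorted(as_key(m) for m, _ in oracle_cluster(bps))
        assert got == want

    def test_random_sets_match_oracle_and_partition(self):
        rng = np.random.default_rng(1234)
        for _ in range(150):
            n = int(rng.integers(1, 9))
            bps = []
            for i in range(n):
                p = int(rng.integers(0, 60))
                lo = p - int(rng.integers(0, 12))
                hi = p + int(rng.integers(0, 12))
                bps.append(bp(p, lo, hi, caller=f"c{i}"))
            clusters = cns.cluster_by_ci(bps)
            # partition of the input
            got_all = sorted(as_key([m for c in clusters for m in c.members]))
            assert got_all == sorted(as_key(bps))
            oracle = oracle_cluster(bps)
            assert sorted(as_key(c.members) for c in clusters) == sorted(as_key(m) for m, _ in oracle)
            ci_by_key = {tuple(as_key(c.members)): c.ci for c in clusters}
            for members, ci in oracle:
                assert ci_by_key[tuple(as_key(members))] == ci
            for c in clusters:
                lo = max(m.lo for m in c.members)
                hi = min(m.hi for m in c.members)
                if lo <= hi:
                    assert c.ci == (lo, hi)  # consensus CI subset of every member CI


class TestConsensusBreakpoint:
    @pytest.mark.parametrize("points,expected", [([100, 100, 105], 100), ([100, 105], 100), ([100], 100)])
    def test_mode_with_smallest_tiebreak(self, points, expected):
        assert cns.consensus_breakpoint(points) == expected

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            cns.consensus_breakpoint([])


class TestQCFilter:
    def _cc(self, start, end, callers=("a",), svtype="DEL"):
        members = [SVCall("chr1", start, end, svtype, source=c) for c in callers]
        return cns.ConsensusCall("chr1", start, end, svtype, members)

    def test_centromere_overlap_labeled(self):
        calls = [self._cc(1000, 2000)]
        cns.qc_filter(calls, {"chr1": [(1500, 3000)]})
        assert calls[0].label == "telomere_centromere"

    def test_oversize_labeled(self):
        calls = [self._cc(0, 2_000_000)]
        cns.qc_filter(calls, {})
        assert calls[0].label == "oversize"

    def test_singleton_overlapping_cluster_is_redundancy(self):
        cluster = self._cc(0, 1000, callers=("a", "b", "c"))
        singleton = self._cc(0, 600, callers=("d",))
        cns.qc_filter([cluster, singleton], {})
        assert cluster.label == "PASS"
        assert singleton.label == "redundancy"

    def test_plain_call_passes(self):
        calls = [self._cc(10_000, 12_000, callers=("a", "b"))]
        cns.qc_filter(calls, {"chr1": [(0, 100)]})
        assert calls[0].label == "PASS"


class TestLengthConcordance:
    @pytest.mark.parametrize("lq,lt,expected", [(100, 100, 1.0), (50, 100, 0.5), (70, 100, 0.7)])
    def test_ratio(self, lq, lt, expected):
        q = SVCall("chr1", 0, lq, "DEL")
        t = SVCall("chr1", 0, lt, "DEL")
        assert cns.length_concordance(q, t) == pytest.approx(expected)


class TestCombinations:
    def test_single_concordance_fraction(self):
        calls = [SVCall("chr1", i * 10_000, i * 10_000 + 500, "DEL", source="a", id=str(i)) for i in range(10)]
        oracle = lambda c: int(c.id) != 0  # noqa: E731
        res = cns.evaluate_combinations({"a": calls, "b": []}, oracle, max_k=2)
        (r,) = [x for x in res if x.n_calls == 10]
        assert r.ncr == pytest.approx(0.1)

    def test_disjoint_union_ncr_is_weighted_mean(self):
        a = [SVCall("chr1", i * 10_000, i * 10_000 + 500, "DEL", source="a", id=f"a{i}") for i in range(10)]
        b = [SVCall("chr2", i * 10_000, i * 10_000 + 500, "DEL", source="b", id=f"b{i}") for i in range(10)]
        oracle = lambda c: c.source == "a"  # noqa: E731  a: NCR 0, b: NCR 1
        (r,) = cns.evaluate_combinations({"a": a, "b": b}, oracle, max_k=2)
        assert r.n_calls == 20 and r.ncr == pytest.approx(0.5)

    def test_counts_nested(self, small_genome):
        truth = syn.plant_svs(small_genome, 120, ins_fraction=0.0, seed=21)
        profiles = [
            syn.CallerProfile("a", 0.7, 1.0, 10.0, detectable_types=("DEL",)),
            syn.CallerProfile("b", 0.6, 1.5, 20.0, detectable_types=("DEL",)),
            syn.CallerProfile("c", 0.5, 2.0, 40.0, detectable_types=("DEL",)),
        ]
        callsets = syn.simulate_caller_callsets(truth, profiles, small_genome, seed=21)
        res = cns.evaluate_combinations(callsets, lambda c: c.truth_id is not None)
        by_mode = {(r.mode, tuple(sorted(r.combo))): r for r in res}
        u3 = by_mode[("union3", ("a", "b", "c"))]
        t23 = by_mode[("two_of_three", ("a", "b", "c"))]
        assert u3.n_calls >= t23.n_calls
        for pair in (("a", "b"), ("a", "c"), ("b", "c")):
            assert u3.n_calls >= by_mode[("union2", pair)].n_calls
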