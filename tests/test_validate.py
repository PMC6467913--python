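"""Long-read validation calculus vs exhaustive/hand-computed oracles."""

import itertools
import math

import numpy as np
import pytest

from svharmonize import validate as val
from svharmonize.core import SVCall
from svharmonize.validate import LocalAssembly, ReadObservation, SupportEvidence


class TestReadHaplotype:
    def test_no_snvs_is_ambiguous(self):
        assert val.assign_read_haplotype(ReadObservation("r", [])) == "ambiguous"

    def test_three_matching_snvs_assign_h1(self):
        obs = ReadObservation("r", [(i, True, 0.01) for i in range(3)])
        assert val.assign_read_haplotype(obs) == "H1"

    def test_single_weak_snv_is_ambiguous(self):
        # phred gap = 10*log10(0.75/0.25) ~ 4.77 < 10
        obs = ReadObservation("r", [(0, True, 0.25)])
        assert val.assign_read_haplotype(obs) == "ambiguous"

    def test_swap_symmetry(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(1, 11))
            snvs = [(i, bool(rng.random() < 0.5), float(rng.uniform(0.001, 0.3))) for i in range(n)]
            a = val.assign_read_haplotype(ReadObservation("r", snvs))
            flipped = [(p, not m, q) for p, m, q in snvs]
            b = val.assign_read_haplotype(ReadObservation("r", flipped))
            assert {a, b} in ({"ambiguous"}, {"H1", "H2"}) or (a == "ambiguous" and b == "ambiguous")

    def test_matches_product_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(0, 11))
            snvs = [(i, bool(rng.random() < 0.5), float(rng.uniform(0.001, 0.45))) for i in range(n)]
            s1 = math.prod((1 - q) if m else q for _, m, q in snvs) if snvs else 1.0
            s2 = math.prod(q if m else (1 - q) for _, m, q in snvs) if snvs else 1.0
            if not snvs or 10 * abs(math.log10(s1 / s2)) <= 10:
                want = "ambiguous"
            else:
                want = "H1" if s1 > s2 else "H2"
            assert val.assign_read_haplotype(ReadObservation("r", snvs)) == want


def edges_oracle(assemblies, max_gap=100_000, min_overlap=10_000):
    out = set()
    for i, a in enumerate(assemblies):
        for j, b in enumerate(assemblies):
            if i == j or a.chrom != b.chrom:
                continue
            if (a.start, a.end, a.id) < (b.start, b.end, b.id):
                gap = b.start - a.end
                ov = max(0, min(a.end, b.end) - max(a.start, b.start))
                if gap <= max_gap and ov >= min_overlap:
                    out.add((i, j))
    return out


def union_length(path, assemblies):
    ivs = sorted((assemblies[i].start, assemblies[i].end) for i in path)
    total, cur_s, cur_e = 0, None, None
    for s, e in ivs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def best_path_by_enumeration(assemblies):
    """Exhaustive longest (max union length) path per weakly connected component."""
    import networkx as nx

    edges = edges_oracle(assemblies)
    g = nx.DiGraph()
    g.add_nodes_from(range(len(assemblies)))
    g.add_edges_from(edges)
    best = {}
    for comp in nx.weakly_connected_components(g):
        comp = sorted(comp)
        best_len = 0
        for start in comp:
            stack = [[start]]
            while stack:
                path = stack.pop()
                best_len = max(best_len, union_length(path, assemblies))
                for nxt in g.successors(path[-1]):
                    stack.append(path + [nxt])
        best[frozenset(comp)] = best_len
    return best


class TestMergeAssemblies:
    def test_overlapping_chain_forms_one_contig(self):
        tiles = [LocalAssembly(f"a{i}", "chr1", i * 40_000, i * 40_000 + 60_000) for i in range(3)]
        contigs = val.merge_local_assemblies(tiles)
        assert len(contigs) == 1 and [a.id for a in contigs[0]] == ["a0", "a1", "a2"]

    def test_distant_assemblies_stay_separate(self):
        a = LocalAssembly("a", "chr1", 0, 60_000)
        b = LocalAssembly("b", "chr1", 260_000, 320_000)
        assert len(val.merge_local_assemblies([a, b])) == 2

    def test_explicit_alignment_overlap_bridges_gap(self):
        a = LocalAssembly("a", "chr1", 0, 60_000)
        b = LocalAssembly("b", "chr1", 100_000, 160_000)
        assert len(val.merge_local_assemblies([a, b])) == 2
        contigs = val.merge_local_assemblies([a, b], overlaps={("a", "b"): 12_000})
        assert len(contigs) == 1

    def test_random_dags_match_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            n = int(rng.integers(2, 11))
            assemblies = []
            for i in range(n):
                s = int(rng.integers(0, 500)) * 1000
                L = int(rng.integers(30, 90)) * 1000
                assemblies.append(LocalAssembly(f"a{i}", "chr1", s, s + L))
            contigs = val.merge_local_assemblies(assemblies)
            oracle = best_path_by_enumeration(assemblies)
            idx = {a.id: i for i, a in enumerate(assemblies)}
            import networkx as nx

            g = nx.DiGraph()
            g.add_nodes_from(range(n))
            g.add_edges_from(edges_oracle(assemblies))
            comp_of = {}
            for comp in nx.weakly_connected_components(g):
                for v in comp:
                    comp_of[v] = frozenset(comp)
            # one contig per weakly connected component, each achieving the
            # exhaustive-enumeration optimum; off-path assemblies are absorbed
            assert len(contigs) == len(oracle)
            seen = set()
            for contig in contigs:
                members = [idx[a.id] for a in contig]
                comp = comp_of[members[0]]
                assert all(comp_of[m] == comp for m in members)
                assert union_length(members, assemblies) == oracle[comp]
                seen.add(comp)
            assert seen == set(oracle)


class TestClusterWindow:
    def test_nearby_deletions_cluster(self):
        a = SVCall("chr1", 5000, 5500, "DEL")
        b = SVCall("chr1", 5100, 5600, "DEL")
        assert len(val.cluster_svs_by_window([a, b])) == 1

    def test_separated_deletions_split(self):
        a = SVCall("chr1", 5000, 5500, "DEL")
        b = SVCall("chr1", 5300, 5800, "DEL")
        assert len(val.cluster_svs_by_window([a, b])) == 2

    def test_evaluation_interval_rule(self):
        (cl,) = val.cluster_svs_by_window([SVCall("chr1", 5000, 5500, "DEL")])
        assert (cl.eval_start, cl.eval_end) == (4000, 6500)
        (cl,) = val.cluster_svs_by_window([SVCall("chr1", 5000, 5000, "INS", length=300)])
        assert (cl.eval_start, cl.eval_end) == (4000, 6000)


class TestDecisionBoundaries:
    def test_pbrc_strict_threshold(self):
        assert val.pbrc_validate(SupportEvidence("c", 5)) is True
        assert val.pbrc_validate(SupportEvidence("c", 4)) is False
        assert val.pbrc_validate(SupportEvidence("c", 0)) is False
        assert val.pbrc_validate(None) is False

    def test_fbn_formula_and_argmin(self):
        cands = [SVCall("chr1", 0, 950, "DEL"), SVCall("chr1", 0, 700, "DEL")]
        best, f, ok = val.fbn_match(cands, 1000)
        assert best.length == 950 and f == pytest.approx(0.05) and ok

    def test_fbn_boundary_not_validated(self):
        (best, f, ok) = val.fbn_match([SVCall("chr1", 0, 880, "DEL")], 1000)
        assert f == pytest.approx(0.12) and not ok
        (_, f, ok) = val.fbn_match([SVCall("chr1", 0, 900, "DEL")], 1000)
        assert f == pytest.approx(0.10) and not ok  # strict f < 0.1

    def test_fbn_exact_length_zero(self):
        (_, f, ok) = val.fbn_match([SVCall("chr1", 0, 1000, "DEL")], 1000)
        assert f == 0.0 and ok

    def test_fbn_no_candidates(self):
        assert val.fbn_match([], 1000) == (None, None, False)

    def test_depth_constant_profiles(self):
        assert val.depth_validate_deletion(np.full(5000, 20.0), 1000) is True
        assert val.depth_validate_deletion(np.full(5000, 40.0), 1000) is False

    def test_depth_dip_detected(self):
        prof = np.full(5000, 40.0)
        prof[2000:3000] = 10.0
        assert val.depth_validate_deletion(prof, 1000) is True

    def test_depth_short_profile_errors(self):
        with pytest.raises(ValueError):
            val.depth_validate_deletion(np.full(100, 10.0), 1000)

    def test_depth_matches_bruteforce_window_minimum(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(50, 400))
            w = int(rng.integers(5, n + 1))
            prof = rng.uniform(0, 60, size=n)
            mins = min(prof[i : i + w].mean() for i in range(n - w + 1))
            assert val.depth_validate_deletion(prof, w) == (mins < 30.0)


class TestILConcordance:
    def test_assembly_length_concordance(self):
        q = SVCall("chr1", 10_000, 10_500, "DEL", source="IL")
        t = SVCall("chr1", 10_050, 10_450, "DEL", source="PB")
        assert val.il_concordance_filter(q, pb_assembly_calls=[t])

    def test_three_concordant_reads(self):
        q = SVCall("chr1", 10_000, 10_400, "DEL", source="IL")
        reads = [SVCall("chr1", 10_020, 10_320, "DEL", source="read") for _ in range(3)]
        assert val.il_concordance_filter(q, pb_read_calls=reads)
        assert not val.il_concordance_filter(q, pb_read_calls=reads[:2])

    def test_low_depth_deletion(self):
        q = SVCall("chr1", 10_000, 10_400, "DEL", source="IL", id="q")
        ev = SupportEvidence("q", 0, None, np.full(2400, 10.0), profile_start=9000)
        assert val.il_concordance_filter(q, depth_profile=ev)

    def test_dotplot_predicate_defaults_unsupported(self):
        q = SVCall("chr1", 10_000, 10_400, "DEL", source="IL")
        assert not val.il_concordance_filter(q)
        assert val.il_concordance_filter(q, dotplot_predicate=lambda c: True)


class TestMergeHaplotypes:
    TR = {"chr1": [(100_000, 102_000)]}

    def test_identical_calls_merge_homozygous(self):
        a = [SVCall("chr1", 10_000, 11_000, "DEL", haplotype="H1", id="a")]
        b = [SVCall("chr1", 10_000, 11_000, "DEL", haplotype="H2", id="b")]
        res = val.merge_haplotypes(a, b, self.TR)
        assert len(res.diploid_calls) == 1 and res.diploid_calls[0].genotype == "1/1"

    def test_h1_only_is_het(self):
        a = [SVCall("chr1", 10_000, 11_000, "DEL", haplotype="H1", id="a")]
        res = val.merge_haplotypes(a, [], self.TR)
        assert res.diploid_calls[0].genotype == "1/0"

    def test_tr_locus_with_six_svs_set_aside(self):
        h1 = [SVCall("chr1", 100_100 + i * 200, 100_150 + i * 200, "DEL", id=f"h1_{i}") for i in range(6)]
        h2 = [SVCall("chr1", 100_120, 100_170, "DEL", id="h2_0")]
        res = val.merge_haplotypes(h1, h2, self.TR)
        assert res.removed_loci and len(res.removed_calls) == 7
        assert res.diploid_calls == []

    def test_ro_threshold_boundary_non_tr(self):
        # RO exactly 0.10 merges (inclusive); below does not
        a = [SVCall("chr1", 0, 1000, "DEL", id="a")]
        b = [SVCall("chr1", 900, 1900, "DEL", id="b")]  # RO = 0.10
        res = val.merge_haplotypes(a, b, {"chr1": []})
        assert [c.genotype for c in res.diploid_calls] == ["1/1"]
        b2 = [SVCall("chr1", 901, 1901, "DEL", id="b")]  # RO = 0.099
        res2 = val.merge_haplotypes(a, b2, {"chr1": []})
        assert sorted(c.genotype for c in res2.diploid_calls) == ["0/1", "1/0"]

    def test_tr_calls_need_tight_overlap(self):
        a = [SVCall("chr1", 100_100, 100_600, "DEL", id="a")]
        b = [SVCall("chr1", 100_400, 100_900, "DEL", id="b")]  # RO = 0.4 < 0.5 inside TR
        res = val.merge_haplotypes(a, b, self.TR)
        assert sorted(c.genotype for c in res.diploid_calls) == ["0/1", "1/0"]

    def test_swap_symmetry_and_idempotence(self):
        rng = np.random.default_rng(9)
        h1, h2 = [], []
        for i in range(30):
            s = int(rng.integers(0, 2_000_000))
            L = int(rng.integers(100, 5000))
            h1.append(SVCall("chr1", s, s + L, "DEL", id=f"x{i}"))
            if rng.random() < 0.5:
                j1 = int(rng.integers(-50, 50))
                h2.append(SVCall("chr1", s + j1, s + L + j1, "DEL", id=f"y{i}"))
        res = val.merge_haplotypes(h1, h2, self.TR)
        swapped = val.merge_haplotypes(h2, h1, self.TR)
        flip = {"1/0": "0/1", "0/1": "1/0", "1/1": "1/1"}
        a = sorted((c.chrom, c.start, c.end, c.genotype) for c in res.diploid_calls)
        b = sorted((c.chrom, c.start, c.end, flip[c.genotype]) for c in swapped.diploid_calls)
        assert a == b
        # idempotence: re-splitting the merged calls reproduces the genotypes
        r1 = [SVCall(c.chrom, c.start, c.end, c.svtype, id=c.id) for c in res.diploid_calls if c.genotype in ("1/1", "1/0")]
        r2 = [SVCall(c.chrom, c.start, c.end, c.svtype, id=c.id) for c in res.diploid_calls if c.genotype in ("1/1", "0/1")]
        again = val.merge_haplotypes(r1, r2, self.TR)
        assert sorted((c.chrom, c.start, c.end, c.genotype) for c in again.diploid_calls) == a


class TestUnifyPB:
    def _ev(self, calls, support):
        return {c.id: SupportEvidence(c.id, support) for c in calls}

    def test_bng_rescues_low_support_call(self):
        c = SVCall("chr1", 10_000, 11_000, "DEL", source="phased_sv", id="p0")
        bng = SVCall("chr1", 9_900, 11_100, "DEL", length=1050, id="bng0")
        out = val.unify_pb([c], [], self._ev([c], 2), [bng])
        assert out == [c] and c.meta["tier"] == "bng"

    def test_nearby_mspac_call_excluded(self):
        p = SVCall("chr1", 10_000, 11_000, "DEL", source="phased_sv", id="p0")
        m = SVCall("chr1", 16_000, 16_500, "DEL", source="mspac", id="m0")
        out = val.unify_pb([p], [m], self._ev([p, m], 10), [])
        assert [c.id for c in out] == ["p0"]

    def test_distal_mspac_call_included(self):
        p = SVCall("chr1", 10_000, 11_000, "DEL", source="phased_sv", id="p0")
        m = SVCall("chr1", 40_000, 40_500, "DEL", source="mspac", id="m0")
        out = val.unify_pb([p], [m], self._ev([p, m], 10), [])
        assert sorted(c.id for c in out) == ["m0", "p0"]

    def test_pbrc_above_three_included(self):
        p = SVCall("chr1", 10_000, 11_000, "DEL", source="phased_sv", id="p0")
        out = val.unify_pb([p], [], self._ev([p], 4), [])
        assert out == [p]
        p2 = SVCall("chr1", 10_000, 11_000, "DEL", source="phased_sv", id="p1")
        assert val.unify_pb([p2], [], self._ev([p2], 3), []) == []


class TestPanSV:
    def test_triple_match_uses_pb_representation(self):
        pb = SVCall("chr1", 10_000, 11_000, "DEL", source="PB", id="pb")
        il = SVCall("chr1", 10_020, 11_020, "DEL", source="IL", id="il")
        bng = SVCall("chr1", 9_500, 11_500, "DEL", length=1100, id="bng")
        (rec,) = val.build_pan_sv([il], [bng], [pb])
        assert rec.provenance == frozenset({"PB", "IL", "BNG"})
        assert rec.representative.id == "pb"

    def test_il_bng_pair_uses_il_representation(self):
        il = SVCall("chr1", 10_000, 11_000, "DEL", source="IL", id="il")
        bng = SVCall("chr1", 9_500, 11_500, "DEL", length=1100, id="bng")
        (rec,) = val.build_pan_sv([il], [bng], [])
        assert rec.provenance == frozenset({"IL", "BNG"}) and rec.representative.id == "il"

    def test_bng_only_insertion(self):
        bng = SVCall("chr1", 10_000, 12_000, "INS", length=800, id="bng")
        (rec,) = val.build_pan_sv([], [bng], [])
        assert rec.provenance == frozenset({"BNG"})

    def test_partition_of_inputs(self):
        pb = [SVCall("chr1", i * 20_000, i * 20_000 + 500, "DEL", source="PB", id=f"pb{i}") for i in range(5)]
        il = [SVCall("chr1", i * 20_000 + 10, i * 20_000 + 510, "DEL", source="IL", id=f"il{i}") for i in range(3)]
        recs = val.build_pan_sv(il, [], pb)
        ids = sorted(m.id for r in recs for m in r.members)
        assert ids == sorted([c.id for c in pb] + [c.id for c in il])
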