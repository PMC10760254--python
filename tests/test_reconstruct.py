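"""Segment graph construction and derivative-walk enumeration."""

from __future__ import annotations

import pytest

from svdissect import reconstruct as rc
from svdissect import synthgenome as sg
from svdissect.cma import CnvCall
from svdissect.svdetect import JunctionCall


def gain(s, e):
    return CnvCall(start=s, end=e, state="gain", n_probes=10, mean_log2=0.58)


def seg(seg_id, s, e, total):
    return rc.Segment(seg_id=seg_id, start=s, end=e, total_copies=total,
                      label_state="dup" if total > 2 else "normal")


@pytest.fixture(scope="module")
def truth_calls():
    ref = sg.make_reference(1)
    plan = sg.default_plan(ref)
    truth = sg.truth_from_plan(ref, plan)
    cnvs = [gain(s, e) for s, e in (sg.DUP1, sg.DUP2, sg.DUP3)]
    juncs = [
        JunctionCall(breakend_a=a, breakend_b=b, split_case=9, inserted_seq=ins)
        for a, b, ins in truth.novel_junctions
    ]
    return ref, plan, cnvs, juncs


class TestSegmentation:
    def test_default_calls_give_seven_segments(self, truth_calls):
        ref, _plan, cnvs, juncs = truth_calls
        segments = rc.segment_reference(cnvs, juncs, (1, len(ref)))
        assert [s.seg_id for s in segments] == ["S0", "D1", "S1", "D2", "S2", "D3", "S3"]
        assert [s.total_copies for s in segments] == [2, 3, 2, 3, 2, 3, 2]
        assert (segments[1].start, segments[1].end) == sg.DUP1

    def test_one_cnv_no_junctions_gives_three_segments(self):
        segments = rc.segment_reference([gain(5_000, 8_000)], [], (1, 20_000))
        assert len(segments) == 3
        assert [s.total_copies for s in segments] == [2, 3, 2]

    def test_nearby_boundaries_merge(self):
        juncs = [JunctionCall(breakend_a=(5_003, "L"), breakend_b=(8_000, "R"), split_case=5)]
        segments = rc.segment_reference([gain(5_000, 8_000)], juncs, (1, 20_000),
                                        window=10)
        # the 3 bp offset between CNV edge and breakend collapses to one cut
        assert len(segments) == 3

    def test_unmatched_breakend_is_kept_and_flagged(self):
        juncs = [JunctionCall(breakend_a=(12_000, "R"), breakend_b=(15_000, "L"),
                              split_case=5)]
        segments = rc.segment_reference([gain(5_000, 8_000)], juncs, (1, 20_000))
        assert len(segments) == 5
        flagged = [s for s in segments if s.unmatched_boundary]
        assert flagged  # junction cuts with no CNV edge nearby


class TestGraph:
    def test_default_graph_counts(self, truth_calls):
        ref, _plan, cnvs, juncs = truth_calls
        segments = rc.segment_reference(cnvs, juncs, (1, len(ref)))
        graph = rc.build_graph(segments, juncs)
        assert len(graph.reference_edges) == 6
        assert len([e for e in graph.novel_edges if not e.flagged]) == 3

    def test_tandem_duplication_self_loop(self):
        segments = [seg("S0", 1, 1_000, 2), seg("D1", 1_001, 2_000, 3),
                    seg("S1", 2_001, 3_000, 2)]
        juncs = [JunctionCall(breakend_a=(2_000, "R"), breakend_b=(1_001, "L"),
                              split_case=6)]
        graph = rc.build_graph(segments, juncs)
        e = graph.novel_edges[0]
        assert {e.end_a, e.end_b} == {(1, "R"), (1, "L")}

    def test_distant_breakend_is_flag_excluded(self):
        segments = [seg("S0", 1, 1_000, 2), seg("S1", 1_001, 2_000, 2)]
        juncs = [JunctionCall(breakend_a=(500, "R"), breakend_b=(1_500, "L"),
                              split_case=6)]
        graph = rc.build_graph(segments, juncs)
        assert graph.novel_edges[0].flagged


class TestWalks:
    def test_no_novel_edges_all_cn2_gives_identity(self):
        segments = [seg("S0", 1, 10, 2), seg("S1", 11, 20, 2), seg("S2", 21, 30, 2)]
        words, truncated, diag = rc.solve_walks(rc.SegmentGraph(segments, []))
        assert [str(w) for w in words] == ["+S0 +S1 +S2"]
        assert not truncated and diag is None

    def test_deletion_forces_unique_word(self):
        segments = [seg("S0", 1, 10, 2), seg("S1", 11, 20, 1), seg("S2", 21, 30, 2)]
        juncs = [JunctionCall(breakend_a=(10, "R"), breakend_b=(21, "L"), split_case=6)]
        graph = rc.build_graph(segments, juncs)
        words, _t, _d = rc.solve_walks(graph)
        assert [str(w) for w in words] == ["+S0 +S2"]

    def test_tandem_duplication_word(self):
        segments = [seg("S0", 1, 1_000, 2), seg("D1", 1_001, 2_000, 3),
                    seg("S1", 2_001, 3_000, 2)]
        juncs = [JunctionCall(breakend_a=(2_000, "R"), breakend_b=(1_001, "L"),
                              split_case=6)]
        graph = rc.build_graph(segments, juncs)
        words, _t, _d = rc.solve_walks(graph)
        assert "+S0 +D1 +D1 +S1" in [str(w) for w in words]

    def test_impossible_graph_diagnosed(self):
        segments = [seg("S0", 1, 10, 2), seg("S1", 11, 20, 1), seg("S2", 21, 30, 2)]
        words, _t, diag = rc.solve_walks(rc.SegmentGraph(segments, []))
        assert words == [] and diag is not None

    def test_default_graph_contains_plan_word(self, truth_calls):
        ref, plan, cnvs, juncs = truth_calls
        segments = rc.segment_reference(cnvs, juncs, (1, len(ref)))
        graph = rc.build_graph(segments, juncs)
        words, truncated, _d = rc.solve_walks(graph)
        assert not truncated
        assert any(rc.word_matches_plan(w, plan.word) for w in words)

    def test_max_solutions_truncation(self, truth_calls):
        ref, _plan, cnvs, juncs = truth_calls
        segments = rc.segment_reference(cnvs, juncs, (1, len(ref)))
        graph = rc.build_graph(segments, juncs)
        words, truncated, _d = rc.solve_walks(graph, max_solutions=2)
        assert truncated and len(words) <= 2

    def test_symmetry_under_breakend_order_reversal(self, truth_calls):
        ref, _plan, cnvs, juncs = truth_calls
        segments = rc.segment_reference(cnvs, juncs, (1, len(ref)))
        flipped = [
            JunctionCall(breakend_a=j.breakend_b, breakend_b=j.breakend_a,
                         split_case=j.split_case, disc_case=j.disc_case,
                         inserted_seq=(
                             sg.revcomp(j.inserted_seq) if j.inserted_seq else ""
                         ))
            for j in juncs
        ]
        g1 = rc.build_graph(segments, juncs)
        g2 = rc.build_graph(segments, flipped)
        w1, _, _ = rc.solve_walks(g1)
        w2, _, _ = rc.solve_walks(g2)
        strip = lambda ws: sorted(
            " ".join(str(x) for x in w.word if not x.is_insertion) for w in ws
        )
        assert strip(w1) == strip(w2)


class TestOracleEquivalence:
    def graphs(self):
        out = []
        # identity
        out.append(rc.SegmentGraph(
            [seg("S0", 1, 10, 2), seg("S1", 11, 20, 2)], []
        ))
        # deletion
        segs_del = [seg("S0", 1, 10, 2), seg("S1", 11, 20, 1), seg("S2", 21, 30, 2)]
        out.append(rc.build_graph(
            segs_del,
            [JunctionCall(breakend_a=(10, "R"), breakend_b=(21, "L"), split_case=6)],
        ))
        # tandem duplication
        segs_td = [seg("S0", 1, 10, 2), seg("D1", 11, 20, 3), seg("S1", 21, 30, 2)]
        out.append(rc.build_graph(
            segs_td,
            [JunctionCall(breakend_a=(20, "R"), breakend_b=(11, "L"), split_case=6)],
        ))
        # inverted duplication
        segs_inv = [seg("S0", 1, 10, 2), seg("D1", 11, 20, 3), seg("S1", 21, 30, 2)]
        out.append(rc.build_graph(
            segs_inv,
            [JunctionCall(breakend_a=(20, "R"), breakend_b=(20, "R"), split_case=6)],
        ))
        return out

    @pytest.mark.parametrize("graph_idx", range(4))
    def test_small_graphs_match_brute_force(self, graph_idx):
        graph = self.graphs()[graph_idx]
        words, truncated, _d = rc.solve_walks(graph, max_solutions=1_000)
        assert not truncated
        solver = sorted(
            " ".join(str(x) for x in w.word if not x.is_insertion) for w in words
        )
        assert solver == rc.brute_force_walks(graph)

    def test_default_seven_segment_graph_matches_brute_force(self, truth_calls):
        ref, _plan, cnvs, juncs = truth_calls
        segments = rc.segment_reference(cnvs, juncs, (1, len(ref)))
        graph = rc.build_graph(segments, juncs)
        words, _t, _d = rc.solve_walks(graph, max_solutions=1_000)
        solver = sorted(
            {" ".join(str(x) for x in w.word if not x.is_insertion) for w in words}
        )
        assert solver == rc.brute_force_walks(graph, cap=5_000_000)


class TestInversionReport:
    def test_default_word_reports_two_megabase_block(self, truth_calls):
        ref, plan, cnvs, juncs = truth_calls
        segments = rc.segment_reference(cnvs, juncs, (1, len(ref)))
        graph = rc.build_graph(segments, juncs)
        words, _t, _d = rc.solve_walks(graph)
        w = next(w for w in words if rc.word_matches_plan(w, plan.word))
        report = rc.inversion_report(w, graph)
        assert len(report) == 1
        (start, end), length = report[0]
        assert (start, end) == (346_084, 2_351_089)
        assert length == 2_005_006

    def test_identity_word_has_no_inversions(self):
        segments = [seg("S0", 1, 10, 2), seg("S1", 11, 20, 2)]
        graph = rc.SegmentGraph(segments, [])
        words, _t, _d = rc.solve_walks(graph)
        assert rc.inversion_report(words[0], graph) == []

    def test_single_inverted_segment(self):
        segments = [seg("S0", 1, 10, 2), seg("S1", 11, 20, 2), seg("S2", 21, 30, 2)]
        word = rc.DerivativeWord(
            word=[sg.SignedSegment("S0", "+"), sg.SignedSegment("S1", "-"),
                  sg.SignedSegment("S2", "+")],
            used_novel_edges={},
        )
        graph = rc.SegmentGraph(segments, [])
        assert rc.inversion_report(word, graph) == [((11, 20), 10)]
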