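"""Generator module: planted truth, determinism, conservation laws."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from svdissect import synthgenome as sg
from svdissect._dna import revcomp


class TestReference:
    def test_cassette_planted_with_splice_flanks(self, ref):
        s, e = ref.cassette_interval
        assert ref.sequence[s - 1 : e] == sg.CRYPTIC_CASSETTE
        assert len(sg.CRYPTIC_CASSETTE) == 48
        assert ref.sequence[s - 3 : s - 1] == "AG"
        assert ref.sequence[e : e + 2] == "GT"

    def test_deterministic_and_seed_sensitive(self):
        a = sg.make_reference(1)
        b = sg.make_reference(1)
        c = sg.make_reference(2)
        assert a.sequence == b.sequence
        assert a.sequence != c.sequence
        # planted cassette identical across seeds
        s, e = a.cassette_interval
        assert c.sequence[s - 1 : e] == a.sequence[s - 1 : e]

    def test_length_floor_enforced(self):
        with pytest.raises(ValueError, match=str(sg.MIN_REFERENCE_LENGTH)):
            sg.make_reference(1, length=1_000_000)

    def test_gene_layout_matches_duplication_intervals(self, ref):
        kank1 = ref.gene("kank1_like")
        assert sg.DUP1[0] <= kank1.promoter[0] and kank1.exons[1][1] <= sg.DUP1[1]
        dmrt1 = ref.gene("dmrt1_like")
        assert dmrt1.exons[0][1] < sg.DUP2[0]
        assert all(sg.DUP2[0] <= s and e <= sg.DUP2[1] for s, e in dmrt1.exons[1:])
        cs, ce = ref.cassette_interval
        assert sg.DUP2[0] < cs and ce < dmrt1.exons[1][0]

    def test_snvs_are_heterozygous_markers_near_breakpoints(self, ref):
        for pos, ref_base, alt_base in ref.snv_sites:
            assert ref.sequence[pos - 1] == ref_base != alt_base
            assert min(abs(pos - b) for b in ref.planned_breakpoints) <= 1_000


class TestPlanAndDerivative:
    def test_default_plan_truth(self, ref, plan, truth):
        assert len(truth.novel_junctions) == 3
        assert truth.breakpoints == {346084, 700056, 788363, 864099, 2271746, 2351089}
        assert truth.inversion_span_bp == 2_351_089 - 346_084 + 1 == 2_005_006
        for seg in ("S0", "S1", "S2", "S3"):
            assert truth.copy_numbers[seg] == 2
        for seg in ("D1", "D2", "D3"):
            assert truth.copy_numbers[seg] == 3

    def test_derivative_length_conservation(self, ref, plan):
        derivative, truth = sg.apply_plan(ref, plan)
        expected = sum(
            plan.segment_length(w.segment_id)
            for w in plan.word if not w.is_insertion
        ) + sum(
            len(plan.insertions[w.segment_id[4:]])
            for w in plan.word if w.is_insertion
        )
        assert len(derivative) == expected
        assert len(derivative) == len(ref) + 353_973 + 75_737 + 79_344 + 500

    def test_identity_word_reproduces_reference(self, ref, plan):
        ident = sg.RearrangementPlan(
            boundaries=plan.boundaries,
            word=[
                sg.SignedSegment(s, "+")
                for s in sorted(plan.boundaries, key=lambda k: plan.boundaries[k])
            ],
        )
        derivative, truth = sg.apply_plan(ref, ident)
        assert derivative == ref.sequence
        assert truth.novel_junctions == []
        assert truth.inversion_span_bp == 0

    def test_toy_permutation_free_identity(self):
        # a 10 bp toy reference cut into three segments, all forward
        seq = "ACGTACGTAC"
        ref = sg.make_reference(1)
        toy = sg.RearrangementPlan(
            boundaries={"S0": (1, 3), "D1": (4, 7), "S1": (8, 10)},
            word=[sg.SignedSegment(x, "+") for x in ("S0", "D1", "S1")],
        )
        toy.validate(10)
        parts = [seq[s - 1 : e] for s, e in (toy.boundaries[w.segment_id] for w in toy.word)]
        assert "".join(parts) == seq

    def test_junctions_invariant_under_word_reversal(self, ref, plan, truth):
        flipped = sg.RearrangementPlan(
            boundaries=plan.boundaries,
            word=[
                sg.SignedSegment(w.segment_id, "+" if w.orientation == "-" else "-")
                for w in reversed(plan.word)
            ],
            insertions=plan.insertions,
        )
        rev_truth = sg.truth_from_plan(ref, flipped, validate=False)
        assert sorted(rev_truth.novel_junctions) == sorted(truth.novel_junctions)

    def test_derivative_with_alts_is_heterozygous(self, ref, plan):
        derivative, _ = sg.apply_plan(ref, plan, apply_snv_alts=True)
        # the first D1 copy sits at the reference offset, so planted alts
        # inside D1 are directly addressable
        pos, ref_base, alt_base = next(s for s in ref.snv_sites if s[0] == 346_184)
        assert derivative[pos - 1] == alt_base
        assert ref.sequence[pos - 1] == ref_base


class TestReadSimulation:
    def test_pair_count_formula(self):
        rng = np.random.default_rng(0)
        h = "".join("ACGT"[i] for i in rng.integers(0, 4, 1_000_000))
        rs = sg.simulate_paired_reads([h, h], coverage=20, read_length=150,
                                      insert_mean=400, insert_sd=60, seed=4)
        assert abs(rs.n_pairs - round(2_000_000 * 20 / 300)) <= 1

    def test_error_free_reads_are_exact_substrings(self):
        rng = np.random.default_rng(5)
        h = "".join("ACGT"[i] for i in rng.integers(0, 4, 20_000))
        rs = sg.simulate_paired_reads([h], coverage=3, error_rate=0.0, seed=6)
        for r1, r2, hom, (fs, fe) in rs.pairs():
            frag = h[fs - 1 : fe]
            assert r1 in frag or revcomp(r1) in frag
            assert r2 in frag or revcomp(r2) in frag

    def test_determinism_and_param_validation(self):
        h = "ACGT" * 5_000
        a = sg.simulate_paired_reads([h], coverage=2, seed=9)
        b = sg.simulate_paired_reads([h], coverage=2, seed=9)
        assert np.array_equal(a.r1, b.r1) and np.array_equal(a.r2, b.r2)
        with pytest.raises(ValueError):
            sg.simulate_paired_reads([h], coverage=0)
        with pytest.raises(ValueError):
            sg.simulate_paired_reads([h], coverage=1, insert_mean=200, read_length=150)


class TestProbeTrack:
    def test_noise_free_track_reproduces_log2_copy_ratio(self, ref, truth):
        track = sg.simulate_probe_track(ref, truth, spacing=1_000, noise_sd=0.0)
        in_d2 = (track.positions >= sg.DUP2[0]) & (track.positions <= sg.DUP2[1])
        in_s1 = (track.positions > sg.DUP1[1]) & (track.positions < sg.DUP2[0])
        assert np.allclose(track.log2[in_d2], np.log2(3 / 2))
        assert np.allclose(track.log2[in_s1], 0.0)

    def test_aberrant_probe_count_matches_interval_arithmetic(self, ref, truth):
        track = sg.simulate_probe_track(ref, truth, spacing=1_000, noise_sd=0.0)
        n_aberrant = int(np.sum(track.log2 > 0.1))
        expected = sum((e - s + 1) // 1_000 for s, e in (sg.DUP1, sg.DUP2, sg.DUP3))
        assert abs(n_aberrant - expected) <= 3

    def test_spacing_validation(self, ref, truth):
        with pytest.raises(ValueError):
            sg.simulate_probe_track(ref, truth, spacing=50)


class TestRnaSimulation:
    def test_sense_strand_only_and_determinism(self, ref, plan):
        seq, _labels = sg.chimeric_transcript_truth(ref, plan)
        rna = sg.simulate_rna_reads([(seq, 1.0)], read_length=100, n_reads=200, seed=2)
        assert all(read in seq for read in rna.reads)
        again = sg.simulate_rna_reads([(seq, 1.0)], read_length=100, n_reads=200, seed=2)
        assert rna.reads == again.reads

    def test_empty_request(self):
        assert sg.simulate_rna_reads([], n_reads=0).n_reads == 0


class TestPedigreeFixture:
    def test_counts_and_generations(self):
        ped = sg.make_pedigree_fixture()
        affected = [r for r in ped.individuals if r[4] == "yes"]
        genotyped_affected = [r for r in affected if ped.status(r[0]) != "untested"]
        assert len(genotyped_affected) == 11
        assert all(ped.status(r[0]) == "carrier" for r in genotyped_affected)
        unaffected_genotyped = [
            r for r in ped.individuals
            if r[4] == "no" and ped.status(r[0]) != "untested"
        ]
        assert len(unaffected_genotyped) == 11
        assert sum(ped.status(r[0]) == "carrier" for r in unaffected_genotyped) == 0
        assert ped.n_generations() == 5

    def test_roundtrip_through_ped_files(self, tmp_path):
        ped = sg.make_pedigree_fixture()
        sg.write_ped(tmp_path / "f.ped", tmp_path / "g.tsv", ped)
        back = sg.read_ped(tmp_path / "f.ped", tmp_path / "g.tsv")
        assert {r[0] for r in back.individuals} == {r[0] for r in ped.individuals}
        assert back.genotypes == ped.genotypes


@settings(max_examples=25, deadline=None)
@given(
    n_segs=st.integers(2, 5),
    seed=st.integers(0, 10_000),
    data=st.data(),
)
def test_conservation_property_on_random_toy_plans(n_segs, seed, data):
    """Derivative length equals the multiplicity-weighted segment sum plus
    insertions, for arbitrary valid toy words."""
    rng = np.random.default_rng(seed)
    lengths = rng.integers(5, 30, n_segs)
    bounds, pos = {}, 1
    for i, ln in enumerate(lengths):
        bounds[f"X{i}"] = (pos, pos + int(ln) - 1)
        pos += int(ln)
    total_len = pos - 1
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, total_len))
    ids = sorted(bounds, key=lambda k: bounds[k])
    middle = data.draw(
        st.lists(
            st.tuples(st.sampled_from(ids[1:-1] or ids), st.sampled_from("+-")),
            max_size=6,
        )
    )
    word = (
        [sg.SignedSegment(ids[0], "+")]
        + [sg.SignedSegment(s, o) for s, o in middle]
        + [sg.SignedSegment(ids[-1], "+")]
    )
    plan = sg.RearrangementPlan(boundaries=bounds, word=word, insertions={"I": "ACGTA"})
    plan.validate(total_len)
    parts = []
    for w in plan.word:
        s, e = plan.boundaries[w.segment_id]
        seg = seq[s - 1 : e]
        parts.append(seg if w.orientation == "+" else revcomp(seg))
    expected_len = sum(
        plan.segment_length(w.segment_id) for w in plan.word
    )
    assert len("".join(parts)) == expected_len
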