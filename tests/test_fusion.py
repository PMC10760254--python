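"""Splice scoring, annotation liftover, transcript prediction, ORF/NMD."""

from __future__ import annotations

import numpy as np
import pytest

from svdissect import fusion as fu
from svdissect import synthgenome as sg


@pytest.fixture(scope="module")
def derivative(ref, plan):
    der, _truth = sg.apply_plan(ref, plan)
    return der


@pytest.fixture(scope="module")
def lifted(ref, plan):
    return fu.liftover_annotations(plan.word, plan.boundaries, ref.genes, plan.insertions)


@pytest.fixture(scope="module")
def der_sites(derivative, lifted):
    return fu.score_splice_sites(derivative, annotations=lifted)


@pytest.fixture(scope="module")
def predicted(derivative, lifted, der_sites):
    return fu.predict_transcripts(derivative, lifted, der_sites)


class TestSpliceScoring:
    def test_cassette_flanks_found_de_novo(self, ref):
        sites = fu.score_splice_sites(ref.sequence)
        cs, ce = ref.cassette_interval
        sa = [s for s in sites if s.kind == "SA" and s.position == cs]
        sd = [s for s in sites if s.kind == "SD" and s.position == ce]
        assert len(sa) == 1 and len(sd) == 1
        assert sa[0].score == sd[0].score == pytest.approx(fu.DENOVO_SCORE_CAP)

    def test_poly_c_sequence_has_no_sites(self):
        assert fu.score_splice_sites("C" * 500) == []

    def test_annotated_kank1_exon2_donor_is_sd1(self, ref):
        lifted_ref = fu.reference_liftover(ref)
        sites = fu.score_splice_sites(ref.sequence, annotations=lifted_ref)
        kank1 = ref.gene("kank1_like")
        sd1 = [s for s in sites if s.label == "SD1"]
        assert len(sd1) == 1
        assert sd1[0].position == kank1.exons[1][1]
        assert sd1[0].score == 1.0

    def test_donor_sites_have_gt_context(self, ref):
        sites = fu.score_splice_sites(ref.sequence)
        for s in sites:
            if s.kind == "SD":
                assert ref.sequence[s.position : s.position + 2] == "GT"
            else:
                assert ref.sequence[s.position - 3 : s.position - 1] == "AG"


class TestLiftover:
    def test_identity_word_is_identity_map(self, ref):
        lifted_ref = fu.reference_liftover(ref)
        for f in lifted_ref:
            assert f.strand == "+"
            assert not f.truncated
        kank1 = ref.gene("kank1_like")
        ex1 = next(f for f in lifted_ref if f.gene == kank1.name and f.exon_number == 1)
        assert (ex1.start, ex1.end) == kank1.exons[0]

    def test_kank1_features_appear_twice_once_inverted(self, lifted, ref):
        kank1 = ref.gene("kank1_like")
        promoters = [f for f in lifted if f.gene == kank1.name and f.kind == "promoter"]
        assert len(promoters) == 2
        assert sorted(p.strand for p in promoters) == ["+", "-"]

    def test_feature_crossing_boundary_is_truncated(self, lifted, ref):
        dock8 = ref.gene("dock8_like")
        # dock8's middle exon straddles the dup1 left boundary
        copies = [
            f for f in lifted if f.gene == dock8.name and f.exon_number == 2
        ]
        assert any(f.truncated for f in copies)


class TestTranscriptPrediction:
    def test_chimera_structure(self, predicted, derivative):
        chimera = [t for t in predicted if t.is_chimeric]
        assert len(chimera) == 1
        t = chimera[0]
        assert t.n_exons == 11
        labels = t.exon_labels()
        assert labels[0].endswith("exon1") and labels[1].endswith("exon2")
        assert labels[2] == "novel"
        assert [lab.split("exon")[-1] for lab in labels[3:]] == [
            str(i) for i in range(2, 10)
        ]
        # transcript sequence is exactly the concatenated exon substrings
        assert t.sequence == "".join(derivative[s - 1 : e] for s, e, _lab in t.exons)

    def test_reference_has_no_chimeric_transcripts(self, ref):
        lifted_ref = fu.reference_liftover(ref)
        sites = fu.score_splice_sites(ref.sequence, annotations=lifted_ref)
        transcripts = fu.predict_transcripts(ref.sequence, lifted_ref, sites)
        assert transcripts
        assert sum(t.is_chimeric for t in transcripts) == 0

    def test_raised_threshold_skips_cryptic_exon(self, derivative, lifted, der_sites):
        high = fu.predict_transcripts(derivative, lifted, der_sites, threshold=0.995)
        chimera = [t for t in high if t.is_chimeric]
        assert chimera and chimera[0].n_exons == 10
        assert "novel" not in chimera[0].exon_labels()

    def test_threshold_monotonicity(self, derivative, lifted, der_sites):
        lo = fu.predict_transcripts(derivative, lifted, der_sites, threshold=0.97)
        hi = fu.predict_transcripts(derivative, lifted, der_sites, threshold=0.995)
        lo_chim = [t for t in lo if t.is_chimeric]
        hi_chim = [t for t in hi if t.is_chimeric]
        assert hi_chim[0].n_exons <= lo_chim[0].n_exons


def _exon_spans(transcript):
    spans, pos = [], 0
    for s, e, _lab in transcript.exons:
        spans.append((pos, pos + (e - s + 1)))
        pos += e - s + 1
    return spans


class TestOrf:
    def test_cassette_frame_scan_oracle(self):
        """Brute-force scan of the 48-mer: a stop codon exists in exactly
        one frame and it is TGA at offset 41."""
        scan = fu.scan_frames_for_stops(sg.CRYPTIC_CASSETTE)
        frames_with_stop = [f for f, stops in scan.items() if stops]
        assert frames_with_stop == [2]
        assert scan[2][0] == (41, "TGA")

    def test_fusion_orf_stop_inside_cassette(self, predicted, lifted, ref):
        t = next(t for t in predicted if t.is_chimeric)
        report = fu.analyze_orf(t, lifted, ref.genes)
        exon_idx, offset, codon = report.premature_stop
        assert t.exon_labels()[exon_idx] == "novel"
        assert (offset, codon) == (41, "TGA")
        assert report.nmd_predicted
        assert not report.frame_compatible

    def test_phase_bookkeeping_matches_translation(self, predicted, lifted, ref):
        t = next(t for t in predicted if t.is_chimeric)
        report = fu.analyze_orf(t, lifted, ref.genes)
        start = report.translation_start_offset
        spans = _exon_spans(t)
        for (o0, _o1), phase in zip(spans, report.entry_phases):
            if phase is not None:
                assert phase == (o0 - start) % 3

    def test_skip_variant_remains_frame_incompatible(self, derivative, lifted, der_sites, ref):
        high = fu.predict_transcripts(derivative, lifted, der_sites, threshold=0.995)
        t = next(t for t in high if t.is_chimeric)
        report = fu.analyze_orf(t, lifted, ref.genes)
        assert not report.frame_compatible

    def test_nmd_boundary_at_exactly_50nt(self):
        """A stop ending exactly 50 nt before the last junction predicts
        decay; one base closer does not."""
        def toy_transcript(gap):
            # two exons; CDS starts at 0 with ATG, stop immediately after,
            # then `gap` bases to the junction
            exon1 = "ATG" + "TGA" + "C" * gap
            exon2 = "G" * 60
            t = fu.ChimericTranscript(
                exons=[(1, len(exon1), "g1:exon1"), (len(exon1) + 1, len(exon1) + 60, "g1:exon2")],
                sequence=exon1 + exon2,
                source_genes=["g1"],
            )
            return t

        lifted = [
            fu.LiftedFeature(
                gene="G1", role="kank1_like", kind="cds_start", exon_number=None,
                start=1, end=1, strand="+", truncated=False, copy_index=0,
            )
        ]
        genes = []
        # stop codon ends at offset 6; junction sits at 6 + gap
        at_50 = fu.analyze_orf(toy_transcript(50), lifted, genes)
        assert at_50.nmd_predicted
        at_49 = fu.analyze_orf(toy_transcript(49), lifted, genes)
        assert not at_49.nmd_predicted


class TestRnaVerification:
    def test_simulated_reads_support_every_junction_forward_only(self, predicted, ref, plan):
        t = next(t for t in predicted if t.is_chimeric)
        true_seq, _labels = sg.chimeric_transcript_truth(ref, plan)
        assert true_seq == t.sequence
        rna = sg.simulate_rna_reads([(true_seq, 1.0)], read_length=100,
                                    n_reads=1_000, seed=5)
        support = fu.verify_with_rna([t], rna)[0]
        assert support.all_supported
        assert support.n_forward == 1_000 and support.n_reverse == 0

    def test_control_reads_do_not_support_fusion_junctions(self, predicted, ref):
        """RNA from the normal kank1-like transcript never spans the
        kank1-exon2/cryptic-exon junction."""
        t = next(t for t in predicted if t.is_chimeric)
        kank1 = ref.gene("kank1_like")
        normal = "".join(ref.sequence[s - 1 : e] for s, e in kank1.exons)
        rna = sg.simulate_rna_reads([(normal, 1.0)], read_length=100,
                                    n_reads=500, seed=6)
        support = fu.verify_with_rna([t], rna)[0]
        # junction index 1 joins kank1 exon 2 to the cryptic exon
        assert support.support[1] == 0

    def test_min_overhang_respected(self, predicted):
        t = next(t for t in predicted if t.is_chimeric)
        o = t.junction_offsets()[0]
        # a read ending min_overhang-1 bases after the junction cannot support it
        read = t.sequence[o - 93 : o + 7]
        rna = sg.RnaReadSet(reads=[read], origin=np.zeros(1, np.int32),
                            offset=np.zeros(1, np.int64), read_length=100, seed=0)
        support = fu.verify_with_rna([t], rna, min_overhang=8)[0]
        assert support.support[0] == 0
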