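"""Junction detection: evidence filters, clustering, SNV phasing,
microhomology and insertion assembly."""

from __future__ import annotations

import logging

import numpy as np
import pytest

from svdissect import svdetect as sv
from svdissect import synthgenome as sg
from svdissect._dna import revcomp
from svdissect.align import AlignmentTable, PairTable
from svdissect.svdetect import JunctionCall, _Cluster


def make_table(rows, read_length=150, n_pairs=None):
    """rows: (pair, mate, read_start, read_end, ref_start, ref_end, strand, supp)."""
    arr = np.array(rows, dtype=np.int64)
    if n_pairs is None:
        n_pairs = int(arr[:, 0].max()) + 1 if len(rows) else 0
    return AlignmentTable(
        pair_idx=arr[:, 0], mate=arr[:, 1].astype(np.int8),
        read_start=arr[:, 2].astype(np.int32), read_end=arr[:, 3].astype(np.int32),
        ref_start=arr[:, 4], ref_end=arr[:, 5],
        strand=arr[:, 6].astype(np.int8), mismatches=np.zeros(len(rows), np.int32),
        is_supplementary=arr[:, 7].astype(bool),
        read_length=read_length, n_pairs=n_pairs,
    )


class TestPassingFilters:
    @pytest.mark.parametrize(
        "split_case,split_ctrl,disc_case,disc_ctrl,expected",
        [
            (4, 0, 0, 0, True),    # split arm at its minimum
            (0, 0, 5, 1, True),    # discordant arm at its minimum
            (4, 1, 4, 0, False),   # control split read poisons one arm, counts fail the other
            (3, 0, 4, 0, False),   # both arms below threshold
            (10, 0, 10, 2, True),  # discordant control excess, split arm carries it
            (0, 0, 5, 2, False),   # too many control discordant pairs
        ],
    )
    def test_or_of_two_evidence_arms(self, split_case, split_ctrl, disc_case, disc_ctrl, expected):
        call = JunctionCall(
            breakend_a=(100, "R"), breakend_b=(500, "L"),
            split_case=split_case, split_ctrl=split_ctrl,
            disc_case=disc_case, disc_ctrl=disc_ctrl,
        )
        assert call.passes is expected

    def test_breakends_canonicalised_and_insertion_reoriented(self):
        call = JunctionCall(
            breakend_a=(500, "L"), breakend_b=(100, "R"), inserted_seq="AACCC"
        )
        assert call.breakend_a == (100, "R")
        assert call.inserted_seq == revcomp("AACCC")


class TestSplitClustering:
    def split_read_rows(self, pair, primary_end, supp_start):
        return [
            (pair, 0, 0, 100, primary_end - 100, primary_end, 0, 0),
            (pair, 0, 100, 150, supp_start, supp_start + 50, 0, 1),
        ]

    def test_matching_supplementary_required(self):
        rows = []
        for p in range(2):
            rows += self.split_read_rows(p, 5_000, 20_000)
        for p in range(2, 4):
            rows += self.split_read_rows(p, 5_000, 30_000)  # same A side, far B side
        tab = make_table(rows)
        clusters = sv.cluster_split_evidence(tab, None)
        assert len(clusters) == 2
        assert sorted(c.n_case for c in clusters) == [2, 2]

    def test_empty_input(self):
        tab = make_table([(0, 0, 0, 150, 100, 250, 0, 0)])
        assert sv.cluster_split_evidence(tab, None) == []

    def test_study_split_clusters_match_truth(self, study):
        clusters = sv.cluster_split_evidence(study["case_tab"], study["ctrl_tab"])
        big = [c for c in clusters if c.n_case >= 4]
        positions = sorted({c.refined_a for c in big} | {c.refined_b for c in big})
        # the two split-covered junctions: fusion and dup1-start/dup3-start
        for true_pos in (346_084, 700_056, 788_363, 2_271_746):
            assert any(abs(p - true_pos) <= 10 for p in positions)
        assert all(c.n_ctrl == 0 for c in big)


class TestCallJunctions:
    def test_split_and_discordant_candidates_merge(self):
        split = [_Cluster("R", "L", [700_056] * 5, [788_363] * 5, n_case=5,
                          refined_a=700_056, refined_b=788_363)]
        disc = [_Cluster("R", "L", [699_900, 699_800], [788_500, 788_600], n_case=6,
                         refined_a=700_056, refined_b=788_363)]
        passing, audit = sv.call_junctions(split, disc)
        assert len(audit) == 1
        assert passing[0].split_case == 5 and passing[0].disc_case == 6

    def test_insertion_candidate_passes_without_splits(self):
        disc = [_Cluster("R", "R", [864_099], [2_351_089], n_case=7, n_ctrl=0,
                         refined_a=864_099, refined_b=2_351_089,
                         inserted_seq="A" * 500, insertion_type=True)]
        passing, _ = sv.call_junctions([], disc)
        assert len(passing) == 1
        assert passing[0].split_case == 0
        assert passing[0].inserted_seq == "A" * 500


class TestSnvClassification:
    def test_case_sample_shows_all_categories_het_sv(self, study):
        snv = next(s for s in study["ref"].snv_sites if s[0] == 699_956)
        pc = sv.classify_pairs_by_snv(
            study["case_tab"], study["case_pt"], study["case_reads"], snv,
            breakend_pos=700_056,
        )
        assert pc.category1 > 0 and pc.category2 > 0 and pc.category3 > 0
        assert pc.homolog_inference == "het_sv"
        assert pc.total_classified == pc.category1 + pc.category2 + pc.category3

    def test_control_sample_is_reference_only(self, study):
        snv = next(s for s in study["ref"].snv_sites if s[0] == 699_956)
        pc = sv.classify_pairs_by_snv(
            study["ctrl_tab"], study["ctrl_pt"], study["ctrl_reads"], snv,
            breakend_pos=700_056,
        )
        assert pc.category2 == pc.category3 == 0
        assert pc.category1 > 0
        assert pc.homolog_inference == "ambiguous"

    def test_haploid_junction_sample_is_category2_only(self):
        """A haploid genome carrying a deletion junction has no concordant
        copy of the breakend region: every breakend-spanning pair is
        discordant with the alternative allele."""
        rng = np.random.default_rng(31)
        ref_seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 40_000))
        pos = 9_950
        alt = "A" if ref_seq[pos - 1] != "A" else "C"
        hap = ref_seq[:pos - 1] + alt + ref_seq[pos - 1 + 1 : 10_000] + ref_seq[20_000:]
        reads = sg.simulate_paired_reads([hap], coverage=20, error_rate=0.0, seed=8)
        from svdissect import align

        index = align.build_index(ref_seq)
        tab = align.align_readset(reads, index)
        pt = align.classify_pairs(tab, reads.insert_mean, reads.insert_sd)
        pc = sv.classify_pairs_by_snv(
            tab, pt, reads, (pos, ref_seq[pos - 1], alt), breakend_pos=10_000
        )
        assert pc.category2 > 0
        assert pc.category1 == 0 and pc.category3 == 0
        assert pc.homolog_inference == "ambiguous"


class TestMicrohomology:
    def test_designed_slide_both_directions(self):
        # junction joins (p='...TTGG end', R) to (q='TTGG...', L); the
        # reference continues with GG after p and with TT before q
        left = "CATGCATGCA" + "TT"
        right_context = "CCCCCCCCTT"
        middle = "GG" + "ACACACACAC"
        ref_seq = left + middle + right_context + "GG" + "TGCATGCATG"
        p = len(left)  # breakend A at the last T of 'TT'
        q = len(left) + len(middle) + len(right_context) + 1  # first G of 'GG'
        call = JunctionCall(breakend_a=(p, "R"), breakend_b=(q, "L"))
        mh = sv.measure_microhomology(ref_seq, call)
        assert mh == "TTGG"

    def test_no_shared_sequence_gives_empty(self):
        ref_seq = "CCCCCCCCCCAAAAAAAAAAGGGGGGGGGGTTTTTTTTTT"
        call = JunctionCall(breakend_a=(10, "R"), breakend_b=(31, "L"))
        assert sv.measure_microhomology(ref_seq, call) == ""

    def test_planted_polya_at_dup2_dup3_junction(self, study):
        j2 = next(j for j in study["passing"] if j.inserted_seq)
        mh = sv.measure_microhomology(study["ref"].sequence, j2)
        assert mh != ""
        assert set(mh) <= {"A", "T"}


class TestInsertionAssembly:
    def test_too_few_reads_yields_empty_with_warning(self, study, caplog):
        tab = make_table([
            (0, 0, 0, 100, 9_900, 10_000, 0, 0),
            (1, 0, 0, 100, 9_900, 10_000, 0, 0),
        ])
        reads = sg.simulate_paired_reads(
            [study["ref"].sequence[:20_000]], coverage=1, seed=2
        )
        with caplog.at_level(logging.WARNING, logger="svdissect.svdetect"):
            seq, n = sv.assemble_junction_insertion(
                tab, reads, study["ref"].sequence, (10_000, "R"), (15_000, "L")
            )
        assert seq == ""

    def test_clean_junction_assembles_nothing(self, study):
        fusion_call = next(
            j for j in study["passing"]
            if abs(j.breakend_a[0] - 700_056) <= 10 or abs(j.breakend_b[0] - 700_056) <= 10
        )
        seq, _n = sv.assemble_junction_insertion(
            study["case_tab"], study["case_reads"], study["ref"].sequence,
            fusion_call.breakend_a, fusion_call.breakend_b,
        )
        assert seq == ""

    def test_study_insertion_recovered(self, study):
        j2 = next(j for j in study["passing"] if j.inserted_seq)
        assert abs(len(j2.inserted_seq) - 500) <= 2


class TestSpecificity:
    def test_control_vs_control_full_scale(self, study):
        """Swapping cohorts: the control sample against the case as control
        yields no passing junctions."""
        passing, _ = sv.detect_junctions(
            study["ctrl_tab"], study["ctrl_pt"], study["ctrl_reads"],
            study["ref"].sequence, study["case_tab"], study["case_pt"],
            400, 60,
        )
        assert passing == []

    @pytest.mark.parametrize("seed", range(10))
    def test_no_calls_on_junction_free_samples_across_seeds(self, seed):
        """Specificity at reduced scale: two junction-free cohorts from the
        same 100 kb sequence never produce a passing junction."""
        rng = np.random.default_rng(1_000 + seed)
        h = "".join("ACGT"[i] for i in rng.integers(0, 4, 100_000))
        from svdissect import align

        index = align.build_index(h)
        case = sg.simulate_paired_reads([h, h], coverage=20, seed=2_000 + seed)
        ctrl = sg.simulate_paired_reads([h, h], coverage=20, seed=3_000 + seed)
        ctab = align.align_readset(case, index)
        cpt = align.classify_pairs(ctab, case.insert_mean, case.insert_sd)
        ttab = align.align_readset(ctrl, index)
        tpt = align.classify_pairs(ttab, ctrl.insert_mean, ctrl.insert_sd)
        passing, _ = sv.detect_junctions(
            ctab, cpt, case, h, ttab, tpt, case.insert_mean, case.insert_sd
        )
        assert passing == []
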