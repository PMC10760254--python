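"""End-to-end orchestration: simulate -> align -> CNV + SV calling ->
reconstruction -> fusion prediction -> segregation, from one config and seed.

``run_all`` is deterministic for a fixed seed and writes every intermediate
in its standard format (FASTA/GFF3/FASTQ/TSV/VCF/GTF/PED/JSON) plus a
summary JSON with the headline numbers of the analysis: CNV calls, passing
junctions and breakpoints, the reconstructed derivative word(s), the
inversion span, the chimeric transcript structure and its PTC/NMD status,
and the pedigree co-segregation counts.

Among all evidence-consistent derivative words the pipeline proposes the
one with the largest contiguous inverted span. The junction geometry proves
that inverted sequence is present; gathering it into a single inversion is
the most parsimonious interpretation (one inversion event rather than
several), and matches how an orthogonal long-molecule confirmation of such
a rearrangement is read. All alternative words are still reported.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import align, cma, fusion, reconstruct, segregation, svdetect, synthgenome as sg
from ._dna import child_seed

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters; defaults reproduce the study's thresholds."""

    seed: int = 1
    reference_length: int = sg.DEFAULT_REFERENCE_LENGTH
    coverage: float = sg.DEFAULT_COVERAGE
    read_length: int = sg.DEFAULT_READ_LENGTH
    insert_mean: float = sg.DEFAULT_INSERT_MEAN
    insert_sd: float = sg.DEFAULT_INSERT_SD
    error_rate: float = sg.DEFAULT_ERROR_RATE
    probe_spacing: int = sg.DEFAULT_PROBE_SPACING
    probe_noise_sd: float = sg.DEFAULT_PROBE_NOISE_SD
    split_case_min: int = svdetect.SPLIT_CASE_MIN
    split_ctrl_max: int = svdetect.SPLIT_CTRL_MAX
    disc_case_min: int = svdetect.DISC_CASE_MIN
    disc_ctrl_max: int = svdetect.DISC_CTRL_MAX
    cnv_min_probes: int = cma.DEFAULT_MIN_PROBES
    gain_threshold: float = cma.DEFAULT_GAIN_THRESHOLD
    loss_threshold: float = cma.DEFAULT_LOSS_THRESHOLD
    window: int = svdetect.DEFAULT_WINDOW
    splice_threshold: float = fusion.DEFAULT_SPLICE_THRESHOLD
    rna_reads: int = 1_000
    rna_read_length: int = 100
    control_only: bool = False
    write_reads: bool = True

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_all(config: RunConfig, outdir: str | Path, keep_objects: bool = False):
    """Run the whole analysis; returns the summary dict (also written as
    ``summary.json`` in ``outdir``), or (summary, objects) when
    ``keep_objects`` is set — the objects dict exposes the in-memory
    intermediates (reads, alignment tables, graph, transcripts, ...)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    provenance: dict[str, str] = {}
    summary: dict = {"config": asdict(config)}

    def stage(name):
        logger.info("stage %s", name)
        return time.time()

    try:
        t = stage("simulate")
        ref = sg.make_reference(config.seed, config.reference_length)
        plan = sg.default_plan(ref)
        if config.control_only:
            plan = sg.RearrangementPlan(
                boundaries=plan.boundaries,
                word=[
                    sg.SignedSegment(s, "+")
                    for s in sorted(plan.boundaries, key=lambda k: plan.boundaries[k])
                ],
                insertions={},
            )
        derivative, truth = sg.apply_plan(ref, plan, apply_snv_alts=not config.control_only)
        case_reads = sg.simulate_paired_reads(
            [ref.sequence, derivative], config.coverage, config.read_length,
            config.insert_mean, config.insert_sd, config.error_rate,
            seed=child_seed(config.seed, 10),
        )
        ctrl_reads = sg.simulate_paired_reads(
            [ref.sequence, ref.sequence], config.coverage, config.read_length,
            config.insert_mean, config.insert_sd, config.error_rate,
            seed=child_seed(config.seed, 11),
        )
        track = sg.simulate_probe_track(
            ref, truth, config.probe_spacing, config.probe_noise_sd,
            seed=child_seed(config.seed, 12),
        )
        sg.write_fasta(out / "reference.fa", {ref.name: ref.sequence})
        sg.write_gff3(out / "genes.gff3", ref)
        sg.write_fasta(out / "derivative.fa", {ref.name + "_der": derivative})
        sg.write_probe_tsv(out / "probes.tsv", track, ref.name)
        sg.write_truth_json(out / "truth.json", truth)
        ped = sg.make_pedigree_fixture()
        sg.write_ped(out / "family.ped", out / "genotypes.tsv", ped)
        if config.write_reads:
            sg.write_fastq(out / "case_R1.fastq", case_reads, 1)
            sg.write_fastq(out / "case_R2.fastq", case_reads, 2)
            sg.write_fastq(out / "control_R1.fastq", ctrl_reads, 1)
            sg.write_fastq(out / "control_R2.fastq", ctrl_reads, 2)
        logger.info("simulate done in %.1fs", time.time() - t)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"simulate: {exc}") from exc

    try:
        t = stage("cma")
        cnv_calls = cma.call_cnvs(
            track, config.gain_threshold, config.loss_threshold, config.cnv_min_probes
        )
        for c in cnv_calls:
            c.iscn = cma.format_iscn(c)
        cma.write_calls(out / "cnv_calls.tsv", cnv_calls, ref.name)
        cma.write_calls_bed(out / "cnv_calls.bed", cnv_calls, ref.name)
        logger.info("cma done in %.1fs: %d calls", time.time() - t, len(cnv_calls))
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"cma: {exc}") from exc

    try:
        t = stage("align")
        index = align.build_index(ref.codes)
        case_tab = align.align_readset(case_reads, index)
        case_pt = align.classify_pairs(case_tab, config.insert_mean, config.insert_sd)
        ctrl_tab = align.align_readset(ctrl_reads, index)
        ctrl_pt = align.classify_pairs(ctrl_tab, config.insert_mean, config.insert_sd)
        if config.write_reads:
            align.write_sam(out / "case.sam", case_tab, case_reads, ref.name, len(ref))
        align.write_table_tsv(out / "case_alignments.tsv", case_tab)
        logger.info("align done in %.1fs", time.time() - t)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"align: {exc}") from exc

    try:
        t = stage("svcall")
        passing, audit = svdetect.detect_junctions(
            case_tab, case_pt, case_reads, ref.sequence, ctrl_tab, ctrl_pt,
            config.insert_mean, config.insert_sd, config.window,
        )
        svdetect.write_vcf(out / "junctions.vcf", passing, ref.sequence, ref.name)
        svdetect.write_audit_tsv(out / "junctions_audit.tsv", audit)
        snv_phasing = {}
        called_bps = [p for j in passing for p, _s in (j.breakend_a, j.breakend_b)]
        for snv in ref.snv_sites:
            nearest = min(called_bps, key=lambda b: abs(b - snv[0]), default=None)
            pc = svdetect.classify_pairs_by_snv(
                case_tab, case_pt, case_reads, snv, breakend_pos=nearest
            )
            snv_phasing[snv[0]] = {
                "category1": pc.category1, "category2": pc.category2,
                "category3": pc.category3, "inference": pc.homolog_inference,
            }
        logger.info("svcall done in %.1fs: %d passing", time.time() - t, len(passing))
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"svcall: {exc}") from exc

    try:
        t = stage("reconstruct")
        segments = reconstruct.segment_reference(
            cnv_calls, passing, (1, len(ref)), config.window,
            cnv_tolerance=config.probe_spacing + config.window,
        )
        graph = reconstruct.build_graph(segments, passing, config.window)
        words, truncated, diagnostic = reconstruct.solve_walks(graph)
        reconstruct.write_words(out / "derivative_words.txt", words)
        reconstruct.write_structure_json(out / "structure.json", graph, words, truncated)
        reconstruct.write_bedpe(out / "novel_adjacencies.bedpe", graph, ref.name)
        proposed = None
        inversion = None
        if words:
            def max_inv(w):
                blocks = w.inversion_blocks(graph)
                return max((ln for _s, _e, ln in blocks), default=0)

            proposed = max(words, key=lambda w: (max_inv(w), str(w)))
            inv_blocks = reconstruct.inversion_report(proposed, graph)
            if inv_blocks:
                inversion = max(inv_blocks, key=lambda b: b[1])
        logger.info("reconstruct done in %.1fs: %d words", time.time() - t, len(words))
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"reconstruct: {exc}") from exc

    try:
        t = stage("fuse")
        chimeric = []
        orf = None
        rna_support = None
        transcripts = []
        if proposed is not None and not config.control_only:
            called_plan = sg.RearrangementPlan(
                boundaries={s.seg_id: (s.start, s.end) for s in graph.segments},
                word=proposed.word,
                insertions={
                    w.segment_id[4:]: _edge_insertion(graph, proposed, w)
                    for w in proposed.word if w.is_insertion
                },
            )
            called_der, _ = sg.apply_plan(ref, called_plan)
            lifted = fusion.liftover_annotations(
                proposed.word, called_plan.boundaries, ref.genes, called_plan.insertions
            )
            sites = fusion.score_splice_sites(
                called_der, threshold=config.splice_threshold, annotations=lifted
            )
            transcripts = fusion.predict_transcripts(
                called_der, lifted, sites, config.splice_threshold
            )
            chimeric = [tr for tr in transcripts if tr.is_chimeric]
            fusion.write_gtf(out / "transcripts.gtf", transcripts, ref.name + "_der")
            fusion.write_transcript_fasta(out / "transcripts.fa", transcripts)
            if chimeric:
                orf = fusion.analyze_orf(chimeric[0], lifted, ref.genes)
                fusion.write_orf_json(out / "orf_report.json", chimeric[0], orf)
                true_seq, _labels = sg.chimeric_transcript_truth(ref, plan)
                rna = sg.simulate_rna_reads(
                    [(true_seq, 1.0)], config.rna_read_length, config.rna_reads,
                    seed=child_seed(config.seed, 13),
                )
                rna_support = fusion.verify_with_rna(chimeric[:1], rna)[0]
                fusion.write_junction_support_tsv(out / "rna_support.tsv", [rna_support])
        logger.info("fuse done in %.1fs: %d chimeric", time.time() - t, len(chimeric))
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"fuse: {exc}") from exc

    try:
        stage("segregate")
        seg_result = segregation.cosegregation_counts(ped)
        violations, transmissions = segregation.transmission_check(ped)
        segregation.write_result_json(out / "segregation.json", seg_result)
    except Exception as exc:  # noqa: BLE001
        raise StageError(f"segregate: {exc}") from exc

    breakpoints = sorted({p for j in passing for p, _s in (j.breakend_a, j.breakend_b)})
    summary.update(
        {
            "n_cnv_calls": len(cnv_calls),
            "cnv_iscn": [c.iscn for c in cnv_calls],
            "n_passing_junctions": len(passing),
            "n_breakpoints": len(breakpoints),
            "breakpoints": breakpoints,
            "junction_insertion_lengths": [len(j.inserted_seq) for j in passing],
            "microhomologies": [j.microhomology for j in passing],
            "snv_phasing": snv_phasing,
            "n_words": len(words),
            "words_truncated": truncated,
            "words": [str(w) for w in words],
            "proposed_word": str(proposed) if proposed else None,
            "inversion_interval": list(inversion[0]) if inversion else None,
            "inversion_span_bp": inversion[1] if inversion else 0,
            "walk_diagnostic": diagnostic,
            "n_transcripts": len(transcripts),
            "n_chimeric_transcripts": len(chimeric),
            "chimeric_exon_count": chimeric[0].n_exons if chimeric else 0,
            "chimeric_exon_labels": chimeric[0].exon_labels() if chimeric else [],
            "premature_stop": list(orf.premature_stop) if orf and orf.premature_stop else None,
            "frame_compatible": orf.frame_compatible if orf else None,
            "nmd_predicted": orf.nmd_predicted if orf else None,
            "rna_all_junctions_supported": rna_support.all_supported if rna_support else None,
            "rna_forward_fraction": (
                rna_support.n_forward / max(rna_support.n_forward + rna_support.n_reverse, 1)
                if rna_support else None
            ),
            "segregation": {
                "n_affected_genotyped": seg_result.n_affected_genotyped,
                "n_affected_carriers": seg_result.n_affected_carriers,
                "n_unaffected_genotyped": seg_result.n_unaffected_genotyped,
                "n_unaffected_carriers": seg_result.n_unaffected_carriers,
                "perfect_cosegregation": seg_result.perfect_cosegregation,
                "transmission_violations": len(violations),
                "carrier_transmissions": transmissions,
            },
        }
    )
    for artifact in sorted(out.iterdir()):
        if artifact.name != "summary.json" and artifact.is_file():
            provenance[artifact.name] = _sha(artifact)
    summary["provenance"] = provenance
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    if keep_objects:
        objects = {
            "ref": ref, "plan": plan, "truth": truth, "derivative": derivative,
            "case_reads": case_reads, "ctrl_reads": ctrl_reads, "track": track,
            "cnv_calls": cnv_calls, "index": index,
            "case_tab": case_tab, "case_pt": case_pt,
            "ctrl_tab": ctrl_tab, "ctrl_pt": ctrl_pt,
            "passing": passing, "audit": audit, "snv_phasing": snv_phasing,
            "segments": segments, "graph": graph, "words": words,
            "proposed": proposed, "transcripts": transcripts,
            "chimeric": chimeric, "orf": orf, "rna_support": rna_support,
            "pedigree": ped,
        }
        return summary, objects
    return summary


def _edge_insertion(graph, word, ins_segment) -> str:
    """Insertion sequence for an INS word element, from the graph's edges."""
    label = ins_segment.segment_id[4:]  # e.g. 'ins1'
    idx = int(label.replace("ins", ""))
    edges = [e for e in graph.novel_edges if not e.flagged]
    seq = edges[idx].insertion
    return seq
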