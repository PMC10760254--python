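"""Synthetic genomes emulating a complex 9p24-like rearrangement.

This module generates every input the analysis pipeline consumes, with planted
ground truth: a ~2.6 Mb reference region carrying schematic DOCK8/KANK1/DMRT1
stand-in gene models, a rearrangement plan describing a derivative homolog with
three duplications, a ~2 Mb inversion and a 500 bp SINE insertion, paired-end
DNA reads from diploid case/control samples, array probe log2-ratio tracks,
stranded RNA reads from a chosen transcript, and a five-generation pedigree.

Coordinates in the public dataclasses and in all files are 1-based inclusive;
numpy code arrays used internally are 0-based half-open.

The planted duplication boundaries are::

    dup1: 346,084..700,056    dup2: 788,363..864,099    dup3: 2,271,746..2,351,089

and the default derivative word is::

    +S0 +D1 +D2 +INS:SINE -D3 -S2 -D2 -S1 -D1 +D3 +S3

which realises exactly three novel junctions over six breakpoints, duplicates
D1/D2/D3, and inverts the whole 346,084..2,351,089 span (2,005,006 bp).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np

from ._dna import child_seed, decode, encode, random_codes, revcomp

# ---------------------------------------------------------------------------
# Planted constants
# ---------------------------------------------------------------------------

MIN_REFERENCE_LENGTH = 2_600_000
DEFAULT_REFERENCE_LENGTH = 2_600_000

DUP1 = (346_084, 700_056)
DUP2 = (788_363, 864_099)
DUP3 = (2_271_746, 2_351_089)

#: 48-nt cryptic exon cassette activated by the rearrangement.
CRYPTIC_CASSETTE = "GTACCTACGCTTGGAAGTGCCAGCACTATTACGTTTCACTCTGAACAG"
CASSETTE_START = 790_000  # 1-based start of the cassette in the reference
CASSETTE_INTERVAL = (CASSETTE_START, CASSETTE_START + len(CRYPTIC_CASSETTE) - 1)

#: Acceptor context planted immediately 5' of the cassette (ends in AG) and
#: donor context immediately 3' (starts with GT): consensus-perfect so the
#: motif scorer recovers the cassette without annotation.
CASSETTE_ACCEPTOR_CONTEXT = "TTTTTTTTTTCCAG"
CASSETTE_DONOR_CONTEXT = "GTAAGT"


def _make_sine(length: int = 500, tail: int = 16) -> str:
    """Fixed Alu-consensus-like 500 bp element ending in a polyA tail."""
    head = "GGCCGGGCGCGGTGGCTCACGCCTGTAATCCCAGCACTTTGGGAGGCCGAGGCGGGCGGATCACGAGGTCAGGAGATCGAGACCATCCCGGCTAAAACGGTGAAACCCCGTCTCTACTAAAAATACAAAAAATTAGCCGGGCGTGGTGGC"
    rng = np.random.default_rng(971_203)
    body_len = length - len(head) - tail
    body = decode(random_codes(rng, body_len))
    return head + body + "A" * tail


SINE_SEQUENCE = _make_sine()

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """Schematic gene: ordered exons, optional CDS start, promoter, role."""

    name: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    promoter: tuple[int, int]
    role: str
    cds_start: Optional[int] = None
    cds_start_phase: Optional[int] = None

    def __post_init__(self) -> None:
        ordered = self.exons if self.strand == "+" else self.exons[::-1]
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if e1 >= s2:
                raise ValueError(f"{self.name}: exons overlap or are unsorted")
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.name}: empty exon")

    @property
    def terminal_exon(self) -> tuple[int, int]:
        return self.exons[-1]


@dataclass
class ReferenceAssembly:
    """Synthetic reference region with planted features and truth coordinates."""

    name: str
    sequence: str
    genes: list[GeneModel]
    snv_sites: list[tuple[int, str, str]]  # (1-based pos, ref base, alt base)
    seed: int
    cassette_interval: tuple[int, int] = CASSETTE_INTERVAL
    planned_breakpoints: tuple[int, ...] = (
        DUP1[0], DUP1[1], DUP2[0], DUP2[1], DUP3[0], DUP3[1],
    )

    def __post_init__(self) -> None:
        self._codes = encode(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        return self._codes

    def sequence_with_alts(self) -> str:
        """Reference sequence with every planted SNV alt allele applied."""
        codes = self._codes.copy()
        for pos, _ref, alt in self.snv_sites:
            codes[pos - 1] = encode(alt)[0]
        return decode(codes)

    def gene(self, role: str) -> GeneModel:
        for g in self.genes:
            if g.role == role:
                return g
        raise KeyError(role)


@dataclass(frozen=True)
class SignedSegment:
    """One oriented element of a derivative word (segment or insertion)."""

    segment_id: str
    orientation: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.orientation not in "+-":
            raise ValueError("orientation must be '+' or '-'")

    @property
    def is_insertion(self) -> bool:
        return self.segment_id.startswith("INS:")

    def __str__(self) -> str:
        return f"{self.orientation}{self.segment_id}"


@dataclass
class RearrangementPlan:
    """Segment boundaries plus an ordered signed word describing a derivative."""

    boundaries: dict[str, tuple[int, int]]
    word: list[SignedSegment]
    insertions: dict[str, str] = field(default_factory=dict)

    def validate(self, ref_length: int) -> None:
        intervals = sorted(self.boundaries.values())
        if not intervals:
            raise ValueError("plan has no segments")
        if intervals[0][0] != 1 or intervals[-1][1] != ref_length:
            raise ValueError("segments do not tile the reference")
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            if s2 != e1 + 1:
                raise ValueError("segments overlap or leave gaps")
        order = sorted(self.boundaries, key=lambda k: self.boundaries[k])
        first, last = order[0], order[-1]
        core = [w for w in self.word if not w.is_insertion]
        if not core or core[0] != SignedSegment(first, "+") or core[-1] != SignedSegment(last, "+"):
            raise ValueError(f"word must begin with +{first} and end with +{last}")
        for w in self.word:
            if w.is_insertion:
                if w.segment_id[4:] not in self.insertions:
                    raise ValueError(f"insertion {w.segment_id} has no sequence")
            elif w.segment_id not in self.boundaries:
                raise ValueError(f"unknown segment id {w.segment_id}")

    def segment_length(self, seg_id: str) -> int:
        s, e = self.boundaries[seg_id]
        return e - s + 1


Breakend = tuple[int, str]  # (1-based position, side 'L' or 'R')


@dataclass
class TruthSet:
    """Planted ground truth derived deterministically from a plan."""

    novel_junctions: list[tuple[Breakend, Breakend, str]]
    copy_numbers: dict[str, int]
    inversion_span_bp: int
    inversion_interval: Optional[tuple[int, int]]
    expected_fusion: list[str]
    segment_intervals: dict[str, tuple[int, int]]

    @property
    def breakpoints(self) -> set[int]:
        out: set[int] = set()
        for a, b, _ins in self.novel_junctions:
            out.add(a[0])
            out.add(b[0])
        return out


@dataclass
class ReadSet:
    """Paired-end reads with recorded truth origins, stored as code matrices."""

    r1: np.ndarray  # (n, read_length) uint8
    r2: np.ndarray
    homolog: np.ndarray  # origin homolog index per pair
    frag_start: np.ndarray  # 0-based start on the origin homolog
    frag_len: np.ndarray
    flipped: np.ndarray  # True when read1 is the fragment-end mate
    read_length: int
    insert_mean: float
    insert_sd: float
    error_rate: float
    seed: int

    @property
    def n_pairs(self) -> int:
        return int(self.r1.shape[0])

    def pairs(self) -> Iterator[tuple[str, str, int, tuple[int, int]]]:
        """Yield (read1, read2, origin homolog, origin 1-based fragment interval)."""
        for i in range(self.n_pairs):
            s = int(self.frag_start[i])
            yield (
                decode(self.r1[i]),
                decode(self.r2[i]),
                int(self.homolog[i]),
                (s + 1, s + int(self.frag_len[i])),
            )


@dataclass
class ProbeTrack:
    """Array probes: strictly increasing positions with log2 copy ratios."""

    positions: np.ndarray  # 1-based
    log2: np.ndarray
    spacing: int
    noise_sd: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("probe positions must be strictly increasing")
        if not np.all(np.isfinite(self.log2)):
            raise ValueError("log2 ratios must be finite")

    def __len__(self) -> int:
        return int(self.positions.size)


@dataclass
class RnaReadSet:
    """Single-end stranded RNA reads with recorded transcript origins."""

    reads: list[str]
    origin: np.ndarray  # transcript index per read
    offset: np.ndarray  # 0-based start offset within the transcript
    read_length: int
    seed: int

    @property
    def n_reads(self) -> int:
        return len(self.reads)


@dataclass
class Pedigree:
    """Pedigree rows plus carrier genotypes for a structural variant."""

    individuals: list[tuple[str, str, Optional[str], Optional[str], str]]
    genotypes: dict[str, str]  # id -> carrier | non_carrier (untested ids absent)

    def __post_init__(self) -> None:
        ids = {row[0] for row in self.individuals}
        for _id, _sex, father, mother, affected in self.individuals:
            for parent in (father, mother):
                if parent is not None and parent not in ids:
                    raise ValueError(f"parent {parent} not in pedigree")
            if affected not in ("yes", "no", "unknown"):
                raise ValueError(f"bad affection status {affected}")
        for gid in self.genotypes:
            if gid not in ids:
                raise ValueError(f"genotype for unknown id {gid}")

    def status(self, individual_id: str) -> str:
        return self.genotypes.get(individual_id, "untested")

    def n_generations(self) -> int:
        parents = {row[0]: (row[2], row[3]) for row in self.individuals}

        def depth(iid: str) -> int:
            f, m = parents[iid]
            return 1 + max((depth(p) for p in (f, m) if p is not None), default=0)

        return max(depth(row[0]) for row in self.individuals)


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------

_STOP_CODONS = {"TAA", "TAG", "TGA"}


def _default_gene_models() -> list[GeneModel]:
    dock8 = GeneModel(
        name="DOCK8L",
        strand="+",
        exons=((341_500, 341_799), (345_900, 346_299), (347_000, 347_399)),
        promoter=(340_000, 340_999),
        role="dock8_like",
    )
    kank1 = GeneModel(
        name="KANK1L",
        strand="+",
        exons=(
            (348_600, 348_799),   # exon 1 (5' UTR)
            (349_100, 349_549),   # exon 2, CDS starts here
            (705_000, 705_199),   # exon 3, beyond the dup1 boundary
            (710_000, 710_599),   # terminal exon
        ),
        promoter=(347_500, 348_499),
        role="kank1_like",
        cds_start=349_450,        # CDS length in exon 2 = 100 ≡ 1 (mod 3)
        cds_start_phase=0,
    )
    dmrt1 = GeneModel(
        name="DMRT1L",
        strand="+",
        exons=(
            (770_000, 770_150),   # exon 1, left of dup2; CDS length 102 ≡ 0 (mod 3)
            (792_000, 792_199),
            (800_000, 800_159),
            (808_000, 808_139),
            (816_000, 816_159),
            (824_000, 824_139),
            (832_000, 832_159),
            (840_000, 840_139),
            (848_000, 848_699),   # terminal exon
        ),
        promoter=(768_800, 769_799),
        role="dmrt1_like",
        cds_start=770_049,
        cds_start_phase=0,
    )
    return [dock8, kank1, dmrt1]


_SNV_POSITIONS = (346_184, 699_956, 788_463, 863_949, 2_271_846, 2_350_989)


def _plant(codes: np.ndarray, pos_1based: int, seq: str) -> None:
    codes[pos_1based - 1 : pos_1based - 1 + len(seq)] = encode(seq)


def make_reference(
    seed: int, length: int = DEFAULT_REFERENCE_LENGTH, name: str = "chr9p_syn"
) -> ReferenceAssembly:
    """Build the synthetic reference region with all planted features.

    Deterministic for a fixed seed. ``length`` must be at least
    ``MIN_REFERENCE_LENGTH`` so that every planned breakpoint coordinate
    (up to 2,351,089) fits with flanking sequence.
    """
    length = int(length)
    if length < MIN_REFERENCE_LENGTH:
        raise ValueError(
            f"reference length {length} too small; minimum is {MIN_REFERENCE_LENGTH}"
        )
    rng = np.random.default_rng(child_seed(seed, 1))
    codes = random_codes(rng, length)
    genes = _default_gene_models()

    # Splice dinucleotides at annotated exon boundaries: AG ends the intron
    # before every internal exon, GT starts the intron after every
    # non-terminal exon.
    for gene in genes:
        for i, (s, e) in enumerate(gene.exons):
            if i > 0:
                _plant(codes, s - 2, "AG")
            if i < len(gene.exons) - 1:
                _plant(codes, e + 1, "GT")

    # Stop-free CDS from the kank1-like ATG to the end of its exon 2 so the
    # first in-frame stop of the fusion product falls inside the cassette.
    kank1 = next(g for g in genes if g.role == "kank1_like")
    cds_start = kank1.cds_start
    exon2_end = kank1.exons[1][1]
    n_codons = (exon2_end - cds_start + 1 - 3) // 3
    cds = ["ATG"]
    bases = "ACGT"
    for _ in range(n_codons):
        while True:
            codon = "".join(bases[b] for b in rng.integers(0, 4, 3))
            if codon not in _STOP_CODONS:
                break
        cds.append(codon)
    cds_seq = "".join(cds)
    cds_seq += decode(random_codes(rng, exon2_end - cds_start + 1 - len(cds_seq)))
    _plant(codes, cds_start, cds_seq)

    # Cryptic cassette with consensus-perfect acceptor/donor contexts.
    _plant(codes, CASSETTE_START - len(CASSETTE_ACCEPTOR_CONTEXT), CASSETTE_ACCEPTOR_CONTEXT)
    _plant(codes, CASSETTE_START, CRYPTIC_CASSETTE)
    _plant(codes, CASSETTE_INTERVAL[1] + 1, CASSETTE_DONOR_CONTEXT)

    # polyA/T simple repeats flanking the dup2-end / dup3-end breakpoints so
    # the dup2-dup3 junction shows polyA/T microhomology.
    _plant(codes, DUP2[1] - 7, "A" * 8)
    _plant(codes, DUP2[1] + 1, "AAAA")
    _plant(codes, DUP3[1] - 7, "T" * 8)

    snv_sites = []
    for pos in _SNV_POSITIONS:
        ref_base = "ACGT"[codes[pos - 1]]
        alt_base = "ACGT"[(codes[pos - 1] + 2) % 4]
        snv_sites.append((pos, ref_base, alt_base))

    return ReferenceAssembly(
        name=name, sequence=decode(codes), genes=genes, snv_sites=snv_sites, seed=seed
    )


# ---------------------------------------------------------------------------
# Rearrangement plan and derivative genome
# ---------------------------------------------------------------------------


def default_plan(ref: ReferenceAssembly) -> RearrangementPlan:
    """The derivative structure consistent with all planted constraints."""
    length = len(ref)
    boundaries = {
        "S0": (1, DUP1[0] - 1),
        "D1": DUP1,
        "S1": (DUP1[1] + 1, DUP2[0] - 1),
        "D2": DUP2,
        "S2": (DUP2[1] + 1, DUP3[0] - 1),
        "D3": DUP3,
        "S3": (DUP3[1] + 1, length),
    }
    word = [
        SignedSegment("S0", "+"),
        SignedSegment("D1", "+"),
        SignedSegment("D2", "+"),
        SignedSegment("INS:SINE", "+"),
        SignedSegment("D3", "-"),
        SignedSegment("S2", "-"),
        SignedSegment("D2", "-"),
        SignedSegment("S1", "-"),
        SignedSegment("D1", "-"),
        SignedSegment("D3", "+"),
        SignedSegment("S3", "+"),
    ]
    plan = RearrangementPlan(
        boundaries=boundaries, word=word, insertions={"SINE": SINE_SEQUENCE}
    )
    plan.validate(length)
    return plan


def _exit_breakend(plan: RearrangementPlan, seg: SignedSegment) -> Breakend:
    s, e = plan.boundaries[seg.segment_id]
    return (e, "R") if seg.orientation == "+" else (s, "L")


def _entry_breakend(plan: RearrangementPlan, seg: SignedSegment) -> Breakend:
    s, e = plan.boundaries[seg.segment_id]
    return (s, "L") if seg.orientation == "+" else (e, "R")


def _is_reference_adjacency(a: Breakend, b: Breakend) -> bool:
    (pa, sa), (pb, sb) = a, b
    return (sa == "R" and sb == "L" and pb == pa + 1) or (
        sa == "L" and sb == "R" and pa == pb + 1
    )


def canonical_junction(a: Breakend, b: Breakend, ins: str) -> tuple[Breakend, Breakend, str]:
    """Order breakends by (position, side); reverse-complement the insertion
    when the order flips so both orientations of a word yield one record."""
    if (a[0], a[1]) <= (b[0], b[1]):
        return (a, b, ins)
    return (b, a, revcomp(ins))


def truth_from_plan(
    ref: ReferenceAssembly, plan: RearrangementPlan, validate: bool = True
) -> TruthSet:
    if validate:
        plan.validate(len(ref))
    junctions: list[tuple[Breakend, Breakend, str]] = []
    core: list[tuple[SignedSegment, str]] = []  # (segment, insertion before it)
    pending_ins = ""
    for w in plan.word:
        if w.is_insertion:
            ins_seq = plan.insertions[w.segment_id[4:]]
            pending_ins += ins_seq if w.orientation == "+" else revcomp(ins_seq)
        else:
            core.append((w, pending_ins))
            pending_ins = ""
    for (prev, _), (cur, ins) in zip(core, core[1:]):
        a = _exit_breakend(plan, prev)
        b = _entry_breakend(plan, cur)
        if ins or not _is_reference_adjacency(a, b):
            junctions.append(canonical_junction(a, b, ins))

    copy_numbers = {seg_id: 1 for seg_id in plan.boundaries}
    for w, _ in core:
        copy_numbers[w.segment_id] += 1

    inv_spans = _inversion_spans(plan)
    if inv_spans:
        interval = max(inv_spans, key=lambda iv: iv[1] - iv[0])
        span = interval[1] - interval[0] + 1
    else:
        interval, span = None, 0

    fusion_junction = canonical_junction((DUP1[1], "R"), (DUP2[0], "L"), "")
    expected_fusion: list[str] = []
    if any(j[:2] == fusion_junction[:2] for j in junctions):
        expected_fusion = (
            ["kank1_like:exon1", "kank1_like:exon2", "cryptic48"]
            + [f"dmrt1_like:exon{i}" for i in range(2, 10)]
        )

    return TruthSet(
        novel_junctions=junctions,
        copy_numbers=copy_numbers,
        inversion_span_bp=span,
        inversion_interval=interval,
        expected_fusion=expected_fusion,
        segment_intervals=dict(plan.boundaries),
    )


def _inversion_spans(plan: RearrangementPlan) -> list[tuple[int, int]]:
    spans: list[tuple[int, int]] = []
    run: list[str] = []
    for w in plan.word:
        if not w.is_insertion and w.orientation == "-":
            run.append(w.segment_id)
        elif run and not w.is_insertion:
            spans.append(_run_span(plan, run))
            run = []
    if run:
        spans.append(_run_span(plan, run))
    return spans


def _run_span(plan: RearrangementPlan, run: list[str]) -> tuple[int, int]:
    starts = [plan.boundaries[s][0] for s in run]
    ends = [plan.boundaries[s][1] for s in run]
    return (min(starts), max(ends))


def apply_plan(
    ref: ReferenceAssembly,
    plan: RearrangementPlan,
    apply_snv_alts: bool = False,
) -> tuple[str, TruthSet]:
    """Materialise the derivative sequence and the associated truth set.

    When ``apply_snv_alts`` is set the derivative carries the planted
    heterozygous alt alleles, making the case sample heterozygous at every
    marker and phasing the alt allele with the rearranged homolog.
    """
    plan.validate(len(ref))
    base = ref.sequence_with_alts() if apply_snv_alts else ref.sequence
    parts: list[str] = []
    for w in plan.word:
        if w.is_insertion:
            ins = plan.insertions[w.segment_id[4:]]
            parts.append(ins if w.orientation == "+" else revcomp(ins))
        else:
            s, e = plan.boundaries[w.segment_id]
            seg = base[s - 1 : e]
            parts.append(seg if w.orientation == "+" else revcomp(seg))
    return "".join(parts), truth_from_plan(ref, plan)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

DEFAULT_COVERAGE = 20.0
DEFAULT_READ_LENGTH = 150
DEFAULT_INSERT_MEAN = 400.0
DEFAULT_INSERT_SD = 60.0
DEFAULT_ERROR_RATE = 0.001


def simulate_paired_reads(
    homologs: Sequence[str],
    coverage: float = DEFAULT_COVERAGE,
    read_length: int = DEFAULT_READ_LENGTH,
    insert_mean: float = DEFAULT_INSERT_MEAN,
    insert_sd: float = DEFAULT_INSERT_SD,
    error_rate: float = DEFAULT_ERROR_RATE,
    seed: int = 0,
) -> ReadSet:
    """Simulate FR paired-end reads from a set of homolog sequences.

    Fragments are drawn uniformly across homologs proportional to length;
    the pair count is ``round(total_length * coverage / (2 * read_length))``;
    substitution errors are i.i.d. per base. Deterministic per seed.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if insert_mean <= 2 * read_length:
        raise ValueError("insert_mean must exceed twice the read length")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    if insert_sd < 0:
        raise ValueError("insert_sd must be non-negative")

    codes = [encode(h) for h in homologs]
    lengths = np.array([c.size for c in codes])
    if np.any(lengths < read_length):
        raise ValueError("every homolog must be at least one read long")
    total = int(lengths.sum())
    n_pairs = int(round(total * coverage / (2 * read_length)))

    rng = np.random.default_rng(child_seed(seed, 2))
    hom = rng.choice(len(codes), size=n_pairs, p=lengths / total)
    frag = np.rint(rng.normal(insert_mean, insert_sd, size=n_pairs)).astype(np.int64)
    frag = np.maximum(frag, read_length)
    frag = np.minimum(frag, lengths[hom])
    start = (rng.random(n_pairs) * (lengths[hom] - frag + 1)).astype(np.int64)
    flipped = rng.random(n_pairs) < 0.5

    r1 = np.empty((n_pairs, read_length), dtype=np.uint8)
    r2 = np.empty((n_pairs, read_length), dtype=np.uint8)
    offsets = np.arange(read_length)
    for h, c in enumerate(codes):
        sel = np.where(hom == h)[0]
        if sel.size == 0:
            continue
        fwd = c[start[sel, None] + offsets]
        end = c[(start[sel] + frag[sel] - read_length)[:, None] + offsets]
        rev = 3 - end[:, ::-1]
        r1[sel] = fwd
        r2[sel] = rev
    # A flipped fragment was sequenced from the opposite strand: mate roles swap.
    fsel = np.where(flipped)[0]
    tmp = r1[fsel].copy()
    r1[fsel] = r2[fsel]
    r2[fsel] = tmp

    if error_rate > 0:
        for mat in (r1, r2):
            mask = rng.random(mat.shape) < error_rate
            shift = rng.integers(1, 4, size=int(mask.sum()), dtype=np.uint8)
            mat[mask] = (mat[mask] + shift) % 4

    return ReadSet(
        r1=r1, r2=r2, homolog=hom.astype(np.int32), frag_start=start,
        frag_len=frag, flipped=flipped, read_length=read_length,
        insert_mean=float(insert_mean), insert_sd=float(insert_sd),
        error_rate=float(error_rate), seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Probe track simulation
# ---------------------------------------------------------------------------

DEFAULT_PROBE_SPACING = 1_000
DEFAULT_PROBE_NOISE_SD = 0.06


def simulate_probe_track(
    ref: ReferenceAssembly,
    truth: TruthSet,
    spacing: int = DEFAULT_PROBE_SPACING,
    noise_sd: float = DEFAULT_PROBE_NOISE_SD,
    seed: int = 0,
) -> ProbeTrack:
    """Array probes every ``spacing`` bp with mean log2(CN/2) plus Gaussian noise."""
    if spacing < 100:
        raise ValueError("probe spacing must be at least 100 bp")
    positions = np.arange(spacing, len(ref) + 1, spacing, dtype=np.int64)
    cn = np.full(positions.size, 2.0)
    for seg_id, (s, e) in truth.segment_intervals.items():
        total = truth.copy_numbers.get(seg_id, 2)
        if total != 2:
            inside = (positions >= s) & (positions <= e)
            cn[inside] = total
    log2 = np.log2(cn / 2.0)
    if noise_sd > 0:
        rng = np.random.default_rng(child_seed(seed, 3))
        log2 = log2 + rng.normal(0.0, noise_sd, size=log2.size)
    return ProbeTrack(positions=positions, log2=log2, spacing=spacing, noise_sd=noise_sd)


# ---------------------------------------------------------------------------
# RNA read simulation
# ---------------------------------------------------------------------------


def simulate_rna_reads(
    transcripts: Sequence[tuple[str, float]],
    read_length: int = 100,
    n_reads: int = 1_000,
    seed: int = 0,
) -> RnaReadSet:
    """Stranded single-end RNA reads sampled from transcript sense strands."""
    if n_reads == 0 or not transcripts:
        return RnaReadSet(
            reads=[], origin=np.empty(0, np.int32), offset=np.empty(0, np.int64),
            read_length=read_length, seed=int(seed),
        )
    for seq, _expr in transcripts:
        if len(seq) < read_length:
            raise ValueError("every transcript must be at least one read long")
    rng = np.random.default_rng(child_seed(seed, 4))
    weights = np.array([max(expr, 0.0) for _seq, expr in transcripts], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("total expression must be positive")
    origin = rng.choice(len(transcripts), size=n_reads, p=weights / weights.sum())
    spans = np.array([len(seq) - read_length + 1 for seq, _ in transcripts])
    offset = (rng.random(n_reads) * spans[origin]).astype(np.int64)
    reads = [
        transcripts[t][0][o : o + read_length]
        for t, o in zip(origin.tolist(), offset.tolist())
    ]
    return RnaReadSet(
        reads=reads, origin=origin.astype(np.int32), offset=offset,
        read_length=read_length, seed=int(seed),
    )


# ---------------------------------------------------------------------------
# Pedigree fixture
# ---------------------------------------------------------------------------


def make_pedigree_fixture() -> Pedigree:
    """Five-generation pedigree: 11 genotyped affected carriers, 11 genotyped
    unaffected non-carriers, plus untested members (founder, spouses, and the
    untested affected children of the last generation)."""
    C, N, U = "carrier", "non_carrier", None
    rows: list[tuple[str, str, Optional[str], Optional[str], str, Optional[str]]] = [
        # id, sex, father, mother, affected, genotype
        ("I-1", "M", None, None, "yes", U),
        ("I-2", "F", None, None, "no", U),
        ("II-1", "M", "I-1", "I-2", "yes", C),
        ("II-2", "F", None, None, "no", U),
        ("II-3", "F", "I-1", "I-2", "yes", C),
        ("II-4", "M", None, None, "no", U),
        ("II-5", "M", "I-1", "I-2", "yes", C),
        ("II-6", "F", None, None, "no", U),
        ("II-7", "F", "I-1", "I-2", "no", N),
        ("II-8", "M", None, None, "no", U),
        ("III-1", "F", "II-1", "II-2", "yes", C),
        ("III-2", "M", "II-1", "II-2", "no", N),
        ("III-3", "M", "II-1", "II-2", "yes", C),
        ("III-4", "F", "II-4", "II-3", "no", N),
        ("III-5", "F", "II-4", "II-3", "yes", C),
        ("III-6", "M", "II-4", "II-3", "no", N),
        ("III-7", "M", "II-5", "II-6", "yes", C),
        ("III-8", "F", "II-5", "II-6", "no", N),
        ("III-9", "M", "II-8", "II-7", "no", N),
        ("III-10", "M", None, None, "no", U),  # spouse of III-1
        ("III-11", "M", None, None, "no", U),  # spouse of III-5
        ("III-12", "F", None, None, "no", U),  # spouse of III-7
        ("IV-1", "M", "III-10", "III-1", "yes", C),  # proband
        ("IV-2", "F", "III-10", "III-1", "no", N),
        ("IV-3", "F", "III-11", "III-5", "yes", C),
        ("IV-4", "M", "III-11", "III-5", "no", N),
        ("IV-5", "M", "III-11", "III-5", "yes", C),
        ("IV-6", "F", "III-7", "III-12", "no", N),
        ("IV-7", "M", "III-7", "III-12", "yes", C),
        ("IV-8", "F", None, None, "no", U),  # spouse of IV-1
        ("IV-9", "M", None, None, "no", U),  # spouse of IV-3
        ("V-1", "M", "IV-1", "IV-8", "yes", U),   # affected infant, not tested
        ("V-2", "F", "IV-1", "IV-8", "no", N),    # conceived after embryo selection
        ("V-3", "M", "IV-1", "IV-8", "no", N),    # conceived after embryo selection
        ("V-4", "F", "IV-9", "IV-3", "yes", U),   # alive affected, not tested
        ("V-5", "M", "IV-9", "IV-3", "yes", U),   # alive affected, not tested
    ]
    individuals = [(r[0], r[1], r[2], r[3], r[4]) for r in rows]
    genotypes = {r[0]: r[5] for r in rows if r[5] is not None}
    return Pedigree(individuals=individuals, genotypes=genotypes)


# ---------------------------------------------------------------------------
# True chimeric transcript (generator-side truth for RNA simulation)
# ---------------------------------------------------------------------------


def chimeric_transcript_truth(
    ref: ReferenceAssembly, plan: RearrangementPlan
) -> tuple[str, list[str]]:
    """Sequence and exon labels of the planted KANK1-like/DMRT1-like fusion
    transcript: kank1 exons 1-2, the 48-nt cryptic exon, dmrt1 exons 2-9."""
    kank1 = ref.gene("kank1_like")
    dmrt1 = ref.gene("dmrt1_like")
    seq = ref.sequence
    parts, labels = [], []
    for i, (s, e) in enumerate(kank1.exons[:2], start=1):
        parts.append(seq[s - 1 : e])
        labels.append(f"kank1_like:exon{i}")
    cs, ce = ref.cassette_interval
    parts.append(seq[cs - 1 : ce])
    labels.append("cryptic48")
    for i, (s, e) in enumerate(dmrt1.exons[1:], start=2):
        parts.append(seq[s - 1 : e])
        labels.append(f"dmrt1_like:exon{i}")
    return "".join(parts), labels


# ---------------------------------------------------------------------------
# File writers (1-based coordinates in all formats)
# ---------------------------------------------------------------------------


def write_fasta(path: str | Path, records: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(path: str | Path, ref: ReferenceAssembly) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {ref.name} 1 {len(ref)}\n")
        for gene in ref.genes:
            gs = min(gene.promoter[0], gene.exons[0][0])
            ge = max(gene.promoter[1], gene.exons[-1][1])
            attrs = f"ID={gene.name};role={gene.role}"
            if gene.cds_start is not None:
                attrs += f";cds_start={gene.cds_start};cds_start_phase={gene.cds_start_phase}"
            fh.write(
                f"{ref.name}\tsvdissect\tgene\t{gs}\t{ge}\t.\t{gene.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{ref.name}\tsvdissect\tpromoter\t{gene.promoter[0]}\t{gene.promoter[1]}"
                f"\t.\t{gene.strand}\t.\tParent={gene.name}\n"
            )
            for i, (s, e) in enumerate(gene.exons, start=1):
                fh.write(
                    f"{ref.name}\tsvdissect\texon\t{s}\t{e}\t.\t{gene.strand}\t.\t"
                    f"Parent={gene.name};exon_number={i}\n"
                )
        cs, ce = ref.cassette_interval
        fh.write(
            f"{ref.name}\tsvdissect\tcryptic_exon\t{cs}\t{ce}\t.\t+\t.\tID=cryptic48\n"
        )


def write_fastq(path: str | Path, reads: ReadSet, mate: int) -> None:
    mat = reads.r1 if mate == 1 else reads.r2
    qual = "I" * reads.read_length
    with open(path, "w") as fh:
        for i in range(reads.n_pairs):
            fh.write(f"@pair{i}/{mate}\n{decode(mat[i])}\n+\n{qual}\n")


def write_probe_tsv(path: str | Path, track: ProbeTrack, chrom: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tprobe_id\tlog2\n")
        for i, (pos, val) in enumerate(zip(track.positions.tolist(), track.log2.tolist())):
            fh.write(f"{chrom}\t{pos}\tP{i:06d}\t{val:.6f}\n")


def read_probe_tsv(path: str | Path) -> ProbeTrack:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    positions = df["pos"].to_numpy(np.int64)
    spacing = int(np.min(np.diff(positions))) if positions.size > 1 else 0
    return ProbeTrack(
        positions=positions, log2=df["log2"].to_numpy(float),
        spacing=spacing, noise_sd=float("nan"),
    )


def write_ped(path: str | Path, genotype_path: str | Path, ped: Pedigree) -> None:
    sex_code = {"M": "1", "F": "2"}
    aff_code = {"no": "1", "yes": "2", "unknown": "0"}
    with open(path, "w") as fh:
        for iid, sex, father, mother, affected in ped.individuals:
            fh.write(
                "\t".join(
                    ["FAM1", iid, father or "0", mother or "0",
                     sex_code[sex], aff_code[affected]]
                )
                + "\n"
            )
    with open(genotype_path, "w") as fh:
        fh.write("id\tcarrier_status\n")
        for iid, *_ in ped.individuals:
            fh.write(f"{iid}\t{ped.status(iid)}\n")


def read_ped(path: str | Path, genotype_path: str | Path) -> Pedigree:
    sex_code = {"1": "M", "2": "F", "0": "M"}
    aff_code = {"1": "no", "2": "yes", "0": "unknown"}
    individuals = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            _fam, iid, father, mother, sex, aff = line.split()[:6]
            individuals.append(
                (iid, sex_code[sex], None if father == "0" else father,
                 None if mother == "0" else mother, aff_code[aff])
            )
    genotypes = {}
    with open(genotype_path) as fh:
        next(fh)
        for line in fh:
            iid, status = line.split()
            if status != "untested":
                genotypes[iid] = status
    return Pedigree(individuals=individuals, genotypes=genotypes)


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models (with role/CDS attributes) back from GFF3."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        exons = sorted(
            (f.start, f.end)
            for f in db.features_of_type("exon")
            if f.attributes.get("Parent", [None])[0] == g.id
        )
        promoter = next(
            (f.start, f.end)
            for f in db.features_of_type("promoter")
            if f.attributes.get("Parent", [None])[0] == g.id
        )
        cds_start = g.attributes.get("cds_start", [None])[0]
        phase = g.attributes.get("cds_start_phase", [None])[0]
        genes.append(
            GeneModel(
                name=g.id, strand=g.strand, exons=tuple(exons), promoter=promoter,
                role=g.attributes.get("role", ["other"])[0],
                cds_start=int(cds_start) if cds_start is not None else None,
                cds_start_phase=int(phase) if phase is not None else None,
            )
        )
    return genes


def write_truth_json(path: str | Path, truth: TruthSet) -> None:
    payload = {
        "novel_junctions": [
            {"breakend_a": list(a), "breakend_b": list(b), "inserted_seq": ins}
            for a, b, ins in truth.novel_junctions
        ],
        "copy_numbers": truth.copy_numbers,
        "inversion_span_bp": truth.inversion_span_bp,
        "inversion_interval": truth.inversion_interval,
        "expected_fusion": truth.expected_fusion,
        "segment_intervals": {k: list(v) for k, v in truth.segment_intervals.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2))
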