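"""Breakpoint junction detection with case/control filters.

Evidence model (mirrors a manual WGS breakpoint analysis):

* split reads — one read aligned in two blocks to different loci/strands,
  clustered only when primary-end and supplementary-start breakends AND the
  supplementary locus/strand agree within a small window;
* discordant pairs — both mates mapped but violating FR geometry or the
  insert-size window, clustered by mate positions and strands; pairs with
  one unmapped mate (one-end-anchored) are counted on the discordant arm
  too, which is how an insertion of novel sequence longer than the library
  insert presents in short-read data;
* a junction call passes when split support is >= 4 in case with 0 in
  control, OR discordant support is >= 5 in case with <= 1 in control
  (the two arms are OR-ed: an insertion junction can pass with no split
  reads at all).

The module also classifies read pairs at a heterozygous SNV near a breakend
into (1) concordant/reference, (2) discordant/alternative, (3)
concordant/alternative — category 3 demonstrates that both homologs carry a
reference-structure copy of the breakend region — measures junction
microhomology, and assembles inserted sequence from clipped tails and
orphaned mates.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ._dna import decode, revcomp
from .align import AlignmentTable, PairTable
from .synthgenome import ReadSet

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 10
SPLIT_CASE_MIN = 4
SPLIT_CTRL_MAX = 0
DISC_CASE_MIN = 5
DISC_CTRL_MAX = 1
MIN_CLIP_EVIDENCE = 20
MIN_ASSEMBLY_READS = 3
MIN_ASSEMBLY_OVERLAP = 20

Breakend = tuple[int, str]  # (1-based position, 'L' | 'R')


@dataclass
class JunctionCall:
    """A pair of breakends with case/control evidence counts."""

    breakend_a: Breakend
    breakend_b: Breakend
    split_case: int = 0
    split_ctrl: int = 0
    disc_case: int = 0
    disc_ctrl: int = 0
    inserted_seq: str = ""
    microhomology: str = ""

    def __post_init__(self) -> None:
        if (self.breakend_a[0], self.breakend_a[1]) > (self.breakend_b[0], self.breakend_b[1]):
            self.breakend_a, self.breakend_b = self.breakend_b, self.breakend_a
            self.inserted_seq = revcomp(self.inserted_seq)

    @property
    def passes(self) -> bool:
        split_ok = self.split_case >= SPLIT_CASE_MIN and self.split_ctrl <= SPLIT_CTRL_MAX
        disc_ok = self.disc_case >= DISC_CASE_MIN and self.disc_ctrl <= DISC_CTRL_MAX
        return split_ok or disc_ok


@dataclass
class PairClassification:
    """Read-pair categories at one SNV near a breakend."""

    category1: int  # concordant pair, reference allele
    category2: int  # discordant pair, alternative allele
    category3: int  # concordant pair, alternative allele
    unclassified: int = 0

    @property
    def homolog_inference(self) -> str:
        return "het_sv" if self.category1 > 0 and self.category2 > 0 else "ambiguous"

    @property
    def total_classified(self) -> int:
        return self.category1 + self.category2 + self.category3


# ---------------------------------------------------------------------------
# Split-read evidence
# ---------------------------------------------------------------------------


def _split_adjacencies(tab: AlignmentTable) -> list[tuple[Breakend, Breakend]]:
    """Breakend pairs implied by adjacent blocks of each split read."""
    supp_idx = np.flatnonzero(tab.is_supplementary)
    keys = {(int(tab.pair_idx[i]), int(tab.mate[i])) for i in supp_idx}
    out: list[tuple[Breakend, Breakend]] = []
    for p, m in keys:
        sel = np.flatnonzero((tab.pair_idx == p) & (tab.mate == m))
        sel = sel[np.argsort(tab.read_start[sel])]
        for a, b in zip(sel, sel[1:]):
            if tab.strand[a] == 0:
                ea: Breakend = (int(tab.ref_end[a]), "R")
            else:
                ea = (int(tab.ref_start[a]) + 1, "L")
            if tab.strand[b] == 0:
                eb: Breakend = (int(tab.ref_start[b]) + 1, "L")
            else:
                eb = (int(tab.ref_end[b]), "R")
            if ea <= eb:
                out.append((ea, eb))
            else:
                out.append((eb, ea))
    return out


@dataclass
class _Cluster:
    side_a: str
    side_b: str
    pos_a: list[int]
    pos_b: list[int]
    n_case: int = 0
    n_ctrl: int = 0
    refined_a: Optional[int] = None
    refined_b: Optional[int] = None
    inserted_seq: str = ""
    insertion_type: bool = False

    def center(self) -> tuple[float, float]:
        return (float(np.mean(self.pos_a)), float(np.mean(self.pos_b)))


def _cluster_breakend_pairs(
    items: list[tuple[Breakend, Breakend, bool]], window: float
) -> list[_Cluster]:
    """Greedy clustering of (breakend_a, breakend_b, is_case) records; both
    breakends and both sides must agree within the window."""
    clusters: list[_Cluster] = []
    for (pa, sa), (pb, sb), is_case in sorted(items, key=lambda t: (t[0], t[1])):
        home = None
        for cl in clusters:
            ca, cb = cl.center()
            if (
                cl.side_a == sa and cl.side_b == sb
                and abs(pa - ca) <= window and abs(pb - cb) <= window
            ):
                home = cl
                break
        if home is None:
            home = _Cluster(side_a=sa, side_b=sb, pos_a=[], pos_b=[])
            clusters.append(home)
        home.pos_a.append(pa)
        home.pos_b.append(pb)
        if is_case:
            home.n_case += 1
        else:
            home.n_ctrl += 1
    return clusters


def cluster_split_evidence(
    case_aln: AlignmentTable,
    ctrl_aln: Optional[AlignmentTable],
    window: int = DEFAULT_WINDOW,
) -> list[_Cluster]:
    """Candidate junctions from split reads, case and control tallied
    together so control support lands in the matching cluster."""
    items = [(a, b, True) for a, b in _split_adjacencies(case_aln)]
    if ctrl_aln is not None:
        items += [(a, b, False) for a, b in _split_adjacencies(ctrl_aln)]
    clusters = _cluster_breakend_pairs(items, window)
    for cl in clusters:
        # split breakends are base-precise (up to microhomology slide)
        cl.refined_a = int(Counter(cl.pos_a).most_common(1)[0][0])
        cl.refined_b = int(Counter(cl.pos_b).most_common(1)[0][0])
    return clusters


# ---------------------------------------------------------------------------
# Discordant-pair evidence (including one-end-anchored insertion evidence)
# ---------------------------------------------------------------------------


def _mate_breakend(strand: int, ref_start: int, ref_end: int) -> Breakend:
    """Junction side implied by one mate: the fragment continues past the
    read's 3' end, i.e. ref-right for '+' and ref-left for '-'."""
    return (int(ref_end), "R") if strand == 0 else (int(ref_start) + 1, "L")


def _discordant_items(pt: PairTable) -> list[tuple[Breakend, Breakend]]:
    both = pt.mapped.all(axis=1)
    disc = both & ~pt.concordant
    out = []
    for i in np.flatnonzero(disc):
        b1 = _mate_breakend(pt.strand[i, 0], pt.ref_start[i, 0], pt.ref_end[i, 0])
        b2 = _mate_breakend(pt.strand[i, 1], pt.ref_start[i, 1], pt.ref_end[i, 1])
        out.append((b1, b2) if b1 <= b2 else (b2, b1))
    return out


def _oea_items(pt: PairTable) -> list[tuple[Breakend, int]]:
    """(anchored breakend, pair index) for pairs with one unmapped mate."""
    one = pt.mapped.sum(axis=1) == 1
    out = []
    for i in np.flatnonzero(one):
        m = 0 if pt.mapped[i, 0] else 1
        out.append((_mate_breakend(pt.strand[i, m], pt.ref_start[i, m], pt.ref_end[i, m]), int(i)))
    return out


def refine_breakend_with_clips(
    tab: AlignmentTable,
    approx_pos: float,
    side: str,
    slack: float,
    min_clip: int = MIN_CLIP_EVIDENCE,
    min_support: int = 2,
) -> Optional[int]:
    """Soft-clip consensus position near an approximate breakend estimate.

    Clips attach at a block's ref-right edge for side R and ref-left edge
    for side L regardless of strand; the most common exact position wins
    when at least ``min_support`` clipped reads agree.
    """
    prim = ~tab.is_supplementary
    clip_l = tab.read_start
    clip_r = tab.read_length - tab.read_end
    if side == "R":
        has_clip = ((tab.strand == 0) & (clip_r >= min_clip)) | (
            (tab.strand == 1) & (clip_l >= min_clip)
        )
        pos = tab.ref_end
    else:
        has_clip = ((tab.strand == 0) & (clip_l >= min_clip)) | (
            (tab.strand == 1) & (clip_r >= min_clip)
        )
        pos = tab.ref_start + 1
    sel = prim & has_clip & (np.abs(pos - approx_pos) <= slack)
    if not np.any(sel):
        return None
    common = Counter(pos[sel].tolist()).most_common(1)[0]
    if common[1] < min_support:
        return None
    return int(common[0])


def cluster_discordant_evidence(
    case_aln: AlignmentTable,
    case_pairs: PairTable,
    ctrl_aln: Optional[AlignmentTable],
    ctrl_pairs: Optional[PairTable],
    insert_mean: float,
    insert_sd: float,
    window: int = DEFAULT_WINDOW,
) -> list[_Cluster]:
    """Candidate junctions from discordant mate pairs.

    Mate coordinates of pairs spanning one junction scatter over the
    fragment length, so clustering uses an insert-sized window
    (insert_mean + 4 sd); the implied breakend is the innermost mate
    coordinate, refined to the soft-clip consensus when clipped reads
    pinpoint the junction.
    """
    big_window = insert_mean + 4 * insert_sd
    items = [(a, b, True) for a, b in _discordant_items(case_pairs)]
    if ctrl_pairs is not None:
        items += [(a, b, False) for a, b in _discordant_items(ctrl_pairs)]
    clusters = _cluster_breakend_pairs(items, big_window)
    for cl in clusters:
        est_a = max(cl.pos_a) if cl.side_a == "R" else min(cl.pos_a)
        est_b = max(cl.pos_b) if cl.side_b == "R" else min(cl.pos_b)
        cl.refined_a = refine_breakend_with_clips(case_aln, est_a, cl.side_a, big_window) or int(est_a)
        cl.refined_b = refine_breakend_with_clips(case_aln, est_b, cl.side_b, big_window) or int(est_b)
    return clusters


def cluster_insertion_evidence(
    case_aln: AlignmentTable,
    case_pairs: PairTable,
    case_reads: ReadSet,
    ref_seq: str,
    ctrl_aln: Optional[AlignmentTable],
    ctrl_pairs: Optional[PairTable],
    insert_mean: float,
    insert_sd: float,
    window: int = DEFAULT_WINDOW,
    min_side_support: int = 2,
) -> list[_Cluster]:
    """Insertion-type junction candidates from one-end-anchored pairs.

    Anchored mates are clustered per breakend side; two facing clusters are
    joined into one junction when the clipped tails and orphaned mates from
    both sides assemble into a single inserted-sequence contig.
    """
    big_window = insert_mean + 4 * insert_sd
    sides: list[dict] = []
    for (pa, sa), pair_i in sorted(_oea_items(case_pairs)):
        home = None
        for s in sides:
            if s["side"] == sa and abs(pa - np.mean(s["pos"])) <= big_window:
                home = s
                break
        if home is None:
            home = {"side": sa, "pos": [], "pairs": []}
            sides.append(home)
        home["pos"].append(pa)
        home["pairs"].append(pair_i)
    sides = [s for s in sides if len(s["pairs"]) >= min_side_support]
    for s in sides:
        est = max(s["pos"]) if s["side"] == "R" else min(s["pos"])
        s["breakend"] = (
            refine_breakend_with_clips(case_aln, est, s["side"], big_window) or int(est),
            s["side"],
        )

    # count control one-end-anchored pairs near each side
    ctrl_counts = [0] * len(sides)
    if ctrl_pairs is not None:
        for (pa, sa), _ in _oea_items(ctrl_pairs):
            for i, s in enumerate(sides):
                if s["side"] == sa and abs(pa - s["breakend"][0]) <= big_window:
                    ctrl_counts[i] += 1

    clusters: list[_Cluster] = []
    used: set[int] = set()
    for i in range(len(sides)):
        for j in range(i + 1, len(sides)):
            if i in used or j in used:
                continue
            be_i, be_j = sides[i]["breakend"], sides[j]["breakend"]
            a, b = (be_i, be_j) if be_i <= be_j else (be_j, be_i)
            contig, n_support = assemble_junction_insertion(
                case_aln, case_reads, ref_seq, a, b, window=window,
                extra_pair_indices=sides[i]["pairs"] + sides[j]["pairs"],
            )
            if not contig:
                continue
            cl = _Cluster(
                side_a=a[1], side_b=b[1], pos_a=[a[0]], pos_b=[b[0]],
                n_case=len(sides[i]["pairs"]) + len(sides[j]["pairs"]),
                n_ctrl=ctrl_counts[i] + ctrl_counts[j],
                refined_a=a[0], refined_b=b[0],
                inserted_seq=contig, insertion_type=True,
            )
            clusters.append(cl)
            used.update((i, j))
    return clusters


# ---------------------------------------------------------------------------
# Junction calling: merge evidence arms, apply case/control filters
# ---------------------------------------------------------------------------


def call_junctions(
    split_clusters: Sequence[_Cluster],
    disc_clusters: Sequence[_Cluster],
    window: int = DEFAULT_WINDOW,
    insert_scale: float = 640.0,
) -> tuple[list[JunctionCall], list[JunctionCall]]:
    """Merge split and discordant candidates and apply the evidence filters.

    Returns (passing junctions, full audit list including rejected
    candidates). Split/refined positions merge within ``window``;
    a discordant candidate whose breakends could not be clip-refined merges
    within ``insert_scale``.
    """
    calls: list[JunctionCall] = []

    def find(cl: _Cluster, tol: float) -> Optional[JunctionCall]:
        for c in calls:
            if (
                c.breakend_a[1] == cl.side_a and c.breakend_b[1] == cl.side_b
                and abs(c.breakend_a[0] - cl.refined_a) <= tol
                and abs(c.breakend_b[0] - cl.refined_b) <= tol
            ):
                return c
        return None

    for cl in split_clusters:
        c = find(cl, window)
        if c is None:
            c = JunctionCall((cl.refined_a, cl.side_a), (cl.refined_b, cl.side_b))
            calls.append(c)
        c.split_case += cl.n_case
        c.split_ctrl += cl.n_ctrl
    for cl in disc_clusters:
        tol = window if cl.insertion_type or _was_refined(cl) else insert_scale
        c = find(cl, tol)
        if c is None:
            c = JunctionCall((cl.refined_a, cl.side_a), (cl.refined_b, cl.side_b))
            calls.append(c)
        c.disc_case += cl.n_case
        c.disc_ctrl += cl.n_ctrl
        if cl.inserted_seq and not c.inserted_seq:
            c.inserted_seq = cl.inserted_seq

    passing = [c for c in calls if c.passes]
    return passing, calls


def _was_refined(cl: _Cluster) -> bool:
    # a cluster is breakend-precise when a clip consensus replaced the
    # innermost-mate estimate; heuristically: refined position coincides
    # with one of the member positions exactly and >= 2 members agree
    return (
        Counter(cl.pos_a)[cl.refined_a] >= 2 or Counter(cl.pos_b)[cl.refined_b] >= 2
        or cl.insertion_type
    )


def detect_junctions(
    case_aln: AlignmentTable,
    case_pairs: PairTable,
    case_reads: ReadSet,
    ref_seq: str,
    ctrl_aln: Optional[AlignmentTable],
    ctrl_pairs: Optional[PairTable],
    insert_mean: float,
    insert_sd: float,
    window: int = DEFAULT_WINDOW,
) -> tuple[list[JunctionCall], list[JunctionCall]]:
    """Full junction detection: split + discordant + insertion evidence,
    microhomology annotated on passing calls."""
    split_cl = cluster_split_evidence(case_aln, ctrl_aln, window)
    disc_cl = cluster_discordant_evidence(
        case_aln, case_pairs, ctrl_aln, ctrl_pairs, insert_mean, insert_sd, window
    )
    ins_cl = cluster_insertion_evidence(
        case_aln, case_pairs, case_reads, ref_seq, ctrl_aln, ctrl_pairs,
        insert_mean, insert_sd, window,
    )
    passing, audit = call_junctions(split_cl, list(disc_cl) + list(ins_cl), window,
                                    insert_scale=insert_mean + 4 * insert_sd)
    for call in passing:
        call.microhomology = measure_microhomology(ref_seq, call)
    return passing, audit


# ---------------------------------------------------------------------------
# SNV-based read-pair classification
# ---------------------------------------------------------------------------


def classify_pairs_by_snv(
    tab: AlignmentTable,
    pairs: PairTable,
    reads: ReadSet,
    snv: tuple[int, str, str],
    breakend_pos: Optional[int] = None,
) -> PairClassification:
    """Classify read pairs at one heterozygous SNV near a breakend.

    Only pairs whose mapped span covers ``breakend_pos`` (when given) are
    classified: the categories describe how pairs crossing the breakend
    region behave, so a haploid genome carrying the junction shows
    category 2 only — it has no concordant copy of the breakend region.
    """
    pos, ref_base, alt_base = snv
    p0 = pos - 1
    prim = ~tab.is_supplementary
    cover = prim & (tab.ref_start <= p0) & (tab.ref_end > p0)
    if breakend_pos is not None:
        b0 = breakend_pos - 1
        span_lo = np.where(pairs.mapped, pairs.ref_start, np.iinfo(np.int64).max).min(axis=1)
        span_hi = np.where(pairs.mapped, pairs.ref_end, 0).max(axis=1)
        pair_ok = (span_lo <= b0) & (span_hi > b0)
        cover &= pair_ok[tab.pair_idx]
    allele_by_pair: dict[int, set[str]] = {}
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for i in np.flatnonzero(cover):
        p, m = int(tab.pair_idx[i]), int(tab.mate[i])
        mat = reads.r1 if m == 0 else reads.r2
        off = p0 - int(tab.ref_start[i])
        if tab.strand[i] == 0:
            base = "ACGT"[mat[p][int(tab.read_start[i]) + off]]
        else:
            base = comp["ACGT"[mat[p][int(tab.read_end[i]) - 1 - off]]]
        allele_by_pair.setdefault(p, set()).add(base)

    # a pair whose primary alignment carries a long soft clip holds
    # alternative structure in the read itself and is not a concordant copy
    prim_clipped = prim & (
        (tab.read_start >= MIN_CLIP_EVIDENCE)
        | (tab.read_length - tab.read_end >= MIN_CLIP_EVIDENCE)
    )
    clipped_pairs = set(tab.pair_idx[prim_clipped].tolist())

    c1 = c2 = c3 = other = 0
    for p, alleles in allele_by_pair.items():
        if len(alleles) != 1:
            other += 1
            continue
        allele = alleles.pop()
        concordant = bool(pairs.concordant[p]) and p not in clipped_pairs
        if concordant and allele == ref_base:
            c1 += 1
        elif not concordant and allele == alt_base:
            c2 += 1
        elif concordant and allele == alt_base:
            c3 += 1
        else:
            other += 1
    return PairClassification(category1=c1, category2=c2, category3=c3, unclassified=other)


# ---------------------------------------------------------------------------
# Microhomology
# ---------------------------------------------------------------------------

_MH_SCAN = 200


def _flank_strings(ref_seq: str, breakend: Breakend) -> tuple[str, str]:
    """(into-junction flank ending at the breakend, reference continuation
    past the breakend), both in the walk orientation of the breakend."""
    pos, side = breakend
    lo = max(0, pos - _MH_SCAN)
    hi = min(len(ref_seq), pos + _MH_SCAN)
    if side == "R":
        into = ref_seq[lo:pos]
        cont = ref_seq[pos:hi]
    else:
        into = revcomp(ref_seq[pos - 1 : hi])
        cont = revcomp(ref_seq[lo : pos - 1])
    return into, cont


def measure_microhomology(ref_seq: str, junction: JunctionCall) -> str:
    """Longest sequence by which the junction position is ambiguous.

    The breakpoint can slide right by r bases when the reference
    continuation past breakend A matches the first r bases entering B, and
    left by l bases when the flank ending at A matches B's reference
    context just before its breakend. The reported string is the ambiguous
    region in the reference orientation of breakend A.
    """
    in_a, cont_a = _flank_strings(ref_seq, junction.breakend_a)
    # walking out of A enters B against B's walk orientation
    pos_b, side_b = junction.breakend_b
    in_b, cont_b = _flank_strings(ref_seq, (pos_b, side_b))
    out_b = revcomp(in_b)  # sequence leaving the junction into B, A-frame
    pre_b = revcomp(cont_b)  # B's reference context before the junction, A-frame

    r = 0
    while r < min(len(cont_a), len(out_b)) and cont_a[r] == out_b[r]:
        r += 1
    l = 0
    while l < min(len(in_a), len(pre_b)) and in_a[-1 - l] == pre_b[-1 - l]:
        l += 1
    if l + r == 0:
        return ""
    left_part = in_a[len(in_a) - l :] if l else ""
    right_part = out_b[:r]
    return left_part + right_part


# ---------------------------------------------------------------------------
# Insertion assembly
# ---------------------------------------------------------------------------


def _clip_tails(
    tab: AlignmentTable,
    reads: ReadSet,
    breakend: Breakend,
    window: int,
    min_clip: int,
) -> list[str]:
    """Clip sequences continuing past a breakend, in walk-out orientation."""
    pos, side = breakend
    prim = ~tab.is_supplementary
    tails: list[str] = []
    # only clips at exactly the breakend position: a read whose block
    # extension stopped early (sequencing error near the junction) carries
    # flank bases at the start of its tail and would shift the assembly
    if side == "R":
        sel = prim & (tab.ref_end == pos)
    else:
        sel = prim & (tab.ref_start + 1 == pos)
    for i in np.flatnonzero(sel):
        p, m = int(tab.pair_idx[i]), int(tab.mate[i])
        seq = decode((reads.r1 if m == 0 else reads.r2)[p])
        rs, re = int(tab.read_start[i]), int(tab.read_end[i])
        plus = tab.strand[i] == 0
        if side == "R":
            tail = seq[re:] if plus else revcomp(seq[:rs])
        else:
            tail = revcomp(seq[:rs]) if plus else seq[re:]
        if len(tail) >= min_clip:
            tails.append(tail)
    return tails


def _expected_partner_flank(ref_seq: str, partner: Breakend, n: int) -> str:
    """Reference sequence entering the partner breakend, read in the walk
    direction out of the other side (clean-junction continuation)."""
    pos, side = partner
    if side == "L":
        return ref_seq[pos - 1 : pos - 1 + n]
    return revcomp(ref_seq[max(0, pos - n) : pos])


def _matches(a: str, b: str, max_frac: float = 0.1) -> bool:
    n = min(len(a), len(b))
    if n == 0:
        return False
    mism = sum(1 for x, y in zip(a[:n], b[:n]) if x != y)
    return mism <= max_frac * n


def _matches_with_shift(tail: str, expected: str, window: int) -> bool:
    for shift in range(window + 1):
        if _matches(tail, expected[shift:]):
            return True
        if _matches(tail[shift:], expected):
            return True
    return False


def assemble_junction_insertion(
    tab: AlignmentTable,
    reads: ReadSet,
    ref_seq: str,
    breakend_a: Breakend,
    breakend_b: Breakend,
    window: int = DEFAULT_WINDOW,
    extra_pair_indices: Optional[Sequence[int]] = None,
    min_reads: int = MIN_ASSEMBLY_READS,
    min_overlap: int = MIN_ASSEMBLY_OVERLAP,
) -> tuple[str, int]:
    """Assemble inserted sequence at a junction from clipped tails and
    orphaned mates.

    Clip tails that simply continue into the partner breakend's reference
    flank are discarded (clean junction). Remaining tails from side A seed
    the contig in A-frame; side-B tails are reverse-complemented into the
    same frame; unmapped mates are tried in both orientations. Greedy
    overlap layout (min overlap 20 bp) with per-column majority vote.
    Returns (consensus, supporting reads); empty consensus when fewer than
    ``min_reads`` informative reads exist.
    """
    tails_a = _clip_tails(tab, reads, breakend_a, window, min_overlap)
    tails_b = _clip_tails(tab, reads, breakend_b, window, min_overlap)
    # clean-junction tails continue straight into the partner flank; called
    # breakends can sit a few bases off the true junction (microhomology
    # slide), so the comparison tolerates small shifts
    exp_a = _expected_partner_flank(ref_seq, breakend_b, 200)
    exp_b = _expected_partner_flank(ref_seq, breakend_a, 200)
    tails_a = [t for t in tails_a if not _matches_with_shift(t, exp_a, window)]
    tails_b = [t for t in tails_b if not _matches_with_shift(t, exp_b, window)]

    mates: list[str] = []
    if extra_pair_indices:
        for p in set(int(x) for x in extra_pair_indices):
            mapped_mates = set(
                int(tab.mate[i])
                for i in np.flatnonzero((tab.pair_idx == p) & ~tab.is_supplementary)
            )
            for m in (0, 1):
                if m not in mapped_mates:
                    mates.append(decode((reads.r1 if m == 0 else reads.r2)[p]))

    n_informative = len(tails_a) + len(tails_b) + len(mates)
    if n_informative < min_reads or not (tails_a or tails_b):
        if n_informative:
            logger.warning(
                "junction %s-%s: only %d informative reads, insertion not assembled",
                breakend_a, breakend_b, n_informative,
            )
        return "", n_informative

    # oriented reads anchored in a common frame: side-A tails start the
    # insertion, reverse-complemented side-B tails end it, orphan mates can
    # land anywhere in either orientation
    fixed_left = sorted(tails_a, key=len, reverse=True)
    fixed_right = sorted((revcomp(t) for t in tails_b), key=len, reverse=True)
    floating = mates

    if fixed_left:
        contig, seed_kind = fixed_left[0], "left"
    else:
        contig, seed_kind = fixed_right[0], "right"
    placed: list[tuple[int, str]] = [(0, contig)]
    b_end = len(contig) if seed_kind == "right" else None
    pool: list[tuple[str, str]] = (
        [(s, "left") for s in fixed_left[1:]]
        + [(s, "right") for s in fixed_right[1:] if seed_kind == "right"]
        + ([(s, "right") for s in fixed_right] if seed_kind == "left" else [])
        + [(s, "mate") for m in floating for s in (m, revcomp(m))]
    )
    progress = True
    while progress and pool:
        progress = False
        best = None
        for idx, (seq, _kind) in enumerate(pool):
            hit = _best_overlap(contig, seq, min_overlap)
            if hit is not None and hit[1] > 0:
                if best is None or hit[1] > best[2]:
                    best = (idx, hit[0], hit[1])
        if best is not None:
            idx, off, _ext = best
            seq, kind = pool.pop(idx)
            placed.append((off, seq))
            contig = contig + seq[len(contig) - off :]
            if kind == "right":
                b_end = max(b_end or 0, off + len(seq))
            progress = True

    # place remaining reads that are fully contained, then majority vote
    for seq, kind in pool:
        hit = _best_overlap(contig, seq, min_overlap)
        if hit is not None:
            placed.append((hit[0], seq))
            if kind == "right":
                b_end = max(b_end or 0, hit[0] + len(seq))
    consensus = _vote(placed, len(contig))
    # side-B clip tails end exactly at the insertion's 3' boundary, so they
    # delimit the contig; orphan mates straddling that boundary would
    # otherwise drag reference flank bases in
    if b_end is not None:
        consensus = consensus[:b_end]
    return consensus, n_informative


def _vote(placed: list[tuple[int, str]], length: int) -> str:
    counts = np.zeros((length, 4), dtype=np.int32)
    lut = {"A": 0, "C": 1, "G": 2, "T": 3}
    for off, seq in placed:
        for i, ch in enumerate(seq):
            if 0 <= off + i < length:
                counts[off + i, lut[ch]] += 1
    covered = counts.sum(axis=1) > 0
    best = counts.argmax(axis=1)
    return "".join("ACGT"[b] for b, c in zip(best, covered) if c)


def _best_overlap(contig: str, read: str, min_overlap: int) -> Optional[tuple[int, int]]:
    """Place ``read`` against the contig by exact seed search.

    The read's first ``min_overlap`` bases are located in the contig and
    the full overlap verified with a 10% mismatch allowance. Returns
    (offset of the read within the contig, bases of rightward extension),
    preferring the largest-overlap placement, or None.
    """
    seed = read[:min_overlap]
    start = 0
    while True:
        i = contig.find(seed, start)
        if i < 0:
            return None
        o = min(len(contig) - i, len(read))
        if o >= min_overlap and _matches(contig[i : i + o], read[:o]):
            return (i, max(0, len(read) - o))
        start = i + 1


# ---------------------------------------------------------------------------
# VCF BND output and audit table
# ---------------------------------------------------------------------------


def write_vcf(
    path: str | Path,
    junctions: Sequence[JunctionCall],
    ref_seq: str,
    chrom: str,
) -> None:
    """Passing junctions as VCF 4.2 breakend (BND) mate pairs."""
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom},length={len(ref_seq)}>",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate breakend id">',
        '##INFO=<ID=SPLIT_CASE,Number=1,Type=Integer,Description="Case split reads">',
        '##INFO=<ID=SPLIT_CTRL,Number=1,Type=Integer,Description="Control split reads">',
        '##INFO=<ID=DISC_CASE,Number=1,Type=Integer,Description="Case discordant pairs">',
        '##INFO=<ID=DISC_CTRL,Number=1,Type=Integer,Description="Control discordant pairs">',
        '##INFO=<ID=HOMSEQ,Number=1,Type=String,Description="Microhomology">',
        '##INFO=<ID=INSSEQ,Number=1,Type=String,Description="Inserted sequence">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for n, j in enumerate(junctions):
        info_common = (
            f"SVTYPE=BND;SPLIT_CASE={j.split_case};SPLIT_CTRL={j.split_ctrl};"
            f"DISC_CASE={j.disc_case};DISC_CTRL={j.disc_ctrl}"
        )
        if j.microhomology:
            info_common += f";HOMSEQ={j.microhomology}"
        if j.inserted_seq:
            info_common += f";INSSEQ={j.inserted_seq}"
        for k, (this, other) in enumerate(
            ((j.breakend_a, j.breakend_b), (j.breakend_b, j.breakend_a))
        ):
            pos, side = this
            opos, oside = other
            ref_base = ref_seq[pos - 1]
            mate_str = f"]{chrom}:{opos}]" if oside == "R" else f"[{chrom}:{opos}["
            alt = ref_base + mate_str if side == "R" else mate_str + ref_base
            lines.append(
                f"{chrom}\t{pos}\tbnd_{n}_{k}\t{ref_base}\t{alt}\t.\tPASS\t"
                f"{info_common};MATEID=bnd_{n}_{1 - k}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> list[JunctionCall]:
    """Read BND junctions written by :func:`write_vcf` (via pysam)."""
    import pysam

    calls: dict[tuple, JunctionCall] = {}
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            alt = rec.alts[0]
            side = "R" if alt[0] not in "[]" else "L"
            if "]" in alt:
                opos = int(alt.split("]")[1].split(":")[1])
                oside = "R"
            else:
                opos = int(alt.split("[")[1].split(":")[1])
                oside = "L"
            info = rec.info
            call = JunctionCall(
                breakend_a=(rec.pos, side),
                breakend_b=(opos, oside),
                split_case=int(info.get("SPLIT_CASE", 0)),
                split_ctrl=int(info.get("SPLIT_CTRL", 0)),
                disc_case=int(info.get("DISC_CASE", 0)),
                disc_ctrl=int(info.get("DISC_CTRL", 0)),
                inserted_seq=str(info.get("INSSEQ", "") or ""),
                microhomology=str(info.get("HOMSEQ", "") or ""),
            )
            key = (call.breakend_a, call.breakend_b)
            calls.setdefault(key, call)
    return list(calls.values())


def write_audit_tsv(path: str | Path, audit: Sequence[JunctionCall]) -> None:
    with open(path, "w") as fh:
        fh.write(
            "pos_a\tside_a\tpos_b\tside_b\tsplit_case\tsplit_ctrl\t"
            "disc_case\tdisc_ctrl\tinserted_len\tmicrohomology\tpasses\n"
        )
        for j in audit:
            fh.write(
                f"{j.breakend_a[0]}\t{j.breakend_a[1]}\t{j.breakend_b[0]}\t"
                f"{j.breakend_b[1]}\t{j.split_case}\t{j.split_ctrl}\t{j.disc_case}\t"
                f"{j.disc_ctrl}\t{len(j.inserted_seq)}\t{j.microhomology}\t{int(j.passes)}\n"
            )
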