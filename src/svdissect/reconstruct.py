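"""Derivative-chromosome reconstruction from CNV and junction calls.

The reference region is cut into segments at the pooled CNV boundaries and
junction breakends, each segment gets a copy number on the rearranged
homolog (called total copies minus one intact homolog), and the derivative
structure is recovered as a walk through the segment adjacency graph: an
ordered, signed word over segments that starts at the leftmost segment,
ends at the rightmost, uses every segment exactly as many times as its
rearranged-homolog copy number, and traverses every novel junction edge at
least once. The search is exact depth-first enumeration with memoized dead
states — instances are small by construction — and all words satisfying
the evidence are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .cma import CnvCall
from .svdetect import Breakend, JunctionCall
from .synthgenome import SignedSegment

DEFAULT_WINDOW = 10
DEFAULT_MAX_SOLUTIONS = 64


@dataclass
class Segment:
    """One reference segment: 1-based inclusive interval plus copy numbers."""

    seg_id: str
    start: int
    end: int
    total_copies: int  # across the diploid case genome
    label_state: str  # 'dup' or 'normal'
    unmatched_boundary: bool = False

    @property
    def derivative_copies(self) -> int:
        """Copies on the rearranged homolog, assuming one intact homolog."""
        return max(self.total_copies - 1, 0)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class NovelEdge:
    """Novel adjacency between two segment extremities.

    ``end_a``/``end_b`` are (segment index, extremity) with extremity 'R'
    joining the segment's right end and 'L' its left end (breakend sides
    map directly onto extremities).
    """

    end_a: tuple[int, str]
    end_b: tuple[int, str]
    insertion: str = ""
    source: Optional[JunctionCall] = None
    flagged: bool = False


@dataclass
class SegmentGraph:
    segments: list[Segment]
    novel_edges: list[NovelEdge]

    @property
    def reference_edges(self) -> list[tuple[int, int]]:
        return [(i, i + 1) for i in range(len(self.segments) - 1)]


@dataclass
class DerivativeWord:
    """One reconstructed derivative structure."""

    word: list[SignedSegment]
    used_novel_edges: dict[int, int]  # edge index -> times used

    def __str__(self) -> str:
        return " ".join(str(w) for w in self.word)

    def inversion_blocks(self, graph: SegmentGraph) -> list[tuple[int, int, int]]:
        """Maximal reference-contiguous '-' runs as (ref start, ref end, length).

        A run of '-' segments only counts as one inverted block while
        consecutive elements are reference neighbours traversed leftwards;
        a novel-edge jump inside an inverted stretch starts a new block, so
        a block's reference span is genuinely contiguous inverted sequence.
        """
        by_id = {s.seg_id: (i, s) for i, s in enumerate(graph.segments)}
        blocks: list[tuple[int, int, int]] = []
        run: list[Segment] = []
        prev_idx: Optional[int] = None
        for w in self.word:
            if not w.is_insertion and w.orientation == "-":
                idx, seg = by_id[w.segment_id]
                if run and prev_idx is not None and idx != prev_idx - 1:
                    blocks.append(_span(run))
                    run = []
                run.append(seg)
                prev_idx = idx
            elif run and not w.is_insertion:
                blocks.append(_span(run))
                run = []
                prev_idx = None
        if run:
            blocks.append(_span(run))
        return blocks


def _span(run: list[Segment]) -> tuple[int, int, int]:
    start = min(s.start for s in run)
    end = max(s.end for s in run)
    return (start, end, end - start + 1)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def segment_reference(
    cnv_calls: Sequence[CnvCall],
    junction_calls: Sequence[JunctionCall],
    region: tuple[int, int],
    window: int = DEFAULT_WINDOW,
    cnv_tolerance: Optional[float] = None,
) -> list[Segment]:
    """Cut the region at pooled CNV boundaries and junction breakends.

    Junction breakends are base-precise; CNV edges are only probe-precise,
    so a CNV edge within ``cnv_tolerance`` (default: ``window``; the
    pipeline passes roughly one probe spacing) of a junction cut is
    absorbed by it — the breakends "match the boundaries" of the CNV
    segments — rather than producing a sliver segment. Junction cuts merge
    among themselves within ``window``; so do CNV cuts with no junction
    nearby. Breakends far from any CNV edge still cut the region but are
    flagged as unmatched.

    A boundary at position p of side 'R' cuts between p and p+1; side 'L'
    cuts between p-1 and p. A CNV interval (s, e) cuts at s-1 and e.
    """
    if cnv_tolerance is None:
        cnv_tolerance = float(window)
    junc_cuts = [
        float(pos if side == "R" else pos - 1)
        for j in junction_calls
        for pos, side in (j.breakend_a, j.breakend_b)
    ]
    cnv_cuts = [float(x) for c in cnv_calls for x in (c.start - 1, c.end)]

    clusters: list[dict] = []
    for pos in sorted(junc_cuts):
        if clusters and abs(pos - np.mean(clusters[-1]["pos"])) <= window:
            clusters[-1]["pos"].append(pos)
        else:
            clusters.append({"pos": [pos], "junc": True, "cnv": False})
    for pos in sorted(cnv_cuts):
        near = [cl for cl in clusters if abs(pos - np.mean(cl["pos"])) <= cnv_tolerance]
        if near:
            best = min(near, key=lambda cl: abs(pos - np.mean(cl["pos"])))
            best["cnv"] = True  # absorbed: the precise junction position wins
        else:
            clusters.append({"pos": [pos], "junc": False, "cnv": True})

    lo, hi = region
    cut_info: dict[int, dict] = {}
    for cl in clusters:
        p = int(round(float(np.mean(cl["pos"]))))
        if lo - 1 < p < hi:
            cut_info[p] = cl
    bounds = sorted({lo - 1, hi, *cut_info})

    segments: list[Segment] = []
    dup_i = 0
    norm_i = 0
    for a, b in zip(bounds, bounds[1:]):
        start, end = a + 1, b
        over = [c for c in cnv_calls if c.start <= end and start <= c.end]
        overlap = sum(min(c.end, end) - max(c.start, start) + 1 for c in over)
        is_dup = overlap > (end - start + 1) / 2 and any(c.state == "gain" for c in over)
        if is_dup:
            dup_i += 1
            seg_id, total, state = f"D{dup_i}", 3, "dup"
        else:
            seg_id, total, state = f"S{norm_i}", 2, "normal"
            norm_i += 1
        info = cut_info.get(a)
        segments.append(
            Segment(
                seg_id=seg_id, start=start, end=end, total_copies=total,
                label_state=state,
                unmatched_boundary=bool(info and info["junc"] and not info["cnv"]),
            )
        )
    return segments


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------


def build_graph(
    segments: Sequence[Segment],
    junction_calls: Sequence[JunctionCall],
    window: int = DEFAULT_WINDOW,
) -> SegmentGraph:
    """Attach novel edges to segment extremities.

    A breakend of side 'R' at position p joins the right end of the segment
    whose end is within ``window`` of p; side 'L' joins the left end of the
    segment whose start is within ``window`` of p. Junctions whose
    breakends sit at no segment boundary are excluded from walks (flagged).
    """
    segs = list(segments)

    def locate(be: Breakend) -> Optional[tuple[int, str]]:
        pos, side = be
        candidates = []
        for i, s in enumerate(segs):
            anchor = s.end if side == "R" else s.start
            if abs(anchor - pos) <= window:
                candidates.append((abs(anchor - pos), i))
        if not candidates:
            return None
        return (min(candidates)[1], side)

    edges: list[NovelEdge] = []
    for j in junction_calls:
        a = locate(j.breakend_a)
        b = locate(j.breakend_b)
        if a is None or b is None:
            edges.append(
                NovelEdge(end_a=(-1, "?"), end_b=(-1, "?"), insertion=j.inserted_seq,
                          source=j, flagged=True)
            )
            continue
        edges.append(NovelEdge(end_a=a, end_b=b, insertion=j.inserted_seq, source=j))
    return SegmentGraph(segments=segs, novel_edges=edges)


# ---------------------------------------------------------------------------
# Walk search
# ---------------------------------------------------------------------------


def solve_walks(
    graph: SegmentGraph,
    max_solutions: int = DEFAULT_MAX_SOLUTIONS,
) -> tuple[list[DerivativeWord], bool, Optional[str]]:
    """Enumerate derivative words consistent with the graph.

    A walk starts at the leftmost segment (+ orientation), ends at the
    rightmost (+), visits each segment exactly ``derivative_copies`` times,
    and uses every unflagged novel edge at least once. Returns
    (sorted solutions, truncated flag, diagnostic when empty).

    Steps move from the exit extremity of the current oriented segment
    ('R' for +, 'L' for -) through a reference or novel edge into the next
    segment's entry extremity ('L' entering +, 'R' entering -).
    """
    segs = graph.segments
    n = len(segs)
    if n == 0:
        return [], False, "empty graph"
    edges = [e for e in graph.novel_edges if not e.flagged]
    quota = tuple(s.derivative_copies for s in segs)
    if quota[0] < 1 or quota[-1] < 1:
        return [], False, "boundary segment has zero derivative copies"

    # adjacency: from (segment, orientation) exit extremity to candidate
    # (next segment, next orientation, novel edge index or None)
    moves: dict[tuple[int, int], list[tuple[int, int, Optional[int]]]] = {}
    for i in range(n):
        for ori in (0, 1):  # 0 = '+', 1 = '-'
            out: list[tuple[int, int, Optional[int]]] = []
            exit_ext = "R" if ori == 0 else "L"
            # reference adjacency
            if exit_ext == "R" and i + 1 < n:
                out.append((i + 1, 0, None))
            if exit_ext == "L" and i - 1 >= 0:
                out.append((i - 1, 1, None))
            # novel edges attached to this extremity
            for k, e in enumerate(edges):
                for here, there in ((e.end_a, e.end_b), (e.end_b, e.end_a)):
                    if here == (i, exit_ext):
                        j, ext = there
                        out.append((j, 0 if ext == "L" else 1, k))
            moves[(i, ori)] = out

    solutions: list[tuple[tuple[tuple[int, int, Optional[int]], ...], dict[int, int]]] = []
    truncated = False
    n_edges = len(edges)
    path: list[tuple[int, int, Optional[int]]] = []
    dead: set[tuple[int, int, tuple[int, ...], int]] = set()

    def dfs(pos: int, ori: int, remaining: tuple[int, ...], used_mask: int) -> bool:
        """Returns True if any solution found below this state."""
        nonlocal truncated
        if len(solutions) >= max_solutions:
            truncated = True
            return True
        if sum(remaining) == 0:
            if pos == n - 1 and ori == 0 and used_mask == (1 << n_edges) - 1:
                counts: dict[int, int] = {}
                for _p, _o, e in path:
                    if e is not None:
                        counts[e] = counts.get(e, 0) + 1
                solutions.append((tuple(path), counts))
                return True
            return False
        state = (pos, ori, remaining, used_mask)
        if state in dead:
            return False
        found = False
        for nxt, nori, edge in moves[(pos, ori)]:
            if remaining[nxt] <= 0:
                continue
            nrem = list(remaining)
            nrem[nxt] -= 1
            nmask = used_mask | (1 << edge) if edge is not None else used_mask
            path.append((nxt, nori, edge))
            if dfs(nxt, nori, tuple(nrem), nmask):
                found = True
            path.pop()
        if not found:
            dead.add(state)
        return found

    start_remaining = list(quota)
    start_remaining[0] -= 1
    path.append((0, 0, None))
    dfs(0, 0, tuple(start_remaining), 0)
    path.pop()

    words: list[DerivativeWord] = []
    seen: set[str] = set()
    for steps, edge_counts in solutions:
        word: list[SignedSegment] = []
        for (idx, ori, edge) in steps:
            if edge is not None:
                e = edges[edge]
                if e.insertion:
                    # insertion orientation: stored in the canonical junction
                    # frame walking breakend_a -> breakend_b
                    prev_idx, prev_ori = word_state(word, segs)
                    exit_ext = "R" if prev_ori == "+" else "L"
                    fwd = e.end_a == (prev_idx, exit_ext)
                    word.append(
                        SignedSegment("INS:" + _ins_label(edge), "+" if fwd else "-")
                    )
            word.append(SignedSegment(segs[idx].seg_id, "+" if ori == 0 else "-"))
        text = " ".join(str(w) for w in word)
        if text not in seen:
            seen.add(text)
            words.append(DerivativeWord(word=word, used_novel_edges=edge_counts))
    words.sort(key=lambda w: str(w))

    diagnostic = None
    if not words:
        diagnostic = _diagnose(graph, edges, quota)
    return words, truncated, diagnostic


def _ins_label(edge_index: int) -> str:
    return f"ins{edge_index}"


def word_state(word: list[SignedSegment], segs: list[Segment]) -> tuple[int, str]:
    ids = {s.seg_id: i for i, s in enumerate(segs)}
    for w in reversed(word):
        if not w.is_insertion:
            return ids[w.segment_id], w.orientation
    return 0, "+"


def _diagnose(graph: SegmentGraph, edges: list[NovelEdge], quota: tuple[int, ...]) -> str:
    if any(q == 0 for q in quota[1:-1]) and not edges:
        return "segment with zero copies and no novel edge to bypass it"
    degree: dict[tuple[int, str], int] = {}
    for e in edges:
        degree[e.end_a] = degree.get(e.end_a, 0) + 1
        degree[e.end_b] = degree.get(e.end_b, 0) + 1
    return (
        "no walk satisfies copy numbers "
        f"{quota} with {len(edges)} novel edges (edge endpoints: {sorted(degree)})"
    )


def brute_force_walks(graph: SegmentGraph, cap: int = 100_000) -> list[str]:
    """Independent exhaustive enumeration over all orderings/orientations.

    Generates every arrangement of the segment-copy multiset with every
    orientation assignment and keeps those whose consecutive pairs are all
    connected by a reference or novel adjacency, that start/end correctly,
    and that use every novel edge. Only feasible for small graphs; used as
    an oracle for :func:`solve_walks`.
    """
    from itertools import permutations, product

    segs = graph.segments
    n = len(segs)
    edges = [e for e in graph.novel_edges if not e.flagged]
    multiset: list[int] = []
    for i, s in enumerate(segs):
        multiset += [i] * s.derivative_copies
    interior = [i for i in multiset if True]
    # fix first and last elements as the boundary segments
    interior.remove(0)
    interior.remove(n - 1)

    edge_set = {}
    for k, e in enumerate(edges):
        edge_set.setdefault(frozenset([e.end_a, e.end_b]), k)
        if e.end_a == e.end_b:
            edge_set[frozenset([e.end_a])] = k

    def connection(a: int, ao: int, b: int, bo: int) -> list[Optional[int]]:
        out: list[Optional[int]] = []
        exit_ext = (a, "R" if ao == 0 else "L")
        entry_ext = (b, "L" if bo == 0 else "R")
        if ao == bo == 0 and b == a + 1:
            out.append(None)
        if ao == bo == 1 and b == a - 1:
            out.append(None)
        key = frozenset([exit_ext, entry_ext])
        if key in edge_set:
            out.append(edge_set[key])
        return out

    results: set[str] = set()
    seen_perm: set[tuple] = set()
    count = 0
    for perm in set(permutations(interior)):
        order = (0,) + perm + (n - 1,)
        for oris in product((0, 1), repeat=len(perm)):
            count += 1
            if count > cap:
                raise RuntimeError("brute force cap exceeded")
            full_oris = (0,) + oris + (0,)
            # check connectivity; a consecutive pair may connect by several
            # routes — explore all combinations of edge choices
            choices: list[list[Optional[int]]] = []
            ok = True
            for (a, ao), (b, bo) in zip(
                zip(order, full_oris), zip(order[1:], full_oris[1:])
            ):
                conn = connection(a, ao, b, bo)
                if not conn:
                    ok = False
                    break
                choices.append(conn)
            if not ok:
                continue
            for combo in product(*choices):
                used = {e for e in combo if e is not None}
                if used == set(range(len(edges))):
                    word = [
                        ("+" if ori == 0 else "-") + segs[idx].seg_id
                        for idx, ori in zip(order, full_oris)
                    ]
                    results.add(" ".join(word))
                    break
    return sorted(results)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def inversion_report(word: DerivativeWord, graph: SegmentGraph) -> list[tuple[tuple[int, int], int]]:
    """Maximal inverted runs mapped back to reference coordinates."""
    return [((s, e), ln) for s, e, ln in word.inversion_blocks(graph)]


def word_matches_plan(word: DerivativeWord, plan_word: Sequence[SignedSegment]) -> bool:
    """Compare a reconstructed word with a generator plan word, ignoring
    insertion labels (the reconstruction cannot know the generator's name
    for an inserted sequence)."""
    got = [
        ("INS", w.orientation) if w.is_insertion else (w.segment_id, w.orientation)
        for w in word.word
    ]
    want = [
        ("INS", w.orientation) if w.is_insertion else (w.segment_id, w.orientation)
        for w in plan_word
    ]
    return got == want


def write_words(path: str | Path, words: Sequence[DerivativeWord]) -> None:
    with open(path, "w") as fh:
        for w in words:
            fh.write(str(w) + "\n")


def write_structure_json(
    path: str | Path,
    graph: SegmentGraph,
    words: Sequence[DerivativeWord],
    truncated: bool,
) -> None:
    import json

    payload = {
        "segments": [
            {
                "id": s.seg_id, "start": s.start, "end": s.end,
                "total_copies": s.total_copies,
                "derivative_copies": s.derivative_copies,
            }
            for s in graph.segments
        ],
        "novel_edges": [
            {
                "end_a": list(e.end_a), "end_b": list(e.end_b),
                "insertion_length": len(e.insertion), "insertion": e.insertion,
                "flagged": e.flagged,
            }
            for e in graph.novel_edges
        ],
        "words": [str(w) for w in words],
        "inversions": [
            [list(iv), ln] for iv, ln in (inversion_report(words[0], graph) if words else [])
        ],
        "truncated": truncated,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_bedpe(path: str | Path, graph: SegmentGraph, chrom: str) -> None:
    """Used novel adjacencies as BEDPE (0-based half-open, converted)."""
    with open(path, "w") as fh:
        for e in graph.novel_edges:
            if e.flagged or e.source is None:
                continue
            (pa, _), (pb, _) = e.source.breakend_a, e.source.breakend_b
            fh.write(
                f"{chrom}\t{pa - 1}\t{pa}\t{chrom}\t{pb - 1}\t{pb}\t"
                f"novel_edge\t.\t{e.source.breakend_a[1]}\t{e.source.breakend_b[1]}\n"
            )
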