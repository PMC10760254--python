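"""Deterministic k-mer anchor read aligner.

Maps simulated reads to the reference and produces the evidence substrate
for junction detection: primary and supplementary (split) alignments,
soft-clip lengths, per-block mismatch counts, and read-pair concordance.

The aligner is intentionally simple: exact k-mer anchors are chained per
(strand, diagonal) — the substitution-only error model means every true
block lies on a single diagonal — and each chain is extended base-by-base
while the read matches the reference. It is not a general-purpose aligner
(no gapped alignment, no mapping quality model); it is a functional
stand-in for the short-read mapping step of a WGS pipeline, built so that
150 bp reads split at a rearrangement junction retain mappable blocks on
both sides.

A vectorised fast path places the large majority of reads (both terminal
k-mers hit the same unique diagonal); the remainder go through full anchor
chaining in chunks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from ._dna import decode, encode, kmer_codes, revcomp
from .synthgenome import ReadSet

DEFAULT_K = 21
DEFAULT_MAX_HITS = 50
DEFAULT_MIN_BLOCK = 25
DEFAULT_MIN_ANCHOR_KMERS = 3
MAX_BLOCK_OVERLAP = 10  # bp of read overlap tolerated between split blocks
FAST_PATH_MAX_MISMATCH_FRAC = 0.08
CONCORDANT_SD_WINDOW = 4.0


# ---------------------------------------------------------------------------
# Index
# ---------------------------------------------------------------------------


@dataclass
class KmerIndex:
    """Sorted k-mer table over one reference sequence."""

    ref_codes: np.ndarray
    k: int
    max_hits: int
    sorted_codes: np.ndarray = field(repr=False, default=None)
    sorted_pos: np.ndarray = field(repr=False, default=None)

    @property
    def ref_length(self) -> int:
        return int(self.ref_codes.size)

    def n_indexed_kmers(self) -> int:
        """Distinct k-mer positions retained (k-mers over max_hits dropped)."""
        codes = self.sorted_codes
        bounds = np.flatnonzero(np.r_[True, codes[1:] != codes[:-1], True])
        counts = np.diff(bounds)
        return int(counts[counts <= self.max_hits].sum())

    def lookup(self, query_codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(self.sorted_codes, query_codes, side="left")
        hi = np.searchsorted(self.sorted_codes, query_codes, side="right")
        return lo, hi


def build_index(ref: str | np.ndarray, k: int = DEFAULT_K,
                max_hits: int = DEFAULT_MAX_HITS) -> KmerIndex:
    """Index every reference k-mer; k must be in [15, 31]."""
    if not 15 <= k <= 31:
        raise ValueError("k must be between 15 and 31")
    ref_codes = encode(ref) if isinstance(ref, str) else np.asarray(ref, dtype=np.uint8)
    codes = kmer_codes(ref_codes, k)
    order = np.argsort(codes, kind="stable")
    return KmerIndex(
        ref_codes=ref_codes, k=k, max_hits=max_hits,
        sorted_codes=codes[order], sorted_pos=order.astype(np.int64),
    )


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------


@dataclass
class AlignmentRecord:
    """One aligned block of one read (SAM-line-like).

    ``read_start``/``read_end`` are 0-based half-open in the read's original
    (as sequenced) orientation; ``ref_start``/``ref_end`` 0-based half-open
    on the reference. On the '-' strand the reverse complement of the read
    slice matches the reference slice.
    """

    read_id: str
    ref_name: str
    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    strand: str
    mismatches: int
    is_supplementary: bool = False

    @property
    def clip_left(self) -> int:
        return self.read_start

    @property
    def clip_right(self) -> int:
        return self._read_length - self.read_end

    _read_length: int = 0

    @property
    def block_length(self) -> int:
        return self.read_end - self.read_start

    @property
    def mapped(self) -> bool:
        return self.ref_end > self.ref_start


@dataclass
class PairRecord:
    """Pairing of the primary alignments of two mates."""

    orientation: str  # FR, RF, FF, RR, or NA when a mate is unmapped
    observed_insert: int
    concordant: bool
    mate1: Optional[AlignmentRecord]
    mate2: Optional[AlignmentRecord]


# ---------------------------------------------------------------------------
# Chaining core (shared by align_read and the batch slow path)
# ---------------------------------------------------------------------------


def _chain_blocks_one_strand(
    read_codes: np.ndarray,
    index: KmerIndex,
    min_anchor_kmers: int,
) -> list[tuple[int, int, int, int]]:
    """Anchor chains for one read orientation.

    Returns (read_start, read_end, ref_start, mismatches) blocks in the
    coordinates of ``read_codes``.
    """
    k = index.k
    rl = read_codes.size
    if rl < k:
        return []
    qcodes = kmer_codes(read_codes, k)
    lo, hi = index.lookup(qcodes)
    counts = hi - lo
    keep = (counts > 0) & (counts <= index.max_hits)
    if not np.any(keep):
        return []
    kp = np.flatnonzero(keep)
    counts_k = counts[kp]
    total = int(counts_k.sum())
    base = np.repeat(lo[kp], counts_k)
    within = np.arange(total) - np.repeat(np.cumsum(counts_k) - counts_k, counts_k)
    ref_pos = index.sorted_pos[base + within]
    read_pos = np.repeat(kp, counts_k)
    diag = ref_pos - read_pos

    order = np.lexsort((read_pos, diag))
    diag_s, read_s = diag[order], read_pos[order]
    bounds = np.flatnonzero(np.r_[True, diag_s[1:] != diag_s[:-1], True])

    ref_codes = index.ref_codes
    L = ref_codes.size
    blocks: list[tuple[int, int, int, int]] = []
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        if b1 - b0 < min_anchor_kmers:
            continue
        d = int(diag_s[b0])
        rs = int(read_s[b0])
        re = int(read_s[b1 - 1]) + k
        # extend while the read matches the reference exactly
        while rs > 0 and d + rs - 1 >= 0 and ref_codes[d + rs - 1] == read_codes[rs - 1]:
            rs -= 1
        while re < rl and d + re < L and ref_codes[d + re] == read_codes[re]:
            re += 1
        seg_ref = ref_codes[d + rs : d + re]
        mism = int(np.count_nonzero(seg_ref != read_codes[rs:re]))
        blocks.append((rs, re, d + rs, mism))
    return blocks


def _select_blocks(
    blocks: list[tuple[int, int, int, int, str]],
    read_length: int,
    min_block: int,
    min_anchor_kmers: int,
    k: int,
) -> list[tuple[int, int, int, int, str, bool]]:
    """Greedy non-overlapping selection; returns blocks plus primary flag.

    Ties between equally long blocks break by leftmost reference position
    for reproducibility.
    """
    if not blocks:
        return []
    ranked = sorted(blocks, key=lambda b: (-(b[1] - b[0]), b[2], b[4]))
    chosen: list[tuple[int, int, int, int, str]] = []
    for blk in ranked:
        rs, re = blk[0], blk[1]
        overlap = sum(
            max(0, min(re, c[1]) - max(rs, c[0])) for c in chosen
        )
        if overlap > MAX_BLOCK_OVERLAP:
            continue
        if chosen and (re - rs) < min_block:
            continue
        chosen.append(blk)
    if not chosen:
        return []
    primary = chosen[0]
    out = [(b[0], b[1], b[2], b[3], b[4], b is primary) for b in chosen]
    out.sort(key=lambda b: b[0])
    return out


def align_read(
    read: str,
    index: KmerIndex,
    min_anchor_kmers: int = DEFAULT_MIN_ANCHOR_KMERS,
    min_block: int = DEFAULT_MIN_BLOCK,
    read_id: str = "read",
    ref_name: str = "ref",
) -> list[AlignmentRecord]:
    """Align one read; returns primary plus supplementary records (possibly
    empty when nothing maps, including reads shorter than k)."""
    codes = encode(read)
    rl = codes.size
    candidates: list[tuple[int, int, int, int, str]] = []
    for strand, ori_codes in (("+", codes), ("-", (3 - codes)[::-1])):
        for rs, re, ref_s, mism in _chain_blocks_one_strand(ori_codes, index, min_anchor_kmers):
            if strand == "+":
                candidates.append((rs, re, ref_s, mism, "+"))
            else:
                # convert back to original read orientation
                candidates.append((rl - re, rl - rs, ref_s, mism, "-"))
    selected = _select_blocks(candidates, rl, min_block, min_anchor_kmers, index.k)
    records = []
    for rs, re, ref_s, mism, strand, is_primary in selected:
        rec = AlignmentRecord(
            read_id=read_id, ref_name=ref_name,
            read_start=rs, read_end=re,
            ref_start=ref_s, ref_end=ref_s + (re - rs),
            strand=strand, mismatches=mism,
            is_supplementary=not is_primary,
        )
        rec._read_length = rl
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Batch alignment of a ReadSet
# ---------------------------------------------------------------------------


@dataclass
class AlignmentTable:
    """Struct-of-arrays alignment store for one cohort's reads.

    One row per aligned block. ``pair_idx``/``mate`` identify the read;
    coordinates follow the AlignmentRecord conventions.
    """

    pair_idx: np.ndarray
    mate: np.ndarray  # 0 = read1, 1 = read2
    read_start: np.ndarray
    read_end: np.ndarray
    ref_start: np.ndarray
    ref_end: np.ndarray
    strand: np.ndarray  # 0 = '+', 1 = '-'
    mismatches: np.ndarray
    is_supplementary: np.ndarray
    read_length: int
    n_pairs: int

    def __len__(self) -> int:
        return int(self.pair_idx.size)

    @property
    def clip_left(self) -> np.ndarray:
        return self.read_start

    @property
    def clip_right(self) -> np.ndarray:
        return self.read_length - self.read_end

    def primary_matrix(self) -> tuple[np.ndarray, ...]:
        """(n_pairs, 2) arrays: mapped, ref_start, ref_end, strand, has_supp."""
        n = self.n_pairs
        mapped = np.zeros((n, 2), dtype=bool)
        rs = np.zeros((n, 2), dtype=np.int64)
        re = np.zeros((n, 2), dtype=np.int64)
        st = np.zeros((n, 2), dtype=np.int8)
        supp = np.zeros((n, 2), dtype=bool)
        prim = ~self.is_supplementary
        mapped[self.pair_idx[prim], self.mate[prim]] = True
        rs[self.pair_idx[prim], self.mate[prim]] = self.ref_start[prim]
        re[self.pair_idx[prim], self.mate[prim]] = self.ref_end[prim]
        st[self.pair_idx[prim], self.mate[prim]] = self.strand[prim]
        s = self.is_supplementary
        supp[self.pair_idx[s], self.mate[s]] = True
        return mapped, rs, re, st, supp


@dataclass
class PairTable:
    """Vectorised pair concordance classification."""

    mapped: np.ndarray  # (n, 2)
    ref_start: np.ndarray
    ref_end: np.ndarray
    strand: np.ndarray
    has_supp: np.ndarray
    orientation: np.ndarray  # 'FR'/'RF'/'FF'/'RR'/'NA' per pair
    insert: np.ndarray
    concordant: np.ndarray
    insert_mean: float
    insert_sd: float

    @property
    def n_pairs(self) -> int:
        return int(self.mapped.shape[0])


def _fold_kmer(mat: np.ndarray, offset: int, k: int) -> np.ndarray:
    out = np.zeros(mat.shape[0], dtype=np.uint64)
    for j in range(k):
        out <<= np.uint64(2)
        out |= mat[:, offset + j].astype(np.uint64)
    return out


def _fast_path(mat: np.ndarray, index: KmerIndex) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Attempt full-length single-diagonal placement for every read.

    Returns (ok, ref_start, strand, mismatches); reads failing the fast
    path have ok == False.
    """
    n, rl = mat.shape
    k = index.k
    L = index.ref_length
    best_ok = np.zeros(n, dtype=bool)
    best_start = np.zeros(n, dtype=np.int64)
    best_strand = np.zeros(n, dtype=np.int8)
    best_mm = np.full(n, rl, dtype=np.int32)
    max_mm = int(FAST_PATH_MAX_MISMATCH_FRAC * rl)

    for strand, m in ((0, mat), (1, (3 - mat)[:, ::-1])):
        c0 = _fold_kmer(m, 0, k)
        cL = _fold_kmer(m, rl - k, k)
        lo0, hi0 = index.lookup(c0)
        loL, hiL = index.lookup(cL)
        unique = (hi0 - lo0 == 1) & (hiL - loL == 1)
        p0 = np.where(unique, index.sorted_pos[np.minimum(lo0, index.sorted_pos.size - 1)], -1)
        pL = np.where(unique, index.sorted_pos[np.minimum(loL, index.sorted_pos.size - 1)], -1)
        cand = unique & (p0 == pL - (rl - k)) & (p0 >= 0) & (p0 + rl <= L)
        idx = np.flatnonzero(cand)
        if idx.size == 0:
            continue
        # verify whole-read match on the diagonal (chunked gather)
        for c0_ in range(0, idx.size, 200_000):
            sel = idx[c0_ : c0_ + 200_000]
            seg = index.ref_codes[p0[sel, None] + np.arange(rl)]
            mm = np.count_nonzero(seg != m[sel], axis=1).astype(np.int32)
            ok = mm <= max_mm
            better = ok & (mm < best_mm[sel])
            upd = sel[better]
            best_ok[upd] = True
            best_start[upd] = p0[upd]
            best_strand[upd] = strand
            best_mm[upd] = mm[better]
    return best_ok, best_start, best_strand, best_mm


def _slow_path_chunk(
    mat: np.ndarray,
    index: KmerIndex,
    min_anchor_kmers: int,
    min_block: int,
) -> list[list[tuple[int, int, int, int, int, bool]]]:
    """Full chaining for a chunk of reads; returns per-read selected blocks
    as (read_start, read_end, ref_start, mismatches, strand, primary)."""
    n, rl = mat.shape
    per_read: list[list[tuple[int, int, int, int, str]]] = [[] for _ in range(n)]
    k = index.k
    P = rl - k + 1
    ref_codes = index.ref_codes
    L = ref_codes.size

    for strand, m in ((0, mat), (1, (3 - mat)[:, ::-1])):
        # all k-mer codes for all reads in the chunk
        codes = np.zeros((n, P), dtype=np.uint64)
        for j in range(k):
            codes <<= np.uint64(2)
            codes |= m[:, j : j + P].astype(np.uint64)
        lo = np.searchsorted(index.sorted_codes, codes.ravel(), side="left")
        hi = np.searchsorted(index.sorted_codes, codes.ravel(), side="right")
        counts = hi - lo
        counts[counts > index.max_hits] = 0
        total = int(counts.sum())
        if total == 0:
            continue
        base = np.repeat(lo, counts)
        within = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
        ref_pos = index.sorted_pos[base + within]
        lin = np.repeat(np.arange(n * P), counts)
        read_idx = lin // P
        read_pos = lin % P
        diag = ref_pos - read_pos
        order = np.lexsort((read_pos, diag, read_idx))
        ri, dg, rp = read_idx[order], diag[order], read_pos[order]
        key_change = np.r_[True, (ri[1:] != ri[:-1]) | (dg[1:] != dg[:-1]), True]
        bounds = np.flatnonzero(key_change)
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            if b1 - b0 < min_anchor_kmers:
                continue
            r = int(ri[b0])
            d = int(dg[b0])
            rs = int(rp[b0])
            re = int(rp[b1 - 1]) + k
            row = m[r]
            while rs > 0 and d + rs - 1 >= 0 and ref_codes[d + rs - 1] == row[rs - 1]:
                rs -= 1
            while re < rl and d + re < L and ref_codes[d + re] == row[re]:
                re += 1
            mism = int(np.count_nonzero(ref_codes[d + rs : d + re] != row[rs:re]))
            if strand == 0:
                per_read[r].append((rs, re, d + rs, mism, "+"))
            else:
                per_read[r].append((rl - re, rl - rs, d + rs, mism, "-"))

    out: list[list[tuple[int, int, int, int, int, bool]]] = []
    for blocks in per_read:
        sel = _select_blocks(blocks, rl, min_block, min_anchor_kmers, k)
        out.append(
            [(rs, re, f, mm, 0 if s == "+" else 1, prim) for rs, re, f, mm, s, prim in sel]
        )
    return out


def align_readset(
    reads: ReadSet,
    index: KmerIndex,
    min_anchor_kmers: int = DEFAULT_MIN_ANCHOR_KMERS,
    min_block: int = DEFAULT_MIN_BLOCK,
    slow_chunk: int = 20_000,
) -> AlignmentTable:
    """Align every mate of every pair; fast path first, chaining fallback."""
    rl = reads.read_length
    rows: dict[str, list] = {
        "pair_idx": [], "mate": [], "read_start": [], "read_end": [],
        "ref_start": [], "ref_end": [], "strand": [], "mismatches": [],
        "is_supplementary": [],
    }

    for mate, mat in ((0, reads.r1), (1, reads.r2)):
        ok, start, strand, mm = _fast_path(mat, index)
        idx = np.flatnonzero(ok)
        rows["pair_idx"].append(idx)
        rows["mate"].append(np.full(idx.size, mate, dtype=np.int8))
        rows["read_start"].append(np.zeros(idx.size, dtype=np.int32))
        rows["read_end"].append(np.full(idx.size, rl, dtype=np.int32))
        rows["ref_start"].append(start[idx])
        rows["ref_end"].append(start[idx] + rl)
        rows["strand"].append(strand[idx])
        rows["mismatches"].append(mm[idx])
        rows["is_supplementary"].append(np.zeros(idx.size, dtype=bool))

        rest = np.flatnonzero(~ok)
        for c0 in range(0, rest.size, slow_chunk):
            sel = rest[c0 : c0 + slow_chunk]
            per_read = _slow_path_chunk(mat[sel], index, min_anchor_kmers, min_block)
            flat = [
                (int(sel[i]), rs, re, f, mmv, st, prim)
                for i, blocks in enumerate(per_read)
                for rs, re, f, mmv, st, prim in blocks
            ]
            if not flat:
                continue
            arr = np.array([(p, rs, re, f, mmv, st, prim) for p, rs, re, f, mmv, st, prim in flat],
                           dtype=np.int64)
            rows["pair_idx"].append(arr[:, 0])
            rows["mate"].append(np.full(arr.shape[0], mate, dtype=np.int8))
            rows["read_start"].append(arr[:, 1].astype(np.int32))
            rows["read_end"].append(arr[:, 2].astype(np.int32))
            rows["ref_start"].append(arr[:, 3])
            rows["ref_end"].append(arr[:, 3] + (arr[:, 2] - arr[:, 1]))
            rows["strand"].append(arr[:, 5].astype(np.int8))
            rows["mismatches"].append(arr[:, 4].astype(np.int32))
            rows["is_supplementary"].append(arr[:, 6] == 0)

    return AlignmentTable(
        pair_idx=np.concatenate(rows["pair_idx"]).astype(np.int64),
        mate=np.concatenate(rows["mate"]),
        read_start=np.concatenate(rows["read_start"]),
        read_end=np.concatenate(rows["read_end"]),
        ref_start=np.concatenate(rows["ref_start"]).astype(np.int64),
        ref_end=np.concatenate(rows["ref_end"]).astype(np.int64),
        strand=np.concatenate(rows["strand"]),
        mismatches=np.concatenate(rows["mismatches"]),
        is_supplementary=np.concatenate(rows["is_supplementary"]),
        read_length=rl,
        n_pairs=reads.n_pairs,
    )


def classify_pairs(
    table: AlignmentTable, insert_mean: float, insert_sd: float
) -> PairTable:
    """Concordance per pair: same reference, FR orientation, insert within
    insert_mean ± 4·insert_sd."""
    mapped, rs, re, st, supp = table.primary_matrix()
    n = table.n_pairs
    orientation = np.full(n, "NA", dtype="<U2")
    insert = np.zeros(n, dtype=np.int64)
    both = mapped[:, 0] & mapped[:, 1]
    left_is_1 = rs[:, 0] <= rs[:, 1]
    left_strand = np.where(left_is_1, st[:, 0], st[:, 1])
    right_strand = np.where(left_is_1, st[:, 1], st[:, 0])
    code = {(0, 1): "FR", (1, 0): "RF", (0, 0): "FF", (1, 1): "RR"}
    for (a, b), label in code.items():
        sel = both & (left_strand == a) & (right_strand == b)
        orientation[sel] = label
    insert[both] = re[both].max(axis=1) - rs[both].min(axis=1)
    low = insert_mean - CONCORDANT_SD_WINDOW * insert_sd
    high = insert_mean + CONCORDANT_SD_WINDOW * insert_sd
    concordant = both & (orientation == "FR") & (insert >= low) & (insert <= high)
    return PairTable(
        mapped=mapped, ref_start=rs, ref_end=re, strand=st, has_supp=supp,
        orientation=orientation, insert=insert, concordant=concordant,
        insert_mean=float(insert_mean), insert_sd=float(insert_sd),
    )


def pair_reads(
    records1: Sequence[AlignmentRecord],
    records2: Sequence[AlignmentRecord],
    insert_mean: float,
    insert_sd: float,
) -> PairRecord:
    """Pair two mates' alignment records (single-pair API).

    Raises when both mates are unmapped — callers drop such pairs with a
    log entry.
    """
    prim1 = next((r for r in records1 if not r.is_supplementary), None)
    prim2 = next((r for r in records2 if not r.is_supplementary), None)
    if prim1 is None and prim2 is None:
        raise ValueError("both mates unmapped")
    if prim1 is None or prim2 is None:
        return PairRecord("NA", 0, False, prim1, prim2)
    left, right = (prim1, prim2) if prim1.ref_start <= prim2.ref_start else (prim2, prim1)
    orientation = {"++": "FF", "+-": "FR", "-+": "RF", "--": "RR"}[left.strand + right.strand]
    insert = max(prim1.ref_end, prim2.ref_end) - min(prim1.ref_start, prim2.ref_start)
    same_ref = prim1.ref_name == prim2.ref_name
    low = insert_mean - CONCORDANT_SD_WINDOW * insert_sd
    high = insert_mean + CONCORDANT_SD_WINDOW * insert_sd
    concordant = same_ref and orientation == "FR" and low <= insert <= high
    return PairRecord(orientation, insert, concordant, prim1, prim2)


# ---------------------------------------------------------------------------
# SAM output (optional interface; primary I/O is the internal table as TSV)
# ---------------------------------------------------------------------------


def write_table_tsv(path: str | Path, table: AlignmentTable) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "pair_idx": table.pair_idx,
            "mate": table.mate,
            "read_start": table.read_start,
            "read_end": table.read_end,
            "ref_start": table.ref_start,
            "ref_end": table.ref_end,
            "strand": np.where(table.strand == 0, "+", "-"),
            "mismatches": table.mismatches,
            "is_supplementary": table.is_supplementary.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)


def write_sam(
    path: str | Path,
    table: AlignmentTable,
    reads: ReadSet,
    ref_name: str,
    ref_length: int,
) -> None:
    """Plain-text SAM with soft clips and supplementary flags."""
    rl = table.read_length
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{ref_name}\tLN:{ref_length}\n")
        for i in range(len(table)):
            p, m = int(table.pair_idx[i]), int(table.mate[i])
            seq = decode((reads.r1 if m == 0 else reads.r2)[p])
            rs, re = int(table.read_start[i]), int(table.read_end[i])
            neg = table.strand[i] == 1
            if neg:
                seq = revcomp(seq)
                rs, re = rl - re, rl - rs
            cigar = ""
            if rs:
                cigar += f"{rs}S"
            cigar += f"{re - rs}M"
            if rl - re:
                cigar += f"{rl - re}S"
            flag = 1 | (64 if m == 0 else 128) | (16 if neg else 0)
            if table.is_supplementary[i]:
                flag |= 2048
            fh.write(
                f"pair{p}\t{flag}\t{ref_name}\t{int(table.ref_start[i]) + 1}\t"
                f"{60 if not table.is_supplementary[i] else 0}\t{cigar}\t*\t0\t0\t"
                f"{seq}\t*\tNM:i:{int(table.mismatches[i])}\n"
            )
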