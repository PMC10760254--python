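"""Copy-number calling from array probe log2 ratios.

Implements the consecutive-probe rule used in chromosomal microarray
analysis: a CNV call requires at least ``min_probes`` consecutive probes with
aberrant log2 ratios (above a gain threshold or below a loss threshold). Two
same-state aberrant runs separated by exactly one sub-threshold probe are
merged into one call (standard post-segmentation merging; a single noisy
probe inside a multi-hundred-probe duplication should not split it). Calls
are reported as 1-based inclusive intervals spanning the first to the last
aberrant probe, with ISCN-style formatting and a population-polymorphism
flagging step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .synthgenome import ProbeTrack

DEFAULT_GAIN_THRESHOLD = 0.3
DEFAULT_LOSS_THRESHOLD = -0.3
DEFAULT_MIN_PROBES = 3
DEFAULT_BRIDGE_GAP = 1


@dataclass
class CnvCall:
    """One CNV: 1-based inclusive interval, copy state, probe support."""

    start: int
    end: int
    state: str  # 'gain' or 'loss'
    n_probes: int
    mean_log2: float
    iscn: str = ""
    polymorphic: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("call start must not exceed end")
        if self.n_probes < DEFAULT_MIN_PROBES:
            raise ValueError("a call needs at least three supporting probes")
        if (self.state == "gain") != (self.mean_log2 > 0):
            raise ValueError("state and mean log2 ratio disagree")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def copies(self) -> int:
        return 3 if self.state == "gain" else 1


def interval_length(interval: tuple[int, int]) -> int:
    """Length in bp of a 1-based inclusive interval: end - start + 1."""
    start, end = interval
    if start > end:
        raise ValueError("interval start exceeds end")
    return end - start + 1


def call_cnvs(
    track: ProbeTrack,
    gain_threshold: float = DEFAULT_GAIN_THRESHOLD,
    loss_threshold: float = DEFAULT_LOSS_THRESHOLD,
    min_probes: int = DEFAULT_MIN_PROBES,
    bridge_gap: int = DEFAULT_BRIDGE_GAP,
) -> list[CnvCall]:
    """Call CNVs as runs of >= min_probes consecutive aberrant probes.

    A run is maximal; runs of the same state separated by at most
    ``bridge_gap`` non-aberrant probes are merged before the length filter.
    The call interval spans the first to the last aberrant probe position.
    """
    if min_probes < 1:
        raise ValueError("min_probes must be at least 1")
    if not (gain_threshold > 0 > loss_threshold):
        raise ValueError("need gain_threshold > 0 > loss_threshold")
    if len(track) == 0:
        return []

    state = np.zeros(len(track), dtype=np.int8)
    state[track.log2 > gain_threshold] = 1
    state[track.log2 < loss_threshold] = -1

    runs: list[tuple[int, int, int]] = []  # (state, first index, last index)
    i = 0
    n = state.size
    while i < n:
        if state[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and state[j + 1] == state[i]:
            j += 1
        runs.append((int(state[i]), i, j))
        i = j + 1

    merged: list[tuple[int, int, int]] = []
    for run in runs:
        if merged and merged[-1][0] == run[0] and run[1] - merged[-1][2] - 1 <= bridge_gap:
            merged[-1] = (run[0], merged[-1][1], run[2])
        else:
            merged.append(run)

    calls: list[CnvCall] = []
    for st, first, last in merged:
        aberrant = np.where(state[first : last + 1] == st)[0] + first
        if aberrant.size < min_probes:
            continue
        sel = track.log2[aberrant]
        calls.append(
            CnvCall(
                start=int(track.positions[aberrant[0]]),
                end=int(track.positions[aberrant[-1]]),
                state="gain" if st > 0 else "loss",
                n_probes=int(aberrant.size),
                mean_log2=float(sel.mean()),
            )
        )
    calls.sort(key=lambda c: c.start)
    return calls


def format_iscn(call: CnvCall, assembly_label: str = "GRCh38", band_label: str = "9p24.3") -> str:
    """ISCN-style string, e.g. ``arr[GRCh38] 9p24.3(788363_864099)x3``."""
    return f"arr[{assembly_label}] {band_label}({call.start}_{call.end})x{call.copies}"


@dataclass
class PolymorphicRegion:
    start: int
    end: int
    frequency: float


def mask_polymorphic(
    calls: Sequence[CnvCall],
    mask: Sequence[PolymorphicRegion],
    max_frequency: float = 0.01,
) -> list[CnvCall]:
    """Flag (not remove) calls overlapping a polymorphic region with
    population frequency above ``max_frequency``."""
    out = []
    for call in calls:
        flagged = any(
            region.frequency > max_frequency
            and call.start <= region.end
            and region.start <= call.end
            for region in mask
        )
        out.append(
            CnvCall(
                start=call.start, end=call.end, state=call.state,
                n_probes=call.n_probes, mean_log2=call.mean_log2,
                iscn=call.iscn, polymorphic=flagged,
            )
        )
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_calls(path: str | Path, calls: Sequence[CnvCall], chrom: str,
                assembly_label: str = "GRCh38", band_label: str = "9p24") -> None:
    """TSV with an ISCN column; intervals stay 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tstate\tcopies\tn_probes\tmean_log2\tiscn\tpolymorphic\n")
        for c in calls:
            iscn = c.iscn or format_iscn(c, assembly_label, band_label)
            fh.write(
                f"{chrom}\t{c.start}\t{c.end}\t{c.state}\t{c.copies}\t{c.n_probes}\t"
                f"{c.mean_log2:.4f}\t{iscn}\t{int(c.polymorphic)}\n"
            )


def write_calls_bed(path: str | Path, calls: Sequence[CnvCall], chrom: str) -> None:
    """BED output (0-based half-open, converted at this I/O boundary)."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{chrom}\t{c.start - 1}\t{c.end}\t{c.state}\t{c.copies}\n")


def read_calls(path: str | Path) -> list[CnvCall]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [
        CnvCall(
            start=int(r.start), end=int(r.end), state=str(r.state),
            n_probes=int(r.n_probes), mean_log2=float(r.mean_log2),
            iscn=str(r.iscn), polymorphic=bool(r.polymorphic),
        )
        for r in df.itertuples()
    ]
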