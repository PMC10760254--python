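"""Low-level DNA utilities shared across modules.

Sequences are handled in two forms: Python strings over {A,C,G,T} at API
boundaries, and numpy uint8 code arrays (A=0, C=1, G=2, T=3) internally,
which keeps read simulation and alignment vectorisable.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 code array."""
    arr = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if arr.max(initial=0) > 3:
        raise ValueError("sequence contains characters outside ACGT")
    return arr


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to a DNA string."""
    return _DECODE[codes].tobytes().decode()


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer code of every k-mer (2 bits/base, MSB = first base)."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    out = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        out <<= np.uint64(2)
        out |= codes[j : j + n].astype(np.uint64)
    return out


def child_seed(seed: int, offset: int) -> int:
    """Derive a stream seed < 2**31 from a base seed deterministically."""
    return (int(seed) * 1_000_003 + offset) % (2**31 - 1)
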