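"""Low-level nucleotide helpers shared by the simulator and the census.

Sequences travel through the package as plain upper-case ACGT(N) strings;
these helpers convert to/from compact numpy code arrays (A=0, C=1, G=2,
T=3, N=4) for vectorised comparison and k-mer hashing.
"""

from __future__ import annotations

import numpy as np

from .errors import InputError

BASES = "ACGT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# transition partner per code (A<->G, C<->T); transversions are the rest
TRANSITION = np.array([2, 3, 0, 1], dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes; raises on non-ACGTN."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = seq[int(np.argmax(arr == 255))]
        raise InputError(f"non-nucleotide character {bad!r} in sequence")
    return arr


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


def require_acgt(seq: str, what: str = "sequence") -> np.ndarray:
    if not seq:
        raise InputError(f"{what} is empty")
    arr = encode(seq)
    if (arr > 3).any():
        raise InputError(f"{what} contains N/ambiguous bases where ACGT is required")
    return arr


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq.upper()))


def random_seq(length: int, rng: np.random.Generator) -> str:
    return decode(rng.integers(0, 4, size=length, dtype=np.uint8))


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Pack every k-mer of a code array into an integer (4**k alphabet).

    Positions whose window contains an N (code 4) are returned as -1.
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    vals = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    c = codes.astype(np.int64)
    for j in range(k):
        window = c[j : j + n]
        vals = vals * 4 + np.where(window > 3, 0, window)
        bad |= window > 3
    vals[bad] = -1
    return vals
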