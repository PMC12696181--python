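"""Vectorized canonical k-mer encoding shared by the sketch and profile modules.

Bases are 2-bit encoded (A=0, C=1, G=2, T=3) so that numeric comparison of
k-mer codes equals lexicographic comparison of k-mer strings; the canonical
form of a k-mer is therefore ``min(code, revcomp_code)``. Windows containing
any non-ACGT character are skipped.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 255, dtype=np.uint8)
for i, base in enumerate("ACGT"):
    _CODE[ord(base)] = i
    _CODE[ord(base.lower())] = i


def encode(seq: str) -> np.ndarray:
    """2-bit codes (uint8), 255 for non-ACGT characters."""
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    return _CODE[raw]


def canonical_kmer_codes(seq: str, k: int) -> np.ndarray:
    """Canonical k-mer codes (uint64) of all valid windows of ``seq``.

    Returns an empty array when the sequence is shorter than k or contains
    no window free of ambiguous characters.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    codes = encode(seq)
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    invalid = codes == 255
    # window is valid iff it contains no invalid base
    bad = np.convolve(invalid.astype(np.int32), np.ones(k, dtype=np.int32), "valid") > 0
    c = codes.astype(np.uint64)
    c[invalid] = 0  # placeholder; masked out below
    m = n - k + 1
    fwd = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        fwd = fwd * np.uint64(4) + c[j : j + m]
    # reverse complement: complement (3 - c) read right-to-left
    rc = (np.uint64(3) - c)[::-1]
    rev = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        rev = rev * np.uint64(4) + rc[j : j + m]
    rev = rev[::-1]
    canon = np.minimum(fwd, rev)
    return canon[~bad]


def revcomp_code(code: int, k: int) -> int:
    """Reverse-complement of a 2-bit-encoded k-mer code."""
    out = 0
    for _ in range(k):
        out = (out << 2) | (3 - (code & 3))
        code >>= 2
    return out


def decode_kmer(code: int, k: int) -> str:
    bases = "ACGT"
    out = []
    for _ in range(k):
        out.append(bases[code & 3])
        code >>= 2
    return "".join(reversed(out))


_M1 = np.uint64(0xFF51AFD7ED558CCD)
_M2 = np.uint64(0xC4CEB9FE1A85EC53)
_GOLDEN = np.uint64(0x9E3779B97F4A7C15)


def hash64(codes: np.ndarray, seed: int) -> np.ndarray:
    """MurmurHash3-style 64-bit finalizer (fmix64) with a seed mix.

    Deterministic for a fixed seed; avalanche quality is that of the
    murmur3/splitmix64 finalizer family.
    """
    seed_mix = ((seed & 0xFFFFFFFFFFFFFFFF) * 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    x = codes.astype(np.uint64) ^ np.uint64(seed_mix)
    x ^= x >> np.uint64(33)
    x *= _M1
    x ^= x >> np.uint64(33)
    x *= _M2
    x ^= x >> np.uint64(33)
    return x
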