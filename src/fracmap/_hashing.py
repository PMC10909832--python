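"""Vectorised 2-bit k-mer encoding and stable 64-bit hashing.

Every k-mer is packed big-endian into 64-bit words with A=0, C=1, G=2, T=3,
so numeric order on the packed value equals lexicographic order on the
string.  The canonical form (min of forward and reverse complement) is a
single elementwise minimum, and the hash is a splitmix64-style finalizer
applied to the packed canonical k-mer XOR a mixed seed.  The finalizer is
the standard splitmix64 output permutation (Steele et al.), which is
bijective on 64 bits and passes the usual avalanche tests, so hashes are
uniform over the full 64-bit range — the property FracMinHash retention
relies on.

k up to 32 fits one word; 33 <= k <= 64 is packed into a (hi, lo) pair with
lexicographic comparison and both words folded into the hash.
"""

from __future__ import annotations

import numpy as np

_U64 = np.uint64
_GOLDEN = _U64(0x9E3779B97F4A7C15)
_MIX1 = _U64(0xBF58476D1CE4E5B9)
_MIX2 = _U64(0x94D049BB133111EB)

MAX_KSIZE = 64

# ASCII -> 2-bit code; anything not ACGT/acgt (incl. N, IUPAC codes) -> 255
ENCODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    ENCODE_TABLE[_b] = _i
    ENCODE_TABLE[_b + 32] = _i
del _i, _b

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def encode(seq: str | bytes) -> np.ndarray:
    """Map a DNA string to an array of 2-bit codes (255 marks invalid bases)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return ENCODE_TABLE[np.frombuffer(bytes(seq), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` for valid codes."""
    return bytes(np.frombuffer(b"ACGT", dtype=np.uint8)[codes]).decode("ascii")


def _finalize(z: np.ndarray | np.uint64) -> np.ndarray | np.uint64:
    # splitmix64 output permutation; uint64 arithmetic wraps mod 2**64
    with np.errstate(over="ignore"):
        z = z + _GOLDEN
        z = (z ^ (z >> _U64(30))) * _MIX1
        z = (z ^ (z >> _U64(27))) * _MIX2
        return z ^ (z >> _U64(31))


def seed_mix(hash_seed: int) -> np.uint64:
    """Pre-mixed seed word folded into every k-mer hash."""
    return _U64(_finalize(_U64(hash_seed)))


def kmer_hashes(codes: np.ndarray, ksize: int, hash_seed: int) -> np.ndarray:
    """Hashes of the canonical k-mers of every valid window of ``codes``.

    Windows containing any invalid base are skipped.  Returns a uint64 array
    in window order (duplicates retained).
    """
    if not 3 <= ksize <= MAX_KSIZE:
        raise ValueError(f"ksize must be in [3, {MAX_KSIZE}], got {ksize}")
    n = codes.size - ksize + 1
    if n <= 0:
        return np.empty(0, dtype=_U64)

    bad = np.zeros(codes.size + 1, dtype=np.int64)
    np.cumsum(codes > 3, out=bad[1:])
    ok = (bad[ksize:] - bad[:-ksize]) == 0

    c = codes.astype(_U64)
    rc_c = _U64(3) - c  # wraps for invalid codes; those windows are masked out
    seed_word = seed_mix(hash_seed)

    if ksize <= 32:
        fwd = np.zeros(n, dtype=_U64)
        rev = np.zeros(n, dtype=_U64)
        for j in range(ksize):
            fwd = (fwd << _U64(2)) | c[j : j + n]
            rev = (rev << _U64(2)) | rc_c[ksize - 1 - j : ksize - 1 - j + n]
        canon = np.minimum(fwd, rev)[ok]
        return _finalize(canon ^ seed_word)

    khi = ksize - 32
    fhi = np.zeros(n, dtype=_U64)
    flo = np.zeros(n, dtype=_U64)
    rhi = np.zeros(n, dtype=_U64)
    rlo = np.zeros(n, dtype=_U64)
    for j in range(khi):
        fhi = (fhi << _U64(2)) | c[j : j + n]
        rhi = (rhi << _U64(2)) | rc_c[ksize - 1 - j : ksize - 1 - j + n]
    for j in range(32):
        flo = (flo << _U64(2)) | c[khi + j : khi + j + n]
        rlo = (rlo << _U64(2)) | rc_c[31 - j : 31 - j + n]
    use_rc = (rhi < fhi) | ((rhi == fhi) & (rlo < flo))
    chi = np.where(use_rc, rhi, fhi)[ok]
    clo = np.where(use_rc, rlo, flo)[ok]
    return _finalize(_finalize(chi ^ seed_word) ^ clo)


def hash_sequence(seq: str | bytes, ksize: int, hash_seed: int) -> np.ndarray:
    """Convenience wrapper: encode then hash all valid windows."""
    return kmer_hashes(encode(seq), ksize, hash_seed)


def reverse_complement(kmer: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(kmer))
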