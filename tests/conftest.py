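"""Shared fixtures and independent brute-force oracles.

The oracles here re-derive k-mer sets with plain string operations so the
vectorised sketching path is checked against an implementation that shares
no code with it.
"""

from __future__ import annotations

import numpy as np
import pytest

_RC = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def brute_canonical_stream(seq: str, k: int) -> list[str]:
    """All canonical k-mers of valid windows, in order (pure string ops)."""
    seq = seq.upper()
    out = []
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if any(c not in "ACGT" for c in w):
            continue
        r = revcomp(w)
        out.append(w if w <= r else r)
    return out


def brute_containment(query: str, subject: str, k: int) -> float:
    """Exact distinct-canonical-k-mer set containment."""
    qs = set(brute_canonical_stream(query, k))
    ss = set(brute_canonical_stream(subject, k))
    return len(qs & ss) / len(qs)


def random_dna(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def small_genome() -> str:
    return random_dna(2000, seed=424242)
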