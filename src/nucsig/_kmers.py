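"""Integer encoding of DNA k-mers.

Bases map A=0, C=1, G=2, T=3; a k-mer is read most-significant-first, so
``code("ACG") = 0*16 + 1*4 + 2``. N (and anything else) maps to -1 and
poisons every window containing it.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def encode_bases(seq: str) -> np.ndarray:
    """Per-base integer codes (A/C/G/T -> 0..3, other -> -1)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def window_codes(base_codes: np.ndarray, k: int) -> np.ndarray:
    """Codes of all length-k windows; -1 where the window contains an invalid base.

    Returns an array of length ``len(base_codes) - k + 1`` (empty if the
    sequence is shorter than k).
    """
    n = base_codes.size
    if n < k:
        return np.empty(0, dtype=np.int64)
    valid = base_codes >= 0
    codes = np.zeros(n - k + 1, dtype=np.int64)
    ok = np.ones(n - k + 1, dtype=bool)
    for j in range(k):
        sl = base_codes[j : n - k + 1 + j]
        codes = codes * 4 + np.maximum(sl, 0)
        ok &= valid[j : n - k + 1 + j]
    codes[~ok] = -1
    return codes


def kmer_to_index(kmer: str) -> int:
    idx = 0
    for ch in kmer:
        c = _CODE[ord(ch)]
        if c < 0:
            raise ValueError(f"invalid base {ch!r} in k-mer {kmer!r}")
        idx = idx * 4 + int(c)
    return idx


def index_to_kmer(idx: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[idx & 3])
        idx >>= 2
    return "".join(reversed(out))


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def revcomp_index(idx: int, k: int) -> int:
    """Index of the reverse complement of the k-mer with index ``idx``."""
    out = 0
    for _ in range(k):
        out = out * 4 + (3 - (idx & 3))
        idx >>= 2
    return out


def revcomp_permutation(k: int) -> np.ndarray:
    """Permutation p with p[i] = index of revcomp of k-mer i."""
    idx = np.arange(4**k, dtype=np.int64)
    perm = np.zeros_like(idx)
    rem = idx.copy()
    for _ in range(k):
        perm = perm * 4 + (3 - (rem & 3))
        rem >>= 2
    return perm


def all_kmers(k: int) -> list[str]:
    return [index_to_kmer(i, k) for i in range(4**k)]
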