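"""Shared nucleotide-sequence helpers: reverse complements, canonical k-mers,
and mismatch-tolerant substring scans.

All scanners work on plain uppercase A/C/G/T strings; ambiguous bases never
match anything.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3; any other byte becomes -1."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def kmer_codes(seq: str, k: int) -> np.ndarray:
    """Integer codes of all k-mers; windows containing ambiguous bases dropped."""
    enc = encode(seq)
    n = enc.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        col = enc[j : j + n]
        codes = codes * 4 + np.where(col < 0, 0, col)
        valid &= col >= 0
    return codes[valid]


def canonical_kmers(seq: str, k: int) -> np.ndarray:
    """Sorted unique canonical (min of strand pair) k-mer codes of a sequence."""
    fwd = kmer_codes(seq, k)
    rev = kmer_codes(revcomp(seq), k)
    if fwd.size == 0 and rev.size == 0:
        return np.empty(0, dtype=np.int64)
    # canonical code of window i on the forward strand is min(fwd[i], rev[n-1-i]);
    # taking element-wise min of aligned arrays needs both strands valid, so we
    # instead canonicalize by uniting both strands' windows and keeping the
    # smaller member of each complement pair.
    both = np.concatenate([fwd, rev])
    comp = _revcomp_codes(both, k)
    return np.unique(np.minimum(both, comp))


def _revcomp_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement k-mer integer codes (vectorized)."""
    out = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        out = out * 4 + (3 - (tmp & 3))
        tmp >>= 2
    return out


def containment(query: str, reference: str, k: int) -> float:
    """Fraction of the query's canonical k-mers present in the reference.

    Returns 0.0 when the query has no valid k-mers (e.g. shorter than k).
    """
    q = canonical_kmers(query, k)
    if q.size == 0:
        return 0.0
    r = canonical_kmers(reference, k)
    shared = np.isin(q, r, assume_unique=True).sum()
    return float(shared) / float(q.size)


def find_with_mismatches(pattern: str, text: str, max_mismatch: int) -> list[int]:
    """0-based start positions where `pattern` occurs in `text` with at most
    `max_mismatch` substitutions. Ambiguous bases count as mismatches."""
    m, n = len(pattern), len(text)
    if m == 0 or m > n:
        return []
    p = encode(pattern)
    t = encode(text)
    w = n - m + 1
    mism = np.zeros(w, dtype=np.int32)
    for j in range(m):
        col = t[j : j + w]
        mism += (col != p[j]) | (col < 0) | (p[j] < 0)
    return np.nonzero(mism <= max_mismatch)[0].tolist()


def exact_occurs(pattern: str, text: str) -> bool:
    """True iff `pattern` occurs exactly in `text` on either strand."""
    return pattern in text or revcomp(pattern) in text
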