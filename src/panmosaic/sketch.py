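"""(w,k)-minimizer sketching of DNA strings.

A (w,k)-minimizer of a string is any canonical k-mer achieving the minimum
hash in a window of w consecutive k-mers; the sketch of a string is the
union of minimizers over all windows.  The hash is an invertible
splitmix-style mix of the 2-bit packed k-mer, fixed so sketches are
reproducible across runs and machines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = "ACGT"
_U64 = np.uint64
_SENTINEL = np.uint64(0xFFFFFFFFFFFFFFFF)

HASH_FN_ID = "splitmix64-2bit"


@dataclass(frozen=True)
class MinimizerParams:
    """Window size w (in k-mers) and k-mer length k; w <= k is required for
    the k-mer graph to determine path sequences uniquely."""

    w: int = 14
    k: int = 15
    hash_fn_id: str = HASH_FN_ID

    def __post_init__(self) -> None:
        if not 0 < self.w <= self.k:
            raise ValueError("require 0 < w <= k")
        if self.k > 31:
            raise ValueError("k must be <= 31 for 2-bit packing")


class StringMinimizer(NamedTuple):
    hash: int
    pos: int     # 0-based start on the string
    strand: int  # 0 forward, 1 reverse-complement


def _splitmix64(x: np.ndarray | np.uint64) -> np.ndarray | np.uint64:
    x = _U64(x) if np.isscalar(x) or isinstance(x, (int, np.integer)) else x
    with np.errstate(over="ignore"):  # wraparound is the point
        z = x + _U64(0x9E3779B97F4A7C15)
        z = (z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)
        return z ^ (z >> _U64(31))


def kmer_hash(kmer: str) -> int:
    """Hash of a k-mer in its given orientation."""
    code = 0
    for c in kmer:
        code = (code << 2) | _BASE_CODE[c]
    return int(_splitmix64(_U64(code)))


def revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def canonical_kmer(s: str) -> tuple[str, int]:
    """The orientation of a k-mer with the smaller hash, and its strand
    flag (0 forward / 1 reverse); palindromes resolve to forward."""
    rc = revcomp(s)
    hf, hr = kmer_hash(s), kmer_hash(rc)
    if hr < hf:
        return rc, 1
    return s, 0


def _kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-bit packed codes of all k-mers (forward and reverse-complement)
    and a validity mask (False where the k-mer contains non-ACGT)."""
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    code = np.full(n, 4, dtype=np.uint64)
    for b, v in _BASE_CODE.items():
        code[arr == ord(b)] = v
    valid_base = code < 4
    nk = n - k + 1
    if nk <= 0:
        return np.empty(0, _U64), np.empty(0, _U64), np.empty(0, bool)
    fwd = np.zeros(nk, dtype=np.uint64)
    rev = np.zeros(nk, dtype=np.uint64)
    safe = np.where(valid_base, code, 0)
    comp = np.where(valid_base, np.uint64(3) - safe, 0)
    for i in range(k):
        fwd = (fwd << _U64(2)) | safe[i : i + nk]
        # reverse complement read right-to-left: base at i goes to bit 2*i
        rev |= comp[i : i + nk] << _U64(2 * i)
    valid = np.ones(nk, dtype=bool)
    invalid_pos = np.nonzero(~valid_base)[0]
    for p in invalid_pos:
        lo = max(0, p - k + 1)
        hi = min(nk, p + 1)
        valid[lo:hi] = False
    return fwd, rev, valid


def kmer_hashes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Canonical hash and strand per k-mer start; invalid k-mers get a
    sentinel hash of 2^64-1."""
    fwd, rev, valid = _kmer_codes(seq, k)
    hf = _splitmix64(fwd)
    hr = _splitmix64(rev)
    strand = (hr < hf).astype(np.int8)
    h = np.minimum(hf, hr)
    h[~valid] = _SENTINEL
    return h, strand, valid


def string_minimizers(
    seq: str, params: MinimizerParams, allow_short: bool = False
) -> list[StringMinimizer]:
    """All (w,k)-minimizers of a string; ties within a window are all kept.

    Strings shorter than one full window return an empty sketch unless
    ``allow_short``, in which case all k-mers present form a single window
    (used for short reads and short locus paths).
    """
    w, k = params.w, params.k
    n = len(seq)
    if n < k:
        return []
    h, strand, _ = kmer_hashes(seq, k)
    nk = len(h)
    if n < w + k - 1:
        if not allow_short:
            return []
        m = h.min()
        if m == _SENTINEL:
            return []
        pos = np.nonzero(h == m)[0]
        return [StringMinimizer(int(m), int(p), int(strand[p])) for p in pos]
    win = np.lib.stride_tricks.sliding_window_view(h, w)
    mins = win.min(axis=1)
    keep = np.zeros(nk, dtype=bool)
    eq = win == mins[:, None]
    eq[mins == _SENTINEL] = False
    rows, cols = np.nonzero(eq)
    keep[rows + cols] = True
    pos = np.nonzero(keep)[0]
    return [StringMinimizer(int(h[p]), int(p), int(strand[p])) for p in pos]
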