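"""Strand-canonical rolling k-mer hashing and the Bloom filter read index.

Hashing is a buzhash-style rolling scheme over fixed per-base 64-bit seeds:
a forward hash and a reverse-complement hash are rolled together in O(1) per
window, their minimum is strand-canonical, and the ``h`` per-window values
are derived from it by double hashing (odd stride, so the bit indices of one
element are pairwise distinct in a power-of-two-sized filter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterator, Tuple

import numpy as np

from .assembly_graph import revcomp
from .errors import ConfigurationError, HashingError

if TYPE_CHECKING:  # pragma: no cover
    from .seq_io import ReadLibrary

_MASK = (1 << 64) - 1

# Fixed, arbitrary well-mixed 64-bit seeds per base (complement pairs swap).
_SEED = {
    "A": 0x3C8B_FBB3_95C6_0474,
    "C": 0x3193_C185_62A0_2B4C,
    "G": 0x2032_3ED0_8257_2324,
    "T": 0x2955_49F5_4BE2_4456,
}
_CSEED = {"A": _SEED["T"], "C": _SEED["G"], "G": _SEED["C"], "T": _SEED["A"]}

_GOLDEN = 0x9E37_79B9_7F4A_7C15


def _rol(x: int, r: int) -> int:
    r &= 63
    return ((x << r) | (x >> (64 - r))) & _MASK


def _splitmix64(x: int) -> int:
    x = (x + _GOLDEN) & _MASK
    x = ((x ^ (x >> 30)) * 0xBF58_476D_1CE4_E5B9) & _MASK
    x = ((x ^ (x >> 27)) * 0x94D0_49BB_1331_11EB) & _MASK
    return x ^ (x >> 31)


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _mix(base: int, h: int, salt: int) -> Tuple[int, ...]:
    v0 = _splitmix64(base ^ salt)
    v1 = _splitmix64(v0) | 1  # odd stride -> distinct indices mod 2^m
    return tuple((v0 + i * v1) & _MASK for i in range(h))


def canonical_kmer_hashes(
    seq: str, k: int, h: int = 7, salt: int = 0
) -> Iterator[Tuple[int, ...]]:
    """Yield ``h`` hash values for each k-length window of ``seq``.

    The values at window ``i`` depend only on the canonical form of
    ``seq[i:i+k]``; successive windows are computed by an O(1) roll.
    """
    if k < 1 or len(seq) < k:
        raise HashingError(f"sequence of length {len(seq)} has no {k}-mers")
    fh = 0
    rh = 0
    try:
        for j in range(k):
            fh ^= _rol(_SEED[seq[j]], k - 1 - j)
            rh ^= _rol(_CSEED[seq[j]], j)
    except KeyError as exc:
        raise HashingError(f"non-ACGT symbol {exc.args[0]!r} in sequence") from exc
    yield _mix(min(fh, rh), h, salt)
    for i in range(len(seq) - k):
        out_c, in_c = seq[i], seq[i + k]
        if in_c not in _SEED:
            raise HashingError(f"non-ACGT symbol {in_c!r} in sequence")
        fh = _rol(fh, 1) ^ _rol(_SEED[out_c], k) ^ _SEED[in_c]
        rh = _rol(rh ^ _CSEED[out_c], 64 - 1) ^ _rol(_CSEED[in_c], k - 1)
        yield _mix(min(fh, rh), h, salt)


def hash_kmer(kmer: str, h: int = 7, salt: int = 0) -> Tuple[int, ...]:
    """Hash values of a single k-mer (one-window convenience wrapper)."""
    return next(canonical_kmer_hashes(kmer, len(kmer), h, salt))


class KmerBloomFilter:
    """Bit-vector set of canonical k-mers; false positives only, never negatives.

    The requested size is rounded up to a power of two so the double-hashed
    bit indices of a single element are guaranteed distinct.
    """

    def __init__(self, bits: int, h: int = 7, k: int = 0, salt: int = 0):
        if bits < 64 or h < 1:
            raise ConfigurationError("Bloom filter needs bits >= 64 and h >= 1")
        self.num_bits = 1 << max(6, (bits - 1).bit_length())
        self.h = int(h)
        self.k = int(k)
        self.salt = int(salt)
        self._words = np.zeros(self.num_bits // 64, dtype=np.uint64)
        self.n_inserted = 0

    def insert(self, hashes: Tuple[int, ...]) -> None:
        mask = self.num_bits - 1
        words = self._words
        for v in hashes:
            idx = v & mask
            words[idx >> 6] |= np.uint64(1 << (idx & 63))
        self.n_inserted += 1

    def query(self, hashes: Tuple[int, ...]) -> bool:
        mask = self.num_bits - 1
        words = self._words
        for v in hashes:
            idx = v & mask
            if not (int(words[idx >> 6]) >> (idx & 63)) & 1:
                return False
        return True

    def insert_kmer(self, kmer: str) -> None:
        self.insert(hash_kmer(kmer, self.h, self.salt))

    def query_kmer(self, kmer: str) -> bool:
        return self.query(hash_kmer(kmer, self.h, self.salt))

    def popcount(self) -> int:
        return int(np.bitwise_count(self._words).sum())

    @property
    def fpr(self) -> float:
        return theoretical_fpr(self.n_inserted, self.num_bits, self.h)


class ExactKmerIndex:
    """Hash-set oracle with the same read-indexing behaviour as the Bloom filter."""

    def __init__(self, k: int):
        self.k = int(k)
        self._set: set[str] = set()
        self.n_inserted = 0

    def insert_kmer(self, kmer: str) -> None:
        self._set.add(canonical(kmer))
        self.n_inserted += 1

    def query_kmer(self, kmer: str) -> bool:
        return canonical(kmer) in self._set


def theoretical_fpr(n_inserted: int, bits: int, h: int) -> float:
    """Closed-form Bloom false positive rate ``(1 - e^{-h n / B})^h``."""
    if bits <= 0 or h < 1 or n_inserted < 0:
        raise ValueError("need bits > 0, h >= 1, n_inserted >= 0")
    if n_inserted == 0:
        return 0.0
    return (1.0 - math.exp(-h * n_inserted / bits)) ** h


@dataclass
class ReadIndexStats:
    n_reads: int = 0
    n_skipped: int = 0
    n_kmers: int = 0


def build_read_index(
    library: "ReadLibrary",
    k_rresolver: int,
    params,
    exact: bool = False,
):
    """Insert the first ``t`` 5'-anchored k-mers of every read into an index.

    Storing exactly ``t`` (= the support threshold) k-mers per read means a
    single read found along a path is enough to call the path supported.
    Returns ``(index, stats)``; reads whose first ``k + t - 1`` bases contain
    a non-ACGT symbol are skipped and counted.
    """
    t = params.t
    need = k_rresolver + t - 1
    if library.read_length < need:
        raise ConfigurationError(
            f"read length {library.read_length} < k_rresolver + t - 1 "
            f"({k_rresolver} + {t} - 1 = {need})"
        )
    if exact:
        index = ExactKmerIndex(k_rresolver)
    else:
        index = KmerBloomFilter(params.bloom_bits, params.h, k_rresolver)
    stats = ReadIndexStats()
    acgt = set("ACGT")
    for read in library.reads:
        prefix = read[:need]
        if not set(prefix) <= acgt:
            stats.n_skipped += 1
            continue
        if exact:
            for i in range(t):
                index.insert_kmer(prefix[i : i + k_rresolver])
        else:
            for hashes in canonical_kmer_hashes(prefix, k_rresolver, index.h, index.salt):
                index.insert(hashes)
        stats.n_reads += 1
        stats.n_kmers += t
    return index, stats
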