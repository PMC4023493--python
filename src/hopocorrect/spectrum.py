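"""Homopolymer-spectrum construction.

The spectrum is the multiset of canonical k-hopos occurring at least twice
in a read set, together with a coverage cut-off separating *trusted*
(multiplicity >= cutoff) from *untrusted* k-hopos.  Counting follows a
three-stage procedure:

1. stream every canonical window through a Bloom filter; windows seen a
   second time (or colliding with one) become count-table candidates;
2. re-count every occurrence of each candidate from scratch;
3. prune candidates whose exact count is 1 (these are exactly the Bloom
   false positives plus nothing else).

Stage 2 recounts from scratch, so the final table is exact regardless of
how the Bloom filter is sized — an undersized filter only admits extra
candidates that stage 3 removes.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field
from collections import Counter
from typing import Iterable, Sequence

from .hopo_codec import EncodingError, IS_N, canonical, encode_read

logger = logging.getLogger(__name__)

COUNT_CAP = 65_535  # multiplicities saturate at 16 bits to bound memory
DEFAULT_K = 21
DEFAULT_BITS_PER_KEY = 8


class BloomFilter:
    """Plain bit-array Bloom filter with crc32/adler32 double hashing.

    No false negatives; false-positive rate for ``n`` insertions follows
    the usual ``(1 - e^(-hn/m))^h`` estimate.
    """

    def __init__(self, n_bits: int, num_hashes: int):
        if n_bits < 8:
            n_bits = 8
        self.n_bits = n_bits
        self.num_hashes = max(1, num_hashes)
        self._bits = bytearray((n_bits + 7) // 8)
        self.inserted = 0

    @classmethod
    def sized_for(cls, n_keys: int, bits_per_key: float) -> "BloomFilter":
        n_bits = max(64, int(n_keys * bits_per_key))
        h = max(1, round(0.69 * bits_per_key))
        return cls(n_bits, h)

    def _indices(self, key: bytes):
        h1 = zlib.crc32(key)
        h2 = zlib.adler32(key) | 1
        m = self.n_bits
        return ((h1 + i * h2) % m for i in range(self.num_hashes))

    def add(self, key: bytes) -> bool:
        """Insert ``key``; return True if it already tested positive."""
        present = True
        bits = self._bits
        for idx in self._indices(key):
            byte, bit = idx >> 3, 1 << (idx & 7)
            if not bits[byte] & bit:
                present = False
                bits[byte] |= bit
        self.inserted += 1
        return present

    def __contains__(self, key: bytes) -> bool:
        bits = self._bits
        return all(bits[idx >> 3] & (1 << (idx & 7)) for idx in self._indices(key))


class CountTable(dict):
    """Canonical k-hopo code -> exact multiplicity (>= 2 after pruning)."""

    def __init__(self, k: int):
        super().__init__()
        self.k = k
        self.skipped_reads = 0


def _canonical_windows(codes: bytes, k: int):
    """Canonical windows of a read, skipping any window containing N."""
    n = len(codes)
    if n < k:
        return
    n_pos = [j for j in range(n) if IS_N[codes[j]]]
    if not n_pos:
        for i in range(n - k + 1):
            yield canonical(codes[i : i + k])
        return
    banned = bytearray(n - k + 1)
    for j in n_pos:
        lo = max(0, j - k + 1)
        hi = min(n - k, j)
        for i in range(lo, hi + 1):
            banned[i] = 1
    for i in range(n - k + 1):
        if not banned[i]:
            yield canonical(codes[i : i + k])


def count_khopos(
    reads: Sequence[str],
    k: int = DEFAULT_K,
    *,
    bits_per_key: float = DEFAULT_BITS_PER_KEY,
    expected_keys: int | None = None,
    workers: int = 1,
) -> CountTable:
    """Exact multiplicities (>= 2) of all canonical k-hopos in ``reads``.

    ``reads`` must be re-iterable (the procedure makes two passes).  The
    result is independent of read order, of Bloom sizing and of ``workers``
    (keys are routed to per-worker partitions by a hash of the canonical
    code and merged, mirroring a master/slave partitioning; the merged
    table equals the serial one by construction).  Unencodable reads are
    logged, skipped and tallied in ``CountTable.skipped_reads``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    workers = max(1, int(workers))

    encoded: list[bytes] = []
    skipped = 0
    total_pairs = 0
    for seq in reads:
        try:
            codes = encode_read(seq).codes
        except EncodingError as exc:
            logger.warning("skipping unencodable read: %s", exc)
            skipped += 1
            continue
        encoded.append(codes)
        total_pairs += len(codes)

    if expected_keys is None:
        expected_keys = max(64, total_pairs)
    bloom = BloomFilter.sized_for(expected_keys, bits_per_key)

    # Stage 1: Bloom pre-filter selects candidate (likely non-unique) keys.
    parts: list[dict[bytes, int]] = [dict() for _ in range(workers)]
    for codes in encoded:
        for key in _canonical_windows(codes, k):
            if bloom.add(key):
                parts[zlib.crc32(key) % workers].setdefault(key, 0)

    # Stage 2: exact re-count of every occurrence of each candidate.
    for codes in encoded:
        for key in _canonical_windows(codes, k):
            part = parts[zlib.crc32(key) % workers]
            c = part.get(key)
            if c is not None and c < COUNT_CAP:
                part[key] = c + 1

    # Stage 3: prune unique keys (Bloom false positives land here).
    table = CountTable(k)
    table.skipped_reads = skipped
    for part in parts:
        for key, c in part.items():
            if c >= 2:
                table[key] = c
    return table


Histogram = dict  # multiplicity (>=2) -> number of distinct k-hopos


def build_histogram(t: CountTable) -> Histogram:
    """Multiplicity histogram of the count table; mass equals table size."""
    return dict(sorted(Counter(t.values()).items()))


def smooth_histogram(h: Histogram, window: int = 3) -> Histogram:
    """Optional moving-average smoothing for noisy desk-scale histograms."""
    if not h:
        return {}
    lo, hi = min(h), max(h)
    half = window // 2
    out = {}
    for m in range(lo, hi + 1):
        vals = [h.get(j, 0) for j in range(m - half, m + half + 1) if lo <= j <= hi]
        out[m] = sum(vals) / len(vals)
    return out


def estimate_cutoff(h: Histogram) -> int:
    """Coverage cut-off: the multiplicity of smallest density at the valley
    between the error mode (low multiplicity) and the coverage mode.

    Returns the smallest multiplicity ``m >= 3`` that is a local minimum
    (``h[m] <= h[m-1]`` and ``h[m] < h[m+1]``; bins beyond the observed
    support count as zero, so the right edge never qualifies), resolving
    equal-density plateaus to their smallest multiplicity.  A genuine
    valley separates the error mode from the coverage mode, so a local
    minimum only qualifies when the k-hopos above it hold a non-negligible
    share (>= 10%) of the spectrum — this rejects noise dips in the far
    tail of a merged, effectively unimodal histogram.  A histogram with no
    qualifying valley (e.g. monotone non-increasing, or low-coverage data
    whose modes have merged) yields 2 with a warning suggesting a
    user-supplied cut-off.
    """
    if not h:
        raise ValueError("empty histogram: no k-hopos to estimate a cut-off from")
    hi = max(h)
    total = sum(h.values())
    get = lambda m: h.get(m, 0)
    right_mass = total
    for m in range(3, hi + 1):
        right_mass -= get(m - 1)
        cur = get(m)
        if (
            cur <= get(m - 1)
            and (m + 1 <= hi)
            and cur < get(m + 1)
            and right_mass >= 0.10 * total
        ):
            while m > 3 and get(m - 1) == cur:
                m -= 1
            return m
    warnings.warn(
        "multiplicity histogram has no interior valley; falling back to "
        "cut-off 2 — consider supplying a cut-off explicitly",
        stacklevel=2,
    )
    return 2


@dataclass
class SpectrumModel:
    """A count table plus the cut-off defining the trusted k-hopo set."""

    counts: CountTable
    cutoff: int
    k: int
    histogram: Histogram = field(default_factory=dict)

    def __post_init__(self):
        if self.cutoff < 2:
            raise ValueError("cutoff must be >= 2")

    def multiplicity(self, w: bytes) -> int:
        """Stored count of a window (canonicalised lookup), 0 when absent."""
        if len(w) != self.k:
            raise ValueError(f"window length {len(w)} != k={self.k}")
        return self.counts.get(canonical(w), 0)

    def is_trusted(self, w: bytes) -> bool:
        """True iff multiplicity >= cutoff; windows containing N never are."""
        if len(w) != self.k:
            raise ValueError(f"window length {len(w)} != k={self.k}")
        if any(IS_N[v] for v in w):
            return False
        return self.counts.get(canonical(w), 0) >= self.cutoff

    @classmethod
    def from_reads(
        cls,
        reads: Sequence[str],
        k: int = DEFAULT_K,
        cutoff: int | None = None,
        *,
        bits_per_key: float = DEFAULT_BITS_PER_KEY,
        workers: int = 1,
        smooth: bool = False,
    ) -> "SpectrumModel":
        """Count, histogram and (unless overridden) estimate the cut-off."""
        counts = count_khopos(reads, k, bits_per_key=bits_per_key, workers=workers)
        hist = build_histogram(counts)
        if cutoff is None:
            basis = smooth_histogram(hist) if smooth else hist
            cutoff = estimate_cutoff(basis) if basis else 2
        return cls(counts=counts, cutoff=cutoff, k=k, histogram=hist)
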