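"""Homopolymer-space encoding of DNA reads.

A read is represented as a string of *homopolymer pairs*: each maximal run
of identical bases (case-folded) becomes a pair ``(R, X)`` of run length
``R`` and base ``X``.  ``AACCCCCGGGT`` encodes as ``(2,A)(5,C)(3,G)(1,T)``.
Every pair is packed into a single byte::

    value = 128*L + 5*R + B - 4

with ``B`` the base code (A=0, C=1, G=2, T=3, N=4) and ``L`` the lowercase
flag, so run lengths are limited to 1..25 and valid codes lie in [1, 253]
(byte 0 is reserved as a sentinel and never produced).

A *k-hopo* — the homopolymer-space analogue of a k-mer — is a window of
``k`` consecutive pairs.  Throughout the package a k-hopo is simply a
``bytes`` object of length ``k`` holding the packed pair codes; its
canonical form is whichever of the window and its reverse complement has
the lexicographically smaller byte sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby
from typing import Iterator, NamedTuple

ALPHABET = "ACGTN"
BASE_CODE = {b: i for i, b in enumerate(ALPHABET)}
MAX_RUN = 25
N_CODE = 4
_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0, 4: 4}


class EncodingError(ValueError):
    """Input sequence cannot be represented in homopolymer space."""

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message)
        self.offset = offset


class UnencodableRunError(EncodingError):
    """A homopolymer run exceeds the 25-base limit of the byte code."""


class HopoPair(NamedTuple):
    """One homopolymer run: length ``R``, base ``X`` and a lowercase flag."""

    run_length: int
    base: str
    lowercase: bool = False

    @property
    def byte(self) -> int:
        return pair_to_byte(self)


def pair_to_byte(p: HopoPair) -> int:
    """Pack a pair into its one-byte code ``128*L + 5*R + B - 4``."""
    if not 1 <= p.run_length <= MAX_RUN:
        raise UnencodableRunError(
            f"run length {p.run_length} outside [1, {MAX_RUN}]"
        )
    b = BASE_CODE[p.base.upper()]
    return 128 * int(p.lowercase) + 5 * p.run_length + b - 4


def byte_to_pair(v: int) -> HopoPair:
    """Invert :func:`pair_to_byte`; byte 0 and the gap 126..128 are invalid."""
    if not 1 <= v <= 253 or v in (126, 127, 128):
        raise ValueError(f"byte {v} is not a valid homopolymer pair code")
    low = v >= 129
    t = v - (128 if low else 0) + 4
    run, b = divmod(t, 5)
    base = ALPHABET[b]
    return HopoPair(run, base.lower() if low else base, low)


def _make_byte(run: int, base_code: int, low: bool) -> int:
    return 128 * int(low) + 5 * run + base_code - 4


# Per-byte lookup tables (index 0..255; invalid codes hold 0 / False).
RUN_LEN = [0] * 256
BASE_OF = [0] * 256
IS_LOWER = [False] * 256
IS_N = bytearray(256)
_rc_table = bytearray(256)
for _low in (False, True):
    for _r in range(1, MAX_RUN + 1):
        for _b in range(5):
            _v = _make_byte(_r, _b, _low)
            RUN_LEN[_v] = _r
            BASE_OF[_v] = _b
            IS_LOWER[_v] = _low
            IS_N[_v] = 1 if _b == N_CODE else 0
            _rc_table[_v] = _make_byte(_r, _COMPLEMENT[_b], _low)
RC_TABLE = bytes(_rc_table)
del _rc_table, _low, _r, _b, _v


@dataclass(frozen=True)
class HopoString:
    """A read in homopolymer space: an immutable string of packed pair codes."""

    codes: bytes

    def __len__(self) -> int:
        return len(self.codes)

    def __iter__(self) -> Iterator[HopoPair]:
        return (byte_to_pair(v) for v in self.codes)

    @property
    def pairs(self) -> tuple[HopoPair, ...]:
        return tuple(self)

    @property
    def origin_length(self) -> int:
        """Total number of bases represented."""
        return sum(RUN_LEN[v] for v in self.codes)


def encode_read(sequence: str) -> HopoString:
    """Encode a base string into homopolymer space.

    Runs are grouped case-insensitively; the pair's case flag is taken from
    the run's first character (mixed-case runs are normalised to it, a
    documented lossy convention — soft-masking masks whole regions in
    practice).  Raises :class:`EncodingError` on non-ACGTN characters and
    :class:`UnencodableRunError` on runs longer than 25.
    """
    codes = bytearray()
    pos = 0
    for key, grp in groupby(sequence, key=str.upper):
        run = sum(1 for _ in grp)
        b = BASE_CODE.get(key)
        if b is None:
            raise EncodingError(
                f"invalid character {sequence[pos]!r} at offset {pos}", offset=pos
            )
        if run > MAX_RUN:
            raise UnencodableRunError(
                f"homopolymer run of {run} at offset {pos} exceeds {MAX_RUN}",
                offset=pos,
            )
        codes.append(_make_byte(run, b, sequence[pos].islower()))
        pos += run
    return HopoString(bytes(codes))


def decode(h: HopoString | bytes) -> str:
    """Inverse of :func:`encode_read`: emit each run in its flagged case."""
    codes = h.codes if isinstance(h, HopoString) else h
    out = []
    for v in codes:
        base = ALPHABET[BASE_OF[v]]
        if IS_LOWER[v]:
            base = base.lower()
        out.append(base * RUN_LEN[v])
    return "".join(out)


def reverse_complement(h: HopoString | bytes):
    """Reverse the pair order and complement bases (A<->T, C<->G, N->N).

    Run lengths and case flags are preserved; decoding the result equals the
    base-space reverse complement of decoding the input.
    """
    if isinstance(h, HopoString):
        return HopoString(h.codes.translate(RC_TABLE)[::-1])
    return h.translate(RC_TABLE)[::-1]


def canonical(w: bytes) -> bytes:
    """Canonical form of a k-hopo window: the lexicographically smaller of
    the window's byte code and its reverse complement's (strand collapse).
    A self-reverse-complementary window is returned as-is."""
    rc = w.translate(RC_TABLE)[::-1]
    return w if w <= rc else rc


def windows(h: HopoString | bytes, k: int) -> list[bytes]:
    """All k-hopo windows of ``h`` in read order (non-canonical).

    Yields ``max(0, len(h) - k + 1)`` windows; empty when the read has
    fewer than ``k`` homopolymers.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    codes = h.codes if isinstance(h, HopoString) else h
    return [codes[i : i + k] for i in range(len(codes) - k + 1)]
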