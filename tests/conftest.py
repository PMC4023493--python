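"""Shared fixtures and strategies for the test suite."""

from __future__ import annotations

from collections import Counter

import pytest
from hypothesis import strategies as st

from hopocorrect.hopo_codec import HopoPair, HopoString, canonical, encode_read, windows
from hopocorrect.spectrum import CountTable


def naive_khopo_counts(reads, k):
    """Independent exhaustive counting oracle: canonical windows of every
    read, windows containing N dropped, filtered to multiplicity >= 2."""
    counts = Counter()
    for seq in reads:
        try:
            codes = encode_read(seq).codes
        except ValueError:
            continue
        for w in windows(codes, k):
            if any(b in "Nn" for b in _window_bases(w)):
                continue
            counts[canonical(w)] += 1
    return {key: c for key, c in counts.items() if c >= 2}


def _window_bases(w: bytes):
    from hopocorrect.hopo_codec import ALPHABET, BASE_OF

    return [ALPHABET[BASE_OF[v]] for v in w]


@st.composite
def hopo_pairs(draw, alphabet="ACGT"):
    run = draw(st.integers(1, 25))
    base = draw(st.sampled_from(alphabet))
    low = draw(st.booleans())
    return HopoPair(run, base.lower() if low else base, low)


@st.composite
def hopo_strings(draw, min_pairs=0, max_pairs=30, alphabet="ACGT"):
    """Valid homopolymer strings: adjacent pairs differ in case-folded base."""
    n = draw(st.integers(min_pairs, max_pairs))
    pairs = []
    prev = None
    for _ in range(n):
        p = draw(hopo_pairs(alphabet).filter(
            lambda q, prev=prev: prev is None or q.base.upper() != prev
        ))
        pairs.append(p)
        prev = p.base.upper()
    return HopoString(bytes(p.byte for p in pairs))


@pytest.fixture(scope="session")
def small_genome():
    from hopocorrect.sim454 import generate_genome

    return generate_genome(5_000, 0.5, 12345)


def spectrum_from_copies(sequence, k, copies=3, cutoff=2):
    """A noise-free spectrum supporting every window of ``sequence``."""
    from hopocorrect.spectrum import SpectrumModel, count_khopos

    table = count_khopos([sequence] * copies, k)
    return SpectrumModel(counts=table, cutoff=cutoff, k=k)
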