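"""Correction stages: masks, alternatives, two-sided / one-sided / voting."""

import numpy as np
import pytest

from hopocorrect.corrector import (
    CorrectorConfig,
    Read,
    adjust_quality,
    correct_read,
    enumerate_alternatives,
    one_sided,
    trust_mask,
    trusted_regions,
    two_sided,
    voting_refine,
)
from hopocorrect.hopo_codec import byte_to_pair, encode_read
from hopocorrect.sim454 import generate_genome

from conftest import spectrum_from_copies


def pairs_of(codes):
    return [(byte_to_pair(v).run_length, byte_to_pair(v).base) for v in codes]


@pytest.fixture
def ref_spectrum():
    """Noise-free k=3 spectrum built from 3 copies of AACCCCCGGGT."""
    return spectrum_from_copies("AACCCCCGGGT", k=3)


class TestTrustMask:
    def test_error_free_read_fully_trusted(self, ref_spectrum):
        codes = encode_read("AACCCCCGGGT").codes
        assert trust_mask(codes, ref_spectrum) == [True] * 4

    def test_erroneous_read_all_false(self, ref_spectrum):
        codes = encode_read("AACCCCGGGT").codes  # C-run 4 instead of 5
        assert trust_mask(codes, ref_spectrum) == [False] * 4

    def test_read_shorter_than_k(self, ref_spectrum):
        assert trust_mask(encode_read("AC").codes, ref_spectrum) == [False, False]


class TestEnumerateAlternatives:
    def test_length_alternatives_only_when_run_gt1(self):
        cfg = CorrectorConfig(k=3)
        codes = encode_read("AACCCCGGGT").codes  # (2A)(4C)(3G)(1T)
        alts = [pairs_of([a])[0] for a in enumerate_alternatives(codes, 1, cfg)]
        assert sorted(alts) == [(1, "C"), (2, "C"), (3, "C"), (5, "C"), (6, "C"), (7, "C")]

    def test_substitutions_skip_neighbour_bases(self):
        cfg = CorrectorConfig(k=3)
        codes = encode_read("GGGTAA").codes  # (3G)(1T)(2A)
        alts = [pairs_of([a])[0] for a in enumerate_alternatives(codes, 1, cfg)]
        # length alternatives 2..4 of T plus substitution C only (A, G blocked)
        assert sorted(alts) == [(1, "C"), (2, "T"), (3, "T"), (4, "T")]

    def test_n_position_has_no_alternatives(self):
        cfg = CorrectorConfig(k=3)
        codes = encode_read("ANG").codes
        assert enumerate_alternatives(codes, 1, cfg) == []

    def test_delta_respects_byte_range(self):
        cfg = CorrectorConfig(k=3, max_indel_delta=3)
        codes = encode_read("A" + "C" * 25 + "G").codes
        alts = [pairs_of([a])[0] for a in enumerate_alternatives(codes, 1, cfg)]
        # run already at 25: only shrinking alternatives remain
        assert sorted(alts) == [(22, "C"), (23, "C"), (24, "C")]


class TestTwoSided:
    def test_restores_single_run_length_error(self, ref_spectrum):
        read = Read("r1", "AACCCCGGGT")
        fixed, records = two_sided(read, ref_spectrum, CorrectorConfig(k=3))
        assert fixed.sequence == "AACCCCCGGGT"
        assert len(records) == 1
        rec = records[0]
        assert rec.hopo_index == 1
        assert (rec.old.run_length, rec.old.base) == (4, "C")
        assert (rec.new.run_length, rec.new.base) == (5, "C")
        assert rec.stage == "two_sided"
        assert rec.base_offset == 2

    def test_supported_read_unchanged(self, ref_spectrum):
        read = Read("r1", "AACCCCCGGGT")
        fixed, records = two_sided(read, ref_spectrum, CorrectorConfig(k=3))
        assert fixed.sequence == read.sequence and records == []

    def test_two_errors_in_one_window_left_alone(self, ref_spectrum):
        read = Read("r1", "AACCCCGGT")  # C-run and G-run both short
        fixed, records = two_sided(read, ref_spectrum, CorrectorConfig(k=3))
        assert fixed.sequence == read.sequence and records == []


class TestTrustedRegions:
    @pytest.mark.parametrize(
        "mask,k,expected",
        [
            ([False] * 3 + [True] * 3 + [False], 3, [(3, 5)]),
            ([False] * 5, 3, []),
            ([True] * 5, 3, [(0, 4)]),
            ([True] * 2 + [False] + [True] * 4, 3, [(3, 6)]),
        ],
    )
    def test_maximal_runs_of_length_ge_k(self, mask, k, expected):
        assert trusted_regions(mask, k) == expected


class TestOneSided:
    def test_extends_left_from_trusted_anchor(self):
        model = spectrum_from_copies("AACCCCCGGGTAAGGGG", k=3)
        read = Read("r1", "AACCCCGGTAAGGGG")  # C-run 4, G-run 2
        fixed, records = one_sided(read, model, CorrectorConfig(k=3))
        assert fixed.sequence == "AACCCCCGGGTAAGGGG"
        steps = [
            ((r.old.run_length, r.old.base), (r.new.run_length, r.new.base))
            for r in records
        ]
        assert steps == [((2, "G"), (3, "G")), ((4, "C"), (5, "C"))]
        assert all(r.stage == "one_sided" for r in records)

    def test_fully_trusted_read_unchanged(self):
        model = spectrum_from_copies("AACCCCCGGGTAAGGGG", k=3)
        read = Read("r1", "AACCCCCGGGTAAGGGG")
        fixed, records = one_sided(read, model, CorrectorConfig(k=3))
        assert fixed.sequence == read.sequence and records == []

    def test_no_trusted_region_no_anchor(self):
        model = spectrum_from_copies("AACCCCCGGGTAAGGGG", k=3)
        read = Read("r1", "TTTTTCATGCAG")
        fixed, records = one_sided(read, model, CorrectorConfig(k=3))
        assert fixed.sequence == read.sequence and records == []

    def test_rollback_cap_limits_corrections_per_window(self):
        # an orientation may not pile more than the cap into one k-window
        genome = generate_genome(3_000, 0.5, 99)
        model = spectrum_from_copies(genome, k=5)
        seg = genome[100:220]
        read = Read("r1", seg)
        fixed, records = one_sided(
            read, model, CorrectorConfig(k=5, max_corrections_per_window=1)
        )
        from collections import Counter

        pos = [r.hopo_index for r in records]
        for start in range(0, max(pos, default=0) + 1):
            assert sum(1 for p in pos if start <= p < start + 5) <= 1


class TestVoting:
    def test_unanimous_single_fix_applied(self):
        # two-sided is ambiguous here by construction: build a spectrum from
        # a sequence pair so that only the voting stage's unanimity over all
        # untrusted windows pins the fix
        genome = generate_genome(2_000, 0.5, 11)
        model = spectrum_from_copies(genome, k=4)
        h = encode_read(genome)
        seg = h.codes[40:52]
        codes = bytearray(seg)
        mid = 6
        old = codes[mid]
        p = byte_to_pair(old)
        codes[mid] = encode_read(p.base * (p.run_length + 1)).codes[0]
        from hopocorrect.hopo_codec import decode

        read = Read("r1", decode(bytes(codes)))
        fixed, records = voting_refine(read, model, CorrectorConfig(k=4))
        assert fixed.sequence == decode(bytes(seg))
        assert [r.stage for r in records] == ["voting"]

    def test_fully_trusted_unchanged(self, ref_spectrum):
        read = Read("r1", "AACCCCCGGGT")
        fixed, records = voting_refine(read, ref_spectrum, CorrectorConfig(k=3))
        assert fixed.sequence == read.sequence and records == []

    def test_unfixable_double_errors_left_alone(self, ref_spectrum):
        read = Read("r1", "AACCCCGGT")
        fixed, records = voting_refine(read, ref_spectrum, CorrectorConfig(k=3))
        assert fixed.sequence == read.sequence and records == []


class TestCorrectRead:
    def test_composes_stages_and_tags(self, ref_spectrum):
        fixed, records = correct_read(
            Read("r1", "AACCCCGGGT"), ref_spectrum, CorrectorConfig(k=3)
        )
        assert fixed.sequence == "AACCCCCGGGT"
        assert [r.stage for r in records] == ["two_sided"]

    def test_short_read_passthrough(self, ref_spectrum):
        read = Read("r1", "ACG")  # 3 hopos < nothing to window at k=3? equal
        short = Read("r2", "AC")
        fixed, records = correct_read(short, ref_spectrum, CorrectorConfig(k=3))
        assert fixed is short and records == []

    def test_unencodable_read_passthrough(self, ref_spectrum):
        bad = Read("r1", "A" * 30 + "CGT")
        fixed, records = correct_read(bad, ref_spectrum, CorrectorConfig(k=3))
        assert fixed is bad and records == []

    def test_endpoints_and_frame_preserved(self):
        genome = generate_genome(3_000, 0.5, 21)
        model = spectrum_from_copies(genome, k=7)
        rng = np.random.default_rng(3)
        for _ in range(20):
            start = int(rng.integers(0, 2_000))
            seg = genome[start : start + 150]
            h = encode_read(seg)
            codes = bytearray(h.codes)
            i = int(rng.integers(1, len(codes) - 1))
            p = byte_to_pair(codes[i])
            new_run = max(1, min(25, p.run_length + int(rng.choice([-1, 1]))))
            if new_run == p.run_length:
                continue
            codes[i] = encode_read(p.base * new_run).codes[0]
            from hopocorrect.hopo_codec import decode

            read = Read("r", decode(bytes(codes)))
            fixed, _ = correct_read(read, model, CorrectorConfig(k=7))
            fh = encode_read(fixed.sequence)
            assert len(fh) == len(codes)
            assert fh.codes[0] == codes[0] and fh.codes[-1] == codes[-1]

    def test_idempotent_on_trusted_input(self):
        genome = generate_genome(2_000, 0.5, 31)
        model = spectrum_from_copies(genome, k=7)
        read = Read("r", genome[200:380])
        fixed, records = correct_read(read, model, CorrectorConfig(k=7))
        assert fixed.sequence == read.sequence and records == []

    def test_mismatched_k_raises(self, ref_spectrum):
        with pytest.raises(ValueError):
            correct_read(Read("r", "AACCCCCGGGT"), ref_spectrum, CorrectorConfig(k=5))


class TestAdjustQuality:
    def test_extension_replicates_last_symbol(self, ref_spectrum):
        read = Read("r1", "AACCCCGGGT", "IIJJJJKKKL")
        fixed, records = two_sided(read, ref_spectrum, CorrectorConfig(k=3))
        assert fixed.sequence == "AACCCCCGGGT"
        assert fixed.quality == "IIJJJJJKKKL"

    def test_examples(self):
        h = encode_read("AACC")
        rec = type("R", (), {})()
        from hopocorrect.corrector import CorrectionRecord
        from hopocorrect.hopo_codec import HopoPair

        grow = [CorrectionRecord("r", 1, 2, HopoPair(2, "C"), HopoPair(3, "C"), "two_sided")]
        shrink = [CorrectionRecord("r", 1, 2, HopoPair(2, "C"), HopoPair(1, "C"), "two_sided")]
        assert adjust_quality("IIJJ", grow, h) == "IIJJJ"
        assert adjust_quality("IIJJ", shrink, h) == "IIJ"
        assert adjust_quality("IIJJ", [], h) == "IIJJ"

    def test_substitution_leaves_quality(self):
        h = encode_read("ACG")
        from hopocorrect.corrector import CorrectionRecord
        from hopocorrect.hopo_codec import HopoPair

        sub = [CorrectionRecord("r", 1, 1, HopoPair(1, "C"), HopoPair(1, "T"), "voting")]
        assert adjust_quality("IJK", sub, h) == "IJK"
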