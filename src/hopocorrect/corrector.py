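"""Three-stage error correction in homopolymer space.

Stage 1 (two-sided, conservative) assumes at most one error per k-hopo: an
untrusted position is changed only when exactly one alternative makes both
the leftmost and the rightmost covering windows trusted.

Stage 2 (one-sided, aggressive) extends outward from trusted regions one
homopolymer at a time, accepting the alternative that makes the immediate
window trusted, preferring deeper look-ahead validation and then larger
multiplicity, with a rollback cap on corrections per k-hopo span.

Stage 3 (voting refinement) applies only fixes unanimously supported by
every untrusted window covering a position, to keep newly introduced
errors at a minimum.

All stages operate on the packed pair codes; alternatives only change a
single pair's run length — or, for length-1 runs, its base, never to a
neighbouring run's base — so the homopolymer frame (the number of pairs)
is invariant and the first and last homopolymers of a read are never
touched (at a read end the true run may extend beyond the read, so its
length is unknowable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .hopo_codec import (
    BASE_OF,
    IS_LOWER,
    IS_N,
    MAX_RUN,
    RUN_LEN,
    EncodingError,
    HopoPair,
    HopoString,
    _make_byte,
    byte_to_pair,
    decode,
    encode_read,
)
from .spectrum import SpectrumModel

logger = logging.getLogger(__name__)

STAGE_TWO_SIDED = "two_sided"
STAGE_ONE_SIDED = "one_sided"
STAGE_VOTING = "voting"


@dataclass
class Read:
    id: str
    sequence: str
    quality: Optional[str] = None

    def __post_init__(self):
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.id}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )


@dataclass
class CorrectorConfig:
    """Tunables of the correction workflow (defaults are the tool's)."""

    k: int = 21
    max_iterations: int = 2
    max_indel_delta: int = 3
    max_lookahead: int = 2
    max_corrections_per_window: int = 4

    def __post_init__(self):
        for name in (
            "k",
            "max_iterations",
            "max_indel_delta",
            "max_lookahead",
            "max_corrections_per_window",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.max_indel_delta > MAX_RUN - 1:
            raise ValueError(f"max_indel_delta must be <= {MAX_RUN - 1}")


@dataclass
class CorrectionRecord:
    """One applied edit, replayable: which pair changed, into what, when."""

    read_id: str
    hopo_index: int
    base_offset: int  # 0-based offset of the run start at application time
    old: HopoPair
    new: HopoPair
    stage: str


def _base_offset(codes, i: int) -> int:
    return sum(RUN_LEN[v] for v in codes[:i])


def trust_mask(codes, model: SpectrumModel) -> list[bool]:
    """Per-homopolymer trust: position i is trusted iff any trusted window
    covers it.  All False when the read has fewer than k homopolymers."""
    n = len(codes)
    k = model.k
    mask = [False] * n
    if n < k:
        return mask
    cover_end = -1  # last position covered by a trusted window so far
    buf = bytes(codes)
    for i in range(n - k + 1):
        if model.is_trusted(buf[i : i + k]):
            start = max(i, cover_end + 1)
            for j in range(start, i + k):
                mask[j] = True
            cover_end = i + k - 1
    return mask


def enumerate_alternatives(codes, i: int, cfg: CorrectorConfig) -> list[int]:
    """Candidate replacement pair codes for position ``i`` (interior only).

    Run-length alternatives ``R +/- d`` for ``d <= max_indel_delta`` within
    [1, 25]; for a length-1 run additionally base substitutions that match
    neither neighbour (a neighbour-matching base would merge runs and shift
    the homopolymer frame, a scenario outside the 454 error model).
    N positions get no alternatives.
    """
    v = codes[i]
    if IS_N[v]:
        return []
    r, b, low = RUN_LEN[v], BASE_OF[v], IS_LOWER[v]
    out = []
    for d in range(-cfg.max_indel_delta, cfg.max_indel_delta + 1):
        r2 = r + d
        if d != 0 and 1 <= r2 <= MAX_RUN:
            out.append(_make_byte(r2, b, low))
    if r == 1:
        blocked = {b}
        if i > 0:
            blocked.add(BASE_OF[codes[i - 1]])
        if i < len(codes) - 1:
            blocked.add(BASE_OF[codes[i + 1]])
        for b2 in range(4):  # substitutions never introduce N
            if b2 not in blocked:
                out.append(_make_byte(1, b2, low))
    return sorted(out)


def two_sided(
    read: Read, model: SpectrumModel, cfg: CorrectorConfig
) -> tuple[Read, list[CorrectionRecord]]:
    """Conservative pass; see module docstring."""
    codes, err = _encode_or_none(read)
    if codes is None:
        return read, []
    records = _two_sided_codes(codes, read.id, model, cfg)
    return _emit(read, codes, records), records


def _encode_or_none(read: Read):
    try:
        return bytearray(encode_read(read.sequence).codes), None
    except EncodingError as exc:
        logger.warning("read %s left uncorrected: %s", read.id, exc)
        return None, exc


def _emit(read: Read, codes, records) -> Read:
    if not records:
        return read
    seq = decode(bytes(codes))
    qual = (
        adjust_quality(read.quality, records, encode_read(read.sequence))
        if read.quality is not None
        else None
    )
    return Read(read.id, seq, qual)


def _window_diff_exceeds(orig, codes, i, new_byte, k: int, cap: int) -> bool:
    """Would setting ``codes[i] = new_byte`` make some k-window covering i
    differ from the stage-zero read ``orig`` in more than ``cap`` pairs?
    Returns the cap invariant guard used by every stage."""
    n = len(codes)
    lo = max(0, i - k + 1)
    hi = min(i, n - k)
    for s in range(lo, hi + 1):
        cnt = 0
        for j in range(s, s + k):
            v = new_byte if j == i else codes[j]
            if v != orig[j]:
                cnt += 1
        if cnt > cap:
            return True
    return False


def _two_sided_codes(codes, read_id, model, cfg, orig=None) -> list[CorrectionRecord]:
    n, k = len(codes), model.k
    orig = bytes(codes) if orig is None else orig
    records: list[CorrectionRecord] = []
    if n < k:
        return records
    for _ in range(cfg.max_iterations):
        changed = False
        mask = trust_mask(codes, model)
        for i in range(1, n - 1):
            if mask[i]:
                continue
            ls = min(max(0, i - k + 1), n - k)
            rs = min(i, n - k)
            passing = []
            for a in enumerate_alternatives(codes, i, cfg):
                old = codes[i]
                codes[i] = a
                ok = model.is_trusted(bytes(codes[ls : ls + k])) and model.is_trusted(
                    bytes(codes[rs : rs + k])
                )
                codes[i] = old
                if ok:
                    passing.append(a)
                    if len(passing) > 1:
                        break  # ambiguous: keep unchanged
            if len(passing) == 1:
                if _window_diff_exceeds(
                    orig, codes, i, passing[0], k, cfg.max_corrections_per_window
                ):
                    continue
                records.append(
                    CorrectionRecord(
                        read_id,
                        i,
                        _base_offset(codes, i),
                        byte_to_pair(codes[i]),
                        byte_to_pair(passing[0]),
                        STAGE_TWO_SIDED,
                    )
                )
                codes[i] = passing[0]
                changed = True
                mask = trust_mask(codes, model)
        if not changed:
            break
    return records


def trusted_regions(mask: list[bool], k: int) -> list[tuple[int, int]]:
    """Maximal runs of trusted positions of length >= k, as inclusive
    (start, end) homopolymer intervals, sorted."""
    out = []
    start = None
    for i, t in enumerate(mask + [False]):
        if t and start is None:
            start = i
        elif not t and start is not None:
            if i - start >= k:
                out.append((start, i - 1))
            start = None
    return out


def one_sided(
    read: Read, model: SpectrumModel, cfg: CorrectorConfig
) -> tuple[Read, list[CorrectionRecord]]:
    """Aggressive pass; see module docstring."""
    codes, err = _encode_or_none(read)
    if codes is None:
        return read, []
    records = _one_sided_codes(codes, read.id, model, cfg)
    return _emit(read, codes, records), records


def _one_sided_codes(codes, read_id, model, cfg, orig=None) -> list[CorrectionRecord]:
    n, k = len(codes), model.k
    orig = bytes(codes) if orig is None else orig
    records: list[CorrectionRecord] = []
    if n < k:
        return records
    regions = trusted_regions(trust_mask(codes, model), k)
    for ridx, (rs, re_) in enumerate(regions):
        stop_right = regions[ridx + 1][0] - 1 if ridx + 1 < len(regions) else n - 2
        stop_left = regions[ridx - 1][1] + 1 if ridx > 0 else 1
        _extend(codes, read_id, model, cfg, re_ + 1, stop_right, +1, records, orig)
        _extend(codes, read_id, model, cfg, rs - 1, stop_left, -1, records, orig)
    return records


def _extend(codes, read_id, model, cfg, start, stop, step, records, orig) -> None:
    """Walk one orientation away from a trusted region, correcting as we go."""
    n, k = len(codes), model.k
    cap = cfg.max_corrections_per_window
    applied: list[tuple[int, int]] = []  # (position, old byte)
    my_records: list[CorrectionRecord] = []
    j = start
    while (step > 0 and 1 <= j <= min(stop, n - 2)) or (
        step < 0 and max(stop, 1) <= j <= n - 2
    ):
        ws = j - k + 1 if step > 0 else j
        if ws < 0 or ws + k > n:
            break
        if not model.is_trusted(bytes(codes[ws : ws + k])):
            best = _best_alternative(codes, j, ws, step, model, cfg)
            if best is None:
                break
            old = codes[j]
            my_records.append(
                CorrectionRecord(
                    read_id,
                    j,
                    _base_offset(codes, j),
                    byte_to_pair(old),
                    byte_to_pair(best),
                    STAGE_ONE_SIDED,
                )
            )
            codes[j] = best
            applied.append((j, old))
            span = _violated_span(applied, j, n, k, cap)
            if span is None and _window_diff_exceeds(
                orig, codes, j, codes[j], k, cap
            ):
                # corrections accumulated across stages breach the cap in
                # some window: disregard this orientation's share of it
                span = (max(0, j - k + 1), min(j, n - k) + k - 1)
            if span is not None:
                lo, hi = span
                for pos, oldb in applied:
                    if lo <= pos <= hi:
                        codes[pos] = oldb
                my_records = [r for r in my_records if not lo <= r.hopo_index <= hi]
                break
        j += step
    records.extend(my_records)


def _violated_span(applied, j, n, k, cap):
    """Return the k-hopo span around the newest correction holding more
    than ``cap`` corrections from this orientation, or None."""
    positions = [p for p, _ in applied]
    for t in range(max(0, j - k + 1), min(j, n - k) + 1):
        if sum(1 for p in positions if t <= p <= t + k - 1) > cap:
            return (t, t + k - 1)
    return None


def _best_alternative(codes, j, ws, step, model, cfg):
    """Viable alternatives make the immediate window trusted; rank by
    look-ahead depth, then immediate-window multiplicity, then smallest
    run-length change, then smallest byte code."""
    n, k = len(codes), model.k
    r0 = RUN_LEN[codes[j]]
    ranked = []
    for a in enumerate_alternatives(codes, j, cfg):
        old = codes[j]
        codes[j] = a
        win = bytes(codes[ws : ws + k])
        if model.is_trusted(win):
            depth = 0
            for t in range(1, cfg.max_lookahead + 1):
                ws2 = ws + t * step
                if ws2 < 0 or ws2 + k > n:
                    break  # clamped at read ends
                if model.is_trusted(bytes(codes[ws2 : ws2 + k])):
                    depth += 1
                else:
                    break
            ranked.append(
                (-depth, -model.multiplicity(win), abs(RUN_LEN[a] - r0), a)
            )
        codes[j] = old
    if not ranked:
        return None
    return min(ranked)[-1]


def voting_refine(
    read: Read, model: SpectrumModel, cfg: CorrectorConfig
) -> tuple[Read, list[CorrectionRecord]]:
    """Voting pass; see module docstring."""
    codes, err = _encode_or_none(read)
    if codes is None:
        return read, []
    records = _voting_codes(codes, read.id, model, cfg)
    return _emit(read, codes, records), records


def _voting_codes(codes, read_id, model, cfg, orig=None) -> list[CorrectionRecord]:
    n, k = len(codes), model.k
    orig = bytes(codes) if orig is None else orig
    records: list[CorrectionRecord] = []
    if n < k:
        return records
    untrusted = [
        i
        for i in range(n - k + 1)
        if not model.is_trusted(bytes(codes[i : i + k]))
    ]
    if not untrusted:
        return records
    cover: dict[int, int] = {}
    votes: dict[tuple[int, int], int] = {}
    for wsd in untrusted:
        for p in range(max(wsd, 1), min(wsd + k, n - 1)):
            cover[p] = cover.get(p, 0) + 1
            for a in enumerate_alternatives(codes, p, cfg):
                old = codes[p]
                codes[p] = a
                if model.is_trusted(bytes(codes[wsd : wsd + k])):
                    votes[(p, a)] = votes.get((p, a), 0) + 1
                codes[p] = old
    # Unanimity: a fix must be backed by every untrusted window covering p
    # and strictly beat every other alternative at p.
    winners: dict[int, int] = {}
    for p in cover:
        cands = [(a, c) for (pp, a), c in votes.items() if pp == p]
        if not cands:
            continue
        cands.sort(key=lambda t: (-t[1], t[0]))
        a, c = cands[0]
        if c == cover[p] and (len(cands) == 1 or cands[1][1] < c):
            winners[p] = a
    # Fixes sharing a window were not validated jointly: drop both.
    pos = sorted(winners)
    conflicted = {
        p for p in pos if any(q != p and abs(q - p) < k for q in pos)
    }
    for p in pos:
        if p in conflicted:
            continue
        if _window_diff_exceeds(
            orig, codes, p, winners[p], k, cfg.max_corrections_per_window
        ):
            continue
        records.append(
            CorrectionRecord(
                read_id,
                p,
                _base_offset(codes, p),
                byte_to_pair(codes[p]),
                byte_to_pair(winners[p]),
                STAGE_VOTING,
            )
        )
        codes[p] = winners[p]
    return records


def correct_read(
    read: Read, model: SpectrumModel, cfg: CorrectorConfig | None = None
) -> tuple[Read, list[CorrectionRecord]]:
    """Full workflow: two-sided, then one-sided, then voting refinement.

    Reads with fewer than k homopolymers, all-N reads and unencodable
    reads pass through unchanged.  The corrected read always decodes to a
    base string with the input's first and last homopolymers intact and
    the same number of homopolymers.
    """
    cfg = cfg or CorrectorConfig(k=model.k)
    if cfg.k != model.k:
        raise ValueError(f"config k={cfg.k} != spectrum k={model.k}")
    codes, err = _encode_or_none(read)
    if codes is None or len(codes) < cfg.k or all(IS_N[v] for v in codes):
        return read, []
    first, last, n0 = codes[0], codes[-1], len(codes)
    orig = bytes(codes)
    records = _two_sided_codes(codes, read.id, model, cfg, orig)
    records += _one_sided_codes(codes, read.id, model, cfg, orig)
    records += _voting_codes(codes, read.id, model, cfg, orig)
    assert codes[0] == first and codes[-1] == last and len(codes) == n0
    return _emit(read, codes, records), records


def adjust_quality(
    quality: str, records: list[CorrectionRecord], original_hopos: HopoString
) -> str:
    """Carry the quality string through run-length edits.

    A run extended by d replicates its last quality symbol d times; a run
    shortened by d drops its last d symbols; substitutions (length-1 runs)
    leave quality untouched.  The homopolymer frame is stable across
    stages, so edits can be applied per run index in order.
    """
    runs = [RUN_LEN[v] for v in original_hopos.codes]
    if len(quality) != sum(runs):
        raise AssertionError("quality length does not match original read")
    quals = []
    off = 0
    for r in runs:
        quals.append(quality[off : off + r])
        off += r
    for rec in records:
        d = rec.new.run_length - rec.old.run_length
        q = quals[rec.hopo_index]
        if d > 0:
            quals[rec.hopo_index] = q + q[-1] * d
        elif d < 0:
            quals[rec.hopo_index] = q[:d]
    out = "".join(quals)
    return out
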