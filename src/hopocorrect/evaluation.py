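"""Correction-quality accounting against simulator ground truth.

Per read, the error-free (truth), erroneous and corrected sequences are
aligned run-by-run in homopolymer space.  Run-length errors preserve the
homopolymer frame, so the three usually line up index-for-index; when a
substitution has merged or split runs, a banded global alignment (match =
same base with cost |R1 - R2|, unit gap cost, mismatches disallowed)
resolves the frames.

For an interior truth run of length ``t`` observed as ``e`` and corrected
to ``c`` (0 when the run's base is absent at the aligned position)::

    TP += max(0, |e - t| - |c - t|)     errors removed
    FP += max(0, |c - t| - |e - t|)     errors introduced
    FN += min(|e - t|, |c - t|)         errors remaining
    TN += min(t, e, c)                  bases correct throughout

Substitution errors are scored per base from the truth records: a record
whose run is fully restored scores one TP, an untouched or still-wrong
one scores one FN.  The first and last homopolymer of each read are
excluded, mirroring the corrector.  Metrics are reported on the 0-100
scale: recall = TP/(TP+FN), specificity = TN/(FP+TN), gain =
(TP-FP)/(TP+FN), precision = TP/(TP+FP) and the F-score as the harmonic
mean of precision and recall.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .corrector import Read
from .hopo_codec import BASE_OF, RUN_LEN, EncodingError, encode_read
from .sim454 import ERR_SUBSTITUTION, TruthRecord


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
        )


@dataclass
class MetricSet:
    """The five quality metrics on the 0-100 scale; ``undefined`` names
    metrics whose denominator was zero (their value is NaN)."""

    recall: float
    specificity: float
    gain: float
    precision: float
    f_score: float
    undefined: frozenset = frozenset()


def _same_frame(a: bytes, b: bytes) -> bool:
    return len(a) == len(b) and all(
        BASE_OF[x] == BASE_OF[y] for x, y in zip(a, b)
    )


def align_hopo(a: bytes, b: bytes) -> dict[int, int]:
    """Banded global alignment of two homopolymer-code strings.

    Match (same base) costs |Ra - Rb|; gaps cost 1 per run; aligning runs
    of different bases is disallowed (a substitution shows up as a gap
    pair).  Returns a mapping from index in ``a`` to aligned index in
    ``b`` (gapped positions absent).
    """
    la, lb = len(a), len(b)
    band = abs(la - lb) + 8
    inf = math.inf
    # D[i][j] = cost of aligning a[:i] with b[:j], banded around the diagonal
    prev = {0: 0.0}
    back: list[dict[int, str]] = [dict() for _ in range(la + 1)]
    for j in range(1, min(lb, band) + 1):
        prev[j] = float(j)
        back[0][j] = "L"
    for i in range(1, la + 1):
        cur: dict[int, float] = {}
        lo = max(0, i - band)
        hi = min(lb, i + band)
        for j in range(lo, hi + 1):
            best, arrow = inf, ""
            up = prev.get(j, inf) + 1.0
            if up < best:
                best, arrow = up, "U"
            left = cur.get(j - 1, inf) + 1.0
            if left < best:
                best, arrow = left, "L"
            if j > 0:
                diag = prev.get(j - 1, inf)
                if diag < inf and BASE_OF[a[i - 1]] == BASE_OF[b[j - 1]]:
                    d = diag + abs(RUN_LEN[a[i - 1]] - RUN_LEN[b[j - 1]])
                    if d <= best:
                        best, arrow = d, "D"
            cur[j] = best
            back[i][j] = arrow
        prev = cur
    mapping: dict[int, int] = {}
    i, j = la, lb
    while i > 0 or j > 0:
        arrow = back[i].get(j)
        if arrow == "D":
            mapping[i - 1] = j - 1
            i, j = i - 1, j - 1
        elif arrow == "U":
            i -= 1
        elif arrow == "L":
            j -= 1
        else:  # fell off the band; treat the remainder as gaps
            if i > 0:
                i -= 1
            else:
                j -= 1
    return mapping


def confusion_counts(
    truth_read: Read,
    erroneous_read: Read,
    corrected_read: Read,
    sub_records: Optional[Iterable[TruthRecord]] = None,
) -> ConfusionCounts:
    """Score one read triple; see the module docstring for the accounting."""
    t = encode_read(truth_read.sequence).codes
    e = encode_read(erroneous_read.sequence).codes
    c = encode_read(corrected_read.sequence).codes
    map_te = (
        {i: i for i in range(len(t))} if _same_frame(t, e) else align_hopo(t, e)
    )
    map_tc = (
        {i: i for i in range(len(t))} if _same_frame(t, c) else align_hopo(t, c)
    )
    subs = Counter()
    for rec in sub_records or ():
        if rec.error_type == ERR_SUBSTITUTION:
            subs[rec.hopo_index] += 1

    out = ConfusionCounts()
    for j in range(1, len(t) - 1):
        tb, tlen = BASE_OF[t[j]], RUN_LEN[t[j]]
        ej = map_te.get(j)
        cj = map_tc.get(j)
        # mirror the corrector: runs pinned to a read end are not assessed
        if ej in (0, len(e) - 1) or cj in (0, len(c) - 1):
            continue
        e_len = RUN_LEN[e[ej]] if ej is not None and BASE_OF[e[ej]] == tb else 0
        c_len = RUN_LEN[c[cj]] if cj is not None and BASE_OF[c[cj]] == tb else 0
        if j in subs:
            n_sub = subs[j]
            restored = c_len == tlen and (
                cj is None or _region_matches(t, c, j, cj)
            )
            if restored and (e_len != tlen or not _region_matches(t, e, j, ej)):
                out.tp += n_sub
            else:
                out.fn += n_sub
            out.tn += max(0, min(tlen, e_len, c_len) - n_sub)
        else:
            de, dc = abs(e_len - tlen), abs(c_len - tlen)
            out.tp += max(0, de - dc)
            out.fp += max(0, dc - de)
            out.fn += min(de, dc)
            if e_len and c_len:
                out.tn += min(tlen, e_len, c_len)
    return out


def _region_matches(t: bytes, other: bytes, j: int, oj: Optional[int]) -> bool:
    return oj is not None and other[oj] == _case_fold(t[j]) == _case_fold(other[oj])


def _case_fold(v: int) -> int:
    return v if v < 126 else v - 128


def metrics(c: ConfusionCounts) -> MetricSet:
    """The five metrics on the 0-100 scale; zero denominators are flagged
    undefined (NaN value) rather than raising."""
    undefined = set()

    def ratio(name: str, num: float, den: float) -> float:
        if den <= 0:
            undefined.add(name)
            return math.nan
        return 100.0 * num / den

    recall = ratio("recall", c.tp, c.tp + c.fn)
    specificity = ratio("specificity", c.tn, c.fp + c.tn)
    gain = ratio("gain", c.tp - c.fp, c.tp + c.fn)
    precision = ratio("precision", c.tp, c.tp + c.fp)
    if "recall" in undefined or "precision" in undefined or precision + recall <= 0:
        undefined.add("f_score")
        f_score = math.nan
    else:
        f_score = 2.0 * precision * recall / (precision + recall)
    return MetricSet(recall, specificity, gain, precision, f_score, frozenset(undefined))


def evaluate_dataset(
    clean_reads: Sequence[Read],
    erroneous_reads: Sequence[Read],
    corrected_reads: Sequence[Read],
    truth_records: Sequence[TruthRecord],
) -> tuple[MetricSet, ConfusionCounts, pd.DataFrame]:
    """Aggregate confusion counts over all reads, then compute metrics
    (metrics of the summed counts, not a mean of per-read metrics).

    Reads are joined by id; ids present in one set but not another raise
    with the offending ids listed.  Returns the aggregate metrics, the
    summed counts and a per-read table.
    """
    clean = {r.id: r for r in clean_reads}
    err = {r.id: r for r in erroneous_reads}
    corr = {r.id: r for r in corrected_reads}
    missing = (set(clean) ^ set(err)) | (set(clean) ^ set(corr))
    if missing:
        raise ValueError(
            "read ids do not match across inputs: " + ", ".join(sorted(missing)[:10])
        )
    recs_by_read: dict[str, list[TruthRecord]] = {}
    for rec in truth_records:
        recs_by_read.setdefault(rec.read_id, []).append(rec)

    total = ConfusionCounts()
    rows = []
    skipped = 0
    for rid in clean:
        try:
            counts = confusion_counts(
                clean[rid], err[rid], corr[rid], recs_by_read.get(rid, ())
            )
        except EncodingError:
            skipped += 1
            continue
        total = total + counts
        rows.append(
            {
                "read_id": rid,
                "tp": counts.tp,
                "fp": counts.fp,
                "tn": counts.tn,
                "fn": counts.fn,
            }
        )
    table = pd.DataFrame(rows, columns=["read_id", "tp", "fp", "tn", "fn"])
    table.attrs["skipped_reads"] = skipped
    return metrics(total), total, table
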