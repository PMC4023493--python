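"""Scikit-learn-style front end to the correction workflow.

``fit`` builds the homopolymer spectrum (count table, histogram, coverage
cut-off) from a collection of reads; ``transform`` corrects reads against
it.  The estimator composes with sklearn pipelines and ``clone``; the
underlying functional modules (:mod:`~hopocorrect.spectrum`,
:mod:`~hopocorrect.corrector`) remain the low-level surface.
"""

from __future__ import annotations

from typing import Optional, Sequence

from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .corrector import CorrectionRecord, CorrectorConfig, Read, correct_read
from .spectrum import DEFAULT_BITS_PER_KEY, DEFAULT_K, SpectrumModel


def _as_read(x, i: int) -> Read:
    if isinstance(x, Read):
        return x
    return Read(f"read_{i:06d}", str(x))


class HopoSpectrumCorrector(BaseEstimator, TransformerMixin):
    """Homopolymer-spectrum error corrector for 454-style reads.

    Parameters
    ----------
    k : window size in homopolymers (default 21).
    cutoff : coverage cut-off; estimated from the multiplicity histogram's
        valley when None.
    bits_per_key : Bloom-filter sizing for the counting stage (the final
        counts are exact regardless).
    max_iterations, max_indel_delta, max_lookahead,
    max_corrections_per_window : corrector tunables; the per-window
        correction cap defaults to 4.
    workers : counting partitions; results are identical for any value.

    Attributes (after fit)
    ----------------------
    spectrum_ : the fitted :class:`SpectrumModel`.
    histogram_ : multiplicity histogram of the count table.
    cutoff_ : the coverage cut-off in use.
    n_khopos_ : number of distinct non-unique canonical k-hopos.
    skipped_reads_ : unencodable reads ignored during counting.
    """

    def __init__(
        self,
        k: int = DEFAULT_K,
        cutoff: Optional[int] = None,
        bits_per_key: float = DEFAULT_BITS_PER_KEY,
        max_iterations: int = 2,
        max_indel_delta: int = 3,
        max_lookahead: int = 2,
        max_corrections_per_window: int = 4,
        workers: int = 1,
    ):
        self.k = k
        self.cutoff = cutoff
        self.bits_per_key = bits_per_key
        self.max_iterations = max_iterations
        self.max_indel_delta = max_indel_delta
        self.max_lookahead = max_lookahead
        self.max_corrections_per_window = max_corrections_per_window
        self.workers = workers

    def _config(self) -> CorrectorConfig:
        return CorrectorConfig(
            k=self.k,
            max_iterations=self.max_iterations,
            max_indel_delta=self.max_indel_delta,
            max_lookahead=self.max_lookahead,
            max_corrections_per_window=self.max_corrections_per_window,
        )

    def fit(self, X: Sequence, y=None) -> "HopoSpectrumCorrector":
        """Build the spectrum from reads (strings or :class:`Read`)."""
        seqs = [x.sequence if isinstance(x, Read) else str(x) for x in X]
        self.spectrum_ = SpectrumModel.from_reads(
            seqs,
            k=self.k,
            cutoff=self.cutoff,
            bits_per_key=self.bits_per_key,
            workers=self.workers,
        )
        self.histogram_ = self.spectrum_.histogram
        self.cutoff_ = self.spectrum_.cutoff
        self.n_khopos_ = len(self.spectrum_.counts)
        self.skipped_reads_ = self.spectrum_.counts.skipped_reads
        return self

    def transform(self, X: Sequence) -> list:
        """Correct reads; returns the same kind of objects it was given
        (strings in, strings out; Reads in, Reads out)."""
        corrected, _ = self.correct(X)
        if X and not isinstance(X[0], Read):
            return [r.sequence for r in corrected]
        return corrected

    def correct(self, X: Sequence) -> tuple[list[Read], list[CorrectionRecord]]:
        """Correct reads and also return the stage-tagged edit records."""
        check_is_fitted(self, "spectrum_")
        cfg = self._config()
        out, records = [], []
        for i, x in enumerate(X):
            read, recs = correct_read(_as_read(x, i), self.spectrum_, cfg)
            out.append(read)
            records.extend(recs)
        return out, records
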