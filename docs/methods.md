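# Methods

## Homopolymer-space model

A read is a sequence of maximal case-folded homopolymer runs; each run is
the pair (R, X) of length and base, packed into one byte as
`128·L + 5·R + B − 4` (B: A=0, C=1, G=2, T=3, N=4; L: lowercase flag).
The byte code is bijective over the 2·5·25 = 250 valid pairs and maps to
[1, 253]; byte 0 is reserved as a sentinel, bytes 126–128 are unused, and
runs longer than 25 bases are a hard encoding error (such reads are
reported and passed through uncorrected). A *k-hopo* is a window of k
consecutive pairs; its canonical form is the lexicographically smaller of
the window's byte string and that of its reverse complement (order
reversed, bases complemented, lengths and case kept), so both strands of a
locus count as one key. Mixed-case runs are normalised to the case of
their first base — soft-masking masks whole regions in practice, so this
is lossless on real data and documented as lossy otherwise.

In this representation a homopolymer over/under-call, and a substitution
that neither matches a neighbouring run's base nor splits a longer run,
each change exactly one pair. That is the error class the corrector
models; frame-changing events (run merges/splits) are outside it by
design.

## Spectrum construction

Counting is three-pass: (1) every canonical window streams through a
Bloom filter (bit array, crc32/adler32 double hashing; default 8 bits per
expected key, hash count ≈ 0.69 · bits/key); windows that test
already-present become candidates; (2) all occurrences of candidates are
re-counted exactly from scratch; (3) candidates with count 1 — precisely
the Bloom false positives plus nothing else — are pruned. The final table
is therefore exact for every sizing of the filter; the sizing only trades
memory against the number of throw-away candidates. Counts saturate at
65 535. Windows containing N are skipped and never trusted. With
`workers > 1`, keys are routed to per-worker partitions by a hash of the
canonical code and merged, so the result is identical to the serial one
by construction; this package makes the determinism contract explicit
rather than reproducing any particular threading architecture.

### Coverage cut-off

The multiplicity histogram of a healthy dataset is bimodal: an error mode
decaying from multiplicity 2 and a coverage mode near the sequencing
depth (in homopolymer space, roughly depth × (w − k + 1)/w for w runs per
read). The cut-off is the smallest multiplicity m ≥ 3 that is a local
minimum (h[m] ≤ h[m−1], h[m] < h[m+1]; plateaus resolve to their smallest
m), **qualified** by requiring at least 10% of the spectrum's mass at or
above m — a local dip with a negligible trusted side is tail noise, not
the valley between two modes. Histograms with no qualifying valley
(monotone, or low-coverage data whose modes have merged) fall back to
cut-off 2 with a warning recommending an explicit `--cutoff`; at 6×
coverage this fallback is the normal path. Trusted means multiplicity ≥
cut-off (so a k-hopo exactly at the valley is trusted). An optional
window-3 moving average can smooth desk-scale histograms; it is off by
default because the rule is defined on raw densities.

## Correction

Positions are trusted when covered by any trusted window; endpoints
(first/last run) are never corrected or evaluated, because a run at a
read boundary may be truncated by the read itself. Alternatives at a
position are R ± d for d ≤ 3 (within [1, 25]), plus, only for length-1
runs, substitutions to bases matching neither neighbour. Stages:

- **Two-sided** (default 2 passes): scan interior untrusted positions
  left to right; apply an alternative iff it is the *only* one making
  both the leftmost and the rightmost window covering the position
  trusted. The trust mask is recomputed after each applied change — a fix
  can validate neighbours and prevent cascading ambiguity.
- **One-sided**: from each trusted region (maximal trusted stretch of
  length ≥ k), walk outward one run at a time. At the boundary the
  immediate window (ending at the position when walking right, starting
  at it when walking left) must become trusted; among viable alternatives
  the ranking is (deepest run of consecutive trusted look-ahead windows,
  up to 2, clamped at read ends) → (largest immediate-window
  multiplicity) → (smallest |ΔR|) → (smallest byte code). Look-ahead is a
  preference rather than a hard filter: requiring all look-ahead windows
  trusted deadlocks on clustered errors. An orientation stops at the
  first position with no viable alternative or on reaching the next
  trusted region.
- **Voting**: for every still-untrusted window and every interior
  position/alternative in it, one vote is cast per untrusted window the
  alternative solidifies; a fix is applied only if it is unanimous
  (votes = number of untrusted windows covering the position) and
  strictly beats every competing alternative there. Unanimous fixes at
  positions sharing a window were never validated jointly and are all
  dropped.

**Correction cap.** At most 4 pairs of any k-window may end up changed.
Within a one-sided orientation an overflowing span has its corrections
rolled back and the orientation stops; in addition every stage checks the
candidate edit against the *stage-zero* read and refuses edits that would
push any window past the cap, so the bound holds for the final read
across all three stages combined, not merely within one orientation.

**Quality strings.** An extended run replicates its last quality symbol;
a shortened run drops its last symbols; substitutions leave quality
untouched. 454 quality within a run is monotone non-increasing, so the
run's right edge is the low-confidence end.

## Simulator

The generator emulates the pyrosequencing error profile: each true run of
length R is observed as `max(1, R + round(ε))`, `ε ~ N(0, σ₀ + σ₁·R)` —
the error rate grows with run length, as flow-intensity discrimination
degrades for long runs — followed by per-base substitutions at rate
`p_sub` which may merge or split runs. Defaults: 50 kb genome, GC 0.5,
6 000 reads of length N(250, 50) clipped at [50, genome], both strands
equiprobable, σ₀ = 0.1, σ₁ = 0.05, p_sub = 0.002. Under these settings a
250 bp read carries on average ≈1.3 run-length error bases and ≈0.5
substituted bases. Observed runs are clipped to [1, 25]: whole-run
dropouts and over-long runs fall outside the corrector's representable
edit space and are deliberately not simulated. Every injected difference
is logged as a replayable truth record (the truth TSV carries the
substituted base identities so that replay is exact); the error-free
reads are written alongside, since this package evaluates against
simulator truth rather than read mapping.

What the simulator does **not** emulate — real flowgram noise structure,
CAFIE effects, chimeras, amplicon bias, non-uniform genome composition,
true dropouts — bounds what passing tests show: they validate the
algorithmic machinery under the stated error model, not field performance
on arbitrary instruments.

## Evaluation

Truth, erroneous and corrected reads are aligned run-by-run. Run-length
errors preserve the frame, so the common case is an index-for-index match
(verified by comparing lengths and base sequences); otherwise a banded
global alignment in homopolymer space resolves the frames (match = same
base with cost |R₁ − R₂|, unit gap cost, mismatches disallowed so a
substitution resolves as a gap pair; band = length difference + 8). For
an interior truth run with lengths t (true), e (erroneous), c
(corrected), with 0 standing for an absent/other-base aligned run:

    TP += max(0, |e−t| − |c−t|)   FP += max(0, |c−t| − |e−t|)
    FN += min(|e−t|, |c−t|)       TN += min(t, e, c)

Substitution records are scored one erroneous base each: restored run →
TP, otherwise FN; TN for a substitution-carrying run is
min(t, e, c) − (records in the run), floored at 0 — a convention that
slightly undercounts correct bases in frame-changed runs, with negligible
effect at the TN magnitudes involved. Terminal runs (and truth runs whose
aligned partner is terminal) are excluded, mirroring the corrector.
Metrics on the 0–100 scale: recall TP/(TP+FN), specificity TN/(FP+TN),
gain (TP−FP)/(TP+FN), precision TP/(TP+FP), F-score the harmonic mean of
precision and recall; zero denominators are flagged undefined rather than
raising. Dataset-level metrics are computed from summed counts, never by
averaging per-read metrics.

## Problem sizes and reproducibility

The shipped test suite and `scripts/acceptance.py` exercise the system at
desk scale: 5 kb genomes for exact-oracle comparisons (exhaustive
counting, brute-force correction) and a 50 kb genome at 30× and 6× for
the end-to-end runs — sizes at which exhaustive independent oracles are
feasible and a full pipeline run takes well under a minute. All
randomness flows from a single integer seed through
`numpy.random.default_rng`; identical seeds reproduce identical datasets,
spectra and corrections, and results are invariant to read order and to
the `workers` setting.

## Known limitations

- Frame-changing substitutions (inside runs of length > 1, or matching a
  neighbouring base) are not correctable by construction; they dominate
  the residual false negatives in the end-to-end runs.
- Whole-run deletions are neither simulated nor offered as alternatives.
- The counting stage holds the candidate table in memory; genome-scale
  datasets would need disk-backed counting, which is out of scope.
- IUPAC ambiguity codes other than N are rejected at encoding.
- The cut-off estimator assumes a histogram that is either usefully
  bimodal or recognisably not; pathological shapes should use an explicit
  cut-off.
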