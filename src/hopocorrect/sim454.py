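"""Synthetic 454-style datasets with exact ground truth.

Pyrosequencing infers homopolymer run lengths from flow light intensities,
so its dominant errors are run-length over/under-calls whose rate grows
with run length; substitutions are rare.  The generator emulates this:
reads of variable length are sampled from both strands of a random genome,
each run of true length R is observed as ``max(1, R + round(eps))`` with
``eps ~ Normal(0, sigma0 + sigma1*R)``, and each base is afterwards
substituted with a small probability.  Every injected difference is logged
as a replayable :class:`TruthRecord`.

Observed run lengths are clipped to [1, 25]: whole-run dropouts (and runs
beyond the one-byte code) are outside the corrector's representable error
space, a documented simplification relative to real flow-space dropouts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .corrector import Read
from .hopo_codec import MAX_RUN, RUN_LEN, encode_read

ERR_RUN_DELTA = "run_delta"
ERR_SUBSTITUTION = "substitution"

#: Shortest read worth simulating (in bases); Normal length draws are
#: clipped here so every read can hold at least a few k-hopo windows.
MIN_READ_LENGTH = 50


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate a desk-scale 454 run: a 50 kb genome at 30x coverage
    of 250 bp (+/- 50) reads, run-length noise sigma0 + sigma1*R and a
    0.2% substitution rate.
    """

    genome_length: int = 50_000
    gc_fraction: float = 0.5
    n_reads: int = 6_000
    mean_read_length: float = 250.0
    sd_read_length: float = 50.0
    sigma0: float = 0.1
    sigma1: float = 0.05
    p_sub: float = 0.002
    seed: int = 0

    def __post_init__(self):
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")
        if not 0.0 <= self.p_sub <= 1.0:
            raise ValueError("p_sub must lie in [0, 1]")
        if self.sigma0 < 0 or self.sigma1 < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass
class TruthRecord:
    """One injected error, replayable against the error-free read.

    ``hopo_index`` refers to the error-free read's homopolymer frame
    (which run-length errors preserve).  For substitutions ``base_offset``
    is the 0-based position in the erroneous read (run-length errors are
    applied first and substitutions do not shift coordinates); for
    run-length errors it is the run's start in the error-free read.
    """

    read_id: str
    hopo_index: int
    true_len: int
    obs_len: int
    error_type: str
    base_offset: int
    true_base: str = ""
    obs_base: str = ""


@dataclass
class SampledRead:
    """An error-free read with its genomic provenance."""

    read: Read
    start: int
    strand: str  # "+" or "-"


@dataclass
class Dataset:
    genome: str
    clean_reads: list[SampledRead]
    err_reads: list[Read]
    truth: list[TruthRecord]


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def generate_genome(length: int, gc_fraction: float, seed) -> str:
    """Random genome with the requested GC content, reproducible by seed."""
    if length <= 0:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    arr = rng.choice(
        np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=[at, gc, gc, at]
    )
    return arr.tobytes().decode("ascii")


def sample_reads(genome: str, cfg: SimConfig, rng=None) -> list[SampledRead]:
    """Error-free reads: Normal(mean, sd) lengths clipped to
    [MIN_READ_LENGTH, genome length], uniform starts, equiprobable strands."""
    if cfg.mean_read_length >= len(genome):
        raise ValueError("mean_read_length must be below the genome length")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    out = []
    glen = len(genome)
    for i in range(cfg.n_reads):
        length = int(round(rng.normal(cfg.mean_read_length, cfg.sd_read_length)))
        length = max(MIN_READ_LENGTH, min(length, glen))
        start = int(rng.integers(0, glen - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        seq = genome[start : start + length]
        if strand == "-":
            seq = revcomp(seq)
        out.append(SampledRead(Read(f"read_{i:06d}", seq), start, strand))
    return out


def corrupt_read(read: Read, cfg: SimConfig, rng) -> tuple[Read, list[TruthRecord]]:
    """Apply the 454 error model to one error-free read.

    Run-length noise first (frame-preserving: observed length >= 1), then
    per-base substitutions on the perturbed read (these may merge or split
    runs when re-encoded downstream).  With all noise parameters zero the
    read comes back unchanged with no records.
    """
    h = encode_read(read.sequence)
    records: list[TruthRecord] = []
    chunks = []
    clean_off = 0
    for idx, v in enumerate(h.codes):
        r = RUN_LEN[v]
        base = read.sequence[clean_off]
        sigma = cfg.sigma0 + cfg.sigma1 * r
        obs = r
        if sigma > 0:
            obs = int(max(1, min(MAX_RUN, r + round(rng.normal(0.0, sigma)))))
        if obs != r:
            records.append(
                TruthRecord(
                    read.id, idx, r, obs, ERR_RUN_DELTA, clean_off, base, base
                )
            )
        chunks.append(base * obs)
        clean_off += r
    seq = list("".join(chunks))
    if cfg.p_sub > 0:
        hits = np.nonzero(rng.random(len(seq)) < cfg.p_sub)[0]
        # map erroneous-frame offsets back to the run (= clean hopo) index
        run_of = np.repeat(
            np.arange(len(h.codes)),
            [len(c) for c in chunks],
        )
        for pos in hits:
            pos = int(pos)
            old = seq[pos]
            others = [b for b in "ACGT" if b != old]
            new = others[int(rng.integers(0, 3))]
            seq[pos] = new
            idx = int(run_of[pos])
            records.append(
                TruthRecord(
                    read.id,
                    idx,
                    RUN_LEN[h.codes[idx]],
                    len(chunks[idx]),
                    ERR_SUBSTITUTION,
                    pos,
                    old,
                    new,
                )
            )
    return Read(read.id, "".join(seq)), records


def replay_truth(clean_sequence: str, records: list[TruthRecord]) -> str:
    """Reconstruct the erroneous read from the clean read and its records."""
    h = encode_read(clean_sequence)
    runs = [RUN_LEN[v] for v in h.codes]
    bases = []
    off = 0
    for r in runs:
        bases.append(clean_sequence[off])
        off += r
    for rec in records:
        if rec.error_type == ERR_RUN_DELTA:
            runs[rec.hopo_index] = rec.obs_len
    seq = list("".join(b * r for b, r in zip(bases, runs)))
    for rec in records:
        if rec.error_type == ERR_SUBSTITUTION:
            if seq[rec.base_offset] != rec.true_base:
                raise AssertionError("truth replay mismatch")
            seq[rec.base_offset] = rec.obs_base
    return "".join(seq)


def generate_dataset(cfg: SimConfig) -> Dataset:
    """Genome + reads + errors + truth, fully determined by ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    genome = generate_genome(cfg.genome_length, cfg.gc_fraction, rng)
    sampled = sample_reads(genome, cfg, rng)
    err_reads = []
    truth: list[TruthRecord] = []
    for s in sampled:
        err, recs = corrupt_read(s.read, cfg, rng)
        err_reads.append(err)
        truth.extend(recs)
    return Dataset(genome, sampled, err_reads, truth)


TRUTH_COLUMNS = [
    "read_id",
    "hopo_index",
    "true_len",
    "obs_len",
    "error_type",
    "base_offset",
    "true_base",
    "obs_base",
]


def write_truth(records: list[TruthRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(TRUTH_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.read_id,
                    r.hopo_index,
                    r.true_len,
                    r.obs_len,
                    r.error_type,
                    r.base_offset,
                    r.true_base,
                    r.obs_base,
                ]
            )


def read_truth(path) -> list[TruthRecord]:
    out = []
    with open(path, newline="") as fh:
        rd = csv.DictReader(fh, delimiter="\t")
        for row in rd:
            out.append(
                TruthRecord(
                    row["read_id"],
                    int(row["hopo_index"]),
                    int(row["true_len"]),
                    int(row["obs_len"]),
                    row["error_type"],
                    int(row["base_offset"]),
                    row["true_base"],
                    row["obs_base"],
                )
            )
    return out


def write_dataset(ds: Dataset, out_prefix) -> dict[str, Path]:
    """Write reads.fastq (erroneous, placeholder qualities),
    reads_clean.fasta, genome.fasta and truth.tsv next to ``out_prefix``."""
    from . import io as hio

    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "reads": prefix.parent / f"{prefix.name}reads.fastq",
        "clean": prefix.parent / f"{prefix.name}reads_clean.fasta",
        "genome": prefix.parent / f"{prefix.name}genome.fasta",
        "truth": prefix.parent / f"{prefix.name}truth.tsv",
    }
    err_q = [
        Read(r.id, r.sequence, "I" * len(r.sequence)) for r in ds.err_reads
    ]
    hio.write_sequences(err_q, paths["reads"], "fastq")
    hio.write_sequences([s.read for s in ds.clean_reads], paths["clean"], "fasta")
    hio.write_sequences([Read("genome", ds.genome)], paths["genome"], "fasta")
    write_truth(ds.truth, paths["truth"])
    return paths
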