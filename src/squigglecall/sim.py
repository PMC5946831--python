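"""Squiggle simulation: synthetic raw nanopore signal with known ground truth.

The simulator emulates the statistical structure that segmentation-free
basecalling assumes: as DNA translocates through the pore, the measured
current is piecewise-near-constant, with one level per k-mer context, a
dwell of roughly 5-15 samples per base, additive Gaussian noise, and a
per-read baseline offset/scale (which whole-read z-score normalization
removes).  Every read carries exact per-base sample boundaries, so the
labeling, decoding and assembly stages can all be tested against known
truth without any real flowcell data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

BASES = "ACGT"
#: Fixed symbol order of the CTC output distribution.
ALPHABET = ("A", "C", "G", "T", "-")
BLANK = 4

__all__ = [
    "BASES",
    "ALPHABET",
    "BLANK",
    "PoreModel",
    "SimulatedRead",
    "generate_pore_model",
    "random_sequence",
    "simulate_read",
    "simulate_dataset",
    "ideal_probabilities",
    "OracleModel",
    "write_dataset",
]


@dataclass(frozen=True)
class PoreModel:
    """k-mer -> current-level table.

    ``levels`` maps each of the 4**k k-mers to a ``(mean_level, sd_level)``
    pair in arbitrary current units.  ``sd_level`` is strictly positive.
    """

    k: int
    levels: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.levels) != 4**self.k:
            raise ValueError(
                f"pore model for k={self.k} needs {4 ** self.k} k-mers, "
                f"got {len(self.levels)}"
            )
        for kmer, (_, sd) in self.levels.items():
            if sd <= 0:
                raise ValueError(f"sd_level must be > 0 (k-mer {kmer!r})")

    def mean(self, kmer: str) -> float:
        return self.levels[kmer][0]


@dataclass(frozen=True)
class SimulatedRead:
    """A simulated raw read with exact per-base signal boundaries.

    ``boundaries[i]`` is the 0-based half-open sample interval during which
    base ``sequence[i]`` occupies the pore.  Boundaries are contiguous,
    non-overlapping and cover the whole signal.
    """

    read_id: str
    sequence: str
    signal: np.ndarray
    boundaries: tuple[tuple[int, int], ...]
    seed: int

    def __post_init__(self) -> None:
        if len(self.boundaries) != len(self.sequence):
            raise ValueError("one boundary pair per base required")
        pos = 0
        for start, end in self.boundaries:
            if start != pos or end <= start:
                raise ValueError("boundaries must be contiguous with dwell >= 1")
            pos = end
        if pos != len(self.signal):
            raise ValueError("boundaries must cover the whole signal")


def generate_pore_model(k: int, seed: int, *, separation: float = 4.0) -> PoreModel:
    """Draw a synthetic pore model with well-separated k-mer levels.

    Levels are drawn uniformly on [0, separation * 4**k * sd] with
    sd_level = 1, then shuffled over k-mers, so that adjacent levels are
    ``separation`` standard deviations apart on average.  Deterministic for
    a given ``(k, seed)``.
    """
    if not 1 <= k <= 6:
        raise ValueError(f"k must be in [1, 6], got {k}")
    rng = np.random.default_rng(seed)
    n = 4**k
    sd = 1.0
    # evenly spaced levels with small jitter, randomly assigned to k-mers
    levels = separation * sd * (np.arange(n) + rng.uniform(-0.25, 0.25, size=n))
    rng.shuffle(levels)
    kmers = ("".join(p) for p in itertools.product(BASES, repeat=k))
    table = {kmer: (float(lvl), sd) for kmer, lvl in zip(kmers, levels)}
    return PoreModel(k=k, levels=table)


def random_sequence(length: int, seed: int) -> str:
    """Uniform i.i.d. random base string of the given length."""
    if length < 0:
        raise ValueError(f"length must be >= 0, got {length}")
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(BASES), size=length)) if length else ""


def _context(sequence: str, i: int, k: int) -> str:
    """k-mer centered on position i, with terminal-base edge padding."""
    half = k // 2
    padded = sequence[0] * half + sequence + sequence[-1] * (k - 1 - half)
    return padded[i : i + k]


def simulate_read(
    sequence: str,
    model: PoreModel,
    *,
    dwell_range: tuple[int, int] = (5, 15),
    noise_sd: float = 0.05,
    offset: float = 0.0,
    scale: float = 1.0,
    seed: int = 0,
    read_id: str = "sim",
) -> SimulatedRead:
    """Simulate the raw current trace for a base sequence.

    For each base, a dwell length is drawn uniform-integer on
    ``dwell_range`` (default 5-15 samples, matching typical translocation
    vs. sampling rates); that many samples are emitted at
    ``scale * (level(context) + offset)`` plus Gaussian noise of sd
    ``scale * noise_sd``.  The k-mer context is centered on the current
    base, with sequence ends padded by the terminal base.
    """
    if any(b not in BASES for b in sequence):
        raise ValueError("sequence must be over {A,C,G,T}")
    lo, hi = dwell_range
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid dwell_range {dwell_range}")
    rng = np.random.default_rng(seed)
    if not sequence:
        return SimulatedRead(read_id, "", np.zeros(0), (), seed)

    dwells = rng.integers(lo, hi + 1, size=len(sequence))
    total = int(dwells.sum())
    signal = np.empty(total, dtype=float)
    boundaries = []
    pos = 0
    for i, (base, dwell) in enumerate(zip(sequence, dwells)):
        level = model.mean(_context(sequence, i, model.k))
        plateau = scale * (level + offset)
        signal[pos : pos + dwell] = plateau
        boundaries.append((pos, pos + int(dwell)))
        pos += int(dwell)
    if noise_sd > 0:
        signal += rng.normal(0.0, scale * noise_sd, size=total)
    return SimulatedRead(read_id, sequence, signal, tuple(boundaries), seed)


def simulate_dataset(
    n_reads: int,
    *,
    read_length: tuple[int, int] = (200, 400),
    model: PoreModel | None = None,
    k: int = 5,
    dwell_range: tuple[int, int] = (5, 15),
    noise_sd: float = 0.05,
    offset_sd: float = 2.0,
    scale_range: tuple[float, float] = (0.8, 1.2),
    seed: int = 0,
) -> list[SimulatedRead]:
    """Simulate a dataset of reads with per-read offset/scale baselines.

    Each read's offset is drawn N(0, offset_sd) and its scale uniform on
    ``scale_range`` once per read, modeling the per-read calibration that
    whole-read normalization removes.  Read lengths are uniform-integer on
    ``read_length``.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    if model is None:
        model = generate_pore_model(k, seed)
    rng = np.random.default_rng(seed)
    reads = []
    for i in range(n_reads):
        length = int(rng.integers(read_length[0], read_length[1] + 1))
        seq_seed = int(rng.integers(0, 2**31 - 1))
        read_seed = int(rng.integers(0, 2**31 - 1))
        sequence = random_sequence(length, seq_seed)
        reads.append(
            simulate_read(
                sequence,
                model,
                dwell_range=dwell_range,
                noise_sd=noise_sd,
                offset=float(rng.normal(0.0, offset_sd)),
                scale=float(rng.uniform(*scale_range)),
                seed=read_seed,
                read_id=f"sim_{i:05d}",
            )
        )
    return reads


def ideal_probabilities(read: SimulatedRead) -> np.ndarray:
    """Ground-truth T x 5 probability matrix for a simulated read.

    Within each base's dwell every sample is assigned probability 1 for
    that base, except the final sample of the dwell, which is assigned to
    the blank symbol.  Greedy CTC collapse of the resulting argmax path
    therefore recovers the true sequence exactly, including homopolymer
    runs (each repeat is separated by a blank).
    """
    T = len(read.signal)
    probs = np.zeros((T, 5))
    for base, (start, end) in zip(read.sequence, read.boundaries):
        idx = BASES.index(base)
        probs[start : end - 1, idx] = 1.0
        probs[end - 1, BLANK] = 1.0
    return probs


class OracleModel:
    """A caller-compatible model that emits ground-truth probabilities.

    Used to exercise the slice -> decode -> assemble pipeline independently
    of any trained network: ``predict`` looks up the ideal probability
    matrix of the underlying simulated read at each window's offset.
    """

    def __init__(self, read: SimulatedRead):
        self._probs = ideal_probabilities(read)

    def predict(self, windows: np.ndarray, starts: Sequence[int]) -> np.ndarray:
        out = np.empty((len(starts), windows.shape[1], 5))
        for i, start in enumerate(starts):
            out[i] = self._probs[start : start + windows.shape[1]]
        return out


def write_dataset(
    reads: Iterable[SimulatedRead], out_dir: str | Path
) -> dict[str, Path]:
    """Write a simulated dataset to disk.

    Produces one plain-text signal file per read (see
    :mod:`squigglecall.signal_io`), a FASTA of true sequences and a
    tab-separated boundary file with columns
    ``read_id  base_index  start  end`` (0-based half-open).
    """
    from . import signal_io

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    signal_dir = out_dir / "signals"
    signal_dir.mkdir(exist_ok=True)
    fasta = out_dir / "truth.fasta"
    tsv = out_dir / "boundaries.tsv"
    with open(fasta, "w") as fa, open(tsv, "w") as bt:
        bt.write("read_id\tbase_index\tstart\tend\n")
        for read in reads:
            signal_io.write_signal_text(
                signal_io.RawRead(read.read_id, read.signal, "simulated"),
                signal_dir / f"{read.read_id}.signal",
            )
            fa.write(f">{read.read_id}\n{read.sequence}\n")
            for i, (start, end) in enumerate(read.boundaries):
                bt.write(f"{read.read_id}\t{i}\t{start}\t{end}\n")
    return {"signals": signal_dir, "fasta": fasta, "boundaries": tsv}


def read_boundaries(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """Read a boundary TSV back into per-read boundary lists."""
    table: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id"):
            raise ValueError(f"{path}: missing boundary header")
        for line in fh:
            read_id, idx, start, end = line.rstrip("\n").split("\t")
            table.setdefault(read_id, []).append((int(start), int(end)))
    return table
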