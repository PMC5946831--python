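"""Build uniform-length (signal segment, base label) training pairs.

Boundary-annotated reads (from the simulator, or from an external
resquiggling pipeline exported in the boundary TSV dialect) are cut into
windows of fixed length; each window's label is the ordered bases whose
dwell intervals lie fully inside the window.  Bases only partially covered
at the window edges are excluded — their signal evidence is truncated, so
teaching the network to emit them would be misleading.  After labeling,
the per-base boundary detail is discarded: training is segmentation-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .sim import BASES, SimulatedRead, read_boundaries

__all__ = ["LabeledSegment", "cut_segments", "build_training_set",
           "annotated_reads_from_files"]

DEFAULT_LENGTHS = (200, 400, 1000)


@dataclass(frozen=True)
class LabeledSegment:
    signal: np.ndarray
    label: str
    source_read: str
    offset: int

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("label must be non-empty")
        if len(self.label) >= len(self.signal):
            raise ValueError("label must be shorter than the segment")
        if any(b not in BASES for b in self.label):
            raise ValueError("label must be over {A,C,G,T}")


def cut_segments(read: SimulatedRead, length: int, stride: int | None = None,
                 *, normalize_signal: bool = True) -> list[LabeledSegment]:
    """Cut one boundary-annotated read into labeled fixed-length windows.

    Windows start at offsets 0, stride, 2*stride, ...; the default stride
    equals the window length (non-overlapping).  Windows whose label would
    be empty are dropped.  A read shorter than ``length`` yields an empty
    list.  With ``normalize_signal`` the *whole read* is z-scored before
    cutting, matching how signal is normalized at basecalling time.
    """
    if stride is None:
        stride = length
    if stride < 1:
        raise ValueError("stride must be >= 1")
    T = len(read.signal)
    if T < length:
        return []
    signal = np.asarray(read.signal, dtype=float)
    if normalize_signal:
        sd = signal.std()
        if sd < 1e-12:
            return []
        signal = (signal - signal.mean()) / sd
    starts = np.array([b[0] for b in read.boundaries])
    ends = np.array([b[1] for b in read.boundaries])
    segments = []
    for off in range(0, T - length + 1, stride):
        inside = np.nonzero((starts >= off) & (ends <= off + length))[0]
        if len(inside) == 0 or len(inside) >= length:
            continue
        label = "".join(read.sequence[i] for i in inside)
        segments.append(LabeledSegment(
            signal=signal[off:off + length].copy(),
            label=label,
            source_read=read.read_id,
            offset=off,
        ))
    return segments


def build_training_set(reads, lengths=DEFAULT_LENGTHS, *,
                       stride: int | None = None, seed: int = 0,
                       log=None) -> dict[int, list[LabeledSegment]]:
    """Cut a read collection into shuffled per-length segment pools.

    Returns ``{length: [LabeledSegment, ...]}``, one pool per configured
    length, each shuffled with the given seed.  Raises if every pool comes
    out empty (no trainable data).
    """
    reads = list(reads)
    if not reads:
        raise ValueError("no reads supplied")
    rng = np.random.default_rng(seed)
    pools: dict[int, list[LabeledSegment]] = {}
    for length in lengths:
        pool: list[LabeledSegment] = []
        for read in reads:
            pool.extend(cut_segments(read, length, stride))
        order = rng.permutation(len(pool))
        pools[length] = [pool[i] for i in order]
        if log is not None:
            log(f"length {length}: {len(pool)} segments")
    if all(len(p) == 0 for p in pools.values()):
        raise ValueError("all segment pools are empty")
    return pools


def annotated_reads_from_files(fasta: str | Path, boundaries_tsv: str | Path,
                               signal_dir: str | Path) -> list[SimulatedRead]:
    """Assemble boundary-annotated reads from on-disk dataset files.

    Reads the truth FASTA, boundary TSV and per-read signal files written
    by the simulator (or by an external labeling pipeline exporting the
    same dialect).
    """
    from Bio import SeqIO

    from . import signal_io

    bounds = read_boundaries(boundaries_tsv)
    signal_dir = Path(signal_dir)
    reads = []
    for rec in SeqIO.parse(str(fasta), "fasta"):
        if rec.id not in bounds:
            raise ValueError(f"read {rec.id} missing from boundary file")
        raw = signal_io.read_signal_text(signal_dir / f"{rec.id}.signal")
        reads.append(SimulatedRead(
            read_id=rec.id,
            sequence=str(rec.seq),
            signal=raw.signal,
            boundaries=tuple(bounds[rec.id]),
            seed=-1,
        ))
    return reads
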