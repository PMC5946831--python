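"""Raw-signal I/O and per-read normalization.

Real mode reads raw current traces from fast5 (HDF5) containers, both the
single-read layout (``/Raw/Reads/Read_*/Signal``) and the multi-read layout
(``/read_*/Raw/Signal``).  Test mode uses a two-line plain-text dialect:
line 1 is the read id, line 2 the whitespace-separated samples.  Signals
are used as stored (DAC integers or floats) — no pA calibration, since the
whole-read z-score normalization cancels any affine calibration.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import h5py
import numpy as np

__all__ = [
    "RawRead",
    "NormalizedRead",
    "Fast5FormatError",
    "SignalFormatError",
    "DegenerateSignalError",
    "read_fast5",
    "iter_fast5",
    "scan_signal_dir",
    "read_signal_text",
    "write_signal_text",
    "normalize",
    "write_fasta",
    "write_fastq",
    "phred_char",
]

#: FASTQ qualities use Sanger Phred+33; printable range caps scores at 93.
MAX_PHRED = 93


class Fast5FormatError(IOError):
    """Raised when a fast5 container lacks a readable raw-signal dataset."""


class SignalFormatError(IOError):
    """Raised for malformed plain-text signal files."""


class DegenerateSignalError(ValueError):
    """Raised when a read's signal has (near-)zero variance.

    Such reads carry no sequence information and cannot be z-scored.
    """


@dataclass(frozen=True)
class RawRead:
    read_id: str
    signal: np.ndarray
    source: str = "unknown"

    def __post_init__(self) -> None:
        object.__setattr__(self, "signal", np.asarray(self.signal, dtype=float))
        if self.signal.ndim != 1:
            raise ValueError("signal must be one-dimensional")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal must be finite-valued")


@dataclass(frozen=True)
class NormalizedRead:
    read_id: str
    signal: np.ndarray
    mean_used: float
    sd_used: float


def read_fast5(path: str | Path) -> RawRead:
    """Read the (first) raw read from a fast5 file."""
    for read in iter_fast5(path):
        return read
    raise Fast5FormatError(f"{path}: no raw reads found")


def iter_fast5(path: str | Path) -> Iterator[RawRead]:
    """Yield every raw read in a fast5 file (single- or multi-read layout)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        handle = h5py.File(path, "r")
    except OSError as exc:
        raise Fast5FormatError(f"{path}: not a readable HDF5 container ({exc})")
    with handle:
        found = False
        if "Raw/Reads" in handle:  # single-read layout
            for name, group in handle["Raw/Reads"].items():
                if "Signal" not in group:
                    raise Fast5FormatError(f"{path}: {name} has no Signal dataset")
                read_id = group.attrs.get("read_id", name)
                if isinstance(read_id, bytes):
                    read_id = read_id.decode()
                yield RawRead(str(read_id), group["Signal"][()], str(path))
                found = True
        for name in handle:  # multi-read layout
            if name.startswith("read_") and "Raw/Signal" in handle[name]:
                yield RawRead(name[5:], handle[name]["Raw/Signal"][()], str(path))
                found = True
        if not found:
            raise Fast5FormatError(f"{path}: no raw-signal dataset found")


def scan_signal_dir(directory: str | Path) -> list[RawRead]:
    """Load every ``.fast5`` / ``.signal`` read under a directory.

    Malformed files are skipped with a warning on stderr rather than
    aborting the batch.
    """
    import sys

    directory = Path(directory)
    reads: list[RawRead] = []
    for path in sorted(directory.iterdir()):
        try:
            if path.suffix == ".fast5":
                reads.extend(iter_fast5(path))
            elif path.suffix in {".signal", ".txt"}:
                reads.append(read_signal_text(path))
        except (Fast5FormatError, SignalFormatError) as exc:
            print(f"warning: skipping {path}: {exc}", file=sys.stderr)
    return reads


def read_signal_text(path: str | Path) -> RawRead:
    """Read the two-line plain-text signal dialect."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise SignalFormatError(f"{path}: empty file")
        data = fh.readline()
    tokens = data.split()
    try:
        signal = np.array([float(t) for t in tokens], dtype=float)
    except ValueError as exc:
        raise SignalFormatError(f"{path}: non-numeric token ({exc})")
    return RawRead(header.strip(), signal, str(path))


def write_signal_text(read: RawRead, path: str | Path) -> Path:
    """Write a read in the plain-text dialect (lossless for integers)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(read.read_id + "\n")
        fh.write(" ".join(format(s, ".17g") for s in read.signal) + "\n")
    return path


def normalize(read: RawRead) -> NormalizedRead:
    """Whole-read z-score normalization: s' = (s - mean(s)) / std(s).

    The standard deviation is the population sd (divide by T).  Degenerate
    reads (sd below 1e-12) are rejected — they carry no signal.
    """
    if len(read.signal) == 0:
        raise ValueError(f"read {read.read_id}: cannot normalize empty signal")
    mean = float(np.mean(read.signal))
    sd = float(np.std(read.signal))  # population sd
    if sd < 1e-12:
        raise DegenerateSignalError(
            f"read {read.read_id}: signal sd {sd:g} below 1e-12"
        )
    return NormalizedRead(read.read_id, (read.signal - mean) / sd, mean, sd)


def phred_char(q: float) -> str:
    """Sanger Phred+33 encoding of one quality score, capped at 93."""
    return chr(33 + min(MAX_PHRED, max(0, int(round(q)))))


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for read_id, seq in records:
            fh.write(f">{read_id}\n{seq}\n")
    return path


def write_fastq(
    records: list[tuple[str, str, list[float]]], path: str | Path
) -> Path:
    """Write (read_id, sequence, qualities) records as Sanger FASTQ."""
    path = Path(path)
    with open(path, "w") as fh:
        for read_id, seq, quals in records:
            if len(quals) != len(seq):
                raise ValueError(f"{read_id}: quality/sequence length mismatch")
            qline = "".join(phred_char(q) for q in quals)
            fh.write(f"@{read_id}\n{seq}\n+\n{qline}\n")
    return path
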