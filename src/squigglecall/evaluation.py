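"""Read-level basecalling accuracy metrics.

Rates follow the standard per-reference-base definitions: the deletion,
insertion and mismatch rates are the counts of deleted, inserted and
mismatched bases divided by the reference length, the identity rate is
matched bases over reference length, so that

    identity_rate = 100 - deletion_rate - mismatch_rate
    error_rate    = deletion_rate + insertion_rate + mismatch_rate

hold exactly for every alignment.  Alignments are global, with unit edit
costs (match 0); the traceback tie policy is fixed and documented: prefer
an aligned pair (match/mismatch) over an indel, and a deletion over an
insertion.  The architecture-comparison metric is the Levenshtein distance
between call and label divided by label length.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ErrorRates", "align_and_rates", "edit_distance",
           "normalized_edit_distance", "evaluate_run", "read_sequences"]


@dataclass(frozen=True)
class ErrorRates:
    deletion_rate: float
    insertion_rate: float
    mismatch_rate: float
    identity_rate: float
    error_rate: float
    n_ref_bases: int
    n_read_bases: int

    def __post_init__(self) -> None:
        if not np.isclose(self.identity_rate,
                          100.0 - self.deletion_rate - self.mismatch_rate,
                          atol=1e-9):
            raise ValueError("identity rate identity violated")
        if not np.isclose(self.error_rate,
                          self.deletion_rate + self.insertion_rate
                          + self.mismatch_rate, atol=1e-9):
            raise ValueError("error rate identity violated")
        for r in (self.deletion_rate, self.insertion_rate,
                  self.mismatch_rate, self.identity_rate):
            if r < -1e-12:
                raise ValueError("rates must be >= 0")


def _distance_matrix(read: str, ref: str) -> np.ndarray:
    """Full (len(read)+1) x (len(ref)+1) unit-cost edit DP matrix.

    Row updates are vectorized; the in-row left-to-right dependency of the
    insertion term is resolved with a prefix-minimum scan:
    row[j] = min_{k<=j} cand[k] + (j - k).
    """
    m, n = len(read), len(ref)
    ref_arr = np.frombuffer(ref.encode(), dtype=np.uint8)
    read_arr = np.frombuffer(read.encode(), dtype=np.uint8)
    D = np.empty((m + 1, n + 1), dtype=np.int64)
    D[0] = np.arange(n + 1)
    js = np.arange(n + 1)
    for i in range(1, m + 1):
        sub = D[i - 1, :-1] + (read_arr[i - 1] != ref_arr)
        up = D[i - 1, 1:] + 1
        cand = np.empty(n + 1, dtype=np.int64)
        cand[0] = i
        cand[1:] = np.minimum(sub, up)
        D[i] = np.minimum.accumulate(cand - js) + js
    return D


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (unit costs)."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return int(_distance_matrix(a, b)[len(a), len(b)])


def normalized_edit_distance(read: str, label: str) -> float:
    """Levenshtein distance divided by label length."""
    if not label:
        raise ValueError("label must be non-empty")
    return edit_distance(read, label) / len(label)


def align_and_rates(read: str, reference: str) -> ErrorRates:
    """Globally align a call to its reference and compute error rates.

    Counts come from the minimum-edit-cost traceback with the fixed tie
    policy (diagonal > deletion > insertion).  An empty read is 100%
    deletion.
    """
    if not reference:
        raise ValueError("reference must be non-empty")
    n_ref, n_read = len(reference), len(read)
    if not read:
        return ErrorRates(100.0, 0.0, 0.0, 0.0, 100.0, n_ref, 0)

    D = _distance_matrix(read, reference)
    matches = mismatches = deletions = insertions = 0
    i, j = n_read, n_ref
    while i > 0 or j > 0:
        if i > 0 and j > 0 and D[i, j] == D[i - 1, j - 1] + (
                read[i - 1] != reference[j - 1]):
            if read[i - 1] == reference[j - 1]:
                matches += 1
            else:
                mismatches += 1
            i -= 1
            j -= 1
        elif j > 0 and D[i, j] == D[i, j - 1] + 1:  # ref base unaligned
            deletions += 1
            j -= 1
        else:  # read base unaligned
            insertions += 1
            i -= 1

    scale = 100.0 / n_ref
    del_rate = deletions * scale
    ins_rate = insertions * scale
    mm_rate = mismatches * scale
    return ErrorRates(
        deletion_rate=del_rate,
        insertion_rate=ins_rate,
        mismatch_rate=mm_rate,
        identity_rate=100.0 - del_rate - mm_rate,
        error_rate=del_rate + ins_rate + mm_rate,
        n_ref_bases=n_ref,
        n_read_bases=n_read,
    )


def read_sequences(path: str | Path) -> dict[str, str]:
    """Read a FASTA or FASTQ file into {read_id: sequence}."""
    from Bio import SeqIO

    path = Path(path)
    fmt = "fastq" if path.suffix in {".fastq", ".fq"} else "fasta"
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), fmt)}


def evaluate_run(calls: str | Path | dict[str, str],
                 truths: str | Path | dict[str, str]) -> pd.DataFrame:
    """Per-read and aggregate error rates for a basecalling run.

    ``calls``/``truths`` are FASTA/FASTQ paths or id->sequence mappings
    with matching read identifiers.  Returns a DataFrame with one row per
    read plus an ``aggregate`` row whose rates are the reference-length-
    weighted means.
    """
    if not isinstance(calls, dict):
        calls = read_sequences(calls)
    if not isinstance(truths, dict):
        truths = read_sequences(truths)
    missing = sorted(set(truths) - set(calls))
    if missing:
        raise ValueError(f"reads missing from calls: {', '.join(missing)}")

    rows = []
    for read_id in truths:
        rates = align_and_rates(calls[read_id], truths[read_id])
        rows.append({"read_id": read_id, **rates.__dict__})
    table = pd.DataFrame(rows)
    weights = table["n_ref_bases"] / table["n_ref_bases"].sum()
    agg = {"read_id": "aggregate",
           "n_ref_bases": int(table["n_ref_bases"].sum()),
           "n_read_bases": int(table["n_read_bases"].sum())}
    for col in ("deletion_rate", "insertion_rate", "mismatch_rate",
                "identity_rate", "error_rate"):
        agg[col] = float((table[col] * weights).sum())
    return pd.concat([table, pd.DataFrame([agg])], ignore_index=True)


def write_report(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path
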