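"""Whole-read basecalling: slice, decode in batches, reassemble.

A 300-sample window slides over the normalized signal in steps of 30
(10% of the window), each window is decoded into a short "slice" of
roughly 10-20 bases, and overlapping slice calls are merged left-to-right
into one consensus sequence by suffix-prefix alignment of adjacent calls.
Because successive windows overlap by 90%, neighboring slices share most
of their bases, and the reassembly only has to find the maximum overlap
between each adjacent pair.  Windows are decoded in batches (default
1,100 windows per batch) so the forward pass can be parallelized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .decoder import DecodedCall, beam_search_decode, greedy_decode
from .signal_io import NormalizedRead

__all__ = ["SliceCall", "AssembledRead", "SignalWindow", "slice_signal",
           "call_read", "assemble_slices", "Assembler"]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 300
DEFAULT_STEP = 30
DEFAULT_BATCH = 1100


@dataclass(frozen=True)
class SignalWindow:
    start: int
    signal: np.ndarray


@dataclass(frozen=True)
class SliceCall:
    window_start: int
    window_length: int
    call: DecodedCall

    def __post_init__(self) -> None:
        if len(self.call.sequence) > self.window_length:
            raise ValueError("slice call longer than its window")


@dataclass(frozen=True)
class AssembledRead:
    read_id: str
    sequence: str
    qualities: tuple[float, ...]
    n_slices: int

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError("one quality per base required")


def slice_signal(signal: np.ndarray, window: int = DEFAULT_WINDOW,
                 step: int = DEFAULT_STEP) -> list[SignalWindow]:
    """Cut a signal into sliding windows at offsets 0, step, 2*step, ...

    A final window ending exactly at the signal end is appended when the
    last regular window falls short, so every sample is covered.  Signals
    shorter than the window yield a single whole-signal window.
    """
    signal = np.asarray(signal, dtype=float)
    if step < 1 or window < step:
        raise ValueError("need window >= step >= 1")
    T = len(signal)
    if T < 1:
        raise ValueError("empty signal")
    if T <= window:
        return [SignalWindow(0, signal.copy())]
    offsets = list(range(0, T - window + 1, step))
    if offsets[-1] + window < T:
        offsets.append(T - window)  # flush window against the signal end
    return [SignalWindow(off, signal[off:off + window].copy())
            for off in offsets]


def call_read(read: NormalizedRead, model, *, decoder: str = "beam",
              beam_width: int = 50, window: int = DEFAULT_WINDOW,
              step: int = DEFAULT_STEP,
              batch_size: int = DEFAULT_BATCH) -> AssembledRead:
    """Basecall one normalized read end to end.

    ``model`` is anything with ``predict(windows, starts) -> (B, L, 5)``
    probability matrices — a trained network, or a simulator oracle in
    tests.  Windows are decoded in batches of ``batch_size`` and the slice
    calls merged by :func:`assemble_slices`.
    """
    if decoder not in {"greedy", "beam"}:
        raise ValueError(f"unknown decoder {decoder!r}")
    if model is None:
        raise ValueError("no model loaded")
    windows = slice_signal(read.signal, window, step)
    slices: list[SliceCall] = []
    for lo in range(0, len(windows), batch_size):
        batch = windows[lo:lo + batch_size]
        stack = np.stack([w.signal for w in batch])
        starts = [w.start for w in batch]
        probs = model.predict(stack, starts)
        for w, p in zip(batch, probs):
            call = (greedy_decode(p) if decoder == "greedy"
                    else beam_search_decode(p, beam_width))
            slices.append(SliceCall(w.start, len(w.signal), call))
    return assemble_slices(slices, read_id=read.read_id)


class Assembler:
    """Incremental overlap-consensus assembly of ordered slice calls.

    Slices are merged left-to-right as they arrive; only the tail of the
    consensus (up to one window's worth of bases) can still change, so the
    prefix is stable and could be streamed out.  Adjacent calls are merged
    by a suffix-prefix alignment: the new slice's prefix is aligned
    against the consensus tail, and on disagreement the base with the
    higher quality wins (ties keep the earlier slice's base).  If no
    acceptable overlap is found the calls are concatenated with a warning.
    """

    def __init__(self, read_id: str = "read", band: int = 10,
                 min_overlap_score: int = 2):
        self.read_id = read_id
        self.band = band
        self.min_overlap_score = min_overlap_score
        self._seq: list[str] = []
        self._qual: list[float] = []
        self._n = 0
        self._last_start = -1
        self._bases_per_sample: list[float] = []
        self._last_window: tuple[int, int] | None = None

    def add(self, sl: SliceCall) -> None:
        if sl.window_start < self._last_start:
            raise ValueError("slices must arrive ordered by window_start")
        self._last_start = sl.window_start
        self._n += 1
        seq, qual = sl.call.sequence, list(sl.call.per_base_quality)
        if not seq:
            return  # empty slice calls are skipped
        if sl.window_length > 0:
            self._bases_per_sample.append(len(seq) / sl.window_length)
        if not self._seq:
            self._seq, self._qual = list(seq), qual
            self._last_window = (sl.window_start, sl.window_length)
            return
        expected = self._expected_overlap(sl)
        self._merge(seq, qual, expected)
        self._last_window = (sl.window_start, sl.window_length)

    def _expected_overlap(self, sl: SliceCall) -> int:
        """Expected overlapping base count from window geometry."""
        if self._last_window is None:
            return 0
        prev_start, prev_len = self._last_window
        overlap_samples = max(0, prev_start + prev_len - sl.window_start)
        rate = float(np.mean(self._bases_per_sample)) if self._bases_per_sample else 0.05
        return int(round(overlap_samples * rate))

    def _merge(self, seq: str, qual: list[float], expected: int) -> None:
        tail_len = min(len(self._seq), expected + self.band)
        tail = "".join(self._seq[-tail_len:]) if tail_len else ""
        i_start, j_end, score, ops = _best_overlap(tail, seq)
        if score < self.min_overlap_score or j_end == 0:
            logger.warning("%s: no overlap found for slice; concatenating",
                           self.read_id)
            self._seq.extend(seq)
            self._qual.extend(qual)
            return
        # keep everything before the aligned overlap, then rebuild the
        # overlapped region as a consensus
        base_idx = len(self._seq) - tail_len
        new_seq = self._seq[:base_idx + i_start]
        new_qual = self._qual[:base_idx + i_start]
        ti = i_start  # index into tail (old bases)
        si = 0  # index into seq (new bases)
        for op in ops:
            if op == "M":
                old_b, old_q = tail[ti], self._qual[base_idx + ti]
                new_b, new_q = seq[si], qual[si]
                if old_b == new_b:
                    new_seq.append(old_b)
                    new_qual.append(max(old_q, new_q))
                elif new_q > old_q:
                    new_seq.append(new_b)
                    new_qual.append(new_q)
                else:  # tie keeps the earlier slice's base
                    new_seq.append(old_b)
                    new_qual.append(old_q)
                ti += 1
                si += 1
            elif op == "D":  # base present only in the old consensus
                new_seq.append(tail[ti])
                new_qual.append(self._qual[base_idx + ti])
                ti += 1
            else:  # "I": base present only in the new slice
                new_seq.append(seq[si])
                new_qual.append(qual[si])
                si += 1
        # remaining old tail beyond the aligned suffix cannot happen
        # (alignment consumes the whole tail suffix); append the rest of seq
        new_seq.extend(seq[si:])
        new_qual.extend(qual[si:])
        self._seq, self._qual = new_seq, new_qual

    def result(self) -> AssembledRead:
        return AssembledRead(self.read_id, "".join(self._seq),
                             tuple(self._qual), self._n)


def _best_overlap(tail: str, seq: str) -> tuple[int, int, int, list[str]]:
    """Best suffix(tail)-prefix(seq) alignment.

    Scores +1 match, -1 mismatch/gap; the aligned suffix of ``tail`` may
    start anywhere (free leading skip) and the aligned prefix of ``seq``
    may end anywhere.  Returns ``(i_start, j_end, score, ops)``: the
    alignment operations (M/D/I) cover ``tail[i_start:]`` against
    ``seq[:j_end]``.
    """
    m, n = len(tail), len(seq)
    if m == 0 or n == 0:
        return 0, 0, 0, []
    seq_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    S = np.zeros((m + 1, n + 1), dtype=np.int64)
    S[0, 1:] = -np.arange(1, n + 1)  # seq prefix aligned to nothing: gaps
    for i in range(1, m + 1):
        match = S[i - 1, :-1] + np.where(ord(tail[i - 1]) == seq_arr, 1, -1)
        up = S[i - 1, 1:] - 1
        cand = np.maximum(match, up)
        row = S[i]
        row[0] = 0  # free leading skip of tail
        for j in range(1, n + 1):
            row[j] = max(cand[j - 1], row[j - 1] - 1)
    j_best = int(np.argmax(S[m]))
    score = int(S[m, j_best])
    # traceback from (m, j_best); stops when the seq prefix is consumed
    # and the free-skip row is reached
    ops: list[str] = []
    i, j = m, j_best
    while j > 0 or (i > 0 and S[i, 0] != 0):
        if (i > 0 and j > 0
                and S[i, j] == S[i - 1, j - 1]
                + (1 if tail[i - 1] == seq[j - 1] else -1)):
            ops.append("M")
            i -= 1
            j -= 1
        elif i > 0 and j > 0 and S[i, j] == S[i - 1, j] - 1:
            ops.append("D")
            i -= 1
        elif j > 0:
            ops.append("I")
            j -= 1
        else:
            break
    ops.reverse()
    return i, j_best, score, ops


def assemble_slices(slices: Sequence[SliceCall],
                    read_id: str = "read") -> AssembledRead:
    """Merge ordered slice calls into one consensus read."""
    asm = Assembler(read_id)
    for sl in slices:
        asm.add(sl)
    return asm.result()
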