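"""CTC decoding: greedy collapse and prefix beam search, with qualities.

The network emits a T x 5 row-stochastic matrix over (A, C, G, T, blank).
The greedy decoder takes the per-timestep argmax path, collapses
consecutive repeats, then removes blanks (the path ``A A - - - A - - G -``
collapses to ``A - A - G -`` and reads out ``AAG``).  The beam-search
decoder maintains the W most probable *collapsed* prefixes, summing
probability mass over all paths that collapse to each prefix; greedy
decoding is exactly the beam-width-1 special case.

Per-base quality is qs = 10 * log10(P1 / P2), where P1 and P2 are the
largest and second-largest base probabilities at the timestep anchoring
that base: for greedy decoding, the first timestep of the base's argmax
run; for beam search, the timestep at which the best prefix first emitted
the base.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sim import ALPHABET, BASES, BLANK

__all__ = ["DecodedCall", "greedy_decode", "beam_search_decode",
           "quality_score", "write_prob_matrix", "read_prob_matrix"]

NEG_INF = -np.inf


@dataclass(frozen=True)
class DecodedCall:
    sequence: str
    per_base_quality: tuple[float, ...]
    decoder: str
    beam_width: int

    def __post_init__(self) -> None:
        if len(self.per_base_quality) != len(self.sequence):
            raise ValueError("one quality per emitted base required")
        if any(q < 0 for q in self.per_base_quality):
            raise ValueError("qualities must be >= 0")


def _check_probs(probs: np.ndarray) -> np.ndarray:
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != 5:
        raise ValueError("ProbMatrix must be T x 5")
    return probs


def quality_score(p1: float, p2: float) -> float:
    """qs = 10 * log10(P1 / P2) for the top-two base probabilities."""
    if p2 <= 0:
        raise ValueError("P2 must be > 0")
    if not p2 <= p1 <= 1:
        raise ValueError("need 0 < P2 <= P1 <= 1")
    return 10.0 * np.log10(p1 / p2)


def _timestep_quality(row: np.ndarray) -> float:
    """Quality from one probability row: top-two ratio, floored at 0.

    A zero second-best probability is floored at 1e-30 so perfectly
    confident rows get a large finite quality.
    """
    top = np.sort(row)[::-1]
    p1, p2 = float(top[0]), max(float(top[1]), 1e-30)
    if p1 <= 0:
        return 0.0
    return max(0.0, quality_score(p1, min(p1, p2)))


def greedy_decode(probs: np.ndarray) -> DecodedCall:
    """Argmax path -> collapse consecutive repeats -> remove blanks.

    Argmax ties break toward the lowest symbol index.  An empty matrix
    decodes to the empty call.
    """
    probs = _check_probs(probs)
    path = probs.argmax(axis=1)  # np.argmax returns the first (lowest) maximum
    bases = []
    quals = []
    prev = -1
    for t, sym in enumerate(path):
        if sym != prev and sym != BLANK:
            bases.append(BASES[sym])
            quals.append(_timestep_quality(probs[t]))
        prev = sym
    return DecodedCall("".join(bases), tuple(quals), "greedy", 1)


def beam_search_decode(probs: np.ndarray, beam_width: int = 50) -> DecodedCall:
    """CTC prefix beam search over collapsed sequences.

    Each prefix tracks the log probability mass of all paths collapsing to
    it, split into blank-ending and nonblank-ending parts; extensions
    collapse and sum over repeated bases and over blank runs terminated by
    a non-blank.  Beams are pruned by total (summed) prefix mass, except
    that the prefix holding the best *single* path so far is always
    retained: this makes width 1 follow the per-timestep argmax path
    exactly (the greedy special case), while wider beams behave as
    standard total-mass prefix search and, once the width covers every
    prefix, the returned sequence — the one with the highest summed
    posterior — is the exact posterior argmax.  Ties break
    lexicographically.
    """
    probs = _check_probs(probs)
    if beam_width < 1:
        raise ValueError("beam_width must be >= 1")
    T = probs.shape[0]
    with np.errstate(divide="ignore"):
        logp = np.log(probs)

    # prefix -> [sum_blank, sum_nonblank, vit_blank, vit_nonblank, times]
    # sums accumulate with logaddexp, vit entries with max.
    beams: dict[tuple[int, ...], list] = {(): [0.0, NEG_INF, 0.0, NEG_INF, ()]}
    for t in range(T):
        nxt: dict[tuple[int, ...], list] = {}
        for prefix, (sb, snb, vb, vnb, times) in beams.items():
            total = np.logaddexp(sb, snb)
            vit = max(vb, vnb)
            p_blank = logp[t, BLANK]
            # blank extension: prefix unchanged, mass moves to blank-ending
            _merge(nxt, prefix, p_blank + total, NEG_INF,
                   p_blank + vit, NEG_INF, times)
            last = prefix[-1] if prefix else -1
            for sym in range(4):
                p_sym = logp[t, sym]
                if sym == last:
                    # same base: extends the run (prefix unchanged) ...
                    _merge(nxt, prefix, NEG_INF, p_sym + snb,
                           NEG_INF, p_sym + vnb, times)
                    # ... or starts a new base after an intervening blank
                    _merge(nxt, prefix + (sym,), NEG_INF, p_sym + sb,
                           NEG_INF, p_sym + vb, times + (t,))
                else:
                    _merge(nxt, prefix + (sym,), NEG_INF, p_sym + total,
                           NEG_INF, p_sym + vit, times + (t,))
        if len(nxt) > beam_width:
            ranked = sorted(
                nxt.items(),
                key=lambda kv: (-np.logaddexp(kv[1][0], kv[1][1]), kv[0]))
            kept = ranked[:beam_width]
            viterbi_best = min(
                nxt.items(),
                key=lambda kv: (-max(kv[1][2], kv[1][3]), kv[0]))
            if viterbi_best[0] not in (k for k, _ in kept):
                kept[-1] = viterbi_best
            beams = dict(kept)
        else:
            beams = nxt

    best_prefix, entry = min(
        beams.items(),
        key=lambda kv: (-np.logaddexp(kv[1][0], kv[1][1]), kv[0]))
    sequence = "".join(BASES[i] for i in best_prefix)
    quals = tuple(_timestep_quality(probs[t]) for t in entry[4])
    return DecodedCall(sequence, quals, "beam", beam_width)


def _merge(table: dict, prefix: tuple[int, ...], sb: float, snb: float,
           vb: float, vnb: float, times: tuple[int, ...]) -> None:
    entry = table.get(prefix)
    if entry is None:
        table[prefix] = [sb, snb, vb, vnb, times]
        return
    # keep the emission anchor of the route with the better single path
    if max(vb, vnb) > max(entry[2], entry[3]):
        entry[4] = times
    entry[0] = np.logaddexp(entry[0], sb)
    entry[1] = np.logaddexp(entry[1], snb)
    entry[2] = max(entry[2], vb)
    entry[3] = max(entry[3], vnb)


def sequence_posterior(probs: np.ndarray, sequence: str) -> float:
    """Total probability mass of all paths collapsing to ``sequence``.

    Exact CTC marginal (forward algorithm); useful for checking that beam
    search returns the maximum-posterior collapsed sequence.
    """
    from .network import ctc_loss

    try:
        return float(np.exp(-ctc_loss(probs, sequence)))
    except ValueError:
        return 0.0


def write_prob_matrix(probs: np.ndarray, path) -> None:
    """Serialize a ProbMatrix as tab-separated T x 5 with a header row."""
    probs = _check_probs(probs)
    with open(path, "w") as fh:
        fh.write("\t".join(ALPHABET) + "\n")
        for row in probs:
            fh.write("\t".join(format(p, ".17g") for p in row) + "\n")


def read_prob_matrix(path) -> np.ndarray:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != ALPHABET:
            raise ValueError(f"{path}: bad ProbMatrix header {header}")
        rows = [[float(tok) for tok in line.split("\t")] for line in fh if line.strip()]
    return np.asarray(rows, dtype=float).reshape(-1, 5)
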