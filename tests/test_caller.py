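"""Sliding-window slicing and overlap-consensus reassembly."""

import numpy as np
import pytest

from squigglecall import sim
from squigglecall.caller import (AssembledRead, Assembler, SliceCall,
                                 assemble_slices, call_read, slice_signal)
from squigglecall.decoder import DecodedCall
from squigglecall.evaluation import align_and_rates
from squigglecall.signal_io import NormalizedRead


def make_slice(start: int, seq: str, window_length: int = 300,
               quality: float = 20.0, qualities=None) -> SliceCall:
    quals = tuple(qualities) if qualities is not None else (quality,) * len(seq)
    return SliceCall(start, window_length,
                     DecodedCall(seq, quals, "greedy", 1))


class TestSliceSignal:
    def test_exact_window_gives_single_slice(self):
        wins = slice_signal(np.zeros(300), 300, 30)
        assert len(wins) == 1 and wins[0].start == 0

    def test_offsets_for_360_samples(self):
        wins = slice_signal(np.zeros(360), 300, 30)
        assert [w.start for w in wins] == [0, 30, 60]

    def test_short_signal_single_whole_window(self):
        wins = slice_signal(np.zeros(200), 300, 30)
        assert len(wins) == 1 and len(wins[0].signal) == 200

    def test_final_flush_window_covers_tail(self):
        wins = slice_signal(np.zeros(325), 300, 30)
        assert [w.start for w in wins] == [0, 25]
        assert wins[-1].start + len(wins[-1].signal) == 325

    def test_step_larger_than_window_rejected(self):
        with pytest.raises(ValueError):
            slice_signal(np.zeros(100), 30, 40)

    def test_empty_signal_rejected(self):
        with pytest.raises(ValueError):
            slice_signal(np.zeros(0))


class TestAssemble:
    def test_single_slice_identity(self):
        asm = assemble_slices([make_slice(0, "ACGT")])
        assert asm.sequence == "ACGT" and asm.n_slices == 1

    def test_hand_constructed_exact_overlap(self):
        # windows overlap by 250 samples; true overlap "GTACG"
        slices = [make_slice(0, "ACGTACG"), make_slice(50, "GTACGTT")]
        asm = assemble_slices(slices)
        assert asm.sequence == "ACGTACGTT"

    def test_twenty_error_free_slices_reconstruct_sixty_bases(self):
        truth = sim.random_sequence(60, 17)
        # 90% overlap: each slice shows 15 bases, advancing 2-3 per step
        slices = []
        for i, start in enumerate(range(0, 46, 3)):
            piece = truth[start:start + 15]
            slices.append(make_slice(i * 30, piece))
        assert len(slices) >= 16
        asm = assemble_slices(slices)
        assert asm.sequence == truth

    def test_empty_slices_skipped(self):
        slices = [make_slice(0, "ACGT"), make_slice(30, ""),
                  make_slice(60, "GTAA")]
        asm = assemble_slices(slices)
        assert asm.sequence.startswith("ACGT")
        assert asm.n_slices == 3

    def test_all_empty_slices_give_empty_read(self):
        asm = assemble_slices([make_slice(s, "") for s in (0, 30, 60)])
        assert asm.sequence == "" and asm.qualities == ()

    def test_unordered_slices_rejected(self):
        asm = Assembler()
        asm.add(make_slice(30, "ACG"))
        with pytest.raises(ValueError):
            asm.add(make_slice(0, "ACG"))

    def test_disagreement_resolved_by_quality(self):
        # overlap region differs at one base; the later, higher-quality
        # slice should win
        a = make_slice(0, "ACGTAC", qualities=[30, 30, 30, 30, 5, 30])
        b = make_slice(10, "CGTGCGT", qualities=[30, 30, 30, 40, 30, 30, 30])
        asm = assemble_slices([a, b])
        assert asm.sequence == "ACGTGCGT"

    def test_error_free_reconstruction_property(self):
        rng = np.random.default_rng(23)
        for trial in range(20):
            L = int(rng.integers(30, 501))
            truth = sim.random_sequence(L, int(rng.integers(0, 2**31)))
            shown = max(6, int(rng.integers(8, 20)))   # bases per slice
            advance = max(1, shown // 3)               # >= 50% overlap
            starts = list(range(0, max(1, L - shown + 1), advance))
            if starts[-1] + shown < L:
                starts.append(L - shown)
            slices = [make_slice(i * 30, truth[s:s + shown])
                      for i, s in enumerate(starts)]
            asm = assemble_slices(slices)
            assert asm.sequence == truth, f"trial {trial}, L={L}"

    def test_substitution_robustness(self, k5_model):
        """<=5% substitutions in slice calls still give >=95% identity."""
        rng = np.random.default_rng(29)
        identities = []
        for trial in range(100):
            L = int(rng.integers(60, 200))
            truth = sim.random_sequence(L, int(rng.integers(0, 2**31)))
            shown, advance = 15, 3
            slices = []
            starts = list(range(0, max(1, L - shown + 1), advance))
            if starts[-1] + shown < L:
                starts.append(L - shown)
            for i, start in enumerate(starts):
                piece = list(truth[start:start + shown])
                for j in range(len(piece)):
                    if rng.random() < 0.05:
                        piece[j] = "ACGT"[int(rng.integers(0, 4))]
                slices.append(make_slice(i * 30, "".join(piece)))
            asm = assemble_slices(slices)
            identities.append(align_and_rates(asm.sequence, truth).identity_rate)
        assert float(np.mean(identities)) >= 95.0

    def test_junction_slice_joins_disjoint_runs(self):
        """Assembling two halves that share a junction slice equals the
        jointly assembled sequence."""
        truth = sim.random_sequence(40, 31)
        shown, advance = 10, 2
        starts = list(range(0, 31, advance))
        slices = [make_slice(i * 30, truth[s:s + shown])
                  for i, s in enumerate(starts)]
        joint = assemble_slices(slices).sequence
        mid = len(slices) // 2
        left = assemble_slices(slices[:mid + 1]).sequence
        right_sl = [make_slice(s.window_start - slices[mid].window_start,
                               s.call.sequence) for s in slices[mid:]]
        right = assemble_slices(right_sl).sequence
        rejoined = assemble_slices(
            [make_slice(0, left), make_slice(30, right)]).sequence
        assert rejoined == joint


class TestCallRead:
    def test_oracle_round_trip_exact(self, k5_model):
        seq = sim.random_sequence(150, 41)
        read = sim.simulate_read(seq, k5_model, noise_sd=0.0, seed=42,
                                 read_id="rt")
        asm = call_read(NormalizedRead("rt", read.signal, 0.0, 1.0),
                        sim.OracleModel(read), decoder="greedy")
        assert asm.sequence == seq
        assert len(asm.qualities) == len(seq)

    def test_empty_slices_propagate_to_empty_read(self):
        class BlankModel:
            def predict(self, windows, starts):
                out = np.zeros((windows.shape[0], windows.shape[1], 5))
                out[:, :, 4] = 1.0
                return out

        asm = call_read(NormalizedRead("r", np.zeros(400) + np.arange(400),
                                       0.0, 1.0), BlankModel())
        assert asm.sequence == ""

    def test_unknown_decoder_rejected(self):
        with pytest.raises(ValueError):
            call_read(NormalizedRead("r", np.zeros(10), 0, 1), object(),
                      decoder="viterbi")

    def test_missing_model_rejected(self):
        with pytest.raises(ValueError):
            call_read(NormalizedRead("r", np.zeros(10), 0, 1), None)
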