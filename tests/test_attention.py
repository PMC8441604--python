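"""Pair construction, additive attention math, matcher training, highlights."""

import numpy as np
import pytest

from icdcoder.attention_explainer import (
    AttentionMap,
    AttentionPair,
    MatcherConfig,
    additive_attention,
    build_pair_dataset,
    extract_highlights,
    highlight_positions,
    pair_f1,
    train_matcher,
)
from icdcoder.text_pipeline import LabeledNote, LabelSpace, Vocabulary


def space_of(L):
    return LabelSpace({f"C{i}": f"sign{i} mark{i} findings" for i in range(L)})


class TestBuildPairDataset:
    def test_counts_for_one_note(self):
        space = space_of(50)
        note = LabeledNote("n", ["tok"], {"C1", "C2"})
        pairs = build_pair_dataset([note], space, cap=40, seed=0)
        positives = [p for p in pairs if p.label == 1]
        negatives = [p for p in pairs if p.label == 0]
        assert len(positives) == 2 and len(negatives) == 38

    @pytest.mark.parametrize(
        "n_gold, L, cap",
        [(1, 50, 40), (3, 50, 40), (5, 10, 40), (2, 30, 10), (1, 100, 40), (4, 5, 40)],
    )
    def test_pair_budget_law(self, n_gold, L, cap):
        space = space_of(L)
        gold = {f"C{i}" for i in range(n_gold)}
        note = LabeledNote("n", ["tok"], gold)
        pairs = build_pair_dataset([note], space, cap=cap, seed=1)
        n_pos = sum(p.label for p in pairs)
        n_neg = len(pairs) - n_pos
        assert n_pos == n_gold
        assert n_neg == min(cap - n_gold, L - n_gold)

    def test_exhaustion_below_cap(self):
        space = space_of(5)
        note = LabeledNote("n", ["tok"], {"C0"})
        pairs = build_pair_dataset([note], space, cap=40, seed=0)
        assert len(pairs) == 5  # 1 positive + all 4 non-gold codes

    def test_cap_below_gold_errors(self):
        space = space_of(10)
        note = LabeledNote("n", ["tok"], {"C0", "C1", "C2"})
        with pytest.raises(ValueError, match="cap"):
            build_pair_dataset([note], space, cap=2, seed=0)

    def test_deterministic(self):
        space = space_of(20)
        notes = [LabeledNote(str(i), ["tok"], {f"C{i % 5}"}) for i in range(10)]
        a = build_pair_dataset(notes, space, cap=8, seed=4)
        b = build_pair_dataset(notes, space, cap=8, seed=4)
        assert [(p.note.note_id, p.code, p.label) for p in a] == [
            (p.note.note_id, p.code, p.label) for p in b
        ]

    def test_labels_match_gold_membership(self):
        space = space_of(12)
        notes = [LabeledNote(str(i), ["tok"], {f"C{i}", f"C{i + 1}"}) for i in range(5)]
        for p in build_pair_dataset(notes, space, cap=10, seed=2):
            assert p.label == int(p.code in p.note.gold_codes)


class TestAdditiveAttention:
    def _params(self, H, Q, A, rng):
        return (
            rng.standard_normal((H, A)),
            rng.standard_normal((Q, A)),
            rng.standard_normal(A),
        )

    def test_identical_states_uniform_weights(self):
        rng = np.random.default_rng(0)
        w1, w2, v = self._params(4, 3, 5, rng)
        states = np.tile(rng.standard_normal(4), (6, 1))
        _, weights = additive_attention(states, rng.standard_normal(3), w1, w2, v)
        assert np.allclose(weights, 1.0 / 6, atol=1e-9)

    def test_weights_sum_to_one_random_inputs(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(1, 12))
            w1, w2, v = self._params(4, 3, 5, rng)
            states = rng.standard_normal((n, 4))
            ctx, weights = additive_attention(states, rng.standard_normal(3), w1, w2, v)
            assert np.isclose(weights.sum(), 1.0, atol=1e-9)
            assert np.all(weights >= 0)
            assert np.allclose(ctx, weights @ states)

    def test_dominant_score_dominates(self):
        # engineered so one position's score is 10 above the rest
        n, H = 5, 2
        w1 = np.array([[10.0], [0.0]])
        w2 = np.zeros((1, 1))
        v = np.array([10.0])
        states = np.zeros((n, H))
        states[2, 0] = 10.0  # tanh saturates to 1 -> score 10, others 0
        _, weights = additive_attention(states, np.zeros(1), w1, w2, v)
        assert weights[2] > 0.99

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            additive_attention(
                np.zeros((0, 3)), np.zeros(2), np.zeros((3, 4)), np.zeros((2, 4)),
                np.zeros(4),
            )


def tiny_matcher_setup():
    space = LabelSpace({"C0": "alpha beta findings", "C1": "gamma delta findings"})
    notes = [
        LabeledNote("p0", ["alpha", "beta", "filler1", "filler2"], {"C0"}),
        LabeledNote("p1", ["filler3", "gamma", "delta", "filler4"], {"C1"}),
        LabeledNote("p2", ["alpha", "filler2", "beta"], {"C0"}),
        LabeledNote("p3", ["gamma", "filler1", "delta"], {"C1"}),
        LabeledNote("p4", ["filler4", "alpha", "beta"], {"C0"}),
    ]
    vocab = Vocabulary(
        ["alpha", "beta", "gamma", "delta", "findings"]
        + [f"filler{i}" for i in range(1, 5)]
    )
    return space, notes, vocab


class TestTrainMatcher:
    def test_degenerate_labels_rejected(self):
        space, notes, vocab = tiny_matcher_setup()
        pairs = [AttentionPair(notes[0], "C0", ["alpha"], 1)]
        with pytest.raises(ValueError, match="degenerate labels"):
            train_matcher(pairs, vocab, space)

    def test_overfit_small_pair_set(self):
        space, notes, vocab = tiny_matcher_setup()
        pairs = build_pair_dataset(notes, space, cap=2, seed=0)
        cfg = MatcherConfig(embedding_dim=8, gru_hidden=8, attn_size=8, max_len=8,
                            def_max_len=4, epochs=200, learning_rate=1e-2,
                            batch_size=4, seed=0)
        matcher, log = train_matcher(pairs, vocab, space, cfg)
        assert pair_f1(matcher, pairs) == 1.0
        assert log[-1]["train_loss"] < log[0]["train_loss"]

    def test_seeded_reproducibility(self):
        space, notes, vocab = tiny_matcher_setup()
        pairs = build_pair_dataset(notes, space, cap=2, seed=0)
        cfg = MatcherConfig(embedding_dim=8, gru_hidden=8, attn_size=8, max_len=8,
                            def_max_len=4, epochs=5, seed=3)
        _, log_a = train_matcher(pairs, vocab, space, cfg)
        _, log_b = train_matcher(pairs, vocab, space, cfg)
        assert log_a == log_b


class TestHighlights:
    def test_uniform_weights_below_default_threshold(self):
        n = 8
        assert highlight_positions([1.0 / n] * n, 1.5 / n) == []

    def test_zero_threshold_highlights_everything(self):
        weights = [0.1, 0.5, 0.4]
        assert highlight_positions(weights, 0.0) == [0, 1, 2]

    def test_selected_weights_exceed_threshold(self):
        weights = [0.05, 0.6, 0.05, 0.3]
        assert highlight_positions(weights, 0.25) == [1, 3]

    def test_extract_highlights_contract(self, tmp_path):
        space, notes, vocab = tiny_matcher_setup()
        pairs = build_pair_dataset(notes, space, cap=2, seed=0)
        cfg = MatcherConfig(embedding_dim=8, gru_hidden=8, attn_size=8, max_len=8,
                            def_max_len=4, epochs=30, learning_rate=1e-2,
                            batch_size=4, seed=0)
        matcher, _ = train_matcher(pairs, vocab, space, cfg)
        amap, hl = extract_highlights(matcher, notes[0], "C0")
        assert len(amap.weights) == len(notes[0].tokens)
        assert np.isclose(amap.weights.sum(), 1.0, atol=1e-6)
        assert hl.threshold == pytest.approx(1.5 / len(notes[0].tokens))
        for pos in hl.positions:
            assert amap.weights[pos] > hl.threshold

        from icdcoder.attention_explainer import write_highlight_html, write_highlight_json

        write_highlight_json(amap, hl, tmp_path / "h.json")
        write_highlight_html(amap, hl, tmp_path / "h.html")
        assert (tmp_path / "h.json").exists() and (tmp_path / "h.html").exists()

    def test_unknown_code_rejected(self):
        space, notes, vocab = tiny_matcher_setup()
        pairs = build_pair_dataset(notes, space, cap=2, seed=0)
        cfg = MatcherConfig(embedding_dim=8, gru_hidden=8, attn_size=8, max_len=8,
                            def_max_len=4, epochs=1, seed=0)
        matcher, _ = train_matcher(pairs, vocab, space, cfg)
        with pytest.raises(KeyError):
            extract_highlights(matcher, notes[0], "C999")
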