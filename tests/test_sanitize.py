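"""The greedy publisher loop: loss accounting, stopping rule, termination,
local optimality, and publishing."""

from __future__ import annotations

import numpy as np
import pytest

from greedysanitize import (
    ConfusionCounts,
    Corpus,
    GameParams,
    GreedySanitizer,
    greedy_sanitize,
    publisher_loss,
    stopping_delta,
)

from conftest import make_separable_corpus


class TestLossAndDelta:
    @pytest.mark.parametrize("L, C, fn, fp, expected", [
        (1, 1, 0, 0, 0.0),
        (5, 1, 2, 6, 16.0),
        (1, 1, 3, 4, 7.0),
    ])
    def test_publisher_loss(self, L, C, fn, fp, expected):
        counts = ConfusionCounts(tp=0, fp=fp, tn=0, fn=fn)
        assert publisher_loss(counts, GameParams(L=L, C=C)) == expected

    @pytest.mark.parametrize("L, C, tp, fp, expected", [
        (1, 1, 0, 0, 0.0),    # empty prediction: stop
        (5, 1, 3, 6, -9.0),   # continue
        (1, 10, 1, 1, 9.0),   # stop
    ])
    def test_stopping_delta(self, L, C, tp, fp, expected):
        counts = ConfusionCounts(tp=tp, fp=fp, tn=0, fn=0)
        assert stopping_delta(counts, GameParams(L=L, C=C)) == expected

    @pytest.mark.parametrize("kwargs", [
        {"L": 0}, {"C": -1}, {"B": -2}, {"B": 1.5},
    ])
    def test_invalid_game_params(self, kwargs):
        with pytest.raises(ValueError):
            GameParams(**{"L": 10.0, "C": 1.0, **kwargs})


class TestGreedyLoop:
    def test_no_sensitive_tokens_publishes_everything(self, game):
        corpus = Corpus.from_tokens(
            [[(w, 0) for w in "the quick brown fox".split()]])
        res = greedy_sanitize(corpus, learner="lookup", params=game)
        assert res.ensemble == []
        assert res.redacted_train_keys == set()
        assert res.publish().redacted_keys == set()

    def test_empty_corpus(self, game):
        res = greedy_sanitize(Corpus([]), learner="lookup", params=game)
        assert res.ensemble == [] and res.publish().n == 0

    def test_separable_corpus_stops_after_one_classifier(self, separable_corpus, game):
        """Iteration 1 removes every sensitive token; iteration 2's candidate
        finds no true positives on the residual and triggers the stop."""
        res = greedy_sanitize(separable_corpus, learner="lookup",
                              params=game, seed=0)
        assert res.n_iter == 2
        assert len(res.ensemble) == 1
        by_key = separable_corpus.by_key()
        residual_sensitive = sum(by_key[k].label for k in res.residual_keys)
        assert residual_sensitive == 0
        last = res.history[-1]
        assert last.counts.tp == 0 and not last.accepted

    def test_stop_candidate_not_in_ensemble(self, separable_corpus, game):
        res = greedy_sanitize(separable_corpus, learner="lookup", params=game)
        assert res.stop_candidate is not None
        assert res.stop_candidate not in res.ensemble

    def test_termination_within_corpus_size(self):
        """The loop runs at most |X| iterations on randomized corpora."""
        rng = np.random.default_rng(99)
        vocab = ["ana", "bo", "Cedo", "du", "Eka", "fi"]
        for trial in range(30):
            n_docs = int(rng.integers(1, 4))
            docs = [
                [(str(rng.choice(vocab)), int(rng.random() < 0.3))
                 for _ in range(int(rng.integers(1, 8)))]
                for _ in range(n_docs)
            ]
            corpus = Corpus.from_tokens(docs)
            params = GameParams(L=float(rng.choice([1, 2, 10])), C=1.0)
            res = greedy_sanitize(corpus, learner="lookup", params=params,
                                  seed=trial)
            assert len(res.ensemble) <= corpus.n
            assert res.n_iter <= corpus.n + 1

    def test_local_optimality_at_stop(self, small_synth, game):
        """The stop-triggering candidate has TP = 0 or FP/TP >= L/C on the
        residual training data."""
        res = greedy_sanitize(small_synth, learner="lookup", params=game)
        last = res.history[-1].counts
        assert last.tp == 0 or last.fp / last.tp >= game.loss_ratio

    def test_monotone_redaction(self, small_synth, game):
        res = greedy_sanitize(small_synth, learner="lookup", params=game)
        frame = res.history_frame
        residuals = frame["residual_before"].tolist()
        assert residuals == sorted(residuals, reverse=True)
        assert len(res.redacted_train_keys) == \
            frame.loc[frame["accepted"], "n_removed"].sum()

    def test_higher_loss_ratio_weakly_reduces_residual_sensitive(self, small_synth):
        """Sweeping L/C upward leaves weakly fewer sensitive tokens
        unredacted in the published training data."""
        by_key = small_synth.by_key()
        residual_fn = []
        for lc in [0.5, 1.0, 2.0, 5.0, 10.0, 50.0]:
            res = greedy_sanitize(small_synth, learner="lookup",
                                  params=GameParams(L=lc, C=1.0), seed=0)
            residual_fn.append(
                sum(by_key[k].label for k in res.residual_keys))
        assert residual_fn == sorted(residual_fn, reverse=True)

    def test_fit_is_deterministic(self, game):
        corpus = make_separable_corpus()
        r1 = greedy_sanitize(corpus, learner="memm", params=game, seed=4)
        r2 = greedy_sanitize(corpus, learner="memm", params=game, seed=4)
        assert r1.redacted_train_keys == r2.redacted_train_keys
        assert r1.n_iter == r2.n_iter

    def test_unlabeled_corpus_rejected(self, game):
        corpus = Corpus.from_tokens([[("a", None), ("b", 0)]])
        with pytest.raises(ValueError, match="labeled"):
            GreedySanitizer(corpus, game, learner="lookup")


class TestPublish:
    def test_publish_counts_match_worked_example(self, example1):
        """Redacting the 9 predicted positives publishes 17 of 26 tokens."""
        corpus, preds = example1
        positive_keys = {k for k, p in preds.items() if p == 1}
        published = corpus.redact(positive_keys)
        assert published.n == 26
        assert published.n - len(published.redacted_keys) == 17

    def test_apply_to_new_corpus(self, game):
        """A fitted policy generalizes: applying H to a fresh corpus with the
        same planted structure redacts its positives."""
        train_c = make_separable_corpus(n_docs=5)
        test_c = Corpus.from_tokens([[("the", 0), ("Zel0vqz", 1), ("ward", 0)]],
                                    doc_ids=["t0"])
        res = greedy_sanitize(train_c, learner="memm", params=game)
        published = res.publish(test_c)
        assert ("t0", 1) in published.redacted_keys
        assert ("t0", 0) not in published.redacted_keys

    def test_summary_mentions_key_quantities(self, separable_corpus, game):
        res = greedy_sanitize(separable_corpus, learner="lookup", params=game)
        text = res.summary()
        assert "publish ratio" in text and "iterations" in text
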