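"""The greedy publisher loop: train, redact predicted positives, repeat.

The publisher chooses an ordered set of classifiers H = {h_1, ..., h_D}.
Each iteration trains a classifier on the residual training data (tokens not
yet predicted positive), removes its predicted positives, and continues
until adding the new classifier would no longer reduce the publisher's loss

    T(H) = L * FN(H) + C * FP(H),

where FN(H) counts sensitive tokens surviving in the published set and
FP(H) counts non-sensitive tokens suppressed by any member of H.  Because
FN(H u h) = FN(H) - TP(h, P(H)) and FP(H u h) = FP(H) + FP(h, P(H)), the
change in loss from adding candidate h_k is computable from the candidate's
confusion counts on the residual training set alone:

    dT = C * FP(h_k, D_{k-1}) - L * TP(h_k, D_{k-1}),

and the loop stops as soon as dT >= 0.  The stop-triggering candidate is not
added to H.  Termination is guaranteed in at most |X| iterations: while the
loop continues, each iteration removes at least one token (TP >= 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .corpus import ConfusionCounts, Corpus, confusion_counts
from .learners import ClassifierHandle, Key, LearnerRegistry, default_registry, select_best, train

__all__ = [
    "GameParams",
    "publisher_loss",
    "stopping_delta",
    "GreedySanitizer",
    "SanitizeResult",
    "greedy_sanitize",
]


@dataclass(frozen=True)
class GameParams:
    """Publisher-attacker game parameters.

    L is the loss per exploited sensitive instance, C the cost per
    suppressed non-sensitive instance (both in the same utility units), and
    B the attacker's inspection budget in instances.
    """

    L: float = 10.0
    C: float = 1.0
    B: int = 0

    def __post_init__(self) -> None:
        if self.L <= 0 or self.C <= 0:
            raise ValueError("L and C must be > 0")
        if self.B < 0 or int(self.B) != self.B:
            raise ValueError("B must be a non-negative integer")

    @property
    def loss_ratio(self) -> float:
        """L/C, the exchange rate between privacy loss and utility cost."""
        return self.L / self.C


def publisher_loss(counts: ConfusionCounts, params: GameParams) -> float:
    """Total publisher loss T = L*FN + C*FP for the given counts."""
    if min(counts) < 0:
        raise ValueError("confusion counts must be non-negative")
    return params.L * counts.fn + params.C * counts.fp


def stopping_delta(new_counts: ConfusionCounts, params: GameParams) -> float:
    """Change in publisher loss from adding a candidate classifier.

    ``new_counts`` are the candidate's confusion counts on the residual
    training set D_{k-1}.  The greedy loop stops iff the returned value
    is >= 0.
    """
    return params.C * new_counts.fp - params.L * new_counts.tp


@dataclass
class IterationRecord:
    """Per-iteration diagnostics of the greedy loop."""

    k: int
    learner: str
    counts: ConfusionCounts
    delta: float
    residual_before: int
    n_removed: int
    accepted: bool


class GreedySanitizer:
    """Iterative train-and-redact sanitization model for a labeled corpus.

    Parameters
    ----------
    corpus : Corpus
        Fully labeled training corpus X.
    params : GameParams
        Loss/cost parameters driving the stopping rule.
    learner : str
        Name of the registered learner trained each iteration.
    selection : bool
        If True, each iteration picks the most accurate registry learner on
        a held-out split instead of a fixed one.
    registry : LearnerRegistry, optional
        Hypothesis class; defaults to the standard registry.

    Examples
    --------
    >>> model = GreedySanitizer(corpus, GameParams(L=10, C=1))
    >>> res = model.fit(seed=0)
    >>> published = res.publish(corpus)
    """

    def __init__(
        self,
        corpus: Corpus,
        params: GameParams,
        learner: str = "memm",
        selection: bool = False,
        registry: LearnerRegistry | None = None,
    ):
        self.corpus = corpus
        self.params = params
        self.learner = learner
        self.selection = selection
        self.registry = registry or default_registry()
        if not selection and learner not in self.registry:
            raise KeyError(f"learner {learner!r} not registered")
        if corpus.n and not corpus.is_labeled:
            raise ValueError("GreedySanitizer requires a fully labeled corpus")

    def fit(self, seed: int = 0, max_iter: int | None = None) -> "SanitizeResult":
        """Run the greedy loop until the stopping rule triggers.

        The per-iteration seed advances deterministically (seed + k); each
        iteration retrains from scratch on the residual set.
        """
        corpus, params = self.corpus, self.params
        all_keys = {tok.key for tok in corpus.instances()}
        by_key = corpus.by_key()
        residual: set[Key] = set(all_keys)
        redacted: set[Key] = set()
        ensemble: list[ClassifierHandle] = []
        history: list[IterationRecord] = []
        stop_candidate: ClassifierHandle | None = None
        # Every accepted classifier removes >= 1 token, so at most |X| are
        # accepted; one further candidate (on the empty residual) can be
        # needed to trigger the stop.
        limit = max_iter if max_iter is not None else corpus.n + 1

        k = 0
        while True:
            k += 1
            if not residual:
                # TP on the empty set is 0 by definition: dT = 0, stop.
                history.append(IterationRecord(
                    k=k, learner="(none)", counts=ConfusionCounts(0, 0, 0, 0),
                    delta=0.0, residual_before=0, n_removed=0, accepted=False))
                break
            if self.selection:
                handle = select_best(self.registry, corpus, residual,
                                     seed=seed + k)
            else:
                handle = train(self.learner, corpus, residual, seed=seed + k,
                               registry=self.registry)
            preds = handle.predict(corpus, residual, known_positive=redacted)
            subset = [by_key[key] for key in residual]
            counts = confusion_counts(preds, subset)
            delta = stopping_delta(counts, params)
            positives = {key for key, p in preds.items() if p == 1}
            stop = delta >= 0 or k >= limit
            history.append(IterationRecord(
                k=k, learner=handle.name, counts=counts, delta=delta,
                residual_before=len(residual), n_removed=len(positives),
                accepted=not stop))
            if stop:
                stop_candidate = handle
                break
            ensemble.append(handle)
            redacted |= positives
            residual -= positives

        return SanitizeResult(
            model=self,
            ensemble=ensemble,
            n_iter=k,
            history=history,
            redacted_train_keys=redacted,
            residual_keys=residual,
            stop_candidate=stop_candidate,
            seed=seed,
        )


@dataclass
class SanitizeResult:
    """Fitted publisher policy: the classifier set H and loop diagnostics.

    ``n_iter`` is the number of outer iterations executed (trained
    candidates), including the stop-triggering one, which is *not* a member
    of ``ensemble``.  ``redacted_train_keys`` is X_1(H) on the training
    corpus; ``residual_keys`` is the surviving training set (size m in the
    finite-sample analysis).
    """

    model: GreedySanitizer
    ensemble: list[ClassifierHandle]
    n_iter: int
    history: list[IterationRecord]
    redacted_train_keys: set[Key]
    residual_keys: set[Key]
    stop_candidate: ClassifierHandle | None
    seed: int

    @property
    def params(self) -> GameParams:
        return self.model.params

    @property
    def history_frame(self) -> pd.DataFrame:
        """Per-iteration table: counts, loss delta, set sizes."""
        rows = [
            {
                "k": r.k, "learner": r.learner,
                "tp": r.counts.tp, "fp": r.counts.fp,
                "tn": r.counts.tn, "fn": r.counts.fn,
                "delta_T": r.delta,
                "residual_before": r.residual_before,
                "n_removed": r.n_removed,
                "accepted": r.accepted,
            }
            for r in self.history
        ]
        return pd.DataFrame(rows)

    def apply(self, corpus: Corpus) -> set[Key]:
        """X_1(H) on a (possibly new) corpus: union of member positives.

        Classifiers are applied in training order; earlier members'
        positives feed the history state of later sequence taggers.
        """
        redacted: set[Key] = set()
        for handle in self.ensemble:
            redacted |= handle.positives(corpus, known_positive=redacted)
        return redacted

    def publish(self, corpus: Corpus | None = None) -> Corpus:
        """Apply H and return the corpus with predicted positives redacted."""
        if corpus is None or corpus is self.model.corpus:
            return self.model.corpus.redact(self.redacted_train_keys)
        return corpus.redact(self.apply(corpus))

    def train_counts(self) -> ConfusionCounts:
        """Confusion counts of the whole set H on the training corpus X.

        TP/FP count tokens suppressed by any member; FN/TN count survivors.
        """
        corpus = self.model.corpus
        preds = {tok.key: (1 if tok.key in self.redacted_train_keys else 0)
                 for tok in corpus.instances()}
        return confusion_counts(preds, corpus.instances())

    def summary(self) -> str:
        counts = self.train_counts()
        lines = [
            "GreedySanitize results",
            "=" * 54,
            f"learner:            {'selection' if self.model.selection else self.model.learner}",
            f"L, C, L/C:          {self.params.L:g}, {self.params.C:g}, "
            f"{self.params.loss_ratio:g}",
            f"outer iterations:   {self.n_iter}",
            f"classifiers in H:   {len(self.ensemble)}",
            f"tokens in X:        {self.model.corpus.n}",
            f"redacted (X_1(H)):  {len(self.redacted_train_keys)}",
            f"publish ratio:      {1 - len(self.redacted_train_keys) / self.model.corpus.n:.4f}"
            if self.model.corpus.n else "publish ratio:      n/a",
            f"residual FN / FP:   {counts.fn} / {counts.fp}",
            f"publisher loss T:   {publisher_loss(counts, self.params):g}",
            "-" * 54,
            self.history_frame.to_string(index=False),
        ]
        return "\n".join(lines)


def greedy_sanitize(
    corpus: Corpus,
    learner: str = "memm",
    params: GameParams | None = None,
    seed: int = 0,
    selection: bool = False,
    registry: LearnerRegistry | None = None,
) -> SanitizeResult:
    """Convenience wrapper: build and fit a :class:`GreedySanitizer`."""
    model = GreedySanitizer(corpus, params or GameParams(),
                            learner=learner, selection=selection,
                            registry=registry)
    return model.fit(seed=seed)
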