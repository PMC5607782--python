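"""Pluggable binary token classifiers: the hypothesis class shared by
publisher and attacker.

The registry holds four learners mirroring the standard de-identification
toolbox: a maximum-entropy Markov sequence tagger ("memm", greedy
left-to-right logistic regression with label-history features), a
margin-based tagger ("svm", linear SVM with the same history features), a
boosting learner ("adaboost", decision stumps, no history), and a two-stage
ensemble ("ensemble", sequence tagger followed by an SVM that prunes its
predicted positives).  A trivial per-surface majority-vote learner
("lookup") is included for cheap baselines and diagnostics.

All learners accept a positive-class weight ratio for cost-sensitive
training and are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
from sklearn.ensemble import AdaBoostClassifier
from sklearn.feature_extraction import DictVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .corpus import ConfusionCounts, Corpus, TokenInstance, confusion_counts
from .features import token_features

__all__ = [
    "ClassifierHandle",
    "LearnerRegistry",
    "default_registry",
    "train",
    "select_best",
]

Key = tuple[str, int]

_HIST_START = "<s>"


def _doc_feature_dicts(doc: list[TokenInstance], window: int, affix_len: int):
    return [token_features(doc, i, window=window, affix_len=affix_len)
            for i in range(len(doc))]


def _csr32(X):
    """CSR matrix with 32-bit indices (required by the liblinear solvers)."""
    X = X.tocsr()
    X.indices = X.indices.astype(np.int32, copy=False)
    X.indptr = X.indptr.astype(np.int32, copy=False)
    return X


class _ConstantTagger:
    """Predicts a fixed class everywhere (degenerate training data)."""

    def __init__(self, label: int):
        self.label = label

    def fit(self, corpus, keys, ratio, seed):  # pragma: no cover - trivial
        return self

    def predict_doc(self, doc, feats, known_positive):
        return [1 if tok.key in known_positive else self.label for tok in doc]


class _LookupTagger:
    """Cost-weighted majority label per surface form; unseen surfaces -> 0.

    Predicts 1 for a surface iff ratio * #(label 1) > #(label 0) among its
    training occurrences.  Fast, deterministic, and exactly monotone in the
    class-weight ratio.
    """

    def __init__(self):
        self._pos: dict[str, int] = {}
        self._neg: dict[str, int] = {}
        self._ratio = 1.0

    def fit(self, corpus: Corpus, keys: set[Key], ratio: float, seed: int):
        self._ratio = ratio
        for tok in corpus.instances():
            if tok.key not in keys:
                continue
            d = self._pos if tok.label == 1 else self._neg
            d[tok.published_surface] = d.get(tok.published_surface, 0) + 1
        return self

    def predict_doc(self, doc, feats, known_positive):
        out = []
        for tok in doc:
            if tok.key in known_positive:
                out.append(1)
                continue
            s = tok.published_surface
            pos = self._pos.get(s, 0)
            neg = self._neg.get(s, 0)
            out.append(1 if self._ratio * pos > neg else 0)
        return out


class _LinearSequenceTagger:
    """Greedy left-to-right linear tagger with label-history features.

    Trained with gold previous-label history (teacher forcing); decoded
    greedily feeding its own predictions.  Because the model is linear, the
    history contribution is a scalar weight per previous state, so decoding
    adds O(1) work per token on top of one vectorized scoring pass.
    """

    def __init__(self, estimator_factory: Callable[[float, int], object],
                 use_history: bool = True, window: int = 2, affix_len: int = 3):
        self._factory = estimator_factory
        self.use_history = use_history
        self.window = window
        self.affix_len = affix_len
        self._vec: DictVectorizer | None = None
        self._model = None
        self._hist_w: dict[str, float] = {}

    def fit(self, corpus: Corpus, keys: set[Key], ratio: float, seed: int):
        dicts: list[dict] = []
        y: list[int] = []
        for doc in corpus.documents:
            if not any(tok.key in keys for tok in doc):
                continue
            feats = _doc_feature_dicts(doc, self.window, self.affix_len)
            for i, tok in enumerate(doc):
                if tok.key not in keys:
                    continue
                f = feats[i]
                if self.use_history:
                    prev = str(doc[i - 1].label) if i > 0 else _HIST_START
                    f = dict(f, hist=prev)
                dicts.append(f)
                y.append(tok.label)  # type: ignore[arg-type]
        self._vec = DictVectorizer()
        X = _csr32(self._vec.fit_transform(dicts))
        self._model = self._factory(ratio, seed)
        self._model.fit(X, np.asarray(y))
        # Scalar history weights for the O(1)-per-token greedy decode.
        self._hist_w = {}
        if self.use_history:
            coef = np.ravel(self._model.coef_)
            vocab = self._vec.vocabulary_
            for state in ("0", "1", _HIST_START):
                idx = vocab.get(f"hist={state}")
                self._hist_w[state] = float(coef[idx]) if idx is not None else 0.0
        return self

    def _base_scores(self, dicts: list[dict]) -> np.ndarray:
        X = self._vec.transform(dicts)
        return np.ravel(X @ self._model.coef_.T) + float(self._model.intercept_[0])

    def predict_doc(self, doc, feats, known_positive):
        scores = self._base_scores(feats)
        preds: list[int] = []
        state = _HIST_START
        for i, tok in enumerate(doc):
            if tok.key in known_positive:
                preds.append(1)
                state = "1"
                continue
            s = scores[i] + (self._hist_w.get(state, 0.0) if self.use_history else 0.0)
            p = 1 if s > 0 else 0
            preds.append(p)
            state = str(p)
        return preds


class _AdaBoostTagger:
    """Boosted decision stumps over the orthographic features (no history)."""

    def __init__(self, n_estimators: int = 30, window: int = 2, affix_len: int = 3):
        self.n_estimators = n_estimators
        self.window = window
        self.affix_len = affix_len
        self._vec: DictVectorizer | None = None
        self._model: AdaBoostClassifier | None = None

    def fit(self, corpus: Corpus, keys: set[Key], ratio: float, seed: int):
        dicts, y = [], []
        for doc in corpus.documents:
            if not any(tok.key in keys for tok in doc):
                continue
            feats = _doc_feature_dicts(doc, self.window, self.affix_len)
            for i, tok in enumerate(doc):
                if tok.key in keys:
                    dicts.append(feats[i])
                    y.append(tok.label)
        self._vec = DictVectorizer()
        X = _csr32(self._vec.fit_transform(dicts))
        y = np.asarray(y)
        w = np.where(y == 1, ratio, 1.0)
        self._model = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            n_estimators=self.n_estimators,
            random_state=seed,
        )
        self._model.fit(X, y, sample_weight=w)
        return self

    def predict_doc(self, doc, feats, known_positive):
        preds = self._model.predict(_csr32(self._vec.transform(feats)))
        return [1 if tok.key in known_positive else int(p)
                for tok, p in zip(doc, preds)]


class _TwoStageTagger:
    """Sequence tagger for recall, then a linear SVM pruning its positives.

    The second stage is trained on the first stage's predicted positives
    (on training data) to discriminate true from false positives.
    """

    def __init__(self, window: int = 2, affix_len: int = 3):
        self.window = window
        self.affix_len = affix_len
        self._stage1: _LinearSequenceTagger | None = None
        self._vec2: DictVectorizer | None = None
        self._model2 = None
        self._stage2_const: int | None = None

    def fit(self, corpus: Corpus, keys: set[Key], ratio: float, seed: int):
        self._stage1 = _LinearSequenceTagger(_logistic_factory)
        self._stage1.fit(corpus, keys, ratio, seed)
        # Collect stage-1 positives on the training set.
        dicts, y = [], []
        for doc in corpus.documents:
            if not any(tok.key in keys for tok in doc):
                continue
            feats = _doc_feature_dicts(doc, self.window, self.affix_len)
            preds = self._stage1.predict_doc(doc, feats, frozenset())
            for i, tok in enumerate(doc):
                if tok.key in keys and preds[i] == 1:
                    dicts.append(feats[i])
                    y.append(tok.label)
        if not dicts or len(set(y)) < 2:
            # Nothing to prune, or nothing to learn from: pass stage 1 through.
            self._stage2_const = 1
            return self
        self._vec2 = DictVectorizer()
        X = _csr32(self._vec2.fit_transform(dicts))
        self._model2 = _svc_factory(ratio, seed)
        self._model2.fit(X, np.asarray(y))
        return self

    def predict_doc(self, doc, feats, known_positive):
        preds = self._stage1.predict_doc(doc, feats, known_positive)
        pos_idx = [i for i, p in enumerate(preds)
                   if p == 1 and doc[i].key not in known_positive]
        if not pos_idx:
            return preds
        if self._stage2_const is not None:
            keep = [self._stage2_const] * len(pos_idx)
        else:
            keep = self._model2.predict(
                _csr32(self._vec2.transform([feats[i] for i in pos_idx])))
        for i, k in zip(pos_idx, keep):
            preds[i] = int(k)
        return preds


def _logistic_factory(ratio: float, seed: int) -> LogisticRegression:
    return LogisticRegression(
        solver="liblinear",
        C=1.0,
        class_weight={1: ratio, 0: 1.0},
        random_state=seed,
        max_iter=200,
    )


def _svc_factory(ratio: float, seed: int) -> LinearSVC:
    return LinearSVC(
        C=0.5,
        class_weight={1: ratio, 0: 1.0},
        random_state=seed,
        max_iter=5000,
    )


# ---------------------------------------------------------------------------
# Handles and registry
# ---------------------------------------------------------------------------

@dataclass
class ClassifierHandle:
    """A trained classifier with its provenance metadata.

    ``predict`` maps every token of a corpus to {0, 1}; repeated calls on
    identical input agree.  Tokens listed in ``known_positive`` (or already
    redacted in the corpus) are forced to 1 — they are known suppressed
    positives and feed the history state of sequence decoding.
    """

    name: str
    tagger: object
    train_size: int
    train_accuracy: float
    window: int = 2
    affix_len: int = 3

    def predict(
        self,
        corpus: Corpus,
        keys: Iterable[Key] | None = None,
        known_positive: Iterable[Key] = (),
    ) -> dict[Key, int]:
        keyset = set(keys) if keys is not None else None
        known = set(known_positive) | corpus.redacted_keys
        out: dict[Key, int] = {}
        for doc in corpus.documents:
            doc_keys = [tok.key for tok in doc]
            if keyset is not None and not any(k in keyset for k in doc_keys):
                continue
            feats = _doc_feature_dicts(doc, self.window, self.affix_len)
            preds = self.tagger.predict_doc(doc, feats, known)
            for k, p in zip(doc_keys, preds):
                if keyset is None or k in keyset:
                    out[k] = int(p)
        return out

    def positives(self, corpus: Corpus, keys: Iterable[Key] | None = None,
                  known_positive: Iterable[Key] = ()) -> set[Key]:
        preds = self.predict(corpus, keys, known_positive)
        return {k for k, p in preds.items() if p == 1}


class LearnerRegistry:
    """Ordered mapping of learner names to tagger factories.

    Registry order is the tie-break order for best-learner selection.
    """

    def __init__(self, factories: Mapping[str, Callable[[], object]] | None = None):
        self._factories: dict[str, Callable[[], object]] = dict(factories or {})

    def register(self, name: str, factory: Callable[[], object]) -> None:
        self._factories[name] = factory

    def names(self) -> list[str]:
        return list(self._factories)

    def make(self, name: str) -> object:
        try:
            return self._factories[name]()
        except KeyError:
            raise KeyError(
                f"unknown learner {name!r}; registered: {self.names()}"
            ) from None

    def __contains__(self, name: str) -> bool:
        return name in self._factories

    def __len__(self) -> int:
        return len(self._factories)

    def subset(self, names: Iterable[str]) -> "LearnerRegistry":
        return LearnerRegistry({n: self._factories[n] for n in names})


def default_registry() -> LearnerRegistry:
    """The standard four-learner hypothesis class plus the lookup baseline."""
    return LearnerRegistry({
        "memm": lambda: _LinearSequenceTagger(_logistic_factory, use_history=True),
        "svm": lambda: _LinearSequenceTagger(_svc_factory, use_history=True),
        "adaboost": lambda: _AdaBoostTagger(),
        "ensemble": lambda: _TwoStageTagger(),
        "lookup": lambda: _LookupTagger(),
        "constant0": lambda: _ConstantTagger(0),
    })


def train(
    learner_name: str,
    corpus: Corpus,
    keys: Iterable[Key] | None = None,
    class_weight_ratio: float = 1.0,
    seed: int = 0,
    registry: LearnerRegistry | None = None,
) -> ClassifierHandle:
    """Train one registered learner on the given labeled instances.

    ``keys`` restricts training to a subset of the corpus (default: all
    tokens).  Single-class training data yields the constant classifier of
    that class.  ``class_weight_ratio`` is the positive-to-negative
    misclassification weight (L/C for cost-sensitive training, 1 for plain
    accuracy training).
    """
    if class_weight_ratio <= 0:
        raise ValueError("class_weight_ratio must be > 0")
    registry = registry or default_registry()
    keyset = set(keys) if keys is not None else {t.key for t in corpus.instances()}
    labels = [tok.label for tok in corpus.instances() if tok.key in keyset]
    if any(lab is None for lab in labels):
        raise ValueError("training requires labeled instances")
    if len(keyset) == 0 or len(set(labels)) < 2:
        const = labels[0] if labels else 0
        tagger: object = _ConstantTagger(const)
    else:
        tagger = registry.make(learner_name)
        tagger.fit(corpus, keyset, class_weight_ratio, seed)
    handle = ClassifierHandle(
        name=learner_name,
        tagger=tagger,
        train_size=len(keyset),
        train_accuracy=0.0,
    )
    if keyset:
        preds = handle.predict(corpus, keyset)
        subset = [tok for tok in corpus.instances() if tok.key in keyset]
        handle.train_accuracy = confusion_counts(preds, subset).accuracy
    else:
        handle.train_accuracy = 1.0
    return handle


def select_best(
    registry: LearnerRegistry,
    corpus: Corpus,
    keys: Iterable[Key] | None = None,
    seed: int = 0,
    class_weight_ratio: float = 1.0,
    holdout_fraction: float = 0.25,
) -> ClassifierHandle:
    """Train every registered learner and return the most accurate one.

    Documents are split (seeded) into a train and a held-out part; each
    learner is trained on the former and scored on the latter.  Ties break
    by registry order.  With too few documents to split, training accuracy
    is used instead.
    """
    if len(registry) == 0:
        raise ValueError("registry is empty")
    keyset = set(keys) if keys is not None else {t.key for t in corpus.instances()}
    doc_ids = [i for i, doc in enumerate(corpus.documents)
               if any(tok.key in keyset for tok in doc)]
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(doc_ids)))
    n_hold = int(round(holdout_fraction * len(doc_ids)))
    hold_docs = {doc_ids[i] for i in order[:n_hold]}
    train_keys = {tok.key for i, doc in enumerate(corpus.documents)
                  if i not in hold_docs for tok in doc if tok.key in keyset}
    hold_keys = keyset - train_keys
    if not train_keys or not hold_keys:
        train_keys, hold_keys = keyset, keyset

    hold_subset = [tok for tok in corpus.instances() if tok.key in hold_keys]
    best: tuple[float, int] | None = None
    best_handle: ClassifierHandle | None = None
    for idx, name in enumerate(registry.names()):
        handle = train(name, corpus, train_keys, class_weight_ratio,
                       seed=seed, registry=registry)
        preds = handle.predict(corpus, hold_keys)
        acc = confusion_counts(preds, hold_subset).accuracy
        score = (acc, -idx)
        if best is None or score > best:
            best = score
            best_handle = handle
    assert best_handle is not None
    return best_handle
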