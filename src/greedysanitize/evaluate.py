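"""Cross-validated experiment harness and data-utility metrics.

Runs the full game at desk scale: split documents into folds, run the
greedy sanitizer on the training folds, apply the learned classifier set to
the held-out fold, publish, attack at each budget, and aggregate metrics
(publish ratio, residual sensitive count, identified-per-budget, utility
ratio, iteration counts).  Cost-sensitive single-classifier baselines —
one learner trained once with positive-class weight L/C — are run on the
same folds for comparison.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Iterable

import numpy as np

from .attack import attack, utility_ratio
from .corpus import Corpus, read_corpus
from .learners import LearnerRegistry, default_registry, train
from .sanitize import GameParams, GreedySanitizer
from .synth import SyntheticSpec, generate

__all__ = [
    "publish_ratio",
    "document_folds",
    "run_experiment",
    "ExperimentReport",
    "ConfigError",
]


class ConfigError(ValueError):
    """Raised for invalid experiment configuration, naming the key path."""


def publish_ratio(published: Corpus, original: Corpus) -> float:
    """Fraction of original tokens released unredacted: (n - #redacted)/n."""
    if original.n == 0:
        raise ValueError("publish ratio undefined for an empty corpus")
    if published.n != original.n:
        raise ValueError(
            f"corpora are not aligned: {published.n} vs {original.n} tokens")
    return (published.n - len(published.redacted_keys)) / original.n


def document_folds(n_docs: int, n_folds: int, seed: int) -> list[np.ndarray]:
    """Seeded document-level fold assignment (documents, not tokens)."""
    if n_folds < 2 or n_folds > n_docs:
        raise ConfigError(f"folds: need 2 <= folds <= n_docs, got {n_folds}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_docs)
    return [order[i::n_folds] for i in range(n_folds)]


@dataclass
class FoldOutcome:
    """Metrics of one policy on one held-out fold."""

    fold: int
    n_iter: int | None
    n_classifiers: int | None
    publish_ratio: float
    residual_sensitive: int
    n_test_tokens: int
    per_budget: list[dict[str, float]] = field(default_factory=list)


@dataclass
class ExperimentReport:
    """Machine-readable experiment outcome (JSON-serializable)."""

    config: dict[str, Any]
    gs_folds: list[FoldOutcome]
    baseline_folds: dict[str, list[FoldOutcome]]
    aggregate: dict[str, Any]

    def to_dict(self) -> dict[str, Any]:
        return {
            "config": self.config,
            "gs_folds": [asdict(f) for f in self.gs_folds],
            "baseline_folds": {
                name: [asdict(f) for f in folds]
                for name, folds in self.baseline_folds.items()
            },
            "aggregate": self.aggregate,
        }

    def write_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True),
                        encoding="utf-8")
        return path


def _load_corpus(config: dict[str, Any]) -> Corpus:
    if "corpus" in config:
        return read_corpus(config["corpus"], labeled=True)
    if "synth" in config:
        try:
            spec = SyntheticSpec(**config["synth"])
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"synth: {exc}") from exc
        return generate(spec)
    raise ConfigError("config requires either 'corpus' or 'synth'")


def _fold_metrics(
    fold_idx: int,
    test_corpus: Corpus,
    published: Corpus,
    budgets: Iterable[int],
    params: GameParams,
    registry: LearnerRegistry,
    attacker_cfg: dict[str, Any],
    seed: int,
    n_iter: int | None,
    n_classifiers: int | None,
) -> FoldOutcome:
    residual_sens = sum(
        tok.label for tok in test_corpus.instances()
        if tok.key not in published.redacted_keys)
    outcome = FoldOutcome(
        fold=fold_idx,
        n_iter=n_iter,
        n_classifiers=n_classifiers,
        publish_ratio=publish_ratio(published, test_corpus),
        residual_sensitive=int(residual_sens),
        n_test_tokens=test_corpus.n,
    )
    attacker_names = attacker_cfg.get("learners")
    attacker_registry = (registry.subset(attacker_names)
                         if attacker_names else registry)
    for b in budgets:
        res = attack(
            published, test_corpus,
            GameParams(params.L, params.C, int(b)),
            registry=attacker_registry,
            train_fraction=attacker_cfg.get("train_fraction", 0.5),
            seed=seed + int(b),
        )
        entry = {
            "budget": int(b),
            "identified_expected": res.utility_learned / params.L,
            "identified_per_budget": (res.utility_learned / params.L / b
                                      if b else 0.0),
            "attacker_tp": res.attacker_counts.tp,
        }
        try:
            entry["utility_ratio"] = utility_ratio(res)
        except ZeroDivisionError:
            entry["utility_ratio"] = None
        outcome.per_budget.append(entry)
    return outcome


def run_experiment(config: dict[str, Any] | str | Path) -> ExperimentReport:
    """Run the cross-validated publisher-attacker experiment.

    Config keys: ``synth`` (generator spec) or ``corpus`` (path); ``learner``
    (name) or ``selection: true``; ``L``, ``C``; ``budgets`` (list of ints,
    may be empty); ``folds``; ``seed``; optional ``attacker``
    (``train_fraction``, ``learners``) and ``baselines`` (list of learner
    names for cost-sensitive comparison).
    """
    if isinstance(config, (str, Path)):
        import yaml

        config = yaml.safe_load(Path(config).read_text(encoding="utf-8"))
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")

    seed = int(config.get("seed", 0))
    try:
        params = GameParams(L=config.get("L", 10.0), C=config.get("C", 1.0))
    except ValueError as exc:
        raise ConfigError(f"L/C: {exc}") from exc
    n_folds = int(config.get("folds", 4))
    budgets = list(config.get("budgets", []))
    learner = config.get("learner", "memm")
    selection = bool(config.get("selection", False))
    attacker_cfg = dict(config.get("attacker", {}))
    baseline_names = list(config.get("baselines", []))
    registry = default_registry()
    if not selection and learner not in registry:
        raise ConfigError(f"learner: unknown learner {learner!r}")
    for name in baseline_names:
        if name not in registry:
            raise ConfigError(f"baselines: unknown learner {name!r}")

    corpus = _load_corpus(config)
    folds = document_folds(corpus.n_documents, n_folds, seed)

    gs_folds: list[FoldOutcome] = []
    baseline_folds: dict[str, list[FoldOutcome]] = {n: [] for n in baseline_names}
    for f, test_idx in enumerate(folds):
        test_set = set(int(i) for i in test_idx)
        train_idx = [i for i in range(corpus.n_documents) if i not in test_set]
        train_corpus = corpus.subset_documents(train_idx)
        test_corpus = corpus.subset_documents(sorted(test_set))
        fold_seed = seed + 1000 * (f + 1)

        model = GreedySanitizer(train_corpus, params, learner=learner,
                                selection=selection, registry=registry)
        result = model.fit(seed=fold_seed)
        published = result.publish(test_corpus)
        gs_folds.append(_fold_metrics(
            f, test_corpus, published, budgets, params, registry,
            attacker_cfg, fold_seed, result.n_iter, len(result.ensemble)))

        # Cost-sensitive single-classifier baselines at weight L/C.
        for name in baseline_names:
            handle = train(name, train_corpus,
                           class_weight_ratio=params.loss_ratio,
                           seed=fold_seed, registry=registry)
            redacted = handle.positives(test_corpus)
            pub_b = test_corpus.redact(redacted)
            baseline_folds[name].append(_fold_metrics(
                f, test_corpus, pub_b, budgets, params, registry,
                attacker_cfg, fold_seed, None, None))

    def _agg(folds_list: list[FoldOutcome]) -> dict[str, Any]:
        out: dict[str, Any] = {
            "publish_ratio_mean": float(np.mean([x.publish_ratio for x in folds_list])),
            "residual_sensitive_mean": float(np.mean([x.residual_sensitive for x in folds_list])),
        }
        iters = [x.n_iter for x in folds_list if x.n_iter is not None]
        if iters:
            out["n_iter_mean"] = float(np.mean(iters))
            out["n_iter_max"] = int(max(iters))
        if budgets:
            out["identified_per_budget"] = [
                {
                    "budget": int(b),
                    "mean": float(np.mean([
                        x.per_budget[j]["identified_per_budget"]
                        for x in folds_list])),
                }
                for j, b in enumerate(budgets)
            ]
        return out

    aggregate: dict[str, Any] = {"gs": _agg(gs_folds)}
    for name, fl in baseline_folds.items():
        aggregate[f"baseline_{name}"] = _agg(fl)

    clean_config = {k: v for k, v in config.items()}
    return ExperimentReport(
        config=clean_config,
        gs_folds=gs_folds,
        baseline_folds=baseline_folds,
        aggregate=aggregate,
    )
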