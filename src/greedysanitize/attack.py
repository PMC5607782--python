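"""Budget-limited inspection attacker on published data.

The attacker obtains the published corpus P, labels a fraction of it (an
omniscient training holdout), picks the most accurate classifier from the
shared hypothesis class, ranks the remaining instances predicted-positives
first, and manually inspects up to B of them; every inspected token's true
sensitivity is revealed, and each confirmed sensitive instance yields L.

Utilities:

* baseline (uniform-random inspection of B instances from a pool with
  confusion counts (TP, FP, TN, FN) of the attacker's classifier):
      U_A = L * B * (TP + FN) / (TP + FP + TN + FN)
* learned attack, scored in expectation:
      B <= TP + FP:  U*_A = L * B * TP / (TP + FP)
      B >  TP + FP:  U*_A = L * (TP + (B - TP - FP) * FN / (FN + TN))
  (surplus inspections draw uniformly from the predicted negatives).

The ratio U*_A / U_A measures how much learning buys the attacker over
blind sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import ConfusionCounts, Corpus, TokenInstance, confusion_counts
from .learners import ClassifierHandle, Key, LearnerRegistry, default_registry, select_best
from .sanitize import GameParams

__all__ = [
    "AttackResult",
    "attack",
    "baseline_utility",
    "expected_learned_utility",
    "utility_ratio",
    "utility_ratio_from_counts",
]


def baseline_utility(attacker_counts: ConfusionCounts, params: GameParams) -> float:
    """Expected utility of inspecting B instances uniformly at random."""
    total = attacker_counts.total
    if total == 0:
        raise ValueError("baseline utility undefined on an empty pool")
    if params.B > total:
        raise ValueError(f"budget B={params.B} exceeds pool size {total}")
    return params.L * params.B * attacker_counts.n_positive / total


def expected_learned_utility(attacker_counts: ConfusionCounts,
                             params: GameParams) -> float:
    """Expected utility of positives-first inspection with budget B.

    Within each rank class the pool is exchangeable, so the expected number
    of sensitive instances among j inspected predicted positives is
    j*TP/(TP+FP), and among j surplus inspections of predicted negatives is
    j*FN/(FN+TN).
    """
    c = attacker_counts
    if c.total == 0:
        raise ValueError("learned utility undefined on an empty pool")
    if params.B > c.total:
        raise ValueError(f"budget B={params.B} exceeds pool size {c.total}")
    n_pos_pred = c.n_predicted_positive
    if params.B <= n_pos_pred:
        if n_pos_pred == 0:
            return 0.0
        return params.L * params.B * c.tp / n_pos_pred
    surplus = params.B - n_pos_pred
    neg_pool = c.fn + c.tn
    tail = surplus * c.fn / neg_pool if neg_pool else 0.0
    return params.L * (c.tp + tail)


def utility_ratio_from_counts(attacker_counts: ConfusionCounts,
                              params: GameParams) -> float:
    """U*_A / U_A from the attacker's confusion counts (expectation mode)."""
    base = baseline_utility(attacker_counts, params)
    if base <= 0:
        raise ZeroDivisionError("utility ratio undefined: baseline utility is 0")
    return expected_learned_utility(attacker_counts, params) / base


@dataclass
class AttackResult:
    """Outcome of one simulated attack on a published corpus."""

    attacker_classifier: ClassifierHandle
    inspected: list[Key]
    utility_learned: float
    utility_baseline: float
    attacker_counts: ConfusionCounts
    utility_realized: float
    params: GameParams
    pool_size: int
    n_holdout: int

    @property
    def ratio(self) -> float:
        return utility_ratio(self)

    def summary(self) -> str:
        c = self.attacker_counts
        lines = [
            "Attack results",
            "=" * 44,
            f"attacker learner:     {self.attacker_classifier.name}",
            f"budget B:             {self.params.B}",
            f"inspectable pool:     {self.pool_size}",
            f"labeled holdout:      {self.n_holdout}",
            f"attacker counts:      TP={c.tp} FP={c.fp} TN={c.tn} FN={c.fn}",
            f"U*_A (expectation):   {self.utility_learned:.4f}",
            f"U*_A (realized):      {self.utility_realized:.4f}",
            f"U_A (baseline):       {self.utility_baseline:.4f}",
        ]
        try:
            lines.append(f"ratio U*_A/U_A:       {self.ratio:.4f}")
        except ZeroDivisionError:
            lines.append("ratio U*_A/U_A:       undefined (zero baseline)")
        return "\n".join(lines)


def utility_ratio(result: AttackResult) -> float:
    """U*_A / U_A; raises if the baseline utility is zero."""
    if result.utility_baseline <= 0:
        raise ZeroDivisionError("utility ratio undefined: baseline utility is 0")
    return result.utility_learned / result.utility_baseline


def attack(
    published: Corpus,
    truth: Corpus,
    params: GameParams,
    registry: LearnerRegistry | None = None,
    train_fraction: float = 0.5,
    seed: int = 0,
    mode: str = "expectation",
) -> AttackResult:
    """Simulate the ranked-inspection attacker.

    Parameters
    ----------
    published : Corpus
        The published corpus (redacted tokens carry placeholders).
    truth : Corpus
        The aligned fully labeled original; inspection is an oracle lookup
        against it.
    train_fraction : float in [0, 1)
        Fraction of unredacted published instances the attacker labels to
        train on.  Those instances are excluded from the inspectable pool.
        0 means the idealized attacker who trains on all of P and is scored
        over all of P.
    mode : {"expectation", "sampled"}
        How surplus inspections beyond the predicted positives are scored:
        closed-form expectation (default) or an actual seeded random draw.
    """
    if not 0 <= train_fraction < 1:
        raise ValueError("train_fraction must be in [0, 1)")
    if mode not in ("expectation", "sampled"):
        raise ValueError(f"unknown mode {mode!r}")
    registry = registry or default_registry()
    truth_labels = truth.labels()

    visible = [tok for tok in published.instances() if tok.redaction is None]
    if not visible:
        raise ValueError("published corpus has no unredacted instances")
    for tok in visible:
        if tok.key not in truth_labels:
            raise ValueError(f"published instance {tok.key} missing from truth")

    rng = np.random.default_rng(seed)
    if train_fraction > 0:
        n_hold = int(round(train_fraction * len(visible)))
        n_hold = max(1, min(n_hold, len(visible) - 1))
        idx = rng.permutation(len(visible))
        holdout = {visible[i].key for i in idx[:n_hold]}
    else:
        holdout = {tok.key for tok in visible}

    # The attacker's training view: published surfaces, true labels on the
    # holdout.  Labels are injected from truth; surfaces stay published.
    labeled_view = _with_truth_labels(published, truth_labels)
    h_a = select_best(registry, labeled_view, keys=holdout, seed=seed)

    if train_fraction > 0:
        pool = [tok for tok in visible if tok.key not in holdout]
    else:
        pool = visible
    pool_keys = [tok.key for tok in pool]
    preds = h_a.predict(labeled_view, pool_keys)
    pool_labeled = [tok for tok in _iter_with_labels(pool, truth_labels)]
    counts = confusion_counts(preds, pool_labeled)

    # Rank: predicted positives first, then negatives; document order within
    # each class (deterministic tie-break).
    positives = [k for k in pool_keys if preds[k] == 1]
    negatives = [k for k in pool_keys if preds[k] == 0]
    if mode == "sampled":
        positives = [positives[i] for i in rng.permutation(len(positives))]
        negatives = [negatives[i] for i in rng.permutation(len(negatives))]
    ranked = positives + negatives
    budget = min(params.B, len(ranked))
    inspected = ranked[:budget]
    realized = params.L * sum(truth_labels[k] for k in inspected)

    learned = (realized if mode == "sampled"
               else expected_learned_utility(counts, GameParams(params.L, params.C, budget)))
    base = baseline_utility(counts, GameParams(params.L, params.C, budget))
    return AttackResult(
        attacker_classifier=h_a,
        inspected=inspected,
        utility_learned=learned,
        utility_baseline=base,
        attacker_counts=counts,
        utility_realized=realized,
        params=params,
        pool_size=len(pool),
        n_holdout=len(holdout) if train_fraction > 0 else 0,
    )


def _with_truth_labels(published: Corpus,
                       truth_labels: dict[Key, int]) -> Corpus:
    """Published corpus with true labels attached (attacker's omniscient view)."""
    from dataclasses import replace

    documents = [
        [replace(tok, label=truth_labels.get(tok.key)) for tok in doc]
        for doc in published.documents
    ]
    return Corpus(documents)


def _iter_with_labels(tokens: list[TokenInstance],
                      truth_labels: dict[Key, int]):
    from dataclasses import replace

    for tok in tokens:
        yield replace(tok, label=truth_labels[tok.key])
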