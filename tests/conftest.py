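"""Shared fixtures: worked-example corpus, separable toy corpus, small
synthetic corpora, learner registry."""

from __future__ import annotations

import numpy as np
import pytest

from greedysanitize import (
    Corpus,
    GameParams,
    SyntheticSpec,
    default_registry,
    fixture_example1,
    generate,
)

# Positives in the separable toy carry this marker suffix, which never
# occurs on a negative: any non-trivial learner separates them exactly.
MARKER_SUFFIX = "vqz"

_TOY_NEGATIVES = [
    "the", "patient", "was", "seen", "on", "ward", "two", "and", "then",
    "discharged", "home", "with", "a", "stable", "condition", "after",
    "review", "by", "team", "left",
]


@pytest.fixture(scope="session")
def example1():
    """26-token worked-example corpus with fixed attacker predictions."""
    return fixture_example1()


def make_separable_corpus(n_docs: int = 5, doc_len: int = 10,
                          positives_per_doc: int = 2) -> Corpus:
    """50-token corpus whose positives end in a unique marker suffix."""
    rng = np.random.default_rng(123)
    docs = []
    name_id = 0
    for d in range(n_docs):
        pos_slots = set(rng.choice(doc_len, size=positives_per_doc,
                                   replace=False).tolist())
        doc = []
        for i in range(doc_len):
            if i in pos_slots:
                doc.append((f"Zel{name_id}{MARKER_SUFFIX}", 1))
                name_id += 1
            else:
                doc.append((str(rng.choice(_TOY_NEGATIVES)), 0))
        docs.append(doc)
    return Corpus.from_tokens(docs)


def suffix_oracle(corpus: Corpus) -> dict[tuple[str, int], int]:
    """Rule-based oracle for the separable toy: marker suffix => positive."""
    return {
        tok.key: int(tok.surface.endswith(MARKER_SUFFIX))
        for tok in corpus.instances()
    }


@pytest.fixture(scope="session")
def separable_corpus() -> Corpus:
    return make_separable_corpus()


@pytest.fixture(scope="session")
def small_synth() -> Corpus:
    """A quick-to-process synthetic corpus (~2400 tokens, alpha 0.05)."""
    return generate(SyntheticSpec(n_docs=40, tokens_per_doc=60,
                                  alpha_target=0.05, seed=11))


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def game() -> GameParams:
    return GameParams(L=10.0, C=1.0)
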