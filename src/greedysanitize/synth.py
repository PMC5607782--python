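"""Seeded synthetic corpora with the structure de-identification assumes.

Real de-identification corpora (clinical notes, email) share three traits
this generator reproduces: sensitive name tokens are rare (a few percent of
all tokens); some name surface forms are ambiguous, also occurring as
ordinary non-sensitive words (the pronoun-vs-surname problem); and context
cues (honorifics such as "Dr.") make many, but not all, occurrences
learnable.  The token stream itself is synthetic — syllable-sampled
vocabularies and cue templates, not natural language.

Defaults: 500 documents of ~200 tokens, 2% sensitive, 30% of the name
vocabulary ambiguous, honorific cue before 70% of sensitive tokens.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import Corpus, TokenInstance, confusion_counts

__all__ = ["SyntheticSpec", "generate", "fixture_example1"]

_SYLLABLES = [
    "ba", "be", "bo", "da", "de", "do", "ka", "ke", "ko", "la", "le", "lo",
    "ma", "me", "mo", "na", "ne", "no", "ra", "re", "ro", "sa", "se", "so",
    "ta", "te", "to", "va", "ve", "vi", "zu", "zi",
]
_CUES = ["Dr.", "Mr.", "Mrs.", "Ms.", "Prof."]
_FUNCTION_WORDS = [
    "the", "of", "and", "to", "in", "a", "is", "was", "for", "on", "with",
    "as", "at", "by", "he", "she", "it", "that", "this", "had", "has",
]
_PUNCT = [".", ",", ";", ":"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic corpus.

    alpha_target is the target fraction of sensitive tokens;
    ambiguity_rate the fraction of name surface forms that also occur as
    non-sensitive background tokens; context_cue_strength the probability
    that a sensitive token is preceded by an honorific cue.
    """

    n_docs: int = 500
    tokens_per_doc: int = 200
    alpha_target: float = 0.02
    ambiguity_rate: float = 0.3
    name_vocab_size: int = 400
    background_vocab_size: int = 2000
    context_cue_strength: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_docs < 1 or self.tokens_per_doc < 1:
            raise ValueError("n_docs and tokens_per_doc must be positive")
        if not 0 < self.alpha_target < 1:
            raise ValueError("alpha_target must be in (0, 1)")
        if not 0 <= self.ambiguity_rate <= 1:
            raise ValueError("ambiguity_rate must be in [0, 1]")
        if not 0 <= self.context_cue_strength <= 1:
            raise ValueError("context_cue_strength must be in [0, 1]")
        if self.name_vocab_size < 1 or self.background_vocab_size < 1:
            raise ValueError("vocabulary sizes must be positive")
        if self.alpha_target * self.n_docs * self.tokens_per_doc < 1:
            raise ValueError(
                "infeasible spec: alpha_target * expected corpus size < 1 "
                "sensitive token")


def _make_words(rng: np.random.Generator, count: int, n_syllables: int,
                capitalize: bool, taken: set[str]) -> list[str]:
    words: list[str] = []
    while len(words) < count:
        k = int(rng.integers(2, n_syllables + 1))
        w = "".join(rng.choice(_SYLLABLES, size=k))
        if capitalize:
            w = w.capitalize()
        if w in taken:
            continue
        taken.add(w)
        words.append(w)
    return words


def generate(spec: SyntheticSpec, seed: int | None = None) -> Corpus:
    """Generate a fully labeled corpus from the spec (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    taken: set[str] = set(_FUNCTION_WORDS) | set(_CUES)
    names = _make_words(rng, spec.name_vocab_size, 3, True, taken)
    background = _make_words(rng, spec.background_vocab_size, 4, False, taken)

    n_ambiguous = int(round(spec.ambiguity_rate * spec.name_vocab_size))
    ambiguous = names[:n_ambiguous]

    # Zipf-like background distribution over function + content words.
    bg_vocab = _FUNCTION_WORDS + background
    ranks = np.arange(1, len(bg_vocab) + 1, dtype=float)
    bg_p = (1.0 / ranks) / np.sum(1.0 / ranks)

    # Each sensitive event emits 1 + cue_strength tokens on average; the
    # per-slot rate is corrected so the realized fraction hits the target.
    p_sens = spec.alpha_target / (1 - spec.alpha_target * spec.context_cue_strength)
    amb_mass = 0.05 if ambiguous else 0.0  # share of background slots

    documents: list[list[TokenInstance]] = []
    for d in range(spec.n_docs):
        target_len = max(2, int(rng.poisson(spec.tokens_per_doc)))
        surfaces: list[str] = []
        labels: list[int] = []
        while len(surfaces) < target_len:
            u = rng.random()
            if u < p_sens:
                if rng.random() < spec.context_cue_strength:
                    surfaces.append(str(rng.choice(_CUES)))
                    labels.append(0)
                surfaces.append(str(rng.choice(names)))
                labels.append(1)
            else:
                v = rng.random()
                if v < amb_mass:
                    surfaces.append(str(rng.choice(ambiguous)))
                elif v < amb_mass + 0.08:
                    surfaces.append(str(rng.choice(_PUNCT)))
                elif v < amb_mass + 0.10:
                    surfaces.append(str(rng.integers(0, 2030)))
                else:
                    surfaces.append(str(rng.choice(bg_vocab, p=bg_p)))
                labels.append(0)
        doc = [
            TokenInstance(surface=s, doc_id=f"d{d}", position=i, label=lab)
            for i, (s, lab) in enumerate(zip(surfaces, labels))
        ]
        documents.append(doc)
    return Corpus(documents)


def fixture_example1() -> tuple[Corpus, dict[tuple[str, int], int]]:
    """The packaged 26-token worked example with fixed predictions.

    A single short document with 5 sensitive name tokens and a fixed
    prediction map realizing attacker confusion counts
    (TP=3, FP=6, TN=15, FN=2).  The surface "He" occurs both as a pronoun
    (non-sensitive, but predicted positive — a false positive) and as a
    person's name (sensitive).
    """
    # (surface, label S(x), prediction h_A(x))
    rows: list[tuple[str, int, int]] = [
        ("Dr.",      0, 0),
        ("Rebama",   1, 1),   # TP
        ("saw",      0, 0),
        ("the",      0, 0),
        ("patient",  0, 0),
        ("He",       0, 1),   # FP: pronoun predicted as name
        ("was",      0, 0),
        ("seen",     0, 0),
        ("by",       0, 0),
        ("nurse",    0, 0),
        ("Lovato",   1, 1),   # TP
        ("and",      0, 0),
        ("Mr.",      0, 1),   # FP
        ("He",       1, 1),   # TP: surname of the patient
        ("at",       0, 0),
        ("Mercy",    0, 1),   # FP
        ("General",  0, 1),   # FP
        ("Hospital", 0, 1),   # FP
        (".",        0, 0),
        ("Visit",    0, 0),
        ("with",     0, 0),
        ("daughter", 0, 0),
        ("Selena",   1, 0),   # FN
        ("today",    0, 0),
        ("Karim",    1, 0),   # FN
        (".",        0, 1),   # FP
    ]
    doc = [
        TokenInstance(surface=s, doc_id="ex1", position=i, label=lab)
        for i, (s, lab, _) in enumerate(rows)
    ]
    corpus = Corpus([doc])
    predictions = {("ex1", i): pred for i, (_, _, pred) in enumerate(rows)}
    counts = confusion_counts(predictions, corpus.instances())
    assert counts == (3, 6, 15, 2), counts
    return corpus, predictions
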