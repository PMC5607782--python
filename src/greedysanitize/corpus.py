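"""Token corpus data model and CoNLL-style readers/writers.

The unit of sanitization is the token: a corpus is an ordered collection of
documents, each an ordered list of :class:`TokenInstance`.  Labels are binary
(1 = sensitive, e.g. a personal name in a clinical note; 0 = non-sensitive).
The exchange format is a two-column TSV — ``<token>\\t<SENS|O>`` — with blank
lines separating documents; the published (redacted) dialect is the same
layout without the label column, with suppressed tokens replaced by a
bracketed placeholder such as ``[NAME]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple

__all__ = [
    "TokenInstance",
    "Corpus",
    "ConfusionCounts",
    "CorpusFormatError",
    "DEFAULT_PLACEHOLDER",
    "read_corpus",
    "write_corpus",
    "write_published",
    "confusion_counts",
]

DEFAULT_PLACEHOLDER = "[NAME]"

#: Labels used in the two-column exchange format.
_LABEL_TO_INT = {"SENS": 1, "O": 0}
_INT_TO_LABEL = {1: "SENS", 0: "O"}


class CorpusFormatError(ValueError):
    """Raised for malformed corpus files (wrong column count, mixed dialects)."""


@dataclass(frozen=True)
class TokenInstance:
    """One classification unit: a word occurrence at a fixed document position.

    Parameters
    ----------
    surface : str
        The token's surface form as written.
    doc_id : str
        Identifier of the containing document.
    position : int
        0-based index within the document; unique per document.
    label : int or None
        True sensitivity S(x): 1 if the token is a sensitive identifier,
        0 otherwise; None for unannotated corpora.
    redaction : str or None
        Placeholder that replaces the surface in published output when the
        token has been suppressed (e.g. ``[NAME]``); None if not redacted.
    """

    surface: str
    doc_id: str
    position: int
    label: int | None = None
    redaction: str | None = None

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"position must be >= 0, got {self.position}")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")

    @property
    def key(self) -> tuple[str, int]:
        """Globally unique (doc_id, position) identifier."""
        return (self.doc_id, self.position)

    @property
    def published_surface(self) -> str:
        """Surface as it appears after publishing (placeholder if redacted)."""
        return self.redaction if self.redaction is not None else self.surface


class ConfusionCounts(NamedTuple):
    """TP/FP/TN/FN of a binary classifier (or classifier set) on a data set."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else 1.0

    @property
    def n_positive(self) -> int:
        """Number of truly sensitive instances in the scored set."""
        return self.tp + self.fn

    @property
    def n_predicted_positive(self) -> int:
        return self.tp + self.fp


@dataclass
class Corpus:
    """Ordered documents of tokens; the universe X of instances.

    ``n`` is the total token count and ``alpha`` the sensitive fraction
    (defined only when every token is labeled).
    """

    documents: list[list[TokenInstance]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for doc in self.documents:
            for tok in doc:
                if tok.key in seen:
                    raise ValueError(f"duplicate (doc_id, position): {tok.key}")
                seen.add(tok.key)

    # -- basic accessors -------------------------------------------------

    @property
    def n(self) -> int:
        return sum(len(doc) for doc in self.documents)

    @property
    def n_documents(self) -> int:
        return len(self.documents)

    def instances(self) -> Iterator[TokenInstance]:
        for doc in self.documents:
            yield from doc

    def __len__(self) -> int:
        return self.n

    def __iter__(self) -> Iterator[TokenInstance]:
        return self.instances()

    @property
    def is_labeled(self) -> bool:
        return all(tok.label is not None for tok in self.instances())

    @property
    def sensitive_count(self) -> int:
        if not self.is_labeled:
            raise ValueError("sensitive_count requires a fully labeled corpus")
        return sum(tok.label for tok in self.instances())  # type: ignore[misc]

    @property
    def alpha(self) -> float:
        """Fraction of sensitive instances; requires full labels."""
        if self.n == 0:
            return 0.0
        return self.sensitive_count / self.n

    def labels(self) -> dict[tuple[str, int], int]:
        """Map (doc_id, position) -> S(x) for all labeled tokens."""
        return {
            tok.key: tok.label
            for tok in self.instances()
            if tok.label is not None
        }

    def by_key(self) -> dict[tuple[str, int], TokenInstance]:
        return {tok.key: tok for tok in self.instances()}

    @property
    def redacted_keys(self) -> set[tuple[str, int]]:
        return {tok.key for tok in self.instances() if tok.redaction is not None}

    # -- construction helpers --------------------------------------------

    @classmethod
    def from_tokens(
        cls,
        docs: Iterable[Iterable[tuple[str, int | None]]],
        doc_ids: Iterable[str] | None = None,
    ) -> "Corpus":
        """Build a corpus from per-document (surface, label) pairs."""
        docs = list(docs)
        ids = list(doc_ids) if doc_ids is not None else [f"d{i}" for i in range(len(docs))]
        documents = [
            [
                TokenInstance(surface=s, doc_id=did, position=i, label=lab)
                for i, (s, lab) in enumerate(doc)
            ]
            for did, doc in zip(ids, docs)
        ]
        return cls(documents)

    def subset_documents(self, indices: Iterable[int]) -> "Corpus":
        """New corpus holding the selected documents (by index, in given order)."""
        return Corpus([self.documents[i] for i in indices])

    def redact(
        self,
        keys: Iterable[tuple[str, int]],
        placeholder: str = DEFAULT_PLACEHOLDER,
    ) -> "Corpus":
        """Return a copy with the given instances marked redacted.

        Redaction is placeholder replacement, not deletion: token count and
        document boundaries are preserved.
        """
        keyset = set(keys)
        known = {tok.key for tok in self.instances()}
        unknown = keyset - known
        if unknown:
            raise KeyError(f"unknown (doc_id, position) keys: {sorted(unknown)[:5]}")
        documents = [
            [
                replace(tok, redaction=placeholder) if tok.key in keyset else tok
                for tok in doc
            ]
            for doc in self.documents
        ]
        return Corpus(documents)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_corpus(path: str | Path, labeled: bool = True) -> Corpus:
    """Read a blank-line-separated token corpus.

    Labeled dialect: ``<token>\\t<SENS|O>`` per line.  Unlabeled/published
    dialect: one token per line.  Documents are split on blank lines.
    """
    path = Path(path)
    documents: list[list[TokenInstance]] = []
    current: list[TokenInstance] = []
    doc_idx = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                if current:
                    documents.append(current)
                    current = []
                    doc_idx += 1
                continue
            fields = line.split("\t")
            if labeled:
                if len(fields) != 2:
                    raise CorpusFormatError(
                        f"{path}:{lineno}: expected 2 tab-separated fields "
                        f"(token, SENS|O), got {len(fields)}"
                    )
                surface, lab = fields
                if lab not in _LABEL_TO_INT:
                    raise CorpusFormatError(
                        f"{path}:{lineno}: unknown label {lab!r} (expected SENS or O)"
                    )
                tok = TokenInstance(
                    surface=surface,
                    doc_id=f"d{doc_idx}",
                    position=len(current),
                    label=_LABEL_TO_INT[lab],
                )
            else:
                if len(fields) != 1:
                    raise CorpusFormatError(
                        f"{path}:{lineno}: expected 1 field (token), got {len(fields)}"
                    )
                surface = fields[0]
                # Bracketed category tokens in published files are redaction
                # placeholders; keep them marked so consumers (e.g. the
                # attacker simulation) exclude them from inspectable text.
                is_placeholder = (len(surface) > 2 and surface.startswith("[")
                                  and surface.endswith("]"))
                tok = TokenInstance(
                    surface=surface,
                    doc_id=f"d{doc_idx}",
                    position=len(current),
                    redaction=surface if is_placeholder else None,
                )
            current.append(tok)
    if current:
        documents.append(current)
    return Corpus(documents)


def write_corpus(corpus: Corpus, path: str | Path) -> Path:
    """Write the labeled two-column dialect (canonical form)."""
    path = Path(path)
    lines: list[str] = []
    for doc in corpus.documents:
        for tok in doc:
            if tok.label is None:
                raise ValueError(f"token {tok.key} has no label; use write_published")
            lines.append(f"{tok.surface}\t{_INT_TO_LABEL[tok.label]}")
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")
    return path


def write_published(
    corpus: Corpus,
    path: str | Path,
    redacted_ids: Iterable[tuple[str, int]] = (),
    placeholder: str = DEFAULT_PLACEHOLDER,
) -> Path:
    """Write the one-column published dialect with redactions applied.

    ``redacted_ids`` are applied on top of any redactions already marked on
    the corpus; every id must exist in the corpus.
    """
    path = Path(path)
    redacted = corpus.redact(redacted_ids, placeholder) if redacted_ids else corpus
    lines: list[str] = []
    for doc in redacted.documents:
        for tok in doc:
            lines.append(tok.published_surface)
        lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")
    return path


def confusion_counts(
    predictions: Mapping[tuple[str, int], int],
    subset: Iterable[TokenInstance],
) -> ConfusionCounts:
    """Confusion counts of a predictor over a set of labeled instances.

    Follows the set definitions: TP = predicted-1 among sensitive, FP =
    predicted-1 among non-sensitive, etc.; on the empty set all counts are 0.
    """
    tp = fp = tn = fn = 0
    for tok in subset:
        if tok.label is None:
            raise ValueError(f"instance {tok.key} has no label")
        try:
            pred = predictions[tok.key]
        except KeyError:
            raise ValueError(f"instance {tok.key} has no prediction") from None
        if pred not in (0, 1):
            raise ValueError(f"prediction for {tok.key} must be 0/1, got {pred!r}")
        if tok.label == 1:
            if pred == 1:
                tp += 1
            else:
                fn += 1
        else:
            if pred == 1:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
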