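"""Orthographic token features for sensitive-entity classification.

Features per token: surface identity and lowercase form, a capitalization
shape pattern, digit/punctuation flags, short prefixes and suffixes, and a
window of neighboring surfaces.  Part-of-speech information is approximated
by these orthographic and affix cues by default; a hook accepts precomputed
POS columns.  Label-history features are appended by the sequence learners
themselves (they depend on decoding order, not on the document alone).
"""

from __future__ import annotations

from typing import Mapping

from .corpus import Corpus, TokenInstance

__all__ = ["token_shape", "token_features", "extract_features", "PAD"]

PAD = "<PAD>"


def token_shape(surface: str) -> str:
    """Character-class pattern: X upper, x lower, d digit, else verbatim."""
    out = []
    for ch in surface:
        if ch.isupper():
            out.append("X")
        elif ch.islower():
            out.append("x")
        elif ch.isdigit():
            out.append("d")
        else:
            out.append(ch)
    return "".join(out)


def token_features(
    doc: list[TokenInstance],
    i: int,
    window: int = 2,
    affix_len: int = 3,
    pos: Mapping[tuple[str, int], str] | None = None,
) -> dict[str, str | bool]:
    """Feature dict for the token at position ``i`` of ``doc``.

    Deterministic function of the document and position.  Window features at
    document boundaries use the explicit padding symbol ``<PAD>``.
    """
    tok = doc[i]
    # Features are computed on the surface as visible to the consumer:
    # redacted tokens expose only their placeholder, never the original.
    s = tok.published_surface
    feats: dict[str, str | bool] = {
        "w": s,
        "lower": s.lower(),
        "shape": token_shape(s),
        "is_title": s.istitle(),
        "is_upper": s.isupper() and len(s) > 1,
        "is_digit": s.isdigit(),
        "has_digit": any(c.isdigit() for c in s),
        "is_punct": all(not c.isalnum() for c in s) and bool(s),
    }
    for k in range(1, affix_len + 1):
        feats[f"pre{k}"] = s[:k]
        feats[f"suf{k}"] = s[-k:]
    for off in range(-window, window + 1):
        if off == 0:
            continue
        j = i + off
        neighbor = doc[j].published_surface if 0 <= j < len(doc) else PAD
        feats[f"w[{off:+d}]"] = neighbor
        feats[f"lower[{off:+d}]"] = neighbor.lower()
    if pos is not None:
        feats["pos"] = pos.get(tok.key, PAD)
        if i > 0:
            feats["pos[-1]"] = pos.get(doc[i - 1].key, PAD)
    return feats


def extract_features(
    corpus: Corpus,
    window: int = 2,
    affix_len: int = 3,
    pos: Mapping[tuple[str, int], str] | None = None,
) -> dict[tuple[str, int], dict[str, str | bool]]:
    """One feature dict per token, keyed by (doc_id, position)."""
    out: dict[tuple[str, int], dict[str, str | bool]] = {}
    for doc in corpus.documents:
        for i in range(len(doc)):
            out[doc[i].key] = token_features(doc, i, window=window,
                                             affix_len=affix_len, pos=pos)
    return out
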