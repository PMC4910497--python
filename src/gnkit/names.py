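"""Name-string container and Unicode normalization.

A *name-string* is the literal sequence of characters, digits and spaces
used as a label for a taxon.  Normalization here is deliberately timid: it
applies Unicode NFC, trims, and collapses internal whitespace runs, and
does nothing else.  In particular it never folds lookalike codepoints
together — a Cyrillic 'а' stays distinct from a Latin 'a', which is what
makes content-derived identifiers able to expose such lookalikes.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass

_WS_RUN = re.compile(r"\s+")


def normalize(raw: str) -> str:
    """NFC-normalize, trim, and collapse internal whitespace of *raw*."""
    text = unicodedata.normalize("NFC", raw)
    return _WS_RUN.sub(" ", text).strip()


@dataclass(frozen=True)
class NameString:
    """A raw name-string plus its whitespace/NFC-normalized form."""

    raw: str
    normalized: str

    @classmethod
    def of(cls, raw: str) -> "NameString":
        return cls(raw=raw, normalized=normalize(raw))

    def __str__(self) -> str:  # pragma: no cover - convenience only
        return self.normalized
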