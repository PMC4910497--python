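"""Canonical forms of parsed names.

Two latinized reductions are produced.  The *complete* canonical keeps all
latinized elements — subgenus, rank markers, the ``Candidatus`` prefix.
The *standard* canonical keeps only the elements required by the codes of
nomenclature: genus (or uninomial), specific epithet and infraspecific
epithets.  For a bare subgeneric combination (``Aaleniella (Danocythere)``)
the standard form is the subgenus name itself, since the subgenus is the
code-relevant name in that combination.

The *match key* is the standard form lower-cased with hyphens, hybrid
signs and diacritics removed; it is the string actually compared during
cross-mapping, so that ``Indigofera roseo-caerulea`` and ``Indigofera
roseocaerulea`` collide while the standard canonicals keep the code-legal
hyphen.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass

from .names import NameString
from .parser import QUALITY_UNPARSEABLE, ParsedName, parse


class CanonicalizationError(ValueError):
    """Raised when no canonical form exists (unparseable input)."""


@dataclass(frozen=True)
class CanonicalForm:
    complete: str
    standard: str
    match_key: str


_HYBRID_CHARS = re.compile(r"[×хХ]|(?:(?<=\s)|^)[xX](?=\s|$)")


def strip_diacritics(text: str) -> str:
    """Transliterate to ASCII by dropping combining marks (é -> e)."""
    decomposed = unicodedata.normalize("NFKD", text)
    return "".join(c for c in decomposed if not unicodedata.combining(c))


def make_match_key(standard: str) -> str:
    """Lower-case, hyphen-free, hybrid-sign-free, ASCII-folded key."""
    key = _HYBRID_CHARS.sub("", standard)
    key = strip_diacritics(key).lower().replace("-", "")
    return " ".join(key.split())


def canonicalize(parsed: ParsedName) -> CanonicalForm:
    """Build complete and standard canonicals from a parsed name."""
    if parsed.quality == QUALITY_UNPARSEABLE or parsed.head is None:
        raise CanonicalizationError("no canonical form exists for an unparseable name")

    complete_parts: list[str] = []
    if parsed.candidatus_flag:
        complete_parts.append("Candidatus")
    complete_parts.append(parsed.head)
    if parsed.subgenus:
        complete_parts.append(f"({parsed.subgenus})")
    if parsed.specific_epithet:
        complete_parts.append(parsed.specific_epithet)
    for marker, epithet in parsed.infraspecific_parts:
        if marker:
            complete_parts.append(marker)
        complete_parts.append(epithet)

    standard_parts: list[str] = []
    if parsed.specific_epithet is None and not parsed.infraspecific_parts and parsed.subgenus:
        # bare subgeneric combination: the subgenus is the standard name
        standard_parts.append(parsed.subgenus)
    else:
        standard_parts.append(parsed.head)
        if parsed.specific_epithet:
            standard_parts.append(parsed.specific_epithet)
        standard_parts.extend(ep for _, ep in parsed.infraspecific_parts)

    standard = " ".join(standard_parts)
    return CanonicalForm(
        complete=" ".join(complete_parts),
        standard=standard,
        match_key=make_match_key(standard),
    )


def match_key(canonical: CanonicalForm) -> str:
    return canonical.match_key


def canonicalize_string(raw: str) -> CanonicalForm:
    """Parse and canonicalize a raw name-string in one step."""
    return canonicalize(parse(NameString.of(raw)))
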