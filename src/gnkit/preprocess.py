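"""Rule-driven repair of idiosyncratic name-strings before parsing.

Uncurated checklists concatenate genus and species with interpolated
separators (``Triticum_aestivum``, ``Danio0reri``, ``LissXtimor``),
truncate names to 10 characters, append accession numbers, or mangle the
case.  The preprocessor applies an ordered, editable list of regex rules
that split concatenations, strip trailing separators and accession-like
tokens, and repair case — and only that.  It never expands a truncated
epithet (``Danio reri`` is not rewritten to ``Danio rerio``): expansion
without the source's own translation table is guessing, and fuzzy
matching downstream handles it with an explicit edit distance instead.

Strings with no capital and no separator (``corbulasulcata``) cannot be
split without a dictionary and are marked unresolvable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .config import load_default, load_yaml
from .names import NameString, normalize

FLAG_DECONCATENATED = "deconcatenated"
FLAG_TRUNCATED = "truncated_suspect"
FLAG_CASE_REPAIRED = "case_repaired"
FLAG_TAIL_STRIPPED = "tail_stripped"

#: First tokens never promoted to a genus by case repair.
_CASE_STOP_WORDS = frozenset(
    load_default("parser_vocab.yaml")["recovery_stop_words"]
)


@dataclass(frozen=True)
class PreprocessRule:
    id: str
    pattern: str
    replacement: str = ""
    action: str = "sub"
    flags: tuple[str, ...] = ()

    def apply(self, text: str) -> str:
        rx = re.compile(self.pattern)
        if self.action == "sub":
            return rx.sub(self.replacement, text)
        if not rx.search(text):
            return text
        if self.action == "capitalize":
            return text.capitalize()
        if self.action == "capitalize_genus":
            head, _, rest = text.partition(" ")
            if head.lower() in _CASE_STOP_WORDS:
                return text
            return head.capitalize() + (" " + rest if rest else "")
        if self.action == "lower_epithet":
            head, _, rest = text.partition(" ")
            return head + (" " + rest.lower() if rest else "")
        raise ValueError(f"unknown rule action: {self.action!r}")


@dataclass
class PreprocessResult:
    original: str
    repaired: str
    flags: set[str] = field(default_factory=set)
    unresolvable: bool = False
    applied: list[str] = field(default_factory=list)


def load_rules(path: str | None = None) -> list[PreprocessRule]:
    """Load repair rules from YAML (packaged defaults when *path* is None)."""
    raw = load_yaml(path, "preprocess_rules.yaml")
    rules = []
    for entry in raw:
        rules.append(
            PreprocessRule(
                id=entry["id"],
                pattern=entry["pattern"],
                replacement=entry.get("replacement", ""),
                action=entry.get("action", "sub"),
                flags=tuple(entry.get("flags", ())),
            )
        )
    return rules


_default_rules: list[PreprocessRule] | None = None


def default_rules() -> list[PreprocessRule]:
    global _default_rules
    if _default_rules is None:
        _default_rules = load_rules(None)
    return _default_rules


def preprocess(name: NameString | str, rules: list[PreprocessRule] | None = None) -> PreprocessResult:
    """Repair *name* with the ordered *rules*; never raises."""
    if isinstance(name, str):
        name = NameString.of(name)
    if rules is None:
        rules = default_rules()
    if not rules:
        raise ValueError("rules must be nonempty")

    original = name.normalized
    text = original
    result = PreprocessResult(original=original, repaired=original)
    for rule in rules:
        repaired = rule.apply(text)
        if repaired != text:
            result.applied.append(rule.id)
            result.flags.update(rule.flags)
            text = normalize(repaired)
    result.repaired = text

    if len(result.repaired) == 10:
        result.flags.add(FLAG_TRUNCATED)
    if result.repaired and " " not in result.repaired \
            and not any(c.isupper() for c in result.repaired) \
            and result.repaired.isalpha():
        result.unresolvable = True
    if not result.repaired:
        result.unresolvable = True
    return result
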