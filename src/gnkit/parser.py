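"""Scientific-name parsing: decompose a name-string into semantic parts.

The parser is *total*: any byte-valid input yields a :class:`ParsedName`,
degrading gracefully through three quality grades — ``clean`` (every token
accounted for), ``with_tail`` (a latinized core was found but unrecognized
tokens remain), and ``unparseable`` (no latinized core at all).

Rank interpretation is positional: one latinized token is a uninomial, two
are genus + specific epithet, three or more add infraspecific epithets.
Rank markers (``ssp.``, ``var.``, ``f.`` …) attach to the epithet that
follows them.  Authorship — combination authors and years, parenthesized
basionym authors, ``ex`` authors — is recognised heuristically and kept
verbatim as well as decomposed.

Names that lack the leading capital (``litoria ewingii``) get a recovery
pass that retries with the first letter capitalized and flags the repair;
the pass is restricted to multi-token latinate strings so that plain
English words are not promoted to genera.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .config import load_default
from .names import NameString

QUALITY_CLEAN = "clean"
QUALITY_WITH_TAIL = "with_tail"
QUALITY_UNPARSEABLE = "unparseable"

#: Codepoints that act as a hybrid sign when standing alone between
#: tokens: the multiplication sign, Latin x/X, Cyrillic х/Х.
HYBRID_SIGNS = {"×", "x", "X", "х", "Х"}

_CAP_WORD = re.compile(r"^[A-Z][a-zà-öø-ÿ]+(?:-[a-zà-öø-ÿ]+)*$")
_ALLCAP_WORD = re.compile(r"^[A-Z]{2,}$")
_LOWER_WORD = re.compile(r"^[a-zà-öø-ÿ]+(?:-[a-zà-öø-ÿ]+)*$")
_BRACKET_GENUS = re.compile(r"^\[([A-Z][a-zà-öø-ÿ]+)\]$")
_YEAR = re.compile(r"^\(?(\[?)(\d{4})\]?[\.,)]*$")
_AUTHOR_WORD = re.compile(r"^[A-ZÀ-Þ][A-Za-zÀ-ÿ'.-]*[\.,]*$")


@dataclass(frozen=True)
class Annotation:
    """A verbatim annotation token and the kind of signal it carries."""

    kind: str
    token: str


@dataclass
class Authorship:
    combination_authors: list[str] = field(default_factory=list)
    combination_year: Optional[int] = None
    basionym_authors: list[str] = field(default_factory=list)
    basionym_year: Optional[int] = None
    ex_authors: list[str] = field(default_factory=list)
    year_bracketed: bool = False
    verbatim: str = ""


@dataclass
class ParsedName:
    uninomial: Optional[str] = None
    genus: Optional[str] = None
    subgenus: Optional[str] = None
    specific_epithet: Optional[str] = None
    infraspecific_parts: list[tuple[Optional[str], str]] = field(default_factory=list)
    authorship: Optional[Authorship] = None
    annotations: list[Annotation] = field(default_factory=list)
    hybrid_flag: bool = False
    candidatus_flag: bool = False
    case_repaired: bool = False
    tail: str = ""
    quality: str = QUALITY_UNPARSEABLE

    @property
    def head(self) -> Optional[str]:
        """The leading latinized element (uninomial or genus)."""
        return self.genus if self.genus is not None else self.uninomial


class _Vocab:
    def __init__(self) -> None:
        raw = load_default("parser_vocab.yaml")
        self.rank_markers: set[str] = set(raw["rank_markers"])
        self.letter_rank_markers: set[str] = set(raw["letter_rank_markers"])
        self.annotations: dict[str, str] = {}
        for kind, tokens in raw["annotations"].items():
            for tok in tokens:
                self.annotations[tok] = kind
        self.lead_in_words: set[str] = set(raw["lead_in_words"])
        self.recovery_stop_words: set[str] = set(raw["recovery_stop_words"])
        self.author_connectors: set[str] = set(raw["author_connectors"])


_vocab: Optional[_Vocab] = None


def _get_vocab() -> _Vocab:
    global _vocab
    if _vocab is None:
        _vocab = _Vocab()
    return _vocab


def _split_hybrid_signs(text: str) -> str:
    """Detach a hybrid sign glued to the front of a word (``×Aranda``)."""
    return re.sub(r"(^|\s)([×хХ])(?=[A-Za-z])", r"\1\2 ", text)


def detect_hybrid(name: NameString) -> tuple[bool, list[str]]:
    """Recognize hybrid signs and return the component names of a formula.

    A leading sign marks a "natural hybrid" and yields one component; an
    infix sign between two capitalized name-like segments yields the
    formula components.  Lower-case segments after the first inherit the
    genus of the first segment (``Iris brevicaulis x fulva``).
    """
    tokens = _split_hybrid_signs(name.normalized).split()
    if not tokens:
        return False, []
    sign_positions = [i for i, t in enumerate(tokens) if t in HYBRID_SIGNS]
    if not sign_positions:
        return False, []
    segments: list[list[str]] = []
    current: list[str] = []
    for i, tok in enumerate(tokens):
        if i in sign_positions:
            if current:
                segments.append(current)
            current = []
        else:
            current.append(tok)
    if current:
        segments.append(current)
    segments = [s for s in segments if s]
    if not segments:
        return True, []
    if len(segments) == 1:
        return True, [" ".join(segments[0])]
    first = segments[0]
    genus = first[0] if _CAP_WORD.match(first[0]) else None
    # genus-only head + single lower-case continuation is one hybrid name
    if len(first) == 1 and genus and len(segments) == 2 and not _CAP_WORD.match(segments[1][0]):
        return True, [" ".join(first + segments[1])]
    components = []
    for seg in segments:
        if not _CAP_WORD.match(seg[0]) and genus:
            components.append(" ".join([genus] + seg))
        else:
            components.append(" ".join(seg))
    return True, components


def _is_year(tok: str) -> Optional[tuple[int, bool]]:
    m = _YEAR.match(tok)
    if not m:
        return None
    year = int(m.group(2))
    if 1700 <= year <= 2100:
        return year, bool(m.group(1))
    return None


def _author_surname(tok: str) -> str:
    return tok.strip(",()")


class _AuthorRun:
    """Accumulates candidate authorship tokens and validates them."""

    def __init__(self, vocab: _Vocab) -> None:
        self.vocab = vocab
        self.tokens: list[str] = []

    def accepts(self, tok: str) -> bool:
        core = tok.strip("(),")
        if core.lower() in self.vocab.author_connectors:
            return bool(self.tokens)  # connectors never start a run
        if core in {"&", "&amp;"}:
            return bool(self.tokens)
        if _is_year(core):
            return bool(self.tokens) or tok.startswith("(")
        return bool(_AUTHOR_WORD.match(core))

    def push(self, tok: str) -> None:
        self.tokens.append(tok)

    def is_valid(self) -> bool:
        """An authorship run must look like authors, not like an acronym.

        Accept when the run contains a period, an ampersand, a connector or
        a year; or when every token is a capitalized lower-case word.
        All-caps tokens alone (``CCUG``) are rejected.
        """
        if not self.tokens:
            return False
        joined = " ".join(self.tokens)
        if "." in joined or "&" in joined:
            return True
        for tok in self.tokens:
            if _is_year(tok):
                return True
            if tok.lower().strip(",") in self.vocab.author_connectors:
                return True
        return all(
            _CAP_WORD.match(t.strip(",")) or t.lower().strip(",") in self.vocab.author_connectors
            for t in self.tokens
        )

    def build(self) -> Authorship:
        auth = Authorship(verbatim=" ".join(self.tokens))
        in_basionym = False
        target_authors = auth.combination_authors
        pending_ex: list[str] = []
        pending_initials = ""
        for tok in self.tokens:
            stripped = tok.strip(",")
            opens = stripped.startswith("(")
            closes = ")" in stripped
            if opens:
                in_basionym = True
                target_authors = auth.basionym_authors
            core = stripped.strip("()")
            year = _is_year(core) or _is_year(tok)
            low = core.lower().rstrip(",")
            if year:
                value, bracketed = year
                if in_basionym:
                    auth.basionym_year = value
                else:
                    auth.combination_year = value
                auth.year_bracketed = auth.year_bracketed or bracketed
            elif low == "ex":
                # authors seen so far in this segment published "ex"
                pending_ex = list(target_authors)
                target_authors.clear()
            elif core in {"&", "&amp;"} or low in {"et", "and", "al.", "al"}:
                pass
            elif re.fullmatch(r"(?:[A-Z]\.)+", core) and not tok.strip(",").endswith(","):
                # initials: attach to the following surname ("A. Alves");
                # a trailing comma means a standalone author abbreviation
                pending_initials = core
            elif core:
                target_authors.append(
                    (pending_initials + " " + _author_surname(core)).strip()
                )
                pending_initials = ""
            if closes:
                if pending_initials:
                    target_authors.append(pending_initials)
                    pending_initials = ""
                in_basionym = False
                target_authors = auth.combination_authors
        if pending_initials:
            target_authors.append(pending_initials)
        if pending_ex:
            auth.ex_authors = pending_ex
        return auth


def _parse_tokens(tokens: list[str], vocab: _Vocab) -> ParsedName:
    parsed = ParsedName()
    tail: list[str] = []
    i = 0
    n = len(tokens)

    # leading hybrid sign => natural hybrid
    while i < n and tokens[i] in HYBRID_SIGNS:
        parsed.hybrid_flag = True
        parsed.annotations.append(Annotation("hybrid_sign", tokens[i]))
        i += 1

    # lead-in words carry no structure; they go to the tail
    while i < n and tokens[i].lower() in vocab.lead_in_words:
        tail.append(tokens[i])
        i += 1

    if i < n and tokens[i].strip("'\"") == "Candidatus":
        parsed.candidatus_flag = True
        parsed.annotations.append(Annotation("candidatus", tokens[i]))
        i += 1

    head = None
    if i < n:
        tok = tokens[i]
        m = _BRACKET_GENUS.match(tok)
        if m:
            head = m.group(1)
            parsed.annotations.append(Annotation("nom_status", tok))
            i += 1
        elif _CAP_WORD.match(tok.strip("'\"")):
            head = tok.strip("'\"")
            i += 1
    if head is None:
        parsed.tail = " ".join(tokens)
        parsed.quality = QUALITY_UNPARSEABLE
        return parsed
    parsed.uninomial = head

    # optional subgenus: a single parenthesized capitalized word
    if i < n:
        m = re.match(r"^\(([A-Z][a-zà-öø-ÿ-]+)\)$", tokens[i])
        if m:
            parsed.subgenus = m.group(1)
            i += 1

    run = _AuthorRun(vocab)
    segments: list[_AuthorRun] = []

    def flush() -> None:
        nonlocal run
        if run.tokens:
            if run.is_valid():
                segments.append(run)
            else:
                tail.extend(run.tokens)
            run = _AuthorRun(vocab)

    structure_open = True  # more epithets may still be attached
    while i < n:
        tok = tokens[i]
        bare = tok.strip("'\"")
        low = bare.lower()
        nxt = tokens[i + 1].strip("'\"") if i + 1 < n else None
        if tok in HYBRID_SIGNS:
            flush()
            parsed.hybrid_flag = True
            parsed.annotations.append(Annotation("hybrid_sign", tok))
            i += 1
            # a capitalized token after the sign starts a second formula
            # component, which is out of scope for this single parse
            if nxt and _CAP_WORD.match(nxt):
                tail.extend(tokens[i:])
                break
            continue
        if structure_open and bare in vocab.rank_markers and nxt and _LOWER_WORD.match(nxt) \
                and nxt not in vocab.annotations:
            flush()
            parsed.infraspecific_parts.append((bare, nxt))
            i += 2
            continue
        if structure_open and parsed.specific_epithet and bare in vocab.letter_rank_markers \
                and nxt and _LOWER_WORD.match(nxt) and nxt not in vocab.annotations:
            flush()
            parsed.infraspecific_parts.append((bare, nxt))
            i += 2
            continue
        if bare in vocab.annotations:
            flush()
            parsed.annotations.append(Annotation(vocab.annotations[bare], tok))
            if vocab.annotations[bare] == "strain_marker":
                # everything after a strain marker is surrogate tail
                tail.extend(tokens[i + 1:])
                i = n
                structure_open = False
                continue
            i += 1
            continue
        if structure_open and not run.tokens and _LOWER_WORD.match(low) and bare == low \
                and len(bare) >= 2 and low not in vocab.author_connectors:
            if parsed.specific_epithet is None:
                parsed.specific_epithet = bare
            else:
                parsed.infraspecific_parts.append((None, bare))
            i += 1
            continue
        if run.accepts(tok):
            run.push(tok)
            i += 1
            continue
        flush()
        tail.extend(tokens[i:])
        structure_open = False
        break
    flush()

    if segments:
        # the last authorship segment is the authorship of the terminal
        # epithet, i.e. of the name as a whole; earlier segments are kept
        # verbatim so no token is lost
        parsed.authorship = segments[-1].build()
        parsed.authorship.verbatim = " ".join(
            t for seg in segments for t in seg.tokens
        )

    if parsed.specific_epithet is not None:
        parsed.genus = parsed.uninomial
        parsed.uninomial = None
    parsed.tail = " ".join(tail)
    parsed.quality = QUALITY_WITH_TAIL if parsed.tail else QUALITY_CLEAN
    return parsed


def parse(name: NameString) -> ParsedName:
    """Parse a name-string into its semantic components.  Total: never raises."""
    vocab = _get_vocab()
    text = _split_hybrid_signs(name.normalized)
    tokens = text.split()
    if not tokens:
        return ParsedName(quality=QUALITY_UNPARSEABLE, tail="")
    parsed = _parse_tokens(tokens, vocab)
    if parsed.quality != QUALITY_UNPARSEABLE:
        return parsed
    # recovery pass: lower-cased genus ("litoria ewingii"); multi-token
    # latinate strings only, so plain words are not promoted to genera
    first = tokens[0]
    if (
        len(tokens) >= 2
        and _LOWER_WORD.match(first)
        and len(first) >= 3
        and first not in vocab.recovery_stop_words
        and _LOWER_WORD.match(tokens[1])
        and tokens[1] not in vocab.annotations
    ):
        retry = _parse_tokens([first.capitalize()] + tokens[1:], vocab)
        if retry.genus is not None:
            retry.case_repaired = True
            return retry
    return parsed


def parse_string(raw: str) -> ParsedName:
    """Convenience wrapper: normalize and parse a raw string."""
    return parse(NameString.of(raw))
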