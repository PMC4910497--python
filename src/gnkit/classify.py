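"""Classification of name-strings by usefulness for interconnecting data.

Every name-string gets exactly one major class: the clade classes
(species, genus, infraspecies, higher) for latinized scientific names,
``virus``, ``common_name``, ``hybrid``, ``symbiont`` and ``negated`` for
strings that need special handling, and ``not_useful`` — with a minor
subclass — for strings carrying no discoverable taxon at all (acronyms,
environmental samples, numbered codes, unexpanded concatenations …).

Cue priority is fixed: virus > hybrid > symbiont > negated > clade >
common name > not useful.  Virus outranks everything because virus
strings frequently embed a host binomial; a latinized clade class is only
assigned when the tokens are genuinely latinate — a plain-language word
in the vocabulary disqualifies a token from being a genus or epithet,
which is what keeps ``Maltese cross`` out of the species class.

Soft negations (cf., aff., nr.) negate the species but may leave a
usable genus; hard negations (non, nec, not, null) negate the record.
Every decision cites its evidence: the vocabulary terms or the parse
structure that produced it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .config import load_yaml
from .names import NameString
from .parser import ParsedName, QUALITY_UNPARSEABLE, parse

MAJOR_CLASSES = (
    "clade_species",
    "clade_genus",
    "clade_infraspecies",
    "clade_higher",
    "virus",
    "common_name",
    "hybrid",
    "symbiont",
    "negated",
    "not_useful",
)

MINOR_CLASSES = (
    "too_fuzzy",
    "no_genus",
    "numbered",
    "environmental",
    "concatenated_unresolved",
    "abbreviated",
    "strain_surrogate",
    "acronym",
    "organelle",
    "plasmid",
    "molecular",
)


@dataclass(frozen=True)
class NameClassification:
    major: str
    minor: Optional[str] = None
    evidence: tuple[str, ...] = ()


@dataclass
class Vocabulary:
    """Loaded classifier vocabularies (see ``data/vocabularies.yaml``)."""

    virus_terms: set[str] = field(default_factory=set)
    virus_suffixes: tuple[str, ...] = ()
    virus_acronym: Optional[re.Pattern] = None
    virus_prefix: Optional[re.Pattern] = None
    hybrid_terms: set[str] = field(default_factory=set)
    symbiont_terms: set[str] = field(default_factory=set)
    symbiont_phrases: tuple[str, ...] = ()
    hard_negation_kinds: set[str] = field(default_factory=set)
    soft_negation_kinds: set[str] = field(default_factory=set)
    environmental_terms: set[str] = field(default_factory=set)
    english_words: set[str] = field(default_factory=set)
    strain_terms: set[str] = field(default_factory=set)
    organelle_terms: set[str] = field(default_factory=set)
    plasmid_terms: set[str] = field(default_factory=set)
    molecular_terms: set[str] = field(default_factory=set)
    acronym_pattern: Optional[re.Pattern] = None
    higher_rank_suffixes: tuple[str, ...] = ()

    @classmethod
    def load(cls, path: str | None = None) -> "Vocabulary":
        raw = load_yaml(path, "vocabularies.yaml")
        return cls(
            virus_terms=set(raw["virus_terms"]),
            virus_suffixes=tuple(raw["virus_suffixes"]),
            virus_acronym=re.compile(raw["virus_acronym_pattern"]),
            virus_prefix=re.compile(raw["virus_prefix_pattern"]),
            hybrid_terms=set(raw["hybrid_terms"]),
            symbiont_terms=set(raw["symbiont_terms"]),
            symbiont_phrases=tuple(raw["symbiont_phrases"]),
            hard_negation_kinds=set(raw["hard_negation_kinds"]),
            soft_negation_kinds=set(raw["soft_negation_kinds"]),
            environmental_terms=set(raw["environmental_terms"]),
            english_words=set(raw["english_words"]),
            strain_terms=set(raw["strain_terms"]),
            organelle_terms=set(raw["organelle_terms"]),
            plasmid_terms=set(raw["plasmid_terms"]),
            molecular_terms=set(raw["molecular_terms"]),
            acronym_pattern=re.compile(raw["acronym_pattern"]),
            higher_rank_suffixes=tuple(raw["higher_rank_suffixes"]),
        )


_default_vocab: Optional[Vocabulary] = None


def default_vocabulary() -> Vocabulary:
    global _default_vocab
    if _default_vocab is None:
        _default_vocab = Vocabulary.load(None)
    return _default_vocab


_ABBREV = re.compile(r"^[A-Z][a-z]{0,3}\.? [a-z][a-z.-]+")
_NEGATION_WORDS = {"non", "nec", "not", "null"}
_SP_JOIN = re.compile(r"\bsp\.?\s+(?:ex|from|of)\b", re.IGNORECASE)

#: Epithet endings accepted when the parse rested on a case repair: the
#: capitalization was our own invention, so the epithet itself must look
#: convincingly latinate before a clade class is assigned.
_LATINATE_ENDINGS = (
    "a", "um", "us", "is", "ii", "i", "ae", "e", "es", "ix", "ans", "ens",
    "ensis", "oides", "atus", "ata", "atum", "alis", "ale", "aris", "inus",
    "ina", "inum", "icus", "ica", "icum", "osus", "osa", "osum", "ianus",
    "iana", "ianum", "ella", "ellus", "ellum", "ifer", "iger", "oni", "arum",
)

#: Endings that mark a bare epithet rather than an unseparated
#: concatenation of genus and species.
_EPITHET_ONLY_ENDINGS = ("ensis", "oides", "issimus", "issima")


def _tokens(text: str) -> list[str]:
    return [t.strip("'\",;()[]") for t in text.split()]


def _latinate(token: str, vocab: Vocabulary) -> bool:
    """A token counts as latinized only if it is not a plain-language word."""
    if token.lower() in vocab.english_words:
        return False
    # names with two or more hyphens are phrases, not genera
    return token.count("-") < 2


def _epithet_convincing(epithet: str) -> bool:
    return epithet.lower().endswith(_LATINATE_ENDINGS)


def classify(
    parsed: ParsedName,
    raw: NameString | str,
    vocab: Vocabulary | None = None,
) -> NameClassification:
    """Assign exactly one major class (and a minor for not-useful strings)."""
    if isinstance(raw, str):
        raw = NameString.of(raw)
    if vocab is None:
        vocab = default_vocabulary()

    text = raw.normalized
    lower = text.lower()
    toks = _tokens(text)
    low_toks = [t.lower() for t in toks]
    evidence: list[str] = []

    # --- virus -----------------------------------------------------------
    for tok, low in zip(toks, low_toks):
        if any(term in low for term in vocab.virus_terms):
            evidence.append(tok)
        elif any(low.endswith(sfx) for sfx in vocab.virus_suffixes):
            evidence.append(tok)
        elif vocab.virus_acronym and vocab.virus_acronym.fullmatch(tok):
            evidence.append(tok)
        elif vocab.virus_prefix and vocab.virus_prefix.match(tok):
            evidence.append(tok)
    if evidence:
        return NameClassification("virus", evidence=tuple(evidence))

    # --- hybrid ----------------------------------------------------------
    if parsed.hybrid_flag:
        return NameClassification("hybrid", evidence=("hybrid_sign",))
    for low in low_toks:
        if low in vocab.hybrid_terms:
            return NameClassification("hybrid", evidence=(low,))

    # --- symbiont --------------------------------------------------------
    for low in low_toks:
        if low in vocab.symbiont_terms:
            return NameClassification("symbiont", evidence=(low,))
    for phrase in vocab.symbiont_phrases:
        if phrase in lower:
            return NameClassification("symbiont", evidence=(phrase,))
    if _SP_JOIN.search(text):
        return NameClassification("symbiont", evidence=("sp.-join",))

    # --- negated ---------------------------------------------------------
    ann_kinds = {a.kind for a in parsed.annotations}
    if ann_kinds & vocab.hard_negation_kinds or (low_toks and low_toks[0] in _NEGATION_WORDS):
        ev = tuple(a.token for a in parsed.annotations if a.kind in vocab.hard_negation_kinds) \
            or (toks[0],)
        return NameClassification("negated", evidence=ev)
    soft = ann_kinds & vocab.soft_negation_kinds
    if soft:
        if parsed.head and _latinate(parsed.head, vocab):
            # species negated, genus still usable
            return NameClassification(
                "clade_genus",
                evidence=tuple(a.token for a in parsed.annotations if a.kind in soft),
            )
        return NameClassification(
            "negated",
            evidence=tuple(a.token for a in parsed.annotations if a.kind in soft),
        )

    # --- not-useful vocabulary hits, computed before the clade step ------
    env_hits = [low for low in low_toks if low in vocab.environmental_terms]
    plasmid_hits = [low for low in low_toks if low in vocab.plasmid_terms]
    organelle_hits = [low for low in low_toks if low in vocab.organelle_terms]
    molecular_hits = [low for low in low_toks if low in vocab.molecular_terms]
    strain_hits = [
        low for low in low_toks
        if low in vocab.strain_terms or low.startswith("strain")
    ]
    numbered = bool(text) and text[0].isdigit()
    useless_hits = env_hits + plasmid_hits + organelle_hits + molecular_hits + strain_hits

    # a not-useful cue suppresses the clade step when the parse itself is
    # shaky: a case repair, an unparseable core, a bare uninomial with a
    # tail, or the cue sitting inside the parsed structure
    structure_tokens = {t.lower() for t in (
        parsed.head or "", parsed.specific_epithet or "",
        *(ep for _, ep in parsed.infraspecific_parts),
    ) if t}
    shaky = (
        parsed.case_repaired
        or parsed.quality == QUALITY_UNPARSEABLE
        or (parsed.uninomial is not None and parsed.quality != "clean")
        or bool(structure_tokens & set(useless_hits))
    )
    clade_blocked = bool(useless_hits) and shaky

    # --- clade classes ---------------------------------------------------
    if parsed.head and _latinate(parsed.head, vocab) and not clade_blocked:
        epithets = []
        if parsed.specific_epithet:
            epithets.append(parsed.specific_epithet)
        epithets.extend(ep for _, ep in parsed.infraspecific_parts)
        epithets_ok = all(_latinate(ep, vocab) for ep in epithets)
        if epithets_ok and parsed.case_repaired:
            # the capitalization was our repair; demand latinate epithets
            epithets_ok = all(_epithet_convincing(ep) for ep in epithets)
        if epithets_ok:
            if parsed.infraspecific_parts:
                return NameClassification(
                    "clade_infraspecies", evidence=(parsed.head, *epithets)
                )
            if parsed.specific_epithet:
                return NameClassification(
                    "clade_species", evidence=(parsed.head, parsed.specific_epithet)
                )
            head_low = parsed.head.lower()
            for sfx in vocab.higher_rank_suffixes:
                if head_low.endswith(sfx):
                    return NameClassification(
                        "clade_higher", evidence=(parsed.head, f"-{sfx}")
                    )
            return NameClassification("clade_genus", evidence=(parsed.head,))
        elif not parsed.case_repaired:
            # epithet is a plain word ("Rhizobiaceae group"): fall back to
            # the head alone, but only when the head itself proves a clade
            # by its rank suffix — otherwise the string is likely vernacular
            head_low = parsed.head.lower()
            for sfx in vocab.higher_rank_suffixes:
                if head_low.endswith(sfx):
                    return NameClassification(
                        "clade_higher", evidence=(parsed.head, f"-{sfx}")
                    )

    # --- common name -----------------------------------------------------
    blocking = numbered or bool(useless_hits)
    if not blocking:
        english_hits = [low for low in low_toks if low in vocab.english_words]
        possessive = [t for t in toks if re.search(r"[A-Za-z]'s$", t)]
        if english_hits or possessive:
            return NameClassification(
                "common_name", evidence=tuple(english_hits + possessive)
            )
        wordy = (
            (parsed.quality == QUALITY_UNPARSEABLE or parsed.case_repaired)
            and len(toks) >= 2
            and all(re.fullmatch(r"[A-Za-z][A-Za-z'-]*|&", t) for t in toks)
        ) or (
            # hyphenated phrases masquerading as one token
            len(toks) == 1 and toks[0].count("-") >= 2
            and re.fullmatch(r"[A-Za-z][A-Za-z'-]*", toks[0])
        ) or (
            # a plain word survived to here because the clade step vetoed
            # a vocabulary-listed head
            parsed.head is not None and not _latinate(parsed.head, vocab)
        )
        if wordy:
            return NameClassification("common_name", evidence=("natural-language tokens",))

    # --- not useful ------------------------------------------------------
    if numbered:
        return NameClassification("not_useful", "numbered", evidence=(toks[0],))
    if env_hits:
        return NameClassification("not_useful", "environmental", evidence=tuple(env_hits))
    if plasmid_hits:
        return NameClassification("not_useful", "plasmid", evidence=tuple(plasmid_hits))
    if organelle_hits:
        return NameClassification("not_useful", "organelle", evidence=tuple(organelle_hits))
    if molecular_hits:
        return NameClassification("not_useful", "molecular", evidence=tuple(molecular_hits))
    if strain_hits or "strain_marker" in ann_kinds:
        return NameClassification("not_useful", "strain_surrogate",
                                  evidence=tuple(strain_hits) or ("strain marker",))
    if _ABBREV.match(text):
        return NameClassification("not_useful", "abbreviated", evidence=(toks[0],))
    if len(toks) == 1 and re.fullmatch(r"[a-zà-öø-ÿ-]+", toks[0]):
        if len(toks[0]) >= 13 and not toks[0].endswith(_EPITHET_ONLY_ENDINGS):
            return NameClassification(
                "not_useful", "concatenated_unresolved", evidence=(toks[0],)
            )
        return NameClassification("not_useful", "no_genus", evidence=(toks[0],))
    if vocab.acronym_pattern and vocab.acronym_pattern.fullmatch(text):
        return NameClassification("not_useful", "acronym", evidence=(text,))
    # default per vocabulary hits: code-like strings are acronyms,
    # the rest is molecular debris
    if any(c.isdigit() for c in text) or text.isupper():
        return NameClassification("not_useful", "acronym", evidence=(text,))
    return NameClassification("not_useful", "molecular", evidence=(text,))


def classify_string(raw: str, vocab: Vocabulary | None = None) -> NameClassification:
    """Parse and classify a raw name-string in one step."""
    name = NameString.of(raw)
    return classify(parse(name), name, vocab)
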