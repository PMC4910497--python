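"""Synthetic dirty-checklist generation with ground truth.

Real uncurated checklists corrupt scientific names in recurring,
recognisable ways: concatenation with interpolated ``_``/``0``/``X``,
truncation to 10 characters, a dropped leading character, a stripped
genus, authorship noise and chresonym-style author swaps, random
misspellings, case mangling, and appended strain or accession tails.
This module applies those operators to a clean reference list of
binomials under a fixed seed, recording for every dirty string the
pristine name and the exact operators used — so the whole repair +
canonicalize + match pipeline can be tested offline with known truth.

The reference list shipped with the package is the corpus of valid
binomials used throughout the toolkit's examples; pass your own list to
emulate a particular source.

What the generator does *not* emulate: multilingual common names, virus
nomenclature, encoding mojibake, and source-specific translation tables.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

from .canonical import make_match_key
from .config import load_default
from .match import dl_distance

OPERATORS = (
    "concat_underscore",
    "concat_zero",
    "concat_x",
    "truncate_10",
    "drop_leading_char",
    "strip_genus",
    "author_noise",
    "chresonym_swap",
    "misspell_ed_1",
    "misspell_ed_2",
    "case_mangle",
    "add_strain_tail",
    "add_acronym_tail",
)

_AUTHORS = ("Smith, 1901", "L.", "(Schmidt, 1939) Jones", "Muell.Arg.", "Boettger, 1887")
_CHRESONYM_AUTHORS = ("Mertens, 1937", "Peters, 1854", "Wallach Et Al., 2009")
_STRAIN_TAILS = ("str. WB4", "strain DhA-35", "ATCC 36299", "CCUG 53888")
_ACRONYM_TAILS = ("BOLD:AAC1024", "JGZ-2004-1", "MBIC10102", "DQ346653")


@dataclass(frozen=True)
class CorruptionRecord:
    clean_name: str
    dirty_name: str
    operators: tuple[str, ...]
    seed: int


def clean_reference_names() -> list[str]:
    """The packaged list of valid reference binomials."""
    text = load_default("clean_binomials.txt")
    return [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]


def _concat(sep: str) -> Callable[[str, random.Random], str]:
    def op(name: str, rng: random.Random) -> str:
        return name.replace(" ", sep)

    return op


def _truncate_10(name: str, rng: random.Random) -> str:
    return name[:10]


def _drop_leading_char(name: str, rng: random.Random) -> str:
    return name[1:]


def _strip_genus(name: str, rng: random.Random) -> str:
    parts = name.split(" ", 1)
    return parts[1] if len(parts) > 1 else name


def _author_noise(name: str, rng: random.Random) -> str:
    return f"{name} {rng.choice(_AUTHORS)}"


def _chresonym_swap(name: str, rng: random.Random) -> str:
    return f"{name} {rng.choice(_CHRESONYM_AUTHORS)}"


def _case_mangle(name: str, rng: random.Random) -> str:
    return name.upper() if rng.random() < 0.5 else name.lower()


def _add_strain_tail(name: str, rng: random.Random) -> str:
    return f"{name} {rng.choice(_STRAIN_TAILS)}"


def _add_acronym_tail(name: str, rng: random.Random) -> str:
    return f"{name} {rng.choice(_ACRONYM_TAILS)}"


_LETTERS = "abcdefghijklmnopqrstuvwxyz"


def _one_edit(name: str, rng: random.Random) -> str:
    """One random OSA edit on a lower-case letter position (never the
    leading capital, never a space, so the result stays a binomial)."""
    positions = [i for i, c in enumerate(name) if c.islower() and i > 0]
    kind = rng.choice(("sub", "ins", "del", "trans"))
    i = rng.choice(positions)
    if kind == "sub":
        repl = rng.choice([c for c in _LETTERS if c != name[i]])
        return name[:i] + repl + name[i + 1:]
    if kind == "ins":
        return name[:i] + rng.choice(_LETTERS) + name[i:]
    if kind == "del":
        return name[:i] + name[i + 1:]
    # transposition of two adjacent distinct letters
    pairs = [
        i for i in positions
        if i + 1 < len(name) and name[i + 1].islower() and name[i] != name[i + 1]
    ]
    if not pairs:
        return name[:i] + rng.choice([c for c in _LETTERS if c != name[i]]) + name[i + 1:]
    j = rng.choice(pairs)
    return name[:j] + name[j + 1] + name[j] + name[j + 2:]


def _misspell(k: int) -> Callable[[str, random.Random], str]:
    def op(name: str, rng: random.Random) -> str:
        target_key = make_match_key(name)
        for _ in range(100):
            dirty = name
            for _ in range(k):
                dirty = _one_edit(dirty, rng)
            if dl_distance(make_match_key(dirty), target_key) == k:
                return dirty
        raise RuntimeError(f"could not build a distance-{k} misspelling of {name!r}")

    return op


_OPERATOR_FUNCS: dict[str, Callable[[str, random.Random], str]] = {
    "concat_underscore": _concat("_"),
    "concat_zero": _concat("0"),
    "concat_x": _concat("X"),
    "truncate_10": _truncate_10,
    "drop_leading_char": _drop_leading_char,
    "strip_genus": _strip_genus,
    "author_noise": _author_noise,
    "chresonym_swap": _chresonym_swap,
    "misspell_ed_1": _misspell(1),
    "misspell_ed_2": _misspell(2),
    "case_mangle": _case_mangle,
    "add_strain_tail": _add_strain_tail,
    "add_acronym_tail": _add_acronym_tail,
}


def apply_operators(
    clean_name: str, operators: Sequence[str], seed: int
) -> str:
    """Apply *operators* in order under *seed*; deterministic."""
    rng = random.Random(seed)
    dirty = clean_name
    for op in operators:
        dirty = _OPERATOR_FUNCS[op](dirty, rng)
    return dirty


def generate(
    clean_names: Sequence[str] | None,
    mix: Mapping[str, float],
    seed: int,
) -> list[CorruptionRecord]:
    """Corrupt *clean_names* according to the operator-probability *mix*.

    Mix keys are operator names or ``+``-joined chains
    (``"concat_zero+truncate_10"``); probabilities must sum to at most 1,
    the remainder of the mass leaves names clean.  Reproducible under
    *seed*; every record lists the operators that produced it, and
    ``apply_operators(clean, operators, record.seed)`` rebuilds the dirty
    string exactly.
    """
    if clean_names is None:
        clean_names = clean_reference_names()
    if not clean_names:
        raise ValueError("clean name list must be nonempty")
    chains = []
    total = 0.0
    for key, prob in mix.items():
        ops = tuple(key.split("+"))
        for op in ops:
            if op not in _OPERATOR_FUNCS:
                raise ValueError(f"unknown operator {op!r}")
        chains.append((ops, float(prob)))
        total += float(prob)
    if total > 1.0 + 1e-9:
        raise ValueError(f"operator probabilities sum to {total} > 1")

    rng = random.Random(seed)
    records = []
    for name in clean_names:
        draw = rng.random()
        chosen: tuple[str, ...] = ()
        acc = 0.0
        for ops, prob in chains:
            acc += prob
            if draw < acc:
                chosen = ops
                break
        record_seed = rng.randrange(2**31)
        dirty = apply_operators(name, chosen, record_seed) if chosen else name
        records.append(
            CorruptionRecord(
                clean_name=name, dirty_name=dirty, operators=chosen, seed=record_seed
            )
        )
    return records


def golden_classified() -> list[tuple[str, str, str | None]]:
    """The corpus of example name-strings with their published classes."""
    text = load_default("golden_classes.tsv")
    rows = []
    for line in text.splitlines()[1:]:
        name, major, minor = line.split("\t")
        rows.append((name, major, minor or None))
    return rows
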