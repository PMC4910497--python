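"""Fuzzy matching and checklist cross-mapping.

The distance primitive is the restricted Damerau-Levenshtein distance
(optimal string alignment): minimum number of single-character changes,
insertions, deletions and adjacent transpositions, with the restriction
that no substring is edited twice.  This is the variant used by
scientific-name spell-checkers; it is symmetric with identity, but the
triangle inequality is not claimed.

Cross-mapping tries, for every source record, a fixed ladder of match
tiers against the target checklist:

1. exact full-string match;
2. canonical exact match via the match key;
3. canonical fuzzy at edit distance 1;
4. canonical fuzzy at edit distance 2..max_tolerance (auto-flagged for
   human check — beyond one edit, too many matches are wrong);
5. partial canonical: infraspecific epithets stripped, retried exactly;
6. partial canonical fuzzy;
7. genus-part match;
8. no match.

The first tier with at least one hit wins and names the category.  Ties
at equal distance are all returned: multi-target matches are data, and
their rate (the "inflation" of results over records) is reported.

A small heuristic follows spell-checker practice for latinized names:
interchangeable gender terminations (-us/-a/-um), i/y and ae/e are folded
before distance comparison, as an admission rule only — the reported edit
distance is always computed on the unfolded match keys.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .canonical import CanonicalForm, CanonicalizationError, canonicalize, make_match_key
from .names import NameString
from .parser import ParsedName, parse
from .score import (
    AUTHORSHIP_ABSENT,
    AUTHORSHIP_AGREES,
    AUTHORSHIP_CONFLICTS,
    RANK_BINOMIAL,
    RANK_TRINOMIAL_PLUS,
    RANK_UNINOMIAL,
    MatchFeatures,
    ScoringWeights,
    DEFAULT_WEIGHTS,
    score,
)

CATEGORY_EXACT = "exact"
CATEGORY_CANONICAL_EXACT = "canonical_exact"
CATEGORY_CANONICAL_FUZZY = "canonical_fuzzy"
CATEGORY_PARTIAL_CANONICAL = "partial_canonical"
CATEGORY_PARTIAL_CANONICAL_FUZZY = "partial_canonical_fuzzy"
CATEGORY_GENUS_PART = "genus_part"
CATEGORY_NONE = "none"

MAX_TOLERANCE_CEILING = 6


@dataclass(frozen=True)
class EditDistanceParams:
    max_tolerance: int = 1
    allow_transposition: bool = True
    per_token: bool = False
    fold_endings: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.max_tolerance <= MAX_TOLERANCE_CEILING:
            raise ValueError(
                f"max_tolerance must be in [0, {MAX_TOLERANCE_CEILING}]"
            )


@dataclass
class MatchResult:
    source_id: str
    source_name: str
    category: str
    targets: list[tuple[str, str]] = field(default_factory=list)
    edit_distance: Optional[int] = None
    confidence: float = 0.0
    needs_human_check: bool = True
    homonym_alert: bool = False


def _osa(a: str, b: str, allow_transposition: bool = True) -> int:
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    prev2: list[int] = []
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if (
                allow_transposition
                and i > 1
                and j > 1
                and a[i - 1] == b[j - 2]
                and a[i - 2] == b[j - 1]
            ):
                cur[j] = min(cur[j], prev2[j - 2] + 1)
        prev2, prev = prev, cur
    return prev[lb]


def dl_distance(a: str, b: str, params: EditDistanceParams = EditDistanceParams()) -> int:
    """Restricted Damerau-Levenshtein (OSA) distance between two strings.

    With ``per_token`` the genus and epithets are compared separately and
    the per-token distances summed (extra/missing tokens cost their
    length).
    """
    if not params.per_token:
        return _osa(a, b, params.allow_transposition)
    ta, tb = a.split(), b.split()
    total = 0
    for x, y in zip(ta, tb):
        total += _osa(x, y, params.allow_transposition)
    for rest in (ta[len(tb):], tb[len(ta):]):
        total += sum(len(t) for t in rest)
    return total


_FOLDS = (
    (re.compile(r"(us|um)\b"), "a"),
    (re.compile(r"ae"), "e"),
    (re.compile(r"y"), "i"),
)


def fold_endings(key: str) -> str:
    """Fold interchangeable latinized spellings (-us/-a/-um, ae/e, y/i)."""
    for rx, repl in _FOLDS:
        key = rx.sub(repl, key)
    return key


@dataclass(frozen=True)
class _TargetEntry:
    record_id: str
    name: str
    parsed: ParsedName
    canonical: Optional[CanonicalForm]


class TargetIndex:
    """Pre-indexed target checklist: raw strings, match keys, genus parts."""

    def __init__(self, records: Iterable[tuple[str, str]]) -> None:
        self.entries: list[_TargetEntry] = []
        self.by_raw: dict[str, list[_TargetEntry]] = {}
        self.by_key: dict[str, list[_TargetEntry]] = {}
        self.by_genus_key: dict[str, list[_TargetEntry]] = {}
        self._keys_by_len: dict[int, list[str]] = {}
        for record_id, name in records:
            parsed = parse(NameString.of(name))
            try:
                canonical = canonicalize(parsed)
            except CanonicalizationError:
                canonical = None
            entry = _TargetEntry(record_id, name, parsed, canonical)
            self.entries.append(entry)
            self.by_raw.setdefault(NameString.of(name).normalized, []).append(entry)
            if canonical is not None:
                key = canonical.match_key
                bucket = self.by_key.setdefault(key, [])
                if not bucket:
                    self._keys_by_len.setdefault(len(key), []).append(key)
                bucket.append(entry)
                head = parsed.head
                if head:
                    self.by_genus_key.setdefault(make_match_key(head), []).append(entry)

    def candidate_keys(self, key: str, tolerance: int) -> Iterable[str]:
        for length in range(len(key) - tolerance, len(key) + tolerance + 1):
            yield from self._keys_by_len.get(length, ())


def fuzzy_candidates(
    query: CanonicalForm | str,
    targets: TargetIndex,
    params: EditDistanceParams = EditDistanceParams(),
) -> list[tuple[str, int]]:
    """All target match keys within ``max_tolerance`` of the query key.

    Returns ``(key, distance)`` pairs sorted by (distance, key); ties at
    equal distance are all kept.  Distances are computed on the raw match
    keys; the ending-fold heuristic only admits additional candidates.
    """
    key = query.match_key if isinstance(query, CanonicalForm) else query
    folded = fold_endings(key) if params.fold_endings else key
    hits: list[tuple[str, int]] = []
    seen: set[str] = set()
    for cand in targets.candidate_keys(key, params.max_tolerance):
        if cand in seen:
            continue
        seen.add(cand)
        d = dl_distance(key, cand, params)
        admitted = d <= params.max_tolerance
        if not admitted and params.fold_endings:
            df = dl_distance(folded, fold_endings(cand), params)
            admitted = df <= params.max_tolerance
        if admitted:
            hits.append((cand, d))
    hits.sort(key=lambda kv: (kv[1], kv[0]))
    return hits


def _binomial_key(canonical: CanonicalForm) -> Optional[str]:
    """Match key reduced to genus + specific epithet, if infraspecific."""
    tokens = canonical.match_key.split()
    if len(tokens) > 2:
        return " ".join(tokens[:2])
    return None


def _matched_rank(key: str) -> str:
    n = len(key.split())
    if n == 1:
        return RANK_UNINOMIAL
    if n == 2:
        return RANK_BINOMIAL
    return RANK_TRINOMIAL_PLUS


def _surnames(parsed: ParsedName) -> set[str]:
    auth = parsed.authorship
    if auth is None:
        return set()
    names = set(auth.combination_authors) | set(auth.basionym_authors) | set(auth.ex_authors)
    # compare on the surname proper: the last word, dots stripped
    return {n.split()[-1].lower().rstrip(".") for n in names if n.strip()}


def _years(parsed: ParsedName) -> set[int]:
    auth = parsed.authorship
    if auth is None:
        return set()
    return {y for y in (auth.combination_year, auth.basionym_year) if y is not None}


def _names_agree(a: set[str], b: set[str]) -> bool:
    """Author surname sets agree when any pair matches, allowing the
    customary abbreviations (``Rehd.`` for ``Rehder``)."""
    for x in a:
        for y in b:
            if x == y:
                return True
            shorter, longer = sorted((x, y), key=len)
            if len(shorter) >= 3 and longer.startswith(shorter):
                return True
    return False


def _authorship_state(source: ParsedName, entries: Sequence[_TargetEntry]) -> str:
    s_names = _surnames(source)
    if not s_names:
        return AUTHORSHIP_ABSENT
    saw_target_authorship = False
    for entry in entries:
        t_names = _surnames(entry.parsed)
        if not t_names:
            continue
        saw_target_authorship = True
        if _names_agree(s_names, t_names):
            s_years, t_years = _years(source), _years(entry.parsed)
            if not s_years or not t_years or s_years & t_years:
                return AUTHORSHIP_AGREES
    return AUTHORSHIP_CONFLICTS if saw_target_authorship else AUTHORSHIP_ABSENT


class CrossMapper:
    """Hierarchical cross-mapping of a source checklist onto a target."""

    def __init__(
        self,
        target: Iterable[tuple[str, str]],
        params: EditDistanceParams = EditDistanceParams(),
        weights: ScoringWeights = DEFAULT_WEIGHTS,
        homonyms: Iterable[str] = (),
    ) -> None:
        self.index = TargetIndex(target)
        self.params = params
        self.weights = weights
        self.homonyms = {make_match_key(h) for h in homonyms}

    def map_record(self, record_id: str, name: str) -> MatchResult:
        normalized = NameString.of(name).normalized
        parsed = parse(NameString.of(name))
        try:
            canonical = canonicalize(parsed)
        except CanonicalizationError:
            canonical = None

        # tier 1: exact full-string
        entries = self.index.by_raw.get(normalized)
        if entries:
            return self._result(record_id, name, CATEGORY_EXACT, entries, parsed,
                                matched_key=normalized, edit_distance=0)
        if canonical is None:
            return MatchResult(record_id, name, CATEGORY_NONE)
        key = canonical.match_key

        # tier 2: canonical exact via match key
        entries = self.index.by_key.get(key)
        if entries:
            return self._result(record_id, name, CATEGORY_CANONICAL_EXACT, entries,
                                parsed, matched_key=key, edit_distance=0)

        # tiers 3-4: canonical fuzzy at growing distance
        if self.params.max_tolerance >= 1:
            hit = self._fuzzy_tier(key)
            if hit:
                entries, distance = hit
                return self._result(record_id, name, CATEGORY_CANONICAL_FUZZY, entries,
                                    parsed, matched_key=key, edit_distance=distance)

        # tier 5: partial canonical (infraspecific epithets stripped)
        partial = _binomial_key(canonical)
        if partial:
            entries = self.index.by_key.get(partial)
            if entries:
                return self._result(record_id, name, CATEGORY_PARTIAL_CANONICAL, entries,
                                    parsed, matched_key=partial, edit_distance=0)
            # tier 6: partial canonical fuzzy
            if self.params.max_tolerance >= 1:
                hit = self._fuzzy_tier(partial)
                if hit:
                    entries, distance = hit
                    return self._result(record_id, name, CATEGORY_PARTIAL_CANONICAL_FUZZY,
                                        entries, parsed, matched_key=partial,
                                        edit_distance=distance)

        # tier 7: genus part
        head = parsed.head
        if head:
            entries = self.index.by_genus_key.get(make_match_key(head))
            if entries:
                return self._result(record_id, name, CATEGORY_GENUS_PART, entries,
                                    parsed, matched_key=make_match_key(head),
                                    edit_distance=None)

        return MatchResult(record_id, name, CATEGORY_NONE)

    def _fuzzy_tier(self, key: str) -> Optional[tuple[list[_TargetEntry], int]]:
        hits = fuzzy_candidates(key, self.index, self.params)
        if not hits:
            return None
        best = hits[0][1]
        entries: list[_TargetEntry] = []
        for cand, d in hits:
            if d == best:
                entries.extend(self.index.by_key[cand])
        # a fold-admitted candidate can carry a raw distance of 0 only if
        # the keys were equal, which tier 2 already handled
        return entries, max(best, 1)

    def _result(
        self,
        record_id: str,
        name: str,
        category: str,
        entries: Sequence[_TargetEntry],
        parsed: ParsedName,
        matched_key: str,
        edit_distance: Optional[int],
    ) -> MatchResult:
        features = MatchFeatures(
            matched_rank=_matched_rank(matched_key),
            authorship_state=(
                _authorship_state(parsed, entries)
                if category in (CATEGORY_EXACT, CATEGORY_CANONICAL_EXACT,
                                CATEGORY_CANONICAL_FUZZY)
                else AUTHORSHIP_ABSENT
            ),
            edit_distance=edit_distance or 0,
            multi_target=len(entries) > 1,
        )
        conf = score(features, self.weights)
        needs_check = conf.needs_human_check or (edit_distance or 0) >= 2
        alert = any(
            (e.canonical.match_key if e.canonical else "") in self.homonyms
            for e in entries
        )
        return MatchResult(
            source_id=record_id,
            source_name=name,
            category=category,
            targets=[(e.record_id, e.name) for e in entries],
            edit_distance=edit_distance,
            confidence=conf.confidence,
            needs_human_check=needs_check,
            homonym_alert=alert,
        )


def cross_map(
    source: Iterable[tuple[str, str]],
    target: Iterable[tuple[str, str]],
    params: EditDistanceParams = EditDistanceParams(),
    weights: ScoringWeights = DEFAULT_WEIGHTS,
    homonyms: Iterable[str] = (),
) -> list[MatchResult]:
    """Cross-map source records onto a target checklist.

    Source and target are ``(id, name-string)`` pairs; duplicate source
    ids are an error; an empty target yields all-``none`` results.
    """
    source = list(source)
    ids = [rid for rid, _ in source]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate source ids: {dupes}")
    mapper = CrossMapper(target, params=params, weights=weights, homonyms=homonyms)
    return [mapper.map_record(rid, name) for rid, name in source]


def match_profile(results: Sequence[MatchResult]) -> dict[str, object]:
    """Per-category counts plus the multi-target inflation statistic."""
    counts: dict[str, int] = {}
    total_targets = 0
    for res in results:
        counts[res.category] = counts.get(res.category, 0) + 1
        total_targets += max(len(res.targets), 1)
    matched = [r for r in results if r.category != CATEGORY_NONE]
    hit_count = sum(len(r.targets) for r in matched)
    inflation = (hit_count / len(matched) - 1.0) if matched else 0.0
    return {
        "records": len(results),
        "results_with_targets": hit_count,
        "categories": counts,
        "inflation": inflation,
    }
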