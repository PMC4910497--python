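# Methods

This note documents the models, heuristics, parameters and deliberate
design choices behind `gnkit`, and what the test suite does and does not
demonstrate.

## Name-string normalization

A name-string is kept as raw bytes plus a normalized form: Unicode NFC,
trimmed, internal whitespace collapsed. Normalization never merges
distinct non-whitespace codepoints — a Cyrillic `а` remains distinct from
Latin `a` — because content-derived identifiers must be able to expose
lookalike strings. Identifiers are UUID v5 values over the UTF-8 bytes of
the NFC-normalized raw string in the namespace
`uuid5(NAMESPACE_DNS, "globalnames.org")`; they are minted from the raw
string, not the canonical form, so lexical variants of one name keep
distinct identifiers (canonical-form identifiers can be minted separately
by canonicalizing first).

## Parsing

Parsing is total: every input returns a result, graded `clean` (all
tokens accounted for), `with_tail` (a latinized core plus unrecognized
tokens) or `unparseable`. Rank interpretation is positional — one
latinized token is a uninomial, two are genus + specific epithet, further
lower-case tokens are infraspecific epithets; rank markers (`ssp.`,
`var.`, `f.` …, including Greek-letter and single-letter infrasubspecific
markers, accepted only after a full binomial) attach to the epithet that
follows. The marker and annotation vocabularies live in
`src/gnkit/data/parser_vocab.yaml` and are open-ended; unknown markers
fall to the tail rather than being guessed at.

Authorship is recognised heuristically. A candidate run of tokens is
accepted as authorship only if it looks like authors (contains a period,
ampersand, connector word or year, or consists of capitalized lower-case
words); all-caps codes (`CCUG`, `WB4`) are rejected and fall to the tail,
which is what keeps strain and collection numbers out of author fields.
Parenthesized runs become basionym authors; authors before `ex` are
recorded as ex-authors; initials are attached to the following surname;
years must lie in [1700, 2100] and bracketed years (`[1844]`) are
accepted and flagged. When several authorship segments appear (authorship
of the species and of the infraspecific epithet), the last segment — the
authorship of the terminal epithet — populates the structured fields, and
all segments are preserved verbatim.

Two repairs are built into parsing itself: a bracketed genus
(`[Bacillus] sp.`) parses with the genus extracted and an annotation
recording the uncertainty convention, and a lower-cased genus
(`litoria ewingii`) is retried with the first letter capitalized and the
repair flagged. The recovery pass requires at least two tokens, a
latinate second token, and a first token outside a stop-word list, so
plain words (`bird`, `environmental`) are never promoted to genera.

The interpretation of `null` as an annotation token is undefined in
practice; it is recorded verbatim as a negation pending better evidence.

## Hybrid recognition

The hybrid sign appears in many encodings — the multiplication sign `×`,
Latin `x`/`X`, Cyrillic `х`/`Х` — and may be glued to the following word.
A leading sign marks a natural hybrid (one component); infix signs split
a formula into components, with lower-case continuations inheriting the
genus of the first component (`Iris brevicaulis x fulva` yields
`Iris brevicaulis` and `Iris fulva`). Hybridity survives canonicalization
only as a flag: signs are excluded from both canonical forms so that
matching is sign-agnostic.

## Canonical forms and match keys

The *complete* canonical keeps all latinized elements (subgenus in
parentheses, rank markers, the `Candidatus` prefix); the *standard*
canonical keeps only code-required elements: genus or uninomial, specific
epithet, infraspecific epithets. For a bare subgeneric combination the
standard form is the subgenus name. `Candidatus` is kept in the complete
and dropped from the standard form. The *match key* lower-cases the
standard form and removes hyphens, hybrid signs and diacritics (NFKD
decomposition, combining marks stripped). Hyphens are preserved in
standard canonicals — hyphenated epithets are code-legal — but erased in
keys so that `roseo-caerulea` and `roseocaerulea` collide.

## Preprocessing

Repair rules are an ordered YAML list (id, regex, replacement or action,
flags); each application is logged under its rule id, and the packaged
rules can be replaced per source. The default rules: strip edge
separators; map underscore runs to spaces; split `0` and `X`
interpolations at a capital–lowercase boundary (so `DanioXreri` splits
but a hybrid formula's standalone `X` survives); strip trailing
accession-like tokens; repair all-caps, all-lower and capitalized-epithet
case (guarded by a stop-word list). Exactly-10-character repaired strings
are flagged `truncated_suspect`, reflecting the 10-character field limit
that produces them. The preprocessor only splits and reorders what is
present: it never lengthens a token, so `Danio reri` is *not* expanded to
`Danio rerio` — without the source's own translation table that would be
guessing, and the fuzzy matcher downstream handles it with an explicit,
auditable edit distance instead. Strings with no capital and no separator
(`corbulasulcata`) are marked unresolvable; this includes genuinely
ambiguous cases (`Pan__Herm` repairs to `Pan herm`, which remains a
dubious binomial for downstream stages to judge).

## Classification

Cue priority is virus > hybrid > symbiont > negated > clade > common
name > not useful. Virus outranks everything because virus strings often
embed a host binomial (`Yersinia pestis bacteriophage phiA1122`). Soft
negations (`cf.`, `aff.`, `nr.`) demote to the enclosing genus when one
parses; hard negations (`non`, `nec`, `not`, `null`) negate the record. A
clade class demands genuinely latinate tokens: a token listed in the
plain-language vocabulary disqualifies it as genus or epithet, and a
parse that rests on our own case repair must additionally show a
latinate epithet ending. Strings failing these tests fall to the
common-name heuristic (plain-language tokens, possessives, multi-word
lower-case strings) or to a not-useful subclass (numbered, environmental,
plasmid, organelle, molecular, strain surrogate, abbreviated, acronym,
genus-free epithet, unresolved concatenation). All term lists are
config-loaded; every decision records its evidence. No multilingual
common-name lexicon is attempted.

The bundled golden corpus (`data/golden_classes.tsv`, 139 strings) pins
the classifier to its reference behaviour; a handful of published
example strings whose class requires out-of-band knowledge (e.g. a
single capitalized concatenation that is indistinguishable from a valid
genus, or a single-word vernacular with a latinate ending) is excluded
rather than forced.

## Edit distance and fuzzy matching

The distance is the restricted Damerau–Levenshtein / optimal string
alignment (OSA) distance: substitutions, insertions, deletions and
adjacent transpositions, no substring edited twice. This is the variant
used by scientific-name spell-checkers; the triangle inequality is not
claimed. Tolerance is configurable from 0 to 6 — six being the deepest
edit distance at which a correct match has been observed
(`Lasidioplodia pseudobromae` → `Lasiodiplodia pseudotheobromae`).
Candidate retrieval prunes by key length (±tolerance) and computes exact
distances; all ties at the minimal distance are returned, because
multi-target matches are data, not noise. A small heuristic fold —
interchangeable gender terminations `-us`/`-a`/`-um`, `ae`→`e`, `y`→`i`
— may *admit* additional candidates, but the reported edit distance is
always computed on the unfolded keys (and is at least 1 for non-equal
keys), so folding can widen recall without fabricating closeness.

## Cross-mapping tiers

Exact → canonical exact → canonical fuzzy (distance 1, then 2..max) →
partial canonical (infraspecific epithets stripped) → partial canonical
fuzzy → genus part → none; the first tier with a hit names the category.
Only the genus-part tier's last place is externally fixed; placing
canonical fuzzy before the partial tiers is this package's choice,
preferring full-name evidence over truncation. Matches at distance ≥ 2
are kept but auto-flagged for human review — beyond one edit, too many
matches are wrong — preserving the audit trail instead of dropping data.
A configurable homonym list (seeded with a few well-known cross-code
homonyms; extend from a registry such as IRMNG for production use)
raises `homonym_alert` on matched canonicals. The report exposes the
multi-target inflation statistic (results per matched record − 1).

Authorship comparison for scoring uses surname sets (initials attached,
dots stripped) with abbreviation-tolerant matching (`Rehd.` agrees with
`Rehder`); years, when both sides have them, must intersect. Authorship
is excluded from distance computation entirely — comparisons are based
on canonical forms, because the author/date element is the noisiest part
of a name-string.

## Confidence scoring

Points: uninomial match 1.0; binomial 4.0 (trinomial and deeper are
scored as binomial — no published anchor distinguishes them); authorship
agreement +2.3; authorship conflict −3.0; each unit of edit distance
−2.0; multiple tied targets −1.0. Confidence is
`1 / (1 + 3^(-points))`; 0 points is neutral (0.5) and results at or
below 0.5 need a human check. The base and weights are calibrated, not
derived: the published narrative point deltas are mutually inconsistent
under any single logistic, so the printed *output* confidences are
treated as authoritative — base 3 reproduces 1 → 0.75 and 4 → 0.988
exactly, +2.3 reproduces 0.999 at three decimals, −3.0 returns the
conflict case to 0.75, and −2.0 per edit puts a distance-2 binomial
exactly on the 0.5 review boundary. All weights live in
`data/scoring.yaml`.

## Synthetic dirty checklists

The generator corrupts a clean reference list (the 247 valid binomials
from the toolkit's example corpus, shipped as
`data/clean_binomials.txt`) with the operators observed in uncurated
repositories: `_`/`0`/`X` concatenation, truncation to 10 characters,
dropped leading character, stripped genus, authorship noise, chresonym
author swaps, k-edit misspellings (verified against the distance
function, edits confined to lower-case letter positions so the result
stays a binomial), case mangling, strain and accession tails. Output is
deterministic under a seed and every record carries the operators and
per-record seed needed to rebuild it exactly.

What passing the recovery tests shows: concatenation and case corruption
are fully reversible by the rule set, and single-edit misspellings of
names at least 3 edits from any other name are fully recoverable at
tolerance 1. What it does not show: recovery rates on real data, where
corruption co-occurs with vocabulary the generator does not emulate
(multilingual common names, virus nomenclature, encoding mojibake) and
where name spaces are denser than the reference list.

## Numerical and degenerate-input choices

The distance DP keeps three rolling rows (O(min-memory), exact).
`sigmoid` evaluates from the numerically safe side for large negative
points, so it is bounded in [0, 1] for any finite input. Empty input:
parsing returns `unparseable`; canonicalization raises; identifier
minting raises (an identifier for nothing is meaningless). Duplicate
source ids in cross-mapping are an error; an empty target yields all
`none`. Fuzzy ties are ordered by (distance, key) for deterministic
reports; CLI re-runs on identical inputs are byte-identical.

## Scale of the shipped experiments

All tests and the acceptance script run on the bundled fixtures: the
247-name reference list, checklists of tens of records, and 500+
random-pair distance checks against an independent recursive oracle.
These sizes exercise every code path; corpus-scale statistics (millions
of records, overlap percentages between live databases) require the
external dumps and are out of scope.
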