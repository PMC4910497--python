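# gnkit

A toolkit for managing **taxonomic name-strings** — the literal character
sequences used as labels for taxa in sequence databases, checklists and
ecological data sets.

Scientific names are the closest thing biodiversity data has to a shared
index, but the strings that carry them are messy: the same species appears
as `Anolis barkeri`, `Anolis barkeri (Schmidt, 1939)` and `Anolis barkeri
POWELL 2001`; uncurated repositories contribute `Triticum_aestivum`,
`Danio0reri` (truncated to 10 characters), `corbulasulcata` (genus and
epithet concatenated) and `chneumon dorsalis` (leading character lost);
and large fractions of the strings in real sources are not scientific
names at all — vernacular names, virus labels, strain surrogates,
acronyms, symbiont descriptions. `gnkit` provides the pieces needed to
clean, compare and interlink such data:

* **parser** — total decomposition of a name-string into genus, epithets,
  rank markers, authorship (combination, basionym, *ex*), annotations
  (`cf.`, `aff.`, `nr.`, `non`, `sp.` …) and an unparsed tail, with an
  explicit quality grade (`clean` / `with_tail` / `unparseable`);
* **canonical** — *complete* canonical forms (all latinized elements) and
  *standard* canonical forms (only code-required elements), plus the
  normalized match key used for comparison;
* **preprocess** — ordered, editable regex rules that repair concatenated,
  truncated and case-mangled strings before parsing;
* **classify** — one class per string: clade-identifiable
  species/genus/infraspecies/higher, virus, common name, hybrid,
  symbiont, negated, or not-useful (with a diagnostic subclass);
* **match** — restricted Damerau–Levenshtein (optimal string alignment)
  fuzzy matching with name-aware heuristics, and hierarchical
  cross-mapping of a source checklist onto a target checklist;
* **score** — calibrated confidence for every match through a base-3
  logistic, `confidence = 1 / (1 + 3^(-points))`;
* **identifiers** — deterministic UUID v5 identifiers minted from the
  string's own bytes in the `globalnames.org` DNS namespace;
* **fixtures** — a seedable generator of synthetic dirty checklists with
  ground truth, for testing every stage offline.

## The core method

A source record is matched against a target checklist through a fixed
ladder of tiers, stopping at the first tier with a hit:

1. exact full-string match;
2. canonical exact match (match keys equal);
3. canonical fuzzy match at edit distance 1;
4. canonical fuzzy at distance 2–6 (flagged for human review);
5. partial canonical match (infraspecific epithets stripped);
6. partial canonical fuzzy match;
7. genus-part match;
8. no match.

Each result is scored: an exact uninomial match earns 1 point
(confidence 0.75), a binomial canonical match 4 points (0.988), agreeing
full authorship +2.3 (0.999), conflicting authorship −3 (back to 0.75),
each edit of distance −2, tied multi-target matches −1. Confidence at or
below 0.5 means the match needs a human check.

## Worked example

```sh
$ cat src.csv
id,scientificName
1,Triticum_aestivum
2,Acer cappadocicum subsp. sinicum (Rehder) Hand.-Mazz.
3,Lysandra coridon gennargenti
4,Dorsophila melanogaster

$ gnkit crossmap src.csv tgt.csv --tolerance 1 --preprocess
source_id,source_name,category,edit_distance,confidence,needs_human_check,homonym_alert,target_id,target_name
1,Triticum_aestivum,canonical_exact,0,0.988,0,0,10,Triticum aestivum L.
2,Acer cappadocicum subsp. sinicum (Rehder) Hand.-Mazz.,canonical_exact,0,0.999,0,0,11,Acer cappadocicum var. sinicum Rehd.
3,Lysandra coridon gennargenti,genus_part,,0.750,0,0,12,Lysandra
4,Dorsophila melanogaster,canonical_fuzzy,1,0.900,0,0,13,"Drosophila melanogaster Meigen, 1830"
# records: 4
# canonical_exact: 2
# canonical_fuzzy: 1
# genus_part: 1
# multi-target inflation: 0.0%
```

Reading the output: the underscore concatenation was repaired and then
matched canonically (0.988 — binomial, no authorship to compare); the
`subsp.`/`var.` rank variants collapse to the same standard canonical and
the authorships agree, lifting confidence to 0.999; the trinomial found
only its genus in the target (a taxonomically imprecise genus-part
match); the misspelling `Dorsophila` is one adjacent transposition from
`Drosophila` and matched fuzzily at distance 1.

Other subcommands: `gnkit parse`, `gnkit canonical`, `gnkit clean`,
`gnkit classify`, `gnkit score`, `gnkit uuid`, `gnkit simulate` (each
documented under `--help`). For example:

```sh
$ printf 'Homo sapiens\nHomo sаpiens\n' | gnkit uuid /dev/stdin
Homo sapiens	16f235a0-e4a3-529c-9b83-bd15fe722110
Homo sаpiens	093dc7f7-5915-56a5-87de-033e20310b14
```

The second line uses a Cyrillic `а`: byte-derived identifiers expose
lookalike strings that no human eye would separate.

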