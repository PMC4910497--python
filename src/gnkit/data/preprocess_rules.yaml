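# Ordered repair rules for idiosyncratic name-strings.
# Each rule: id, pattern (Python regex), replacement (or action), flags.
# Rules run top to bottom; every application is logged under its id.
# Actions other than plain substitution:
#   capitalize        - lower-case everything, capitalize the first letter
#   capitalize_genus  - capitalize the first token only (guarded by a
#                       stop-word list so plain words are not promoted)
#   lower_epithet     - lower-case every token after the first

- id: strip-edge-separators
  pattern: '^[_\s]+|[_\s]+$'
  replacement: ''
  flags: [tail_stripped]

- id: underscore-separator
  pattern: '_+'
  replacement: ' '
  flags: [deconcatenated]

- id: zero-separator
  pattern: '^([A-Z][a-z]+)0([a-z])'
  replacement: '\1 \2'
  flags: [deconcatenated]

- id: x-separator
  pattern: '^([A-Z][a-z]+)X([a-z])'
  replacement: '\1 \2'
  flags: [deconcatenated]

- id: strip-accession-tail
  pattern: '\s+(?:[A-Z]{1,6}\d{3,}(?:\.\d+)?|\d{4,}|[A-Z]+:[A-Z0-9]+)$'
  replacement: ''
  flags: [tail_stripped]

- id: case-allcaps
  pattern: '^[A-Z]{2,}(?: [A-Z]{2,})*\)?$'
  action: capitalize
  flags: [case_repaired]

- id: case-allcaps-genus
  pattern: '^[A-Z]{2,} [a-z]'
  action: capitalize_genus
  flags: [case_repaired]

- id: case-lower-genus
  pattern: '^[a-z]+(?: [a-zà-öø-ÿ][a-zà-öø-ÿ.-]*)+$'
  action: capitalize_genus
  flags: [case_repaired]

- id: case-upper-epithet
  pattern: '^[A-Z][a-z]+ [A-Z][a-z]+$'
  action: lower_epithet
  flags: [case_repaired]
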