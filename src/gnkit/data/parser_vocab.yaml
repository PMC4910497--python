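# Parser vocabularies: rank markers and annotation tokens.
# The lists are open-ended; unknown markers fall through to the tail.

# Infraspecific / infrasubspecific rank markers. These attach to the
# epithet that follows them.
rank_markers:
  - ssp.
  - ssp
  - subsp.
  - subsp
  - var.
  - var
  - subvar.
  - f.
  - subf.
  - f.sp.
  - forma
  - morph.
  - mut.
  - nat
  - nothosubsp.
  - nothovar.
  - convar.
  - pseudovar.
  - sect.
  - ser.
  - race

# Greek-letter and single-letter infrasubspecific markers; accepted only
# when a full binomial precedes them (standalone letters are noise).
letter_rank_markers:
  - "α"
  - "β"
  - "γ"
  - "δ"
  - "ε"
  - "φ"
  - "θ"
  - "μ"
  - a
  - b
  - c
  - d
  - e
  - g
  - k

# Annotation tokens by kind.
annotations:
  sp_indet: ["sp.", "sp", "spp.", "spp", "spec.", "gen.", "indet."]
  cf: ["cf.", "cf", "cf.:"]
  aff: ["aff.", "aff"]
  nr: ["nr.", "nr"]
  negation: ["non", "nec", "not", "null"]
  sensu_auct: ["sensu", "auct.", "auctt.", "s.l.", "s.str.", "s.s."]
  nom_status: ["nom.", "illeg.", "superfl.", "rej.", "cons.", "nud.", "inval."]
  cultivar: ["cv.", "cv", "cultivar"]
  strain_marker: ["str.", "strain", "isolate", "pv.", "serovar", "biovar"]
  emend: ["emend.", "emend", "corrig."]
  in_part: ["p.p.", "p.p"]

# Lowercase lead-in words that may precede a name and carry no
# nomenclatural information; they are shunted to the tail.
lead_in_words:
  - uncultured
  - unidentified
  - unclassified
  - unassigned
  - unknown

# Lowercase words never treated as a genus by the case-recovery pass.
recovery_stop_words:
  - environmental
  - bacterium
  - fungal
  - uncultured
  - unidentified
  - unclassified
  - unknown
  - strain
  - samples
  - sample

# Lowercase tokens allowed inside authorship runs.
author_connectors:
  - et
  - al.
  - al
  - and
  - ex
  - in
  - van
  - von
  - de
  - del
  - der
  - den
  - da
  - dos
  - du
  - la
  - le
  - ter
  - ten
  - f.
  - f
  - fil.
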