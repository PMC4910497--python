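# Term vocabularies for the name-string classifier.  All lists are
# open-ended: extend them as new pathologies appear in sources.

# Substrings (case-insensitive, matched inside tokens) and suffixes that
# mark virus names; acronyms ending in V are handled by a pattern.
virus_terms:
  - virus
  - viroid
  - virales
  - phage
  - prion
virus_suffixes:
  - viridae
  - virinae
virus_acronym_pattern: '^[A-Z][A-Za-z0-9-]{1,11}V$'
virus_prefix_pattern: '^[A-Z]{1,5}V-'

# Words marking hybrid name-strings beyond the hybrid sign itself.
hybrid_terms:
  - hybrid
  - hybridcultivar

# Words and phrases that signal the record names a symbiont or its host.
symbiont_terms:
  - symbiont
  - symbionts
  - endosymbiont
  - ectosymbiont
  - photobiont
  - phytoplasma
  - phytoplasm
  - parasite
  - parasitic
  - hyperparasite
  - host
  - hindgut
  - trophosome
  - inquiline
symbiont_phrases:
  - "gut protist"
  - "little leaf"
  - "within acanthamoeba"

# Annotation kinds that negate the whole name outright.
hard_negation_kinds: [negation]
# Annotation kinds that negate the species but may leave a usable genus.
soft_negation_kinds: [cf, aff, nr]

# Sample/habitat words: strings made only of these (plus generic filler)
# contain no taxon at all.
environmental_terms:
  - environmental
  - samples
  - sample
  - metagenome
  - metagenomic
  - enrichment
  - landfill
  - clone
  - ensemble
  - soil
  - sludge
  - sediment
  - seawater
  - phytodetritus

# Plain-language words: a token in this list is never accepted as a
# latinized genus or epithet, which routes the string to the
# common-name heuristic instead of a clade class.
english_words:
  - bird
  - fish
  - crab
  - tree
  - grass
  - grasses
  - asp
  - flea
  - fungus
  - moss
  - cross
  - whale
  - bat
  - shrew
  - frog
  - toad
  - fly
  - flies
  - beetle
  - spider
  - worm
  - mushroom
  - salamander
  - mongoose
  - civet
  - caterpillar
  - shrimp
  - spike
  - family
  - group
  - clade
  - lineage
  - lineages
  - complex
  - rat
  - mouse
  - duck
  - swift
  - ruff
  - rough
  - tommy
  - blow
  - northern
  - bottlenose
  - terrible
  - hairy
  - laboratory
  - diverging
  - fungal
  - early
  - daisy
  - clock
  - townhall
  - barf
  - tongues
  - women's
  - thing
  - wave
  - violet-washed
  - depressed
  - flour
  - similar
  - bacterium
  - bacteria
  - hamster
  - wasp
  - barb
  - spirochete
  - disease
  - wall-less
  - spotted
  - fever
  - grenadier
  - salmon
  - trout
  - maltese

# Strain/culture markers for surrogate detection.
strain_terms:
  - strain
  - str.
  - isolate
  - culture
  - type

# Organelle / subcellular terms (not organisms in their own right).
organelle_terms:
  - nucleomorph
  - plastid
  - chloroplast
  - mitochondrion
  - mitochondrial
  - intracisternal
  - a-particle
  - a-type

plasmid_terms:
  - plasmid
  - plasmids
  - plasposon

molecular_terms:
  - satellite
  - satellites
  - betasatellites
  - vector
  - construct
  - sequence
  - integrase
  - t-dna
  - dsrna
  - ssrna
  - rna
  - dna
  - gate
  - reporter
  - recombination

# Pattern for pure acronym/code strings (no latinized structure).
acronym_pattern: '^[A-Z0-9][A-Z0-9 :/_.\-()]*$'

# Suffixes recommended by the codes for ranks above genus.
higher_rank_suffixes:
  - aceae
  - idae
  - oidea
  - oidei
  - ales
  - ineae
  - inae
  - ini
  - formes
  - morpha
  - mycetes
  - mycota
  - mycotina
  - phyta
  - phytina
  - phyceae
  - opsida
  - poda
  - ptera
  - optera
  - archaeota
  - bacteria
  - bacteriales
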