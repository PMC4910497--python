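# Canonical names known to be homonyms across nomenclatural codes.
# One standard canonical per line; used to raise homonym alerts during
# cross-mapping. Extend from a registry (e.g. IRMNG) for production use.
Aotus
Asterina gibbosa
Baileya australis
Agathis
Morus
Pieris
Prunella
Oenanthe
Ficus
Dryas
Erica
Arenaria
Alsophila
Ammophila
Bison
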