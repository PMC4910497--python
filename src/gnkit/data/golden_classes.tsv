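name_string	major	minor
Carex scirpoidea Michx. ssp. convoluta (Kük.) Dunlop	clade_infraspecies	
Bison bison athabascae	clade_infraspecies	
Candida guilliermondii var. membranifaciens	clade_infraspecies	
Trichophyton mentagrophytes var. interdigitale (Priestley) Moraes 1950	clade_infraspecies	
Cucumis melo subsp. melo var. conomon	clade_infraspecies	
Najas guadalupensis subsp. floridana (R.R.Haynes & Wentz) R.R.Haynes & Hellq.	clade_infraspecies	
Pseudolucia tamara	clade_species	
Pseudolucia tamara Balint & Johnson, 1995	clade_species	
Thermus thermophilus (ex Oshima and Imahori 1974) Manaia et al. 1995	clade_species	
Oleria onega n. ssp. ME-2007	clade_species	
Bison bison	clade_species	
Girardinia diversifolia	clade_species	
Pseudomonas syringae	clade_species	
Achromobacter georgiopolitanum	clade_species	
Anolis barkeri Schmidt, 1939	clade_species	
Paludibacter propionicigenes WB4	clade_species	
Helicobacter pylori (Marshall et al. 1985) Goodwin et al. 1989	clade_species	
litoria ewingii	clade_species	
Paramecium sp	clade_genus	
Gambierodiscus aff toxicus	clade_genus	
Angophora BOLD 7117	clade_genus	
Myxococcus Thaxter 1892 emend. Lang and Stackebrandt 2009	clade_genus	
uncultured Candidatus Xenohaliotis sp.	clade_genus	
Bison	clade_genus	
Mumia Lee et al. 2014	clade_genus	
Apiospora	clade_genus	
Characiformes sp. BOLD:AAC1024	clade_higher	
Prochlorotrichaceae Burger-Wiersma et al. 1989	clade_higher	
Rhizobiaceae group	clade_higher	
Pasteurellaceae bacterium 35	clade_higher	
Balaenidae	clade_higher	
Pyrenomycetes	clade_higher	
RTBV	virus	
VESV	virus	
Puumala hantavirus	virus	
Marek's disease virus (MDV)	virus	
Coconut tinangaja viroid	virus	
Prochlorococcus cyanophage P-GSP1	virus	
Novosphingobium phage N-AFCF0707-15	virus	
Yersinia pestis bacteriophage phiA1122	virus	
unassigned Alphaherpesvirinae	virus	
Stejneger's beaked whale gammaherpesvirus	virus	
Human Herpesvirus-1	virus	
Influenza A virus (A/duck/Yangzhou/013/2009(H6N5))	virus	
Bovine viral diarrhea virus 2 C413	virus	
ArceNPV	virus	
TMMMV	virus	
unclassified Circovirus	virus	
Grandidier's Madagascar swift	common_name	
northern bottlenose whale	common_name	
terrible hairy fly	common_name	
daisy family	common_name	
tree	common_name	
grasses	common_name	
crab	common_name	
bird	common_name	
fish	common_name	
blow flies	common_name	
tommy ruff	common_name	
Martens's spike moss	common_name	
Maltese cross	common_name	
laboratory rat	common_name	
depressed flour beetle	common_name	
John-go-to-bed-at-noon	common_name	
sea cucumbers	common_name	
mites & ticks	common_name	
loosestrife family	common_name	
Lyme disease spirochete	common_name	
cai xin	common_name	
calabar angwantibo	common_name	
Zootermopsis hindgut protist	symbiont	
host Paramecium tetraurelia 51KMJ	symbiont	
Alvinella pompejana symbiont APG1Bstab9	symbiont	
Alviniconcha aff. hessleri gill endosymbiont	symbiont	
Incompatibility symbiont of Nasonia vitripennis	symbiont	
Chlorella symbiont of Hydra viridis	symbiont	
Wolbachia endosymbiont 1 of Acromyrmex octospinosus	symbiont	
Onion yellows phytoplasma	symbiont	
Phytoplasma sp. onion yellows	symbiont	
Lariskella endosymbiont of Curculio morimotoi	symbiont	
Urosporidium parasite of Stictodora lari	symbiont	
Euduboscquella sp. ex Favella markusovszkyi	symbiont	
Trypanosoma sp. from Abramis brama	symbiont	
Isospora sp. ex Talpa europaea	symbiont	
Riftia pachyptila trophosome symbiont	symbiont	
Melia azedarach phytoplasma	symbiont	
Star grass white leaf phytoplasma	symbiont	
Magnolia heptapeta x Magnolia quinquepeta	hybrid	
x Aranda	hybrid	
x Cuprocyparis leylandii	hybrid	
Hordeum sp. x Triticum sp.	hybrid	
Iris brevicaulis x fulva x hexagona	hybrid	
Sidalcea oregana subsp. oregana x Sidalcea asprella	hybrid	
Malus x domestica	hybrid	
Gerbera hybridcultivar	hybrid	
Rosa hybrid cultivar	hybrid	
domestic duck x muscovy duck	hybrid	
Labiotermes nr labralis	clade_genus	
Labiotermes cf. labralis	clade_genus	
Dendrobates aff. azureus CFBH 4203	clade_genus	
not Bacteria Haeckel 1894	negated	
not Thiobacteria Cavalier-Smith 1998	negated	
non Lupinus argenteus J.Agardh, nom. illeg.	negated	
A. niger	not_useful	abbreviated
E. coli	not_useful	abbreviated
E. caballus	not_useful	abbreviated
Rh. axei	not_useful	abbreviated
Oxy. cachemiriana	not_useful	abbreviated
pluricinctus	not_useful	no_genus
vancouverensis	not_useful	no_genus
caudata	not_useful	no_genus
936	not_useful	numbered
454594	not_useful	numbered
1-Mar	not_useful	numbered
24-pointed ladybird beetle	not_useful	numbered
309_Lg_sofi_MtRi_Bulg	not_useful	numbered
environmental samples	not_useful	environmental
coal metagenome	not_useful	environmental
tomb wall metagenome	not_useful	environmental
environmental clone CC-9	not_useful	environmental
corbulasulcata	not_useful	concatenated_unresolved
ecoli	not_useful	no_genus
strain serial (Mueller et al.) n 189	not_useful	strain_surrogate
strain number 81 Dorey	not_useful	strain_surrogate
type strain 130333	not_useful	strain_surrogate
strain=UTEX LB 1032	not_useful	strain_surrogate
ATCC 33224	not_useful	acronym
NBRC 14945	not_useful	acronym
CTEARO	not_useful	acronym
Syrian hamster intracisternal A-particle SHIAP18	not_useful	organelle
nucleomorph Pyrenomonas salina	not_useful	organelle
plastid Porphyridium aerugineum	not_useful	organelle
TOL plasmid	not_useful	plasmid
yeast plasmid pGKl2	not_useful	plasmid
promiscuous plasmids	not_useful	plasmid
Betasatellites	not_useful	molecular
beta satellites	not_useful	molecular
artificial sequence	not_useful	molecular
Boolean Integrase Logic XNOR gate	not_useful	molecular
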