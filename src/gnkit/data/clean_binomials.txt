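# Clean reference binomials drawn from the toolkit's example corpus.
# One scientific name (genus + specific epithet) per line.
Ablepharus boutonii
Abramis brama
Abudefduf saxatilis
Abudefduf septemfasciatus
Acacia catechu
Acanthamoeba castellanii
Acanthurus leucosternon
Acer cappadocicum
Achromobacter georgiopolitanum
Acromyrmex octospinosus
Aegilops triaristata
Aegiphila brachiata
Aleiantus incertus
Alvinella pompejana
Alviniconcha hessleri
Amphiglossus robustus
Anabaena planktonica
Anguilla anguilla
Anolis barkeri
Anolis ernestwilliamsi
Anomaloglossus degranvillei
Anopheles kleini
Anopheles sinensis
Anthaenantia villosa
Aphis citricidus
Aporrectodea longa
Aporrectodea nocturna
Arabidopsis thaliana
Asterina gibbosa
Bacillus thuringiensis
Bacillus xiaoxiensis
Baileya australis
Bembidion concolor
Bison bison
Blumea hieracifolia
Bombyx mori
Bothrops taeniata
Botryllus planus
Brucella abortus
Brucella ovis
Burkholderia cenocepacia
Caestocorbula gerardi
Calonectria microconidialis
Campylobacter fetus
Campylobacter jejuni
Candida guilliermondii
Ceropegia anjanerica
Chilomonas paramecium
Citrus reticulata
Citrus sinensis
Citrus unshiu
Cnemidophorus sackii
Cnemidophorus tigris
Coluber haje
Columbicola bacillus
Corbula cotuhensis
Corbula sulcata
Cryptoblepharus boutonii
Cryptomonas paramecium
Cucumis melo
Cupressocyparis leylandii
Cupressus arizonica
Cupressus macrocarpa
Cupressus nootkatensis
Curculio morimotoi
Cyanocitta stelleri
Danio rerio
Darevskia alpina
Darevskia daghestanica
Dendrobates azureus
Diaphanta chryseres
Didemnum vexillum
Didymostilbe sundara
Diloma nigerrima
Diphtherophora lata
Drosophila melanogaster
Emiliania huxleyi
Enteromorpha prolifera
Epichloe uncinata
Erigeron altaicus
Erigeron annuus
Erigeron canadensis
Erysimum odoratum
Escherichia coli
Euglossa cyanaspis
Euphorbia trichotoma
Favella markusovszkyi
Festulolium braunii
Gallus gallus
Gambierodiscus toxicus
Girardinia diversifolia
Griffonia simplicifolia
Helicobacter pylori
Helicteres baruensis
Homo sapiens
Hordeum vulgare
Hydra viridis
Hypericum patulum
Hyperolius viridiflavus
Hypocrea jecorina
Hypothyris anastasia
Ichneumon dorsalis
Inanidrilus exumae
Indigofera argentea
Indigofera grandiflora
Indigofera roseocaerulea
Ipomopsis aggregata
Ipomopsis tenuituba
Iris brevicaulis
Iris fulva
Iris hexagona
Klebsormidium dissectum
Kummerowia striata
Labiotermes labralis
Lacerta capensis
Lacerta vivipara
Lilium regale
Limax graecus
Lissoclinum timorense
Lithastrinus moratus
Litoria ewingii
Litoria moorei
Lobivia leptacantha
Lupinus argenteus
Lysandra coridon
Mageeibacillus indolicus
Magnolia heptapeta
Magnolia quinquepeta
Melanocetus johnsoni
Melia azedarach
Meroles ctenodactylus
Microsporum canis
Monochamus galloprovincialis
Mucor miehei
Myxine glutinosa
Myxosoma cerebralis
Naja haje
Najas guadalupensis
Nasonia vitripennis
Oedipus lincolni
Oikopleura labradoriensis
Osedax roseus
Owenia hillii
Oxalis adenophylla
Paludibacter propionicigenes
Papaver somnifera
Papaver somniferum
Paramecium tetraurelia
Parapercis lutevittata
Parathyma opalina
Pedioplanis laticeps
Phaeophleophleospora epicoccoides
Phaseolus vulgaris
Phenylobacter ium
Pieris japonica
Pineus pini
Pinoyscincus jagori
Plasmodium vivax
Platycladus orientalis
Pocillopora damicornis
Populus alba
Populus glandulosa
Populus maximowiczii
Populus tomentosa
Populus trichocarpa
Porphyra purpurea
Pratia macrodon
Prorocentrum micans
Prunus armeniaca
Pseudallescheria africana
Pseudolucia tamara
Pseudomonas syringae
Pyramimonas cordata
Pyrus hybrida
Ranunculus mirus
Rattus rattus
Rhabditella axei
Rhinella spinulosa
Rhizobiaceae group
Riftia pachyptila
Rorippa hybosperma
Rosa hybrida
Rosa multiflora
Russula xerampelina
Saccharomyces bayanus
Saccharomyces cerevisiae
Sammodictyon panduriforme
Sargus bipunctatus
Sarracenia purpurea
Scincus boutonii
Secale cereale
Sidalcea asprella
Sidalcea oregana
Solanum sendtnerianum
Sophophora melanogaster
Sphagnum affine
Sphagnum aureum
Sphagnum auriculatum
Sphagnum austinii
Sphagnum beringiense
Sphagnum bordasii
Sphagnum brasiliense
Sphagnum cribrosum
Sphagnum crispum
Sphagnum cymbifolioides
Sphagnum ecuadorense
Sphagnum inexspectatum
Sphagnum kenaiense
Sphagnum khasianum
Sphagnum leonii
Sphagnum microcarpum
Sphagnum monzonense
Sphagnum nemoreum
Sphagnum palenae
Sphagnum patens
Sphagnum perfoliatum
Sphagnum pulchricoma
Sphagnum pycnocladum
Sphagnum sjorsii
Sphagnum tenerum
Sphagnum vitjianum
Sphagnum warnstorfii
Sphagnum wheeleri
Spinochlamydosporium variabile
Stagonosporopsis bohemica
Staphylococcus aureus
Stauroneis legumen
Stictodora lari
Streptomyces cinnamomeus
Streptomyces cinnamoneus
Streptostele elgonensis
Talpa europaea
Tamarix androssowii
Tasmanogobius lasti
Tradescantia brevifolia
Triactinomyxon gyrosalmo
Trichoderma reesei
Trichophyton mentagrophytes
Triticum aestivum
Troglodytes troglodytes
Tsuchiyeae wingfieldii
Ureaplasma urealyticum
Ursirivus pyriformis
Vesicomya cordata
Vesicomya gigas
Xanthomonas populi
Zygrhablithus bijugatus
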