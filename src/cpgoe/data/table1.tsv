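species	taxon_class	ordinal_group	mean_gene_body_cpg_oe	mean_repeat_cpg_oe	dnmt_absent	mbd_absent
Actinia tenebrosa	Anthozoa	Actiniaria	0.69	0.90	false	false
Aiptasia pallida	Anthozoa	Actiniaria	0.69	0.98	false	false
Anthopleura elegantissima	Anthozoa	Actiniaria	0.68		false	false
Edwardsiella lineata	Anthozoa	Actiniaria	0.758		false	false
Nematostella vectensis	Anthozoa	Actiniaria	0.77		false	false
Acanthogorgia aspera	Anthozoa	Alcyonacea	0.83		false	false
Briareum asbestinum	Anthozoa	Alcyonacea	0.79		false	false
Clavularia sp.	Anthozoa	Alcyonacea	0.82		false	false
Corallium rubrum	Anthozoa	Alcyonacea	0.84		false	false
Dendronephthya gigantea	Anthozoa	Alcyonacea	0.84	1.03	false	false
Eleutherobia rubra	Anthozoa	Alcyonacea	0.88		false	false
Eunicella cavolinii	Anthozoa	Alcyonacea	0.85		false	false
Eunicella verrucosa	Anthozoa	Alcyonacea	0.84		true	false
Gorgonia ventalina	Anthozoa	Alcyonacea	0.75		false	false
Leptogorgia sarmentosa	Anthozoa	Alcyonacea	0.85		false	false
Xenia sp.	Anthozoa	Alcyonacea	0.79		false	false
Corynactis australis	Anthozoa	Corallimorpharia	0.81		false	false
Rhodactis indosinensis	Anthozoa	Corallimorpharia	0.71		false	false
Ricordea yuma	Anthozoa	Corallimorpharia	0.72		false	false
Heliopora coerulea	Anthozoa	Helioporacea	0.66		false	false
Acropora digitefera	Anthozoa	Scleractinia	0.70	0.90	false	false
Acropora millepora	Anthozoa	Scleractinia	0.72	0.91	false	false
Ctenactis echinata	Anthozoa	Scleractinia	0.64		false	false
Favia lizardensis	Anthozoa	Scleractinia	0.66		false	false
Lobactis scutaria	Anthozoa	Scleractinia	0.67		false	false
Madracis auretenra	Anthozoa	Scleractinia	0.75		false	false
Montastraea cavernosa	Anthozoa	Scleractinia	0.68		false	false
Orbicella faveolata	Anthozoa	Scleractinia	0.73	0.93	false	false
Platygyra carnosus	Anthozoa	Scleractinia	0.72		false	false
Pocillopora damicornis	Anthozoa	Scleractinia	0.70	0.87	false	false
Seriatopora hystrix	Anthozoa	Scleractinia	0.68		false	false
Stylophora pistillata	Anthozoa	Scleractinia	0.70	0.92	false	false
Ectopleura larynx	Hydrozoa	Aplanulata	0.97		false	false
Hydra oligactis	Hydrozoa	Aplanulata	0.75		false	false
Hydra viridissima	Hydrozoa	Aplanulata	0.64		false	false
Hydra vulgaris	Hydrozoa	Aplanulata	0.63	1.03	false	false
Porpita porpita	Hydrozoa	Capitata	0.67		false	false
Velella velella	Hydrozoa	Capitata	0.80		false	false
Hydractinia polyclina	Hydrozoa	Filifera III	0.82		false	false
Hydractinia symbiolongicarpus	Hydrozoa	Filifera III	0.81		false	false
Podocoryna carnea	Hydrozoa	Filifera III	0.63		false	false
Turritopsis sp.	Hydrozoa	Filifera IV	0.83		false	false
Clytia hemisphaerica	Hydrozoa	Leptothecata	0.81		false	false
Dynamena pumila	Hydrozoa	Leptothecata	0.83		false	false
Craspedacusta sowerbyi	Hydrozoa	Limnomedusae	0.90		false	false
Aegina citrea	Hydrozoa	Narcomedusae	0.85		false	true
Abylopsis tetragona	Hydrozoa	Siphonophorae	0.72		false	false
Agalma elegans	Hydrozoa	Siphonophorae	0.76		false	false
Craseoa lathetica	Hydrozoa	Siphonophorae	0.74		false	false
Nanomia bijuga	Hydrozoa	Siphonophorae	0.83		false	false
Physalia physalis	Hydrozoa	Siphonophorae	0.76		false	false
Alatina alata	Cubozoa	Carybdeida	0.75		false	false
Copula sivickisi	Cubozoa	Carybdeida	0.71		false	false
Morbakka virulenta	Cubozoa	Carybdeida	0.65	0.66	false	false
Tripedalia cystophora	Cubozoa	Carybdeida	0.66		false	false
Chironex fleckeri	Cubozoa	Chirodropoda	0.67		false	false
Chironex yamaguchii	Cubozoa	Chirodropoda	0.65		false	false
Atolla vanhoeffeni	Scyphozoa	Coronatae	0.71		false	false
Cassiopea xamachana	Scyphozoa	Rhizostomeae	0.58	0.65	false	false
Nemopilema nomurai	Scyphozoa	Rhizostomeae	0.69		false	false
Rhopilema esculentum	Scyphozoa	Rhizostomeae	0.66		false	false
Stomolophus meleagris	Scyphozoa	Rhizostomeae	0.70		false	false
Aurelia aurita	Scyphozoa	Semaeostomeae	0.69		false	false
Aurelia coerulia	Scyphozoa	Semaeostomeae	0.649	0.74	false	false
Chrysaora fuscescens	Scyphozoa	Semaeostomeae	0.67		false	false
Calvadosia cruxmelitensis	Staurozoa	Stauromedusae	0.78		false	false
Craterolophus convolvulus	Staurozoa	Stauromedusae	0.83		false	false
Haliclystus auricula	Staurozoa	Stauromedusae	0.74		false	false
Haliclystus sanjuanensis	Staurozoa	Stauromedusae	0.73		false	false
Lucernaria quadricornis	Staurozoa	Stauromedusae	0.91		false	false
Henneguya salminicola	Myxozoa	Bivalvulida	1.01		true	true
Myxobolus cerebralis	Myxozoa	Bivalvulida	1.04		true	true
Myxobolus pendula	Myxozoa	Bivalvulida	0.82		true	true
Myxobolus squamalis	Myxozoa	Bivalvulida	1.00	0.62	true	true
Thelohanellus kitauei	Myxozoa	Bivalvulida	0.96	1.07	true	true
Polypodum hydriforme	Polypodiozoa	Polypodiidea	0.68		false	false
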