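# Default hydrocarbon-biodegradation guild (version 1.0).
# Curated set of 63 bacterial genera, each with at least one described
# hydrocarbon-degrading strain or strong environmental evidence of a role in
# hydrocarbon biodegradation (alkanes and/or aromatics), drawn from the
# primary literature on oil-impacted marine and terrestrial microbial
# communities. Membership is a replaceable data asset, not code: edit this
# file or supply your own TSV to redefine the guild. Columns: genus, phylum,
# isolation_environment (marine|terrestrial|both|unknown), synonyms
# (semicolon-separated alternate labels accepted during matching),
# evidence_note (free text).
genus	phylum	isolation_environment	synonyms	evidence_note
Alcanivorax	Proteobacteria	marine		obligate hydrocarbonoclastic; dominant alkane degrader after marine oil spills
Cycloclasticus	Proteobacteria	marine		obligate PAH degrader in seawater and sediments
Oleispira	Proteobacteria	marine		psychrophilic obligate hydrocarbonoclastic alkane degrader
Oleiphilus	Proteobacteria	marine		obligate hydrocarbonoclastic alkane degrader
Thalassolituus	Proteobacteria	marine		obligate hydrocarbonoclastic alkane degrader
Oleibacter	Proteobacteria	marine		alkane degrader from tropical seawater
Marinobacter	Proteobacteria	marine		widespread marine alkane and aromatic degrader
Neptunomonas	Proteobacteria	marine		naphthalene-degrading isolates from marine sediment
Neptuniibacter	Proteobacteria	marine		carbazole and aromatic degradation in seawater
Porticoccus	Proteobacteria	marine		PAH-degrading isolates associated with phytoplankton
Pseudoalteromonas	Proteobacteria	marine		aromatic degradation in cold seawater enrichments
Marinomonas	Proteobacteria	marine		phenanthrene-degrading marine isolates
Colwellia	Proteobacteria	marine		hydrocarbon degradation in cold deep-sea waters
Halomonas	Proteobacteria	both		halotolerant alkane and aromatic degraders
Thalassospira	Proteobacteria	marine		PAH degradation in oligotrophic seawater
Vibrio	Proteobacteria	marine		PAH-degrading strains from coastal sediment
Roseobacter	Proteobacteria	marine		aromatic compound degradation within the marine Roseobacter clade
Roseovarius	Proteobacteria	marine		aromatic degradation; enriched in oiled sediments
Sulfitobacter	Proteobacteria	both		aromatic compound transformation in Roseobacter-clade strains
Jannaschia	Proteobacteria	marine		Roseobacter-clade genus enriched under oil exposure
Paracoccus	Proteobacteria	both		PAH-degrading strains from sediment and soil
Hyphomonas	Proteobacteria	marine		prosthecate genus enriched on oil; PAH transformation
Rhodobacter	Proteobacteria	both		aromatic acid metabolism; oil-enrichment isolates
Sphingomonas	Proteobacteria	terrestrial		versatile aromatic and PAH degrader
Sphingobium	Proteobacteria	terrestrial		PAH and chlorinated aromatic degrader
Novosphingobium	Proteobacteria	both		PAH degradation in estuarine and soil isolates
Sphingopyxis	Proteobacteria	both		alkane and aromatic degradation; oiled-sediment isolates
Parvibaculum	Proteobacteria	both		initial alkane oxidation; linear alkylbenzene degradation
Xanthobacter	Proteobacteria	terrestrial		alkene and cyclic hydrocarbon degradation
Azoarcus	Proteobacteria	terrestrial		anaerobic toluene and ethylbenzene degradation
Thauera	Proteobacteria	terrestrial		anaerobic aromatic hydrocarbon degradation
Georgfuchsia	Proteobacteria	terrestrial		anaerobic aromatic degradation in aquifers
Geobacter	Proteobacteria	terrestrial		anaerobic toluene oxidation coupled to iron reduction
Desulfobacula	Proteobacteria	marine		anaerobic toluene-degrading sulfate reducer
Desulfatibacillum	Proteobacteria	marine		anaerobic alkane-degrading sulfate reducer
Pseudomonas	Proteobacteria	both		model alkane and aromatic degrader (alk, nah pathways)
Acinetobacter	Proteobacteria	both		alkane degradation; emulsifier production
Burkholderia	Proteobacteria	terrestrial		PAH and BTEX degradation in soil
Cupriavidus	Proteobacteria	terrestrial	Ralstonia	aromatic degradation in soil isolates
Polaromonas	Proteobacteria	terrestrial		naphthalene degradation in cold soils
Comamonas	Proteobacteria	terrestrial		phenanthrene and aromatic acid degradation
Delftia	Proteobacteria	terrestrial		aromatic degradation in contaminated soil
Achromobacter	Proteobacteria	terrestrial		BTEX and alkane degradation in soil
Alcaligenes	Proteobacteria	terrestrial		aromatic hydrocarbon degradation
Stenotrophomonas	Proteobacteria	terrestrial		PAH degradation in rhizosphere isolates
Rhodococcus	Actinobacteria	both		broad alkane and aromatic degrader; cold-adapted strains
Mycobacterium	Actinobacteria	both		high-molecular-weight PAH degradation
Nocardia	Actinobacteria	terrestrial		alkane and aromatic degradation
Nocardioides	Actinobacteria	both		PAH degradation; enriched in oiled sediments
Gordonia	Actinobacteria	both		alkane and branched-alkane degradation
Dietzia	Actinobacteria	both		long-chain alkane degradation in saline habitats
Arthrobacter	Actinobacteria	terrestrial		aromatic and phenolic compound degradation
Corynebacterium	Actinobacteria	both		alkane-degrading isolates from oily environments
Streptomyces	Actinobacteria	terrestrial		alkane and aromatic degradation in soil
Microbacterium	Actinobacteria	both		PAH degradation in sediment enrichments
Janibacter	Actinobacteria	both		dibenzofuran and PAH degradation
Williamsia	Actinobacteria	both		alkane degradation; mycolic-acid actinomycete
Flavobacterium	Bacteroidetes	both		aromatic degradation in freshwater and soil
Olleya	Bacteroidetes	marine		enriched on crude oil in seawater mesocosms
Yeosuana	Bacteroidetes	marine		PAH-degrading marine flavobacterium
Bacillus	Firmicutes	both		alkane and PAH-degrading strains from soil and sediment
Paenibacillus	Firmicutes	terrestrial		naphthalene degradation in soil isolates
Planococcus	Firmicutes	marine		alkane degradation in saline environments
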