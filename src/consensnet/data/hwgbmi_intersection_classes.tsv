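# Functional categorization (category / class / family, SPP convention) of the
# 40 genes shared between the mouse weight-gain-prone blood gene set and the
# human weight/BMI-correlated gene set.
gene	category	class	family
Car2	Enzymes	Dehydratases	Carbonic anhydrases (CA)
Ube2f	Enzymes	E2 ubiquitin conjugating enzymes	Ubiquitin conjugating enzymes E2 (UBE2)
Ube2h	Enzymes	E2 ubiquitin conjugating enzymes	Ubiquitin conjugating enzymes E2 (UBE2)
Mkrn1	Enzymes	E3 ubiquitin ligases	Makorin (MKRN)
Marchf8	Enzymes	E3 ubiquitin ligases	Membrane associated ring-CH-type finger
Trim10	Enzymes	E3 ubiquitin ligases	Tripartite motif-containing (TRIM)
Trim58	Enzymes	E3 ubiquitin ligases	Tripartite motif-containing (TRIM)
Mpp1	Enzymes	Kinases	Membrane palmitoylated proteins
Fech	Enzymes	Lyases	Ferrochelatases
Smox	Enzymes	Oxidases	Spermine oxidases
Ctsb	Enzymes	Peptidases	Cathepsins (CTS)
Prdx2	Enzymes	Peroxidases	Peroxiredoxins (PRDX)
Bcl2l1	Enzymes	Regulatory factors	Protein phosphatase 1 regulatory subunits
Hmbs	Enzymes	Transferases	Hydroxymethylbilane synthases
Glul	Enzymes	Other enzymes	Glutamate-ammonia ligases
Glrx5	Enzymes	Other enzymes	Glutaredoxin
E2f2	Transcription factors	E2F/FOX	E2F
Rad23a	Co-nodes	Cell cycle, cell division & DNA repair	Cell cycle checkpoint proteins (RAD)
Gadd45a	Co-nodes	Cell cycle, cell division & DNA repair	Growth arrest and DNA damage inducible
Snca	Co-nodes	CNS Proteins	Synuclein
Dmtn	Co-nodes	Cytoskeleton components & regulators	Dematin actin binding protein
Tpm1	Co-nodes	Cytoskeleton components & regulators	Tropomyosin
Fbxo7	Co-nodes	F box domain	F-box protein
Fbxo9	Co-nodes	F box domain	F-box protein
Fam104a	Co-nodes	Family with sequence similarity	Family with sequence similarity member
Fam210b	Co-nodes	Family with sequence similarity	Family with sequence similarity member
Hbq1b	Co-nodes	Globins	Hemoglobin subunit theta
Tmcc2	Co-nodes	Membrane proteins	Transmembrane and coiled-coil domain
Gabarapl2	Co-nodes	Receptor associated factors	GABA type A receptor associated protein like
Grina	Co-nodes	Receptor associated factors	Glutamate ionotropic receptor NMDA type subunit associated
Rnf10	Co-nodes	Ring finger proteins	Ring finger protein
Rnf11	Co-nodes	Ring finger proteins	Ring finger protein
Dnaja4	Co-nodes	Stress response factors	DnaJ heat shock protein (Hsp40) member
Slc25a37	Co-nodes	Transporters & transport proteins	Solute carrier superfamily member
Slc48a1	Co-nodes	Transporters & transport proteins	Solute carrier superfamily member
Slc4a1	Co-nodes	Transporters & transport proteins	Solute carrier superfamily member
Bnip3l	Co-nodes	Other co-nodes	BCL2 interacting protein like
Creg1	Co-nodes	Other co-nodes	Cellular repressor of E1A stimulated genes
Fundc2	Co-nodes	Other co-nodes	FUN14 domain containing
Pithd1	Co-nodes	Other co-nodes	PITH domain containing
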