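# Default physiological/functional feature ruleset (30 features).
# kind=pathway rules carry the EC content of the encoded pathway; a trailing
# '-' field in an EC pattern is a wildcard.  'alternatives' holds alternative
# EC sets separated by '|'.  kind=gene_list rules are called present when at
# least min_fraction of the listed genes are annotated.  kind=stub features
# are part of the assessed vocabulary but ship without default content; they
# evaluate to not_evaluable until the user configures them.
name	kind	required_ec	alternatives	gene_ids	min_fraction	note
acetate_production	pathway	2.3.1.8,2.7.2.1				acetate production from acetyl-CoA
propionate_production	pathway	2.3.1.8,2.7.2.1	2.3.1.222,2.7.2.1			propionate production from propanoyl-CoA
butyrate_production	pathway	2.8.3.8				butyrate production from butanoyl-CoA
sulfide_serine_to_cysteine_acetate	pathway	2.3.1.30,2.5.1.47				sulfide and L-serine utilised to produce L-cysteine and acetate
glutamate_from_ammonia	pathway	6.3.1.2,1.4.1.-				L-glutamate production from ammonia via L-glutamine
folate_biosynthesis	pathway	1.5.1.3				folate (vitamin B9) biosynthesis from 7,8-dihydrofolate
riboflavin_biosynthesis	pathway	3.5.4.25,3.5.4.26,1.1.1.193,3.1.3.104,4.1.99.12,2.5.1.78,2.5.1.9,2.7.1.26,2.7.7.2				riboflavin (vitamin B2) biosynthesis from GTP
cobalamin_biosynthesis	pathway	2.5.1.17,6.3.5.10,6.2.1.10,2.7.1.156				cobalamin (vitamin B12) biosynthesis from cobinamide
flagella	gene_list			flgB,flgC,flgD,flgE,flgF,flgG,flgH,flgI,flgK,flgL,flhA,flhB,fliA,fliC,fliD,fliE,fliF,fliG,fliH,fliI,fliK,fliM,fliN,fliP,fliQ	0.5	flagellar assembly gene set (n=25)
spore_formation	gene_list			spo0A,spo0B,spo0F,spoIIAA,spoIIAB,spoIIB,spoIID,spoIIE,spoIIGA,spoIIM,spoIIP,spoIIQ,spoIIR,spoIIIAA,spoIIIAB,spoIIIAC,spoIIIAD,spoIIIAE,spoIIIAF,spoIIIAG,spoIIIAH,spoIIID,spoIIIE,spoIIIJ,spoIVA,spoIVB,spoIVCA,spoIVFA,spoIVFB,spoVAA,spoVAB,spoVAC,spoVAD,spoVAE,spoVB,spoVD,spoVE,spoVFA,spoVFB,spoVG,spoVID,spoVK,spoVM,spoVR,spoVS,spoVT,sigE,sigF,sigG,sigK,gerAA,gerAB	0.5	sporulation gene set (n=52)
glucose_utilisation	stub					carbon source; content user-configured
arbutin_utilisation	stub					carbon source; content user-configured
salicin_utilisation	stub					carbon source; content user-configured
cellobiose_utilisation	stub					carbon source; content user-configured
sucrose_utilisation	stub					carbon source; content user-configured
trehalose_utilisation	stub					carbon source; content user-configured
maltose_utilisation	stub					carbon source; content user-configured
starch_utilisation	stub					carbon source; content user-configured
dextran_utilisation	stub					carbon source; content user-configured
cellulose_utilisation	stub					carbon source; content user-configured
urease	stub					content user-configured
siroheme_biosynthesis	stub					content user-configured
eps_biosynthesis	stub					content user-configured
cytochrome_c_oxidase	stub					content user-configured
ammonia_production	stub					content user-configured
nitrification	stub					content user-configured
sulfate_assimilatory_reduction	stub					content user-configured
biotin_biosynthesis	stub					vitamin B7; content user-configured
menaquinone_biosynthesis	stub					vitamin K2; content user-configured
phylloquinone_biosynthesis	stub					vitamin K1; content user-configured
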