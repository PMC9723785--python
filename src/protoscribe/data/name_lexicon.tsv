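# Naming lexicon: environment-keyed genus prefixes, genus stems, and
# trait-keyed epithet roots with explicit gender triples (no algorithmic
# Latin inflection).  Gut/host-environment prefixes follow published
# etymological practice for habitat-derived genus names; prefixes for the
# remaining environments are package-authored illustrative combining forms
# and are expected to be curated by the user.
# section	key	value	gender	etymology
prefix	pig gut	Porcipeletho		L. masc. n. porcus, a piglet; Gr. masc. n. pelethos, dung
prefix	pig gut	Suilimi		L. masc. n. sus, a pig; L. masc. n. limus, dung
prefix	pig gut	Suontho		L. masc. n. sus, a pig; Gr. masc. n. onthos, dung
prefix	pig gut	Huintestini		Gr. masc./fem. n. hus, a pig; L. neut. n. intestinum, the gut
prefix	human gut	Brotolimi		Gr. masc. n. brotos, a mortal human; L. masc. n. limus, dung
prefix	human gut	Brotomerdi		Gr. masc. n. brotos, a mortal human; L. fem. n. merda, dung
prefix	human gut	Brotontho		Gr. masc. n. brotos, a mortal human; Gr. masc. n. onthos, dung
prefix	human gut	Hominimerdi		L. masc. n. homo, a human being; L. fem. n. merda, dung
prefix	human gut	Hoministercor		L. masc. n. homo, a human being; L. neut. n. stercus, dung
prefix	human gut	Anthropogastro		Gr. masc. n. anthropos, a human being; Gr. fem. n. gaster, the stomach
prefix	mouse gut	Muricopro		L. masc. n. mus, a mouse; Gr. fem. n. kopros, dung
prefix	mouse gut	Muriventri		L. masc. n. mus, a mouse; L. masc. n. venter, the belly
prefix	chicken gut	Gallintestini		L. masc. n. gallus, a chicken; L. neut. n. intestinum, the gut
prefix	chicken gut	Laedolimi		Gr. masc. n. laedos, an unknown bird; L. masc. n. limus, dung
prefix	chicken gut	Alitiscato		L. masc./fem. n. ales, a bird; Gr. neut. n. skor, dung
prefix	bovine gut	Bovifimi		L. masc./fem. n. bos, an ox, a bull, a cow; L. neut. n. fimum, dung
prefix	human vagina	Aedoe		Gr. neut. n. aidoion, the female pudendum
prefix	activated sludge	Caeni		L. neut. n. caenum, mud, filth
prefix	coral	Coralli		L. neut. n. corallium, coral
prefix	freshwater	Aqui		L. fem. n. aqua, water
prefix	human lung	Pulmoni		L. masc. n. pulmo, the lung
prefix	human oral	Bucci		L. fem. n. bucca, the mouth, the cheek
prefix	human skin	Cuti		L. fem. n. cutis, the skin
prefix	insect gut	Insecti		L. neut. n. insectum, an insect
prefix	marine	Mari		L. neut. n. mare, the sea
prefix	marine sediment	Sabuli		L. neut. n. sabulum, sand
prefix	plant	Planti		L. fem. n. planta, a plant
prefix	rhizosphere	Rhizo		Gr. fem. n. rhiza, a root
prefix	soil	Terri		L. fem. n. terra, earth, soil
prefix	wastewater	Cloaci		L. fem. n. cloaca, a sewer
stem	monas	monas	fem	L. fem. n. monas, a monad
stem	cola	cola	fem	N.L. masc./fem. suff. -cola (from L. v. colere, to inhabit), an inhabitant of
stem	vivens	vivens	fem	L. pres. part. vivens, living
stem	microbium	microbium	neut	N.L. neut. n. microbium, a microbe
stem	adaptatus	adaptatus	masc	L. past part. adaptatus, adapted
epithet	butyrate_production	butyricus|butyrica|butyricum	adj	Gr. neut. n. boutyron (Latin transliteration butyrum), butter; suff. -icus/-ica/-icum, belonging to::related to butter, butyric
epithet	propionate_production	propionicus|propionica|propionicum	adj	N.L. neut. n. acidum propionicum, propionic acid; suff. -icus/-ica/-icum, pertaining to::pertaining to propionic acid
epithet	acetate_production	aceti|aceti|aceti	gen_n	L. neut. n. acetum, vinegar::of vinegar
epithet	glutamate_from_ammonia	ammoniilyticus|ammoniilytica|ammoniilyticum	adj	N.L. neut. n. ammonium, ammonia; Gr. adj. lytikos, able to loose, able to dissolve::ammonia-degrading
epithet	starch_utilisation	amylophilus|amylophila|amylophilum	adj	Gr. neut. n. amylon, starch; Gr. adj. philos, loving::starch-loving
epithet	cellulose_utilisation	cellulolyticus|cellulolytica|cellulolyticum	adj	N.L. neut. n. cellulosum, cellulose; Gr. adj. lytikos, able to loose, able to dissolve::cellulose-dissolving
epithet	__fallback__	incognitus|incognita|incognitum	adj	L. adj. incognitus, unknown::as-yet-uncharacterised
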