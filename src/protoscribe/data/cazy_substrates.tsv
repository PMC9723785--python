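# Illustrative CAZy-family -> substrate map, editable by the user.
# Entries are textbook family/substrate associations (e.g. GH13 alpha-amylases
# acting on starch); they are starting points for curation, not claims about
# any particular genome.
family	substrate
GH13	starch
GH77	starch
GH5	cellulose
GH9	cellulose
GH1	cellobiose
GH3	cellobiose
GH32	sucrose
GH65	trehalose
GH4	maltose
GH66	dextran
GH49	dextran
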