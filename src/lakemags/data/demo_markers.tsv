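marker_id	function_category
TIGR1282	nitrogen fixation
TIGR1286	nitrogen fixation
TIGR1287	nitrogen fixation
TIGR04246	denitrification
TIGR02376	denitrification
COG5013	denitrification
TIGR01792	urease
PF00016	carbon fixation
PF02788	carbon fixation
PF01266	sulfide oxidation
TIGR04486	thiosulfate oxidation
TIGR04485	thiosulfate oxidation
TIGR03080	methanotrophy
PF00124	photosynthesis
PF00223	photosynthesis
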