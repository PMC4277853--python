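species	location	n_networks
Aegopodium podagraria	Denmark	2
Ageratum conyzoides	Galapagos Islands (Ecuador)	1
Bidens pilosa	Galapagos Islands (Ecuador)	1
Bidens pilosa	Japan	1
Calystegia sepium	Denmark	2
Campanula rotundifolia	Denmark	2
Cirsium arvense	New Zealand	1
Cirsium arvense	United Kingdom	2
Cytisus scoparius	New Zealand	1
Daucus carota	Denmark	2
Daucus carota	United Kingdom	1
Eupatorium cannabinum	Denmark	2
Hieracium pilosella	New Zealand	1
Leucaena leucocephala	Mauritius	1
Leucanthemum vulgare	Azores (Portugal)	1
Linaria vulgaris	United States	1
Lotus corniculatus	Azores (Portugal)	1
Opuntia stricta	Spain	1
Oxalis corniculata	Japan	2
Oxalis pes-caprae	Canary Islands (Spain)	1
Oxalis pes-caprae	Greece	1
Passiflora foetida	Galapagos Islands (Ecuador)	2
Prunus serotina	Denmark	1
Psidium guajava	Galapagos Islands (Ecuador)	1
Scaevola frutescens	Japan	1
Scaevola sericea	Mauritius	1
Senecio lautus	Australia	1
Solidago sempervirens	Azores (Portugal)	1
Tanacetum vulgare	Denmark	2
Trifolium pratense	Denmark	1
Trifolium repens	Denmark	3
Trifolium repens	Japan	3
Trifolium repens	New Zealand	1
Verbascum thapsus	New Zealand	1
Vicia sativa	United Kingdom	1
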