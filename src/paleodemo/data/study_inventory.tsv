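species	common_name	ocean	group	data_type	n	marker	length_bp
Balaenoptera acutorostrata	Common minke whale	North Atlantic	whale	mtdna	931	CR	322
Balaenoptera musculus	Blue whale	North Atlantic	whale	mtdna	325	CR	404
Balaenoptera physalus	Fin whale	North Atlantic	whale	mtdna	280	CR	391
Megaptera novaeangliae	Humpback whale	North Atlantic	whale	mtdna	1086	CR	396
Eubalaena glacialis	North Atlantic right whale	North Atlantic	whale	mtdna	269	CR	381
Balaena mysticetus	Bowhead whale	North Atlantic	whale	mtdna	395	CR	454
Meganyctiphanes norvegica	Northern krill	North Atlantic	prey	mtdna	834	DI	155
Calanus helgolandicus	Copepod	North Atlantic	prey	mtdna	218	16S	408
Centropages typicus	Copepod	North Atlantic	prey	mtdna	79	COI	560
Pleuromamma abdominalis	Copepod	North Atlantic	prey	mtdna	130	COI	441
Clupea harengus	Atlantic herring	North Atlantic	prey	mtdna	98	COI	1551
Mallotus villosus	Capelin	North Atlantic	prey	mtdna	41	CYTB	572
Balaenoptera acutorostrata	Common minke whale	Southern	whale	mtdna	23	CR	322
Balaenoptera musculus	Blue whale	Southern	whale	mtdna	230	CR	404
Balaenoptera physalus	Fin whale	Southern	whale	mtdna	61	CR	391
Megaptera novaeangliae	Humpback whale	Southern	whale	mtdna	500	CR	396
Eubalaena australis	Southern right whale	Southern	whale	mtdna	481	CR	381
Balaenoptera bonaerensis	Antarctic minke whale	Southern	whale	mtdna	180	CR	337
Euphausia superba	Antarctic krill	Southern	prey	mtdna	640	COI	593
Pleuromamma abdominalis	Copepod	Southern	prey	mtdna	231	COI	441
Balaenoptera acutorostrata	Common minke whale	North Atlantic	whale	nuclear	27	SNPs	14304
Eubalaena australis	Southern right whale	Southern	whale	nuclear	45	SNPs	31482
Balaenoptera physalus	Fin whale	North Atlantic	whale	nuclear	28	SNPs	29544
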