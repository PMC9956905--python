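Alanine, aspartate and glutamate metabolism	synthetic KEGG-style snapshot	alanine	aspartate	glutamate	glutamine	succinic acid	fumaric acid
Nicotinate and nicotinamide metabolism	synthetic KEGG-style snapshot	niacinamide	aspartate	succinic acid	fumaric acid
Purine metabolism	synthetic KEGG-style snapshot	hypoxanthine	inosine	IMP	glutamine	glycine
Valine, leucine and isoleucine degradation	synthetic KEGG-style snapshot	valine	leucine	isoleucine
Phenylalanine, tyrosine and tryptophan biosynthesis	synthetic KEGG-style snapshot	phenylalanine	tyrosine	tryptophan
Glycine, serine and threonine metabolism	synthetic KEGG-style snapshot	glycine	betaine	creatine	aspartate
Arginine and proline metabolism	synthetic KEGG-style snapshot	creatine	creatinine	glutamate	aspartate	glutamine
Glycolysis / Gluconeogenesis	synthetic KEGG-style snapshot	beta-glucose	lactic acid	acetic acid
Citrate cycle (TCA cycle)	synthetic KEGG-style snapshot	succinic acid	fumaric acid	acetic acid
Taurine and hypotaurine metabolism	synthetic KEGG-style snapshot	taurine	acetic acid	alanine
Histidine metabolism	synthetic KEGG-style snapshot	carnosine	anserine	glutamate	aspartate
Pyrimidine metabolism	synthetic KEGG-style snapshot	uracil	glutamine	aspartate
Cysteine and methionine metabolism	synthetic KEGG-style snapshot	methionine	taurine	alanine
Lysine degradation	synthetic KEGG-style snapshot	carnitine	O-acetylcarnitine	glutamate	glutamine
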