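amino_acid	anticodon
Ala	AGC
Ala	CGC
Ala	TGC
Arg	ACG
Arg	CCG
Arg	TCT
Arg	CCT
Arg	TCG
Asn	GTT
Asp	GTC
Cys	GCA
Gln	CTG
Gln	TTG
Glu	CTC
Glu	TTC
Gly	GCC
Gly	CCC
Gly	TCC
His	GTG
Ile	AAT
Ile	TAT
Leu	AAG
Leu	CAG
Leu	TAG
Leu	CAA
Leu	TAA
Lys	CTT
Lys	TTT
Met	CAT
Phe	GAA
Pro	AGG
Pro	CGG
Pro	TGG
Ser	AGA
Ser	CGA
Ser	TGA
Ser	GCT
Thr	AGT
Thr	CGT
Thr	TGT
Trp	CCA
Tyr	GTA
Val	AAC
Val	CAC
Val	TAC
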