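# The 20 canonical amino acids mapped to BiGG cytosolic metabolite ids.
L-alanine: ala__L_c
L-arginine: arg__L_c
L-asparagine: asn__L_c
L-aspartate: asp__L_c
L-cysteine: cys__L_c
L-glutamate: glu__L_c
L-glutamine: gln__L_c
glycine: gly_c
L-histidine: his__L_c
L-isoleucine: ile__L_c
L-leucine: leu__L_c
L-lysine: lys__L_c
L-methionine: met__L_c
L-phenylalanine: phe__L_c
L-proline: pro__L_c
L-serine: ser__L_c
L-threonine: thr__L_c
L-tryptophan: trp__L_c
L-tyrosine: tyr__L_c
L-valine: val__L_c
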