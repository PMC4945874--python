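protein_change	class
p.Asp84Glu	R
p.Arg142His	R
p.Arg151Cys	R
p.Arg160Trp	R
p.Asp294His	R
p.Val60Leu	r
p.Val92Met	r
p.Ile155Thr	r
p.Arg163Gln	r
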