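position	wt	clinical_chain	structural_chain
104	Arg	Trp > Gln	Trp > Gln
127	Gly	Asp > Val	Asp > Val
165	His	Asp > Arg > Leu = Tyr	Asp > Arg > Leu = Tyr
210	Asp	Tyr = Val	Tyr > Val
244	Val	Leu >= Met	Leu = Met
250	Arg	Trp > Gln	Trp > Gln
251	Pro	Arg > Ala > Leu	Arg > Ala = Leu
259	Arg	Leu >= Cys > His	Leu = Cys > His
274	Arg	Trp > Gln	Trp > Gln
276	Gln	Arg = His	Arg = His
277	His	Tyr > Arg	Tyr = Arg
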