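protein_change	nt_change	refs
p.Arg104Gln	c.311 G > A	CR27
p.Arg104Trp	c.310 C > T	CR15;CR25;CR26;CR28-CR30
p.Gly127Asp	c.380 G > A	CR2
p.Gly127Val	c.380 G > T	CR35
p.His165Arg	c.494 A > G	CR2;CR3;CR22
p.His165Asp	c.493 C > G	CR21;CR24
p.His165Leu + ALS	c.494 A > T	CR23
p.His165Tyr	c.493 C > T	CR3
p.Asp210Val	c.629 A > T	CR12
p.Asp210Tyr	c.628 G > T	CR36
p.Val244Leu	c.730 G > C	CR40
p.Val244Met	c.730 G > A	CR15;CR39
p.Arg250Gln	c.749 G > A	CR3;CR37
p.Arg250Trp + Arg400* + Arg476*	c.748 C > T	CR3;CR38
p.Pro251Ala	c.751 C > G	CR31
p.Pro251Arg	c.752 C > G	CR37;CR41
p.Pro251Leu	c.752 C > T	CR42
p.Arg259Cys	c.775 C > T	CR17
p.Arg259Leu	c.776 G > T	CR18
p.Arg259His	c.776 G > C	CR19
p.Arg274Gln	c.821 G > A	CR31
p.Arg274Trp	c.820 C > T	CR1
p.Gln276Arg	c.827 A > G	CR32
p.Gln276His	c.828 G > C	CR33
p.His277Arg	c.830 A > G	CR3
p.His277Tyr	c.829 C > T	CR15
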