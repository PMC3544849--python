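# domain_acc	cazy_family	family_class	category
# Curated Pfam -> CAZy mapping restricted to families with a clear Pfam
# model; functional categories follow the Pope-style grouping of GH
# families (cellulases, endohemicellulases, debranching enzymes,
# oligosaccharide-degrading enzymes) plus 'binding' for CBMs.
# User-replaceable data: pass your own TSV with the same four columns.
PF00150	GH5	GH	cellulase
PF01341	GH6	GH	cellulase
PF01270	GH8	GH	cellulase
PF00759	GH9	GH	cellulase
PF01670	GH12	GH	cellulase
PF02011	GH48	GH	cellulase
PF00331	GH10	GH	endohemicellulase
PF00457	GH11	GH	endohemicellulase
PF02156	GH26	GH	endohemicellulase
PF00295	GH28	GH	endohemicellulase
PF07745	GH53	GH	endohemicellulase
PF06964	GH51	GH	debranching
PF03648	GH67	GH	debranching
PF05592	GH78	GH	debranching
PF00232	GH1	GH	oligosaccharide-degrading
PF00703	GH2	GH	oligosaccharide-degrading
PF02836	GH2	GH	oligosaccharide-degrading
PF00933	GH3	GH	oligosaccharide-degrading
PF01915	GH3	GH	oligosaccharide-degrading
PF01120	GH29	GH	oligosaccharide-degrading
PF01301	GH35	GH	oligosaccharide-degrading
PF01074	GH38	GH	oligosaccharide-degrading
PF01229	GH39	GH	oligosaccharide-degrading
PF02449	GH42	GH	oligosaccharide-degrading
PF04616	GH43	GH	oligosaccharide-degrading
PF00553	CBM2	CBM	binding
PF00942	CBM3	CBM	binding
PF03422	CBM6	CBM	binding
PF00686	CBM20	CBM	binding
PF03423	CBM25	CBM	binding
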