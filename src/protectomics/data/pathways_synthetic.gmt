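# Synthetic 12-pathway panel for desk-scale runs and tests.
# Member lists are plausible rat gene symbols for each named KEGG-style
# pathway (estrogen signaling plus neurotransmission/plasticity/disease
# panels), curated by hand for this package; they are a synthetic
# stand-in, NOT an export of the KEGG maps.
GLU	glutamatergic synapse (synthetic panel)	Gria1	Gria2	Gria3	Gria4	Grik1	Grik4	Grik5	Grin1	Grin2a	Grin2b	Grin2d	Grm1	Grm3	Grm5	Slc1a2	Slc1a3	Slc1a6	Slc17a7	Homer1	Shank2	Dlg4	Adcy2	Calm1	Gnao1	Mapk1	Prkcb	Itpr1	Cacna1a	Cacna1c
GABA	GABAergic synapse (synthetic panel)	Gabbr1	Gabbr2	Gabra1	Gabra2	Gabra4	Gabra5	Gabrd	Gabrg2	Gabrq	Slc6a1	Slc6a13	Slc12a5	Gabarapl1	Gad1	Gad2	Adcy5	Gng3	Gnb1	Prkcg	Src	Cacna1b
ACH	cholinergic synapse (synthetic panel)	Chrm3	Chrm4	Chrna7	Chrnb2	Ache	Chat	Slc5a7	Kcnj14	Kcnq2	Camk2a	Camk2b	Camk4	Gng4	Gnai1	Pik3ca	Kcnj3	Creb1	Fos	Jun	Map2k1
DA	dopaminergic synapse (synthetic panel)	Drd1	Drd2	Ddc	Th	Slc6a3	Comt	Gsk3a	Gsk3b	Ppp2r2b	Kcnj5	Kcnj9	Calm2	Akt1	Mapk10	Fos	Gng2	Arrb2	Gnaq	Itpr2	Clock
5HT	serotonergic synapse (synthetic panel)	Htr1a	Htr2a	Htr5b	Htr7	Tph2	Slc6a4	Maoa	Cyp2j3	Gng5	Gng10	Gng11	Gng12	Gnb4	Casp3	Raf1	Mapk3	Adcy6	Ptgs2	Alox12	Htr3a
APO	apoptosis (synthetic panel)	Casp3	Casp8	Casp9	Bax	Bcl2	Bcl2l1	Tnf	Trp53	Jun	Fos	Akt3	Birc2	Apaf1	Cycs	Fas	Tnfrsf1a	Bid	Diablo
CC	cell cycle (synthetic panel)	Cdc16	Cdc20	Mcm4	Ccnd1	Ccne1	Cdk1	Cdk2	Cdk4	Rb1	E2f1	Wee1	Chek1	Mdm2	Hells	Abl1	Smad3	Ywhab	Bub1
SVC	synaptic vesicle cycle (synthetic panel)	Stx1a	Stx2	Syt1	Vamp2	Snap25	Rab3a	Unc13a	Cplx1	Dnm1	Clta	Atp6v0a2	Napa	Nsf	Slc17a7	Slc6a1	Stxbp1	Syn1
LTP	long-term potentiation (synthetic panel)	Gria1	Gria2	Grin1	Grin2a	Grin2b	Camk2a	Camk2b	Camk4	Ppp1ca	Ppp3ca	Prkacb	Rps6ka1	Braf	Crebbp	Atf4	Plcb1	Calm3	Kras	Mapk1	Raf1
LTD	long-term depression (synthetic panel)	Gria1	Gria3	Grm1	Grm5	Gnaq	Pla2g4a	Prkcb	Prkcg	Guca1a	Gucy1a1	Prkg1	Igf1	Lyn	Crh	Gnai2	Hras	Ppp2ca
ALZ	Alzheimer disease (synthetic panel)	App	Apoe	Psen1	Psen2	Bace1	Mapt	Casp3	Casp9	Apbb1	Lrp1	Ide	Ache	Grin2a	Itpr1	Ndufa1	Cycs	Sdha	Uqcrc1	Cox4i1
ESG	estrogen signaling (synthetic panel)	Esr1	Esr2	Gper1	Sp1	Jun	Fos	Mmp9	Pik3r1	Pik3r3	Shc1	Sos1	Sos2	Grb2	Hbegf	Nos3	Oxt	Pgr	Krt19	Tff1	Adcy2	Adcy3	Adcy5	Adcy6	Adcy7	Adcy8	Adcy9	Akt1	Ak3	Hras	Kras	Raf1	Src	Atf4	Atf6b	Calm1	Calm2	Calm3	Gabbr1	Gabbr2	Grm1	Itpr1	Itpr2	Creb1	Creb3l1	Gnai1	Gnai2	Gnai3	Gnao1	Gnaq	Kcnj3	Kcnj5	Kcnj9	Map2k1	Mapk1	Mapk3	Pik3ca	Pik3cb
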