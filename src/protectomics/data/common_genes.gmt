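# Common genes between the estrogen-signaling pathway and the
# neurotransmission pathways (adenylcyclases, oncogenes, transcription
# factors, calmodulins, membrane receptors, binding proteins, ion
# channels and kinases), as annotated in KEGG for the rat.
CG	ESG/neurotransmission common genes	Adcy2	Adcy3	Adcy5	Adcy6	Adcy7	Adcy8	Adcy9	Akt1	Ak3	Fos	Hras	Kras	Raf1	Src	Atf4	Atf6b	Calm1	Calm2	Calm3	Gabbr1	Gabbr2	Grm1	Itpr1	Itpr2	Creb1	Creb3l1	Gnai1	Gnai2	Gnai3	Gnao1	Gnaq	Kcnj3	Kcnj5	Kcnj9	Map2k1	Mapk1	Mapk3	Pik3ca	Pik3cb
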