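code	sequence	group
rdal_51_25/1-15	FLPVIAGVLSKLFGK	short_linear
rdal_21_605/1-6	ILPLIGKVLSGILAK	short_linear
rdal_44_43/1-15	LLPIVGNLLNDLLGK	short_linear
rdal_226_12/1-14	FLPIVTNLLLRFVG	short_linear
rdal-8-600/1-18	FLGFVGQALNALLGKLGK	short_linear
rdal-38-11/1-23	FFPAIFRLVAKVVPSIICSVTKN	short_linear_ranabox
rdal_103_32/1-24	FLPLLAGLAANFLPKIFCKITRKC	short_linear_ranabox
rdal-3-1108/1-20	IVPILLGVVPQLVCAITKKC	short_linear_ranabox
rdal-53-31/1-17	IIPLLLGKVVCAITKKC	short_linear_ranabox
rdal_15_33/1-34	GILLDKLKNFAKTAGKGVLQSLLNTASCKISGQC	brevinin_helical_ranabox
rdal-6-971/1-31	FLWETVKNFGKTFTLNILDKLKCKIGGECPP	esculentin_helical_ranabox
rdal_120_5/1-37	GILSLVKGIAKLAGKGLAKEGGKFGLELMACKIAKQC	esculentin_helical_ranabox
rdal_108_19/1-19	GALRGCWTKSIPPKPCKGK	beta_hairpin
rdal-32-284/1-24	VPQLCFKFQKVIYCEINKTLPNFA	beta_hairpin
rdal-58-29/1-17	AAKIILNPKFRCKAAFC	kunitzin
rdal-77-6/1-35	FLPLVLGKTHSFSEQAELLSWKSSNVEYHLPKCTDV	undefined
rdal_7_282/1-9	GIVEAWPLR	undefined
rdal_40_14/1-15	GLEVLGKILSGLLGK	undefined
rdal-39-24/1-32	NLLGFLQGAKDILKECEADNYQGWLCESSYKPQ	undefined
rdal-110-77/1-21	LANRAARNTQNVLNAITCTL	undefined
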