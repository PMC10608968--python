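name	sequence	c_term	disulfides	exp_mass	theor_mass	ppm	novel
Brevinin 1Da	IIPLLLGKVVCAITKKC	free_acid	11-17	1809.096	1809.098	1.3	0
Brevinin 1Db	FFPAFLKVAAKVVPSILCSITKKC	free_acid	18-24	2607.472	2607.468	1.4	1
Brevinin 2D	GLLSGLKKVGKVVAKNVAVSLMDSLKCKISGDC	free_acid	27-33	3357.852	3357.855	0.9	1
Brevinin 2Rd	GILDSLKNLAKNAAQILLNKASCKLSGQC	free_acid	23-29	3011.626	3011.626	0.3	0
FQ-22 (MRP)	FIGSALKVLAGVLPSVISWVKQ	amide	-	2310.383	2310.383	0.3	0
Temporin A	FLPLIGRVLSGIL	amide	-	1395.896	1395.897	0.4	0
Temporin B	LLPIVGNLLKSLL	amide	-	1390.925	1390.928	1.8	0
Temporin C	LLPILGNLLNGLL	amide	-	1360.877	1360.881	2.6	0
Temporin D	LLPIVGNLLNSLL	amide	-	1376.880	1376.876	3.3	0
Temporin F	FLPLIGKVLSGIL	amide	-	1367.887	1367.890	2.5	0
Temporin G	FFPVIGRILNGIL	amide	-	1456.890	1456.892	1.3	0
Temporin H	LSPNLLKSLL	amide	-	1095.701	1095.702	0.5	0
Temporin K	LLPNLLKSLL	amide	-	1121.754	1121.754	0.3	0
Temporin M	FLPILGKVLSRVL	amide	-	1452.954	1452.954	0.3	0
Temporin 1Da	FLPLIAGLLGKLF	amide	-	1399.896	1399.896	0.3	1
Bradykinin	RPPGFSPFR	free_acid	-	1059.561	1059.561	0.4	0
[desArg9]Br	RPPGFSPF	free_acid	-	903.460	903.460	0.3	0
Br 1-7	RPPGFSP	free_acid	-	756.390	756.392	2.5	0
Br 5-9	FSPFR	free_acid	-	652.334	652.333	1.1	0
Br RI-5-10	FSPFRI	free_acid	-	765.416	765.417	1.8	0
Br RI-10	RPPGFSPFRI	free_acid	-	1172.642	1172.645	3.0	0
Br RA-1-11	RPPGFSPFRIA	free_acid	-	1243.679	1243.683	2.9	0
[desArg1]Br RA-2-11	PPGFSPFRIA	free_acid	-	1087.579	1087.581	2.3	0
Br DR-11	DVRPPGFSPFR	free_acid	-	1273.653	1273.657	2.9	0
[Thr6]Br	RPPGFTPFR	free_acid	-	1073.572	1073.577	4.7	0
[desArg9][Thr6]Br	RPPGFTPF	free_acid	-	917.472	917.476	4.3	0
[Thr6]Br 1-7	RPPGFTP	free_acid	-	770.405	770.408	3.3	0
[Thr6]Br 5-9	FTPFR	free_acid	-	666.347	666.349	2.9	0
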