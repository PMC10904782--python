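ko	gene	module_id	is_mm
K00577	mtrA	M00567	1
K00205	fwdF	M00567	1
K23229	fae	M00567	1
K12234	cofE	M00378	1
K23230	cofF	M00378	1
K00441	frhB	M00378	1
K10946	pmoC	M00174	1
K00925	ackA	M00357	1
K00925	ackA	M00579	0
K00625	pta	M00357	1
K00625	pta	M00579	0
K00198	cooS	M00567	1
K00198	cooS	M00377	0
K00600	glyA	M00563	1
K00600	glyA	M00140	0
K01007	pps	M00357	1
K01007	pps	M00002	0
K00016	ldh	M00357	1
K00016	ldh	M00001	0
K00121	frmA	M00174	1
K00121	frmA	M00356	1
K00121	frmA	M00003	0
K01595	ppc	M00567	1
K01595	ppc	M00009	0
K00024	mdh	M00174	1
K00024	mdh	M00009	0
K03594	bfr	M00890	0
K02703	psbA	M00161	0
K00036	zwf	M00004	0
K01689	eno	M00001	0
K00873	pyk	M00001	0
K01810	pgi	M00001	0
K00134	gap	M00001	0
K00850	pfk	M00001	0
K01623	fba	M00001	0
K00927	pgk	M00001	0
K01834	gpm	M00001	0
K00239	sdhA	M00009	0
K01902	sucD	M00009	0
K00031	idh	M00009	0
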