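comparison	lnc_id	mrna_id	gene_name	r	p	distance_bp	location
D/E-1.46 vs D/E-0.61	XR_523541.1	103398853	slc16a5	0.990	3.82E-07	200	downstream
D/E-1.46 vs D/E-0.61	XR_521587.1	103379464	zfp319	0.972	1.24E-05	19594	upstream
D/E-1.46 vs D/E-0.61	XR_523068.1	103393985	apoa4	0.953	7.22E-05	67904	downstream
D/E-1.46 vs D/E-0.61	XR_521789.1	103381395	mthfd1	0.986	1.06E-06	54	downstream
D/E-1.46 vs D/E-0.61	LNC_000230	103381775	sfxn2	0.961	3.79E-05	52923	downstream
D/E-1.46 vs D/E-0.61	LNC_000230	103381769	scs3	0.955	6.09E-05	191	upstream
D/E-1.46 vs D/E-0.61	LNC_000285	103385419	baz2a	0.958	4.60E-05	837	downstream
D/E-1.46 vs D/E-0.61	LNC_000587	103398248	ce2a	0.970	1.46E-05	4443	downstream
D/E-1.46 vs D/E-0.61	XR_522182.1	103385102	kmt2d	-0.987	9.01E-07	74060	downstream
D/E-1.46 vs D/E-0.61	XR_522818.1	103391927	LOC103391927	0.957	5.37E-05	17005	downstream
D/E-1.46 vs D/E-0.61	LNC_000360	103388031	zfp585a	0.968	1.88E-05	67207	downstream
D/E-1.46 vs D/E-0.61	LNC_000360	103387998	zfp574	0.957	5.02E-05	98036	upstream
D/E-1.46 vs D/E-0.61	LNC_000562	103397059	mdtet3	0.957	5.33E-05	746	downstream
D/E-1.46 vs D/E-0.61	LNC_000314	103386594	php2	0.959	4.23E-05	33381	downstream
D/E-1.46 vs D/E-0.61	LNC_000314	103386602	rps10	-0.968	1.87E-05	69929	upstream
D/E-1.46 vs D/E-0.61	LNC_000255	103384010	usmg5	0.973	9.75E-06	91044	downstream
D/E-1.46 vs D/E-0.61	XR_523487.1	103398370	spc1	0.951	8.46E-05	82748	upstream
D/E-2.75 vs D/E-0.61	XR_523541.1	103398853	slc16a5	0.990	3.82E-07	200	downstream
D/E-2.75 vs D/E-0.61	XR_523068.1	103393985	apoa4	0.953	7.22E-05	67904	downstream
D/E-2.75 vs D/E-0.61	XR_521789.1	103381395	mthfd1	0.990	1.06E-06	54	downstream
D/E-2.75 vs D/E-0.61	LNC_000230	103381775	sfxn2	0.961	3.79E-05	52923	downstream
D/E-2.75 vs D/E-0.61	LNC_000230	103381769	scs3	0.955	6.09E-05	191	upstream
D/E-2.75 vs D/E-0.61	LNC_000285	103385419	baz2a	0.958	4.60E-05	837	downstream
D/E-2.75 vs D/E-0.61	LNC_000587	103398248	ce2a	0.952	7.35E-05	4443	downstream
D/E-2.75 vs D/E-0.61	XR_522182.1	103385102	kmt2d	-0.987	9.01E-07	74060	downstream
D/E-2.75 vs D/E-0.61	XR_522818.1	103391927	LOC103391927	0.957	5.37E-05	17005	downstream
D/E-2.75 vs D/E-0.61	LNC_000360	103388031	zfp585a	0.968	1.88E-05	67207	downstream
D/E-2.75 vs D/E-0.61	LNC_000314	103386594	php2	0.959	4.23E-05	33381	downstream
D/E-2.75 vs D/E-0.61	LNC_000314	103386602	rps10	-0.968	1.87E-05	69929	upstream
D/E-2.75 vs D/E-0.61	LNC_000255	103384010	usmg5	0.973	9.75E-06	91044	downstream
D/E-1.46 vs D/E-2.75	XR_523541.1	103398853	slc16a5	0.990	3.82E-07	200	downstream
D/E-1.46 vs D/E-2.75	XR_521587.1	103379464	zfp319	0.972	1.24E-05	19594	upstream
D/E-1.46 vs D/E-2.75	LNC_000285	103385419	baz2a	0.958	4.60E-05	837	downstream
D/E-1.46 vs D/E-2.75	LNC_000562	103397059	mdtet3	0.957	5.33E-05	746	downstream
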