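week	fetal_sex	parity	bw_mean	bw_sd	pw_mean	pw_sd
34	female	nulliparous	1874	350.0	466	95.0
34	female	parous	1909	350.0	472	95.0
34	male	nulliparous	1919	350.0	474	95.0
34	male	parous	1954	350.0	480	95.0
35	female	nulliparous	2100	350.0	480	95.0
35	female	parous	2135	350.0	486	95.0
35	male	nulliparous	2145	350.0	488	95.0
35	male	parous	2180	350.0	494	95.0
36	female	nulliparous	2314	350.0	494	95.0
36	female	parous	2349	350.0	500	95.0
36	male	nulliparous	2359	350.0	502	95.0
36	male	parous	2394	350.0	508	95.0
37	female	nulliparous	2516	350.0	508	95.0
37	female	parous	2551	350.0	514	95.0
37	male	nulliparous	2561	350.0	516	95.0
37	male	parous	2596	350.0	522	95.0
38	female	nulliparous	2706	350.0	522	95.0
38	female	parous	2741	350.0	528	95.0
38	male	nulliparous	2751	350.0	530	95.0
38	male	parous	2786	350.0	536	95.0
39	female	nulliparous	2884	350.0	536	95.0
39	female	parous	2919	350.0	542	95.0
39	male	nulliparous	2929	350.0	544	95.0
39	male	parous	2964	350.0	550	95.0
40	female	nulliparous	3050	350.0	550	95.0
40	female	parous	3085	350.0	556	95.0
40	male	nulliparous	3095	350.0	558	95.0
40	male	parous	3130	350.0	564	95.0
41	female	nulliparous	3204	350.0	564	95.0
41	female	parous	3239	350.0	570	95.0
41	male	nulliparous	3249	350.0	572	95.0
41	male	parous	3284	350.0	578	95.0
42	female	nulliparous	3346	350.0	578	95.0
42	female	parous	3381	350.0	584	95.0
42	male	nulliparous	3391	350.0	586	95.0
42	male	parous	3426	350.0	592	95.0
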