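variant_id	vasc_class	sbp_increasing_allele	trait_memberships	dbp_discordant
rsS1000	unlikely related	A	DBP,MAP,PP,SBP	False
rsS1001	unknown	G	DBP,MAP,SBP	False
rsS1002	unknown	T	DBP,MAP,PP,SBP	False
rsS1003	vasculature-related	T	DBP,MAP,PP,SBP	False
rsS1004	vasculature-related	C	DBP,MAP,PP,SBP	False
rsS1005	vasculature-related	A	DBP,MAP,PP,SBP	False
rsS1006	unknown	C	DBP,MAP,PP,SBP	False
rsS1007	vasculature-related	T	DBP,MAP,SBP	False
rsS1008	vasculature-related	A	MAP,PP,SBP	False
rsS1009	unlikely related	G	DBP,MAP,SBP	False
rsS1010	unlikely related	T	MAP,PP,SBP	True
rsS1011	vasculature-related	T	DBP,MAP,PP,SBP	False
rsS1012	unlikely related	A	DBP,MAP,SBP	False
rsS1013	unlikely related	G	MAP,PP,SBP	True
rsS1014	vasculature-related	T	DBP,MAP,SBP	False
rsS1015	vasculature-related	T	MAP,PP,SBP	True
rsS1016	unlikely related	C	MAP,PP,SBP	False
rsS1017	vasculature-related	G	MAP,PP,SBP	True
rsS1018	unlikely related	C	MAP,SBP	False
rsS1019	unknown	G	DBP,MAP,SBP	False
rsS1020	unknown	A	DBP,MAP,PP,SBP	False
rsS1021	unknown	A	MAP,SBP	False
rsS1022	unlikely related	T	MAP,PP,SBP	True
rsS1023	vasculature-related	T	DBP,MAP,PP,SBP	False
rsS1024	vasculature-related	A	MAP,PP,SBP	True
rsS1025	unlikely related	G	MAP,PP,SBP	False
rsS1026	unlikely related	T	DBP,MAP,SBP	False
rsS1027	unknown	G	DBP,MAP,PP,SBP	False
rsS1028	unknown	A	DBP,MAP,PP,SBP	False
rsS1029	vasculature-related	A	DBP,MAP,SBP	False
rsS1030	vasculature-related	T	MAP,PP,SBP	False
rsS1031	vasculature-related	G	DBP,MAP,PP,SBP	False
rsS1032	unknown	C	MAP,PP,SBP	False
rsS1033	vasculature-related	G	DBP,MAP,SBP	False
rsS1034	vasculature-related	T	MAP,PP,SBP	True
rsS1035	unknown	T	DBP,MAP,SBP	False
rsS1036	unknown	A	MAP,PP,SBP	False
rsS1037	unlikely related	A	DBP,MAP,SBP	False
rsS1038	vasculature-related	C	DBP,MAP,PP,SBP	False
rsS1039	vasculature-related	G	MAP,PP,SBP	False
rsS1040	unlikely related	A	MAP,SBP	False
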