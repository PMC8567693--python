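variant_id	vasc_class	sbp_increasing_allele	trait_memberships	dbp_discordant
rsT2000	vasculature-related	A	SBP	False
rsT2001	vasculature-related	A	SBP	False
rsT2002	vasculature-related	T	SBP	False
rsT2003	vasculature-related	T	SBP	False
rsT2004	unlikely related	A	SBP	False
rsT2005	unlikely related	G	SBP	False
rsT2006	unlikely related	C	SBP	False
rsT2007	unlikely related	T	SBP	False
rsT2008	unlikely related	A	SBP	False
rsT2009	unknown	A	SBP	False
rsT2010	unlikely related	T	SBP	False
rsT2011	vasculature-related	T	SBP	False
rsT2012	vasculature-related	C	SBP	False
rsT2013	unlikely related	G	SBP	False
rsT2014	unlikely related	C	SBP	False
rsT2015	unknown	G	SBP	False
rsT2016	unlikely related	A	SBP	False
rsT2017	unknown	A	SBP	False
rsT2018	unknown	C	SBP	False
rsT2019	vasculature-related	G	SBP	False
rsT2020	vasculature-related	C	SBP	False
rsT2021	unlikely related	A	SBP	False
rsT2022	vasculature-related	C	SBP	False
rsT2023	unknown	T	SBP	False
rsT2024	unknown	C	SBP	False
rsT2025	unlikely related	A	SBP	False
rsT2026	unlikely related	T	SBP	False
rsT2027	unlikely related	T	SBP	False
rsT2028	unlikely related	A	SBP	False
rsT2029	unlikely related	A	SBP	False
rsT2030	unknown	C	SBP	False
rsT2031	unlikely related	T	SBP	False
rsT2032	vasculature-related	A	SBP	False
rsT2033	vasculature-related	A	SBP	False
rsT2034	unknown	C	SBP	False
rsT2035	vasculature-related	T	SBP	False
rsT2036	vasculature-related	A	SBP	False
rsT2037	vasculature-related	A	SBP	False
rsT2038	vasculature-related	C	SBP	False
rsT2039	unlikely related	T	SBP	False
rsT2040	unknown	C	SBP	False
rsT2041	unknown	G	SBP	False
rsT2042	unlikely related	T	SBP	False
rsT2043	unlikely related	T	SBP	False
rsT2044	unlikely related	A	SBP	False
rsT2045	unknown	A	SBP	False
rsT2046	unlikely related	C	SBP	False
rsT2047	unknown	G	SBP	False
rsT2048	unlikely related	A	SBP	False
rsT2049	unknown	A	SBP	False
rsT2050	vasculature-related	T	SBP	False
rsT2051	unlikely related	G	SBP	False
rsT2052	unlikely related	A	SBP	False
rsT2053	unlikely related	G	SBP	False
rsT2054	unlikely related	C	SBP	False
rsT2055	vasculature-related	G	SBP	False
rsT2056	vasculature-related	C	SBP	False
rsT2057	unknown	G	SBP	False
rsT2058	vasculature-related	C	SBP	False
rsT2059	unknown	G	SBP	False
rsT2060	vasculature-related	C	SBP	False
rsT2061	unlikely related	G	SBP	False
rsT2062	vasculature-related	C	SBP	False
rsT2063	unlikely related	T	SBP	False
rsT2064	unknown	A	SBP	False
rsT2065	unlikely related	A	SBP	False
rsT2066	unlikely related	C	SBP	False
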