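oxidative_phosphorylation	toy pathway	g00000	g00001	g00002	g00022	g00023	g00182	g00183	g00184
cytoskeleton	toy pathway	g00003	g00004	g00024	g00025	g00185	g00186	g00187
cell_cycle_arrest	toy pathway	g00005	g00006	g00007	g00026	g00027	g00188
unrelated_metabolism	toy pathway	g02000	g02001	g02002	g02003	g02004
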