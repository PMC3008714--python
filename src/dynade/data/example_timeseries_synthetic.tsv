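gene	treated_0	treated_40	treated_100	treated_200	treated_340	treated_440	treated_0_rep2	control_0	control_40	control_100	control_200	control_340	control_440	control_0_rep2
G00000	10.17827062	9.908491422	9.948803835	9.969681953	10.02429722	10.25873577	10.21849709	10.07737943	10.39680694	10.1657163	10.11976933	10.13255574	10.28097689	10.0401253
G00001	7.268054466	7.409552714	7.859657851	7.415428902	7.708929841	7.260503847	7.479192529	7.609089488	7.621778729	7.626632504	8.085709671	7.401971548	7.373574113	7.76100253
G00002	10.83952481	10.73348063	10.82049806	10.98846057	10.62277731	10.93065425	10.9094909	10.75288534	10.95651153	11.0295723	10.85255489	10.74912775	10.75136023	10.92360832
G00003	9.624301711	8.666385806	8.303051445	8.592705792	8.477922535	8.623336432	9.828115771	9.703070565	9.720749392	9.682572413	9.451971907	9.623238196	9.60120667	9.549059352
G00004	4.761542248	5.348874953	4.664439096	4.37293687	4.820063926	4.835201845	4.834973525	4.834715568	5.077369639	4.836539712	5.005802725	4.778541086	4.860897993	4.738265445
G00005	11.95083771	11.09539655	10.84327582	10.96201067	10.67740873	10.73632497	11.76088086	11.87272443	11.64860662	11.77067384	11.75450157	11.73641873	11.77545239	11.73471139
G00006	9.93006336	10.02220361	9.852798302	10.19814641	10.05097129	9.836641818	10.27902102	10.34573639	9.940490701	10.25533043	9.800239406	10.03163189	10.1170555	10.16568952
G00007	10.12177595	10.83948787	11.42611866	11.61633913	11.76691445	11.35655248	10.35890798	10.38476084	10.40528413	10.41876675	10.23126051	10.2126052	10.42937753	10.21381493
G00008	4.66712581	4.458579262	5.630527929	5.729996882	5.164123975	4.903595725	5.580186074	4.955739939	4.563664375	4.615151038	4.692466459	5.204665438	5.076405352	4.581771798
G00009	7.565794219	7.885448844	7.64468719	7.561067638	7.328759168	7.15949042	7.651623414	7.785986177	7.48991502	7.645082165	7.768796526	7.521146487	7.724080055	7.264582007
G00010	6.825957634	6.551253513	6.477730004	6.702606808	6.250760981	6.622207301	6.61280579	6.775246067	6.86154855	6.856153333	6.621072829	7.107002656	6.830839296	7.016220783
G00011	11.26959172	11.14655398	10.97542449	11.12412916	10.51414937	10.51639086	11.24724484	11.41564382	11.47275682	11.46858354	11.49527727	11.40210759	11.36249	11.60672247
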