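#locus	min_len	max_len
rpsB	150	1800
rpsC	150	1800
rpsD	150	1800
rpsE	150	1800
rpsF	150	1800
rpsG	150	1800
rpsH	150	1800
rpsI	150	1800
rpsJ	150	1800
rpsK	150	1800
rpsL	150	1800
rpsM	150	1800
rpsN	150	1800
rpsO	150	1800
rpsP	150	1800
rpsQ	150	1800
rpsR	150	1800
rpsS	150	1800
rpsT	150	1800
rpsU	150	1800
rplA	120	1000
rplB	120	1000
rplC	120	1000
rplD	120	1000
rplE	120	1000
rplF	120	1000
rplI	120	1000
rplJ	120	1000
rplK	120	1000
rplL	120	1000
rplM	120	1000
rplN	120	1000
rplO	120	1000
rplP	120	1000
rplQ	120	1000
rplR	120	1000
rplS	120	1000
rplT	120	1000
rplU	120	1000
rplV	120	1000
rplW	120	1000
rplX	120	1000
rplY	120	1000
rpmA	90	450
rpmB	90	450
rpmC	90	450
rpmD	90	450
rpmE	90	450
rpmF	90	450
rpmG	90	450
rpmH	90	450
rpmI	90	450
rpmJ	90	450
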