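complex	homo	lumo	mu	eta	delta_n
AMOX-CS	-188.77	30.21	-79.28	109.49	-413.36
IBU-CS	-196.17	29.21	-83.48	112.69	-154.32
AMOX-GO-1	-159.85	-10.09	-84.97	74.88	-213.62
AMOX-GO-2	-155.27	-22.89	-89.08	66.19	-212.89
IBU-GO-1	-161.78	-11.05	-86.41	75.36	-145.44
IBU-GO-2	-156.46	-23.65	-90.05	66.40	-111.66
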