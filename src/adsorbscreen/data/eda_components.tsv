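complex	e_elect	e_oi	e_pauli	e_int	e_t	e_prep
AMOX-CS	-64.44	-32.31	52.37	-34.70	-25.36	9.41
AMOX-GO-1	-26.79	-21.06	7.39	-33.21	-21.63	11.62
AMOX-GO-2	-24.59	-21.82	7.89	-31.33	-24.71	6.31
IBU-CS	-30.23	-19.79	17.26	-25.50	-22.85	2.62
IBU-GO-1	-13.29	-11.95	-3.47	-24.41	-22.30	2.10
IBU-GO-2	-22.32	-12.00	7.24	-23.21	-19.41	3.80
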