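complex	delta_h	delta_s	delta_g	delta_e_t
AMOX-CS	-42.53	-61.78	-24.11	-25.36
AMOX-GO-1	-36.64	-59.55	-18.88	-21.63
AMOX-GO-2	-39.65	-79.53	-15.93	-24.71
IBU-CS	-27.84	-57.45	-10.71	-22.85
IBU-GO-1	-21.06	-50.55	-5.99	-22.30
IBU-GO-2	-24.51	-54.68	-8.21	-19.41
Tetracycline-CS	-21.06	-51.31	-5.76	-22.73
Oxytetracycline-CS	-37.63	-65.33	-18.15	-31.78
Doxycycline-CS	-22.98	-52.94	-7.20	-23.78
Tetracycline-GO-1	-22.56	-54.83	-6.22	-23.29
Oxytetracycline-GO-1	-20.26	-48.71	-5.74	-22.95
Doxycycline-GO-1	-29.10	-60.42	-11.09	-26.70
Tetracycline-GO-2	-18.56	-50.83	-3.41	-18.09
Oxytetracycline-GO-2	-16.26	-44.71	-2.93	-18.47
Doxycycline-GO-2	-27.10	-56.42	-10.28	-26.03
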