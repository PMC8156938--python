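complex	donor	acceptor	e2
AMOX-CS	BD C14-H18	BD* O89-H90	0.29
AMOX-CS	BD N33-H34	BD* N67-H68	0.56
AMOX-CS	LP O29	BD* C48-H54	0.21
AMOX-CS	LP O31	BD* C49-H55	0.86
AMOX-CS	LP N33	BD* N67-H68	17.25
AMOX-CS	LP O36	BD* O89-H90	0.43
AMOX-CS	LP O33	BD* O89-H90	25.72
AMOX-CS	BD C65-O66	BD* O31-H32	4.54
AMOX-CS	BD C71-O91	BD* C2-H10	0.34
AMOX-CS	BD C87-O88	BD* C2-H10	0.63
AMOX-CS	BD C87-O88	BD* C12-H15	0.23
AMOX-CS	BD O89-H90	BD* C14-O36	0.49
AMOX-CS	LP(1)O66	BD* O31-H32	4.77
AMOX-CS	LP(2)O66	BD* O31-H32	1.51
AMOX-CS	LP(2)O66	BD* N33-H34	0.29
AMOX-CS	LP(2)O66	BD* O31-H32	1.51
AMOX-CS	LP(2)O66	BD* N33-H34	0.29
AMOX-CS	LP N67	BD* C4-H8	0.23
AMOX-CS	LP(1)O88	BD* C2-H10	0.40
AMOX-CS	LP(1)O88	BD* C12-H15	0.69
AMOX-CS	LP(2)O88	BD* C12-H15	1.28
AMOX-CS	LP(1)O91	BD* C1-H6	0.88
AMOX-CS	LP(1)O91	BD* C4-H8	0.21
AMOX-CS	LP(2)O91	BD* C4-H8	0.77
AMOX-CS	BD C8-C9	BD* C70-C71	0.25
AMOX-CS	BD C13-C14	BD* C72-C73	0.21
AMOX-CS	BD C15-C16	LP*(1)C84	0.62
AMOX-CS	LP(1)O67	BD* N88-H89	0.47
IBU-CS	LP O27	BD* O63-H64	1.50
IBU-CS	LP O27	BD* O63-H 64	23.05
IBU-CS	LP O41	BD* C 48-H 54	0.20
IBU-CS	LP O41	BD* C 48-H 54	0.75
IBU-CS	BD C48-C49	RY* H16	0.27
IBU-CS	BD C48-C53	RY* H7	0.29
IBU-CS	BD C 48-C53	BD* C3-H7	0.24
IBU-CS	LP O62	BD* N43-H45	2.20
IBU-CS	BD C49 - H55	BD* C13-H16	0.23
IBU-CS	BD C51 - C52	BD* C5-H9	0.20
IBU-CS	BD C53 - C59	RY* H7	0.55
IBU-CS	BD C61 - O62	RY* H18	0.26
IBU-CS	BD C61 - O62	BD* C14-H18	0.94
IBU-CS	BD O63 - H64	BD* C24-O27	0.36
IBU-CS	LP O62	BD* C14-H18	0.35
IBU-CS	LP O62	BD* N43-H45	1.14
AMOX-GO-1	BD C7-C8	BD* C50-C51	0.41
AMOX-GO-1	BD C41-O42	BD* N68-H69	1.24
AMOX-GO-1	BD C41-O42	BD* C72-O77	1.11
AMOX-GO-1	BD O47-H48	BD* C64-O76	0.34
AMOX-GO-1	BD O47-H48	BD* C64-O76	0.60
AMOX-GO-1	LP(1)O42	BD* N68-H69	3.63
AMOX-GO-1	LP(2)O42	BD* N68-H69	3.74
AMOX-GO-1	BD* C7-C8	BD* C54-C55	0.67
AMOX-GO-1	BD*C41-O42	BD* N68-H69	0.29
AMOX-GO-1	BD C50-C51	LP(1)C3	0.70
AMOX-GO-1	BD C50-C51	LP*(1)C4	0.78
AMOX-GO-1	BD C64-O76	BD* O47-H48	3.44
AMOX-GO-1	LP(1)O76	BD* O47-H48	13.39
AMOX-GO-1	LP(1)O83	BD* O43-H44	2.56
AMOX-GO-1	LP(2)O83	BD* O43-H44	2.43
AMOX-GO-1	BD* C52-C53	BD* C13-C14	0.26
AMOX-GO-1	BD* C54-C55	BD* C13-C14	0.53
AMOX-GO-1	BD* C64-O76	BD* O47-H48	1.60
AMOX-GO-2	BD C8-C9	BD* C70-C71	0.25
AMOX-GO-2	BD C13-C14	BD* C72-C73	0.21
AMOX-GO-2	BD C15-C16	LP*(1)C84	0.62
AMOX-GO-2	LP(1)O67	BD* N88-H89	0.47
AMOX-GO-2	LP(2)O67	BD* N88-H89	2.32
AMOX-GO-2	BD* C11-C12	BD* C70-C71	1.85
AMOX-GO-2	BD* C41-C42	BD* C74-C75	0.55
AMOX-GO-2	BD C61-O62	LP*(1)H105	3.46
AMOX-GO-2	LP(1)O62	LP*(1)H105	2.53
AMOX-GO-2	LP(2)O62	LP*(1)H105	4.90
AMOX-GO-2	BD* C61-O62	LP*(1)H105	3.70
AMOX-GO-2	BD* C41-C42	BD* C74-C75	0.55
IBU-GO-1	LP(1)O72	BD* O47-H48	6.81
IBU-GO-1	LP(2)O72	BD* O47-H48	11.48
IBU-GO-1	BD C22-C23	BD* C79-H82	0.20
IBU-GO-1	BD C69-O70	BD* O47-H48	0.22
IBU-GO-1	BD C69-O72	BD* C13-H15	0.42
IBU-GO-1	BD C69-O72	BD* O47-H48	0.40
IBU-GO-2	LP(1)O62	BD* O92-H91	8.38
IBU-GO-2	BD C72-C73	BD* C10-C27	0.22
IBU-GO-2	BD C89-O92	BD* C21-C22	0.38
IBU-GO-2	LP(2)O90	BD* C21-C22	0.31
IBU-GO-2	LP (1)O92	LP*(1)C61	0.32
IBU-GO-2	LP (2)O92	LP*(1)C61	1.26
IBU-GO-2	BD* C89-O92	BD* C1-C6	0.26
IBU-GO-2	BD* C89-O92	BD* C21-C22	0.37
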