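name	Community
n01	C
n02	F
n03	B
n04	C
n05	D
n06	C
n07	C|E
n08	D
n09	B
n10	D|C
n11	B
n12	D|A
n13	D
n14	A
n15	F
n16	F
n17	A
n18	A|B
n19	F
n20	A|D
n21	F
n22	D
n23	B
n24	D|F
n25	C
n26	B
n27	F|C
n28	D
n29	A
n30	B
n31	E
n32	F
n33	A
n34	C
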