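pp	g01	g02
pp	g01	g03
pp	g01	g04
pp	g04	g05
pp	g03	g06
pp	g04	g07
pp	g05	g08
pp	g06	g09
pp	g01	g10
pp	g05	g11
pp	g02	g12
pp	g05	g13
pp	g13	g14
pp	g08	g15
pp	g02	g16
pp	g09	g17
pp	g02	g06
pp	g09	g14
pp	g18	g19
pp	g19	g20
pp	g19	g21
pp	g21	g22
pp	g19	g23
pp	g18	g24
pp	g21	g25
pp	g21	g26
pp	g23	g27
pp	g27	g28
pp	g21	g29
pp	g28	g30
pp	g19	g31
pp	g22	g32
pp	g29	g33
pp	g21	g34
pp	g29	g35
pp	g26	g36
pp	g27	g37
pp	g36	g38
pp	g35	g39
pp	g36	g40
pp	g17	g30
pp	g03	g40
pp	g06	g22
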