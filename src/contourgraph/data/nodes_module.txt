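name	Symbol	Score	LogFC	PValue	URL	Module	Organism	Component	Function	Pathway	Process
g01	Gene1	0.379	-1.964	0.015761	https://example.org/gene/Gene1	small	mouse		GO:0008083	mmu05200|mmu04520	
g02	Gene2	1.583	0.366	0.019764	https://example.org/gene/Gene2	small	mouse	GO:0016020	GO:0019899	mmu05200|mmu04520	
g03	Gene3	-2.216	2.272	0.045632	https://example.org/gene/Gene3	small	mouse		GO:0008083	mmu05200	
g04	Gene4	4.157	3.035	0.005784	https://example.org/gene/Gene4	small	mouse			mmu04070|mmu04520	
g05	Gene5	2.466	-2.667	0.004309	https://example.org/gene/Gene5	small	mouse	GO:0005737	GO:0008013	mmu04070	GO:0006915
g06	Gene6	1.882	-0.862	0.028076	https://example.org/gene/Gene6	small	mouse	GO:0016020	GO:0008083	mmu04520	GO:0006915
g07	Gene7	1.205	1.055	0.04817	https://example.org/gene/Gene7	small	mouse			mmu04520	
g08	Gene8	2.867	2.369	0.045363	https://example.org/gene/Gene8	small	mouse	GO:0005737		mmu04070	
g09	Gene9	-3.996	0.632	0.035013	https://example.org/gene/Gene9	small	mouse	GO:0016020	GO:0008083		GO:0006915
g10	Gene10	1.842	-1.119	0.003338	https://example.org/gene/Gene10	small	mouse			mmu05200	
g11	Gene11	1.808	0.446	0.04032	https://example.org/gene/Gene11	small	mouse	GO:0005737	GO:0008013		
g12	Gene12	-5.303	-0.025	0.034169	https://example.org/gene/Gene12	small	mouse		GO:0019899	mmu05200|mmu04520	
g13	Gene13	1.041	-0.306	0.007197	https://example.org/gene/Gene13	small	mouse	GO:0005737	GO:0008013|GO:0008083		GO:0006915
g14	Gene14	-0.751	-1.102	0.023248	https://example.org/gene/Gene14	small	mouse		GO:0008013|GO:0008083		GO:0006915
g15	Gene15	2.345	0.581	0.002467	https://example.org/gene/Gene15	small	mouse	GO:0005737		mmu04070	
g16	Gene16	-1.317	0.462	0.040094	https://example.org/gene/Gene16	small	mouse	GO:0016020	GO:0019899	mmu05200	
g17	Gene17	-0.055	-0.139	0.035932	https://example.org/gene/Gene17	small	mouse		GO:0008083		
g18	Gene18	1.029	-0.333	0.040232	https://example.org/gene/Gene18		mouse		GO:0008013		
g19	Gene19	-2.629	-1.927	0.038021	https://example.org/gene/Gene19		mouse				
g20	Gene20	1.796	-0.729	0.013364	https://example.org/gene/Gene20		mouse				
g21	Gene21	-0.315	1.81	0.039487	https://example.org/gene/Gene21		mouse				
g22	Gene22	1.477	-0.286	0.012459	https://example.org/gene/Gene22		mouse				
g23	Gene23	-1.566	-2.16	0.006896	https://example.org/gene/Gene23		mouse				
g24	Gene24	3.259	2.002	0.01952	https://example.org/gene/Gene24		mouse				
g25	Gene25	1.816	0.795	0.024893	https://example.org/gene/Gene25		mouse				
g26	Gene26	-0.534	3.162	0.014292	https://example.org/gene/Gene26		mouse				
g27	Gene27	1.896	0.094	0.03029	https://example.org/gene/Gene27		mouse				
g28	Gene28	3.779	-0.692	0.030126	https://example.org/gene/Gene28		mouse				
g29	Gene29	5.374	-2.171	0.011992	https://example.org/gene/Gene29		mouse				
g30	Gene30	-4.721	1.986	0.031129	https://example.org/gene/Gene30		mouse				
g31	Gene31	2.649	3.854	0.017863	https://example.org/gene/Gene31		mouse				
g32	Gene32	1.395	-1.231	0.036735	https://example.org/gene/Gene32		mouse				
g33	Gene33	-0.282	-0.971	0.014522	https://example.org/gene/Gene33		mouse				
g34	Gene34	-3.02	0.894	0.03994	https://example.org/gene/Gene34		mouse				
g35	Gene35	3.772	-1.246	0.020756	https://example.org/gene/Gene35		mouse				
g36	Gene36	-3.785	-0.406	0.027662	https://example.org/gene/Gene36		mouse				
g37	Gene37	1.701	-0.525	0.033668	https://example.org/gene/Gene37		mouse				
g38	Gene38	3.906	0.288	0.025919	https://example.org/gene/Gene38		mouse				
g39	Gene39	-4.799	1.642	0.012882	https://example.org/gene/Gene39		mouse				
g40	Gene40	-0.908	0.033	0.048969	https://example.org/gene/Gene40		mouse				
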