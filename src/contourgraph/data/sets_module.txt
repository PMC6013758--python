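name	Label	URL	Score
GO:0005737	cytoplasm	https://amigo.geneontology.org/amigo/term/GO:0005737	2.22
GO:0016020	membrane	https://amigo.geneontology.org/amigo/term/GO:0016020	3.94
GO:0008013	beta-catenin binding	https://amigo.geneontology.org/amigo/term/GO:0008013	5.62
GO:0008083	growth factor activity	https://amigo.geneontology.org/amigo/term/GO:0008083	1.72
GO:0019899	enzyme binding	https://amigo.geneontology.org/amigo/term/GO:0019899	2.66
mmu04070	Phosphatidylinositol signaling system	https://www.genome.jp/pathway/mmu04070	7.49
mmu05200	Pathways in cancer	https://www.genome.jp/pathway/mmu05200	7.38
mmu04520	Adherens junction	https://www.genome.jp/pathway/mmu04520	6.28
GO:0006915	apoptotic process	https://amigo.geneontology.org/amigo/term/GO:0006915	8.26
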