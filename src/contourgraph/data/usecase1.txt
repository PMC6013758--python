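# Subnetwork-module workflow: import, select module, generate + annotate
# groups, select enriched sets, export SVG.
network import url=edges_module.txt indexColumnSourceInteraction=2 indexColumnTargetInteraction=3
table import url=nodes_module.txt firstRowAsColumnNames=true keyColumnIndex=1 startLoadRow=1 dataTypeList=s,s,f,f,f,s,s,s,sl,sl,sl,sl
network select nodeList=Module:small
examine generate groups selectedGroupColumns=Function,Pathway
table import url=sets_module.txt firstRowAsColumnNames=true keyColumnIndex=1 startLoadRow=1
examine update settings labelColumn=Symbol urlColumn=URL scoreColumn=Score showScore=true selectedGroupColumns=Component,Function
examine select groups selectedGroups=GO:0008013,GO:0008083,mmu04070,mmu05200,mmu04520
examine export path=fig1a.svg
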