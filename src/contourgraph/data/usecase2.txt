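# Social-network workflow: import GML, generate community groups,
# select all six, export SVG.
network import url=edges_karate_like.gml indexColumnSourceInteraction=2 indexColumnTargetInteraction=3
table import url=nodes_karate_like.txt firstRowAsColumnNames=true keyColumnIndex=1 startLoadRow=1 dataTypeList=s,sl
network select nodeList=all
examine generate groups selectedGroupColumns=Community useAllNodes=true
examine update settings labelColumn=label urlColumn=label showScore=false selectedGroupColumns=Community
examine select groups selectedGroups=A,B,C,D,E,F
examine export path=fig1b.svg
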