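nominative,genitive,gloss
vulpes,vulpis,fox
vespertilio,vespertilionis,bat
triticum,tritici,wheat
homo,hominis,human
canis,canis,dog
felis,felis,cat
mus,muris,mouse
sus,suis,pig
bos,bovis,cattle
ovis,ovis,sheep
apis,apis,honey bee
avis,avis,bird
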