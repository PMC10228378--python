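genus,epithet,provenance
Emesvirus,zinderi,published
Emesvirus,bostonense,synthetic
Emesvirus,vulpis,synthetic
Qubevirus,durum,published
Qubevirus,delbrucki,synthetic
Qubevirus,hominidae,synthetic
Pepevirus,tritici,synthetic
Pepevirus,zairense,synthetic
Pepevirus,vespertilionis,synthetic
Apeevirus,quebecense,published
Apeevirus,tonsillitidis,synthetic
Apeevirus,unicefi,synthetic
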