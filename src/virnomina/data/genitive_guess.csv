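match,replacement,provenance
um,i,attested
us,i,dictionary
a,ae,dictionary
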