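match,replacement,provenance
itis,itidis,attested
oma,omatis,dictionary
osis,osis,dictionary
iasis,iasis,dictionary
ia,iae,dictionary
us,i,dictionary
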