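character,replacement
ß,ss
ẞ,ss
æ,ae
Æ,ae
œ,oe
Œ,oe
ø,o
Ø,o
đ,d
Đ,d
ð,d
Ð,d
þ,th
Þ,th
ł,l
Ł,l
ħ,h
Ħ,h
ŧ,t
Ŧ,t
ı,i
ĸ,k
ŋ,ng
Ŋ,ng
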