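# Default three-step alphanumeric substitution table for the genus forge.
# Each step maps a (digit,letter) pair to a replacement letter; the digit is
# the random 1/2/3 tag interleaved before the letter. Swaps are chosen to
# minimally change phonetics: voiced/unvoiced stop swaps on digit 1, close
# vowel shifts on digit 2, liquid swaps on digit 3. Fully user-overridable.
steps:
  - {"1b": "p", "1p": "b", "1d": "t", "1t": "d", "1g": "k", "1k": "g"}
  - {"2o": "u", "2u": "o", "2e": "i", "2i": "e"}
  - {"3l": "r", "3r": "l"}
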