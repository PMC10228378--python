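# Default root sets for the combinatorial species-epithet generator.
# Habitat roots are Latin/Greek elements describing where a virus (or its
# host community) was found; dweller roots are classical second elements
# meaning roughly "living in"; prefixes multiply the pool for species-rich
# genera (the empty prefix keeps the unprefixed forms). All lists are
# illustrative, dictionary-sourced defaults and are meant to be edited.
habitat_roots:
  - aqua
  - mari
  - limno
  - thermo
  - pelago
  - bentho
  - fluvio
  - lacu
  - palustri
  - fonti
  - rivo
  - stagno
  - litho
  - petro
  - sabulo
  - agro
  - silvo
  - prato
  - caeno
  - halo
  - cryo
  - telluri
  - nivo
  - campo
dweller_roots:
  - cola
  - incola
  - bius
  - bium
  - philus
  - phila
  - philum
  - vorum
  - vivum
  - colum
  - gena
  - genum
prefixes:
  - ""
  - alpha
  - beta
  - gamma
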