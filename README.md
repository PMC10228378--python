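# virnomina

A rule engine for creating **Latinized binomial virus species names**.

Virus species names follow a binomial format: a capitalized genus name
ending in a neuter rank suffix (*-virus*, *-satellite*, *-viriform*,
*-viroid*) plus a lowercase species epithet, e.g. *Emesvirus zinderi*.
Latinizing the epithet is optional but desirable — it makes virus taxonomy
comparable with the rest of biological nomenclature — and, crucially, it can
be done **formulaically, without knowing Latin**. `virnomina` implements
those formulas as deterministic, testable code for virologists and taxonomy
study groups who need to name one virus or eight hundred:

- **Individual epithets** from the four standard naming routes:
  - *geography*: attach the neuter adjectival suffix **-ense**
    (Neanderthal → `neanderthalense`), retaining a final vowel
    (Atlanta → `atlantaense`) unless it repeats the suffix vowel
    (Zaire → `zairense`);
  - *eponyms*: Latinize (base endings -a/-us/-um for feminine/masculine/
    neuter) and decline to genitive -ae/-i/-i
    (Goodall → `goodallae`, Delbrück → `delbrucki`, UNICEF → `unicefi`);
  - *diseases*: rewrite the medical suffix to its genitive
    (tonsillitis → `tonsillitidis`);
  - *hosts*: use the genitive of the host's Latin noun
    (fox, *vulpes/vulpis* → `vulpis`; families in -ae pass through,
    Hominidae → `hominidae`).
- **Batch genus forging**: a seeded mutation pipeline that interleaves
  random digits 1–3 into each input term, applies three phonetically
  conservative substitution maps, strips the digits, and shapes the result
  into a vowel-final stem (duplicate runs collapsed, truncated after 7
  characters) that must hold ≥ 5 characters, ≥ 2 vowels and ≥ 2 consonants
  and must not collide with any established taxon word stem.
- **Combinatorial species epithets**: prefixes × habitat roots × classical
  "living-in" second elements (aqua- + -cola → `aquacola`), with junction
  elision, constraint filtering and deduplication; a few dozen roots yield
  hundreds of well-formed epithets reusable across genera.
- **Validation & uniqueness**: an index over Master-Species-List-style
  taxonomy tables with rank-suffix stripping (Qubevirus → stem `qube`),
  stem-uniqueness checks, and nomenclature-code validation of assembled
  binomials.

All characters are restricted to the ISO basic Latin alphabet; arbitrary
Unicode input is transliterated (ü→u, ß→ss, æ→ae) and unmappable characters
are reported, never dropped.

## Worked example

```python
>>> import virnomina as v
>>> v.geo_epithet("Quebec").text
'quebecense'
>>> v.eponym_epithet("Zinder", v.Gender.MASCULINE).text
'zinderi'
>>> report = v.forge_genus_names(
...     ["boston"], v.MutationConfig(seed=1, substitution_steps=({}, {}, {})),
...     v.TaxonomyIndex.empty())
>>> report.names
['Bostovirus']
```

`boston` passes through unchanged here (identity substitution maps), is
shaped to the vowel-final stem `bosto` (5 characters, 2 vowels, 3
consonants: passes all constraints), capitalized and suffixed to the genus
name `Bostovirus`. With the default substitution maps and a seed, the same
call obfuscates each term reproducibly — run

```sh
$ virnomina latinize geo Neanderthal
neanderthalense
$ virnomina forge-epithets | head -3
agrobium
agrobius
agrocola
```

for the CLI equivalents (`forge-genera`, `assemble`, `validate`,
`check-unique` and `fixtures` subcommands cover the rest of the pipeline).

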