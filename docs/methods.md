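# Methods

## The naming model

`virnomina` treats virus-name creation as string rewriting over a restricted
alphabet. The unit of work is the *Latinized token*: a lowercase string of
ISO basic Latin letters with, at most, internal hyphens. All rules are
deterministic functions of tokens plus, for the batch pipelines, a seeded
random stream; nothing depends on external state, so every run is
reproducible from its inputs and seed.

Because every virus genus suffix (-virus, -satellite, -viriform, -viroid)
is grammatically neuter, no gender-agreement machinery is needed: the
geographic adjective is always the neuter -ense, and species epithets are
fixed strings that can be reused across genera.

### Transliteration

Unicode input is folded to the basic Latin alphabet by canonical
decomposition plus mark stripping (ü→u, é→e, ñ→n), with a packaged fold
table for letters that do not decompose (ß→ss, æ→ae, œ→oe, ø→o, þ→th, …).
Word separators and apostrophes are dropped; hyphens are dropped by default
and kept on request. A character with no fold (Greek, CJK, digits) raises
an error naming the character — silent dropping would corrupt names.
Transliteration is idempotent on its own output (property-tested).

### Vowel accounting and junction elision

Vowels are {a, e, i, o, u}; **y counts as a consonant**. The guidance never
addresses y and no worked name depends on it, so the conservative reading
was fixed once and documented here; the counting functions take plain
tokens, so a caller needing a different convention can count directly.

When a suffix is joined to a stem, exactly one copy of the junction letter
is elided when stem-final and suffix-initial letters are the same vowel
(zaire + ense → zairense); a *different* final vowel is retained
(atlanta + ense → atlantaense). The optional aesthetic variant that drops
the retained vowel (atlantense) is deliberately not implemented; only the
recommended retention rule is.

### Eponym declension order

Eponyms are transliterated first, then declined. If the transliterated name
already carries a Latin base ending (-a, -us, -um), that ending is replaced
by its genitive (-ae, -i, -i) regardless of the declared gender — the
ending is better evidence of the intended declension than the gender flag,
and this reproduces every worked example (Goodalla → goodallae, Delbruckus
→ delbrucki, unicefum → unicefi). The declared gender only selects the
ending appended to names with no Latin ending (Goodall + ae, Zinder + i).
A gender/ending conflict (e.g. a masculine name ending in -a) is resolved
the same way and flagged on the `virnomina.audit` logger.

### Suffix rule tables

Disease and host-genus genitives are first-match-wins ordered suffix
tables, shipped as editable CSV data, not code. The disease table carries
one well-attested row (-itis → -itidis) plus dictionary-sourced rows
(-oma → -omatis, -osis → -osis, -iasis → -iasis, -ia → -iae, -us → -i)
marked by provenance in the file; users are expected to extend it. The
host-genus guess table (-um → -i, -us → -i, -a → -ae) is explicitly a
*guess* — several declensions share nominative endings — so its use is
flagged on the audit logger, and names it cannot handle (third-declension
nouns such as vulpes) raise instead of guessing wrong: those need a
dictionary noun with its listed genitive.

## The genus forge

The batch pipeline obfuscates input terms (so no generated genus points
back at a person, place or object) while keeping results pronounceable:

1. **Digit interleaving** — a digit drawn uniformly from {1, 2, 3} is
   placed before each letter; the stream comes from numpy's default
   (PCG64) generator seeded by the configuration. Reproducibility is
   guaranteed within this package, not across independent implementations
   with other RNGs.
2. **Three substitution steps** — ordered maps from (digit, letter) pairs
   to replacement letters, applied in sequence; the first letter position
   is never rewritten. The default table makes phonetically minimal swaps
   (b↔p, d↔t, g↔k on digit 1; o↔u, e↔i on digit 2; l↔r on digit 3) and is
   plain config data — correctness claims attach to the pipeline
   mechanics, not to any particular table.
3. **Digit stripping and stem shaping** — digits removed; consecutive
   duplicate letters collapsed to one ("repeating letter" is read as a
   *consecutive* run — global deduplication would destroy ordinary Latin
   stems); truncation after `max_stem_chars` (default 7); trailing
   consonants trimmed so the stem ends in a vowel before the rank suffix.
4. **Constraints and uniqueness** — the shaped stem (not the full name)
   must hold ≥ `min_name_chars` (5) characters, ≥ 2 vowels and
   ≥ 2 consonants; its stem must not equal any established taxon word
   stem; and it must not contain a blocklist word (case-insensitive
   substring on the stem — a local, auditable replacement for manual
   novelty/offensiveness searching). Survivors are capitalized and
   suffixed; duplicate outputs keep their first occurrence.

Each input term's fate (acceptance with a per-step trace, or a typed
rejection reason) is recorded in the forge report, which partitions the
input exactly.

## The epithet forge

Species epithets are enumerated combinatorially: prefix × habitat root ×
"living-in" second element, joined with the same junction-elision rule,
filtered by the same character/vowel/consonant constraints as genus stems,
deduplicated and sorted. The shipped root lists (24 habitat roots, 12
dweller roots, 4 prefixes including the empty one) are illustrative
dictionary-sourced defaults; they yield 1152 distinct epithets. No deeper
Latin euphony than junction elision is attempted, and dweller roots are
fixed strings (no per-genus re-declension) since all genera are neuter.

Allocation hands each genus the requested number of *distinct* epithets,
sampling without replacement per genus from one seeded stream, processing
genera in input order — the simplest deterministic contract that permits
epithet reuse across genera while guaranteeing within-genus uniqueness.

## Taxonomy index and validation

Master-Species-List-shaped tables (one row per species, one column per
rank) are read with pandas; every name at every rank contributes word
stems, obtained by stripping the longest matching rank suffix (so "virus"
never truncates a "-viriform" name, and Leviviricetes → levi). Multi-word
legacy species names are indexed word-by-word for collision purposes but
never validated as binomials. Stem uniqueness offers an `exact` mode
(default) and a stricter `substring` mode, since "uniqueness of word
stems" is ambiguous about containment; genus stems are always checked,
epithet stems only on request. Binomial validation is total — it returns a
report listing every violated rule (charset, genus capitalization, neuter
genus suffix, lowercase epithet, non-empty parts) and never raises.

## Synthetic data

The term sampler draws pronounceable consonant/vowel syllable patterns
(default CVCVCV, letter weights loosely following English onset frequency)
— it emulates only the *shape* of real term lists (length, vowel content),
not their semantics, so passing tests demonstrate pipeline mechanics and
sizing, not that real-world term lists survive the constraints at the same
rate. Real lists contain short or vowel-poor terms, which is why the
input-sizing guidance (1.5–2× the demand) exists; with clean CVCVCV terms
the forge yield is near 100 % and the 2× sizing is comfortably sufficient.

The frozen class-scale fixture mirrors the published reorganization that
motivated batch naming: 420 genera in two orders and six families, 883
species of which 12 are manually named and 871 are metagenome-derived
placeholders. The four published genus names and three published species
names are included verbatim; all other genus names were forged once with
this package's own pipeline, the remaining manual epithets were built with
its own latinizer routes and are marked `synthetic` in the data file, and
per-genus placeholder counts follow a truncated geometric (long-tailed)
distribution adjusted to sum exactly to 871. The drawn counts are committed
as CSV (not regenerated in tests) so downstream counts are stable across
platforms; the generator that produced them remains in the package as
tested code.

## Problem sizes and numerical choices

Default test and acceptance scales — 840-term forge runs, the 420-genus /
883-species fixture, a ~1150-epithet pool — were chosen to match the
class-scale case the engine is built for and run in seconds. There is no
floating-point numerics in the package; determinism questions reduce to RNG
seeding (numpy PCG64 throughout; derived seeds via `SeedSequence`) and to
tie-breaks, which are always "first occurrence wins" (suffix tables, forge
duplicate handling) or "input order" (allocation).

## Known limitations

- Contraction-based names (britcolense-style) are human judgment; the
  engine validates but never generates them.
- Phonetic romanization of non-Latin scripts is out of scope; such input
  raises an unmappable-character error rather than guessing.
- The suffix tables are deliberately small defaults, not a Latin
  morphology; anything beyond first-match suffix rewriting needs a
  dictionary entry.
- Hyphens are permitted by validation (the code allows them) but never
  generated de novo.
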