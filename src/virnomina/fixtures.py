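"""Synthetic inputs: pronounceable term lists and MSL-shaped taxonomy tables.

Real batch-naming runs start from lists of terms associated with newly
discovered viruses and from the current official taxonomy. Neither is
shipped here; instead this module samples pronounceable consonant/vowel
terms and rank-complete taxonomy tables so that every pipeline stage can be
exercised deterministically, plus a frozen class-scale fixture (420 genera,
883 species of which 871 are unnamed metagenome-derived placeholders)
mirroring the published reorganization of the Leviviricetes.

The synthetic generators emulate only the *shape* of real inputs (name
lengths, rank structure, per-genus species-count skew), not any biological
signal.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import EmptyInputError
from .genus_forge import MutationConfig, forge_genus_names
from .nomenclator import BinomialName, TaxonomyIndex
from .orthography import LatinizedToken

#: Consonants used by the syllable sampler, with weights loosely following
#: English onset frequency so terms look word-like rather than uniform.
_CONSONANTS = "bcdfghjklmnpqrstvwxz"
_CONSONANT_W = np.array([3, 4, 4, 2, 3, 4, 1, 3, 5, 5, 5, 3, 1, 5, 6, 6, 2, 1, 1, 1], float)
_VOWELS = "aeiou"
_VOWEL_W = np.array([5, 5, 4, 4, 2], float)


@dataclass(frozen=True)
class TermSamplerConfig:
    """Configuration of the pronounceable-term sampler.

    ``syllable_pattern`` is a template over {C, V}; the default CVCVCV gives
    six-letter terms with three consonants and three vowels, comfortably
    above the genus-forge constraints. With ``drop_final_vowel_rate`` > 0 a
    fraction of terms loses its final vowel, mimicking the length variation
    of real term lists.
    """

    seed: int = 0
    n_terms: int = 100
    syllable_pattern: str = "CVCVCV"
    drop_final_vowel_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_terms < 1:
            raise EmptyInputError("n_terms must be >= 1")
        pattern = self.syllable_pattern.upper()
        if set(pattern) - {"C", "V"}:
            raise ValueError("syllable_pattern may contain only C and V")
        if pattern.count("C") < 2 or pattern.count("V") < 2:
            raise ValueError("syllable_pattern needs at least 2 C and 2 V")
        object.__setattr__(self, "syllable_pattern", pattern)
        if not 0.0 <= self.drop_final_vowel_rate <= 1.0:
            raise ValueError("drop_final_vowel_rate must be in [0, 1]")


def sample_terms(config: TermSamplerConfig) -> list[LatinizedToken]:
    """Sample ``n_terms`` pronounceable lowercase terms, deterministically."""
    rng = np.random.default_rng(config.seed)
    cw = _CONSONANT_W / _CONSONANT_W.sum()
    vw = _VOWEL_W / _VOWEL_W.sum()
    terms: list[LatinizedToken] = []
    for _ in range(config.n_terms):
        chars = [
            _CONSONANTS[rng.choice(len(_CONSONANTS), p=cw)]
            if slot == "C"
            else _VOWELS[rng.choice(len(_VOWELS), p=vw)]
            for slot in config.syllable_pattern
        ]
        text = "".join(chars)
        if (
            config.drop_final_vowel_rate
            and text[-1] in _VOWELS
            and rng.random() < config.drop_final_vowel_rate
        ):
            text = text[:-1]
        terms.append(LatinizedToken(text))
    return terms


def _unique_stems(rng: np.random.Generator, n: int, pattern: str = "CVCVCV") -> list[str]:
    """Draw n distinct vowel-final stems from the syllable sampler."""
    stems: list[str] = []
    seen: set[str] = set()
    cw = _CONSONANT_W / _CONSONANT_W.sum()
    vw = _VOWEL_W / _VOWEL_W.sum()
    while len(stems) < n:
        text = "".join(
            _CONSONANTS[rng.choice(len(_CONSONANTS), p=cw)]
            if slot == "C"
            else _VOWELS[rng.choice(len(_VOWELS), p=vw)]
            for slot in pattern
        )
        if text not in seen:
            seen.add(text)
            stems.append(text)
    return stems


def sample_taxonomy(
    seed: int,
    n_genera: int,
    species_counts: "np.ndarray | list[int] | None" = None,
) -> tuple[TaxonomyIndex, pd.DataFrame]:
    """Generate a rank-complete MSL-shaped taxonomy table.

    Genus names end in -virus; per-genus species counts follow
    ``species_counts`` (default: one species per genus). Species epithets
    are sampled pronounceable tokens, unique within their genus. Returns the
    built index and the table (columns Realm…Species, one row per species).
    """
    if n_genera < 1:
        raise EmptyInputError("n_genera must be >= 1")
    rng = np.random.default_rng(seed)
    if species_counts is None:
        species_counts = [1] * n_genera
    counts = [int(c) for c in species_counts]
    if len(counts) != n_genera:
        raise ValueError("species_counts must have one entry per genus")
    realm, kingdom, phylum, klass, order, family = (
        stem.capitalize() + suffix
        for stem, suffix in zip(
            _unique_stems(rng, 6, "CVCV"),
            ("viria", "virae", "viricota", "viricetes", "virales", "viridae"),
        )
    )
    genus_stems = _unique_stems(rng, n_genera)
    rows = []
    for stem, n_sp in zip(genus_stems, counts):
        genus = stem.capitalize() + "virus"
        epithets = _unique_stems(rng, n_sp)
        for epithet in epithets:
            rows.append(
                {
                    "Realm": realm, "Kingdom": kingdom, "Phylum": phylum,
                    "Class": klass, "Order": order, "Family": family,
                    "Genus": genus, "Species": f"{genus} {epithet}",
                }
            )
    table = pd.DataFrame(rows)
    return TaxonomyIndex.from_dataframe(table), table


@dataclass(frozen=True)
class ClassScaleFixture:
    """The frozen class-scale fixture: genus table, manual names, counts.

    ``genus_table`` has one row per genus (Order, Family, Genus, NManual,
    NMetagenomic); ``manual_species`` are the 12 hand-named species;
    ``metagenomic_counts`` maps each genus to its number of unnamed
    metagenome-derived species placeholders.
    """

    genus_table: pd.DataFrame
    manual_species: tuple[BinomialName, ...]
    metagenomic_counts: dict[str, int] = field(repr=False)

    @property
    def genera(self) -> list[str]:
        return list(self.genus_table["Genus"])

    @property
    def n_species(self) -> int:
        return len(self.manual_species) + sum(self.metagenomic_counts.values())

    def species_table(self) -> pd.DataFrame:
        """Expand to an MSL-shaped species table; metagenome-derived
        placeholders carry an empty Species cell until named."""
        manual_by_genus: dict[str, list[str]] = {}
        for bn in self.manual_species:
            manual_by_genus.setdefault(bn.genus, []).append(bn.epithet)
        rows = []
        for rec in self.genus_table.itertuples(index=False):
            for epithet in manual_by_genus.get(rec.Genus, []):
                rows.append(self._row(rec, f"{rec.Genus} {epithet}"))
            for _ in range(int(rec.NMetagenomic)):
                rows.append(self._row(rec, ""))
        return pd.DataFrame(rows)

    @staticmethod
    def _row(rec, species: str) -> dict[str, str]:
        return {
            "Realm": "Riboviria", "Kingdom": "Orthornavirae",
            "Phylum": "Lenarviricota", "Class": "Leviviricetes",
            "Order": rec.Order, "Family": rec.Family,
            "Genus": rec.Genus, "Species": species,
        }

    def taxonomy_index(self) -> TaxonomyIndex:
        # empty Species cells (unnamed placeholders) contribute nothing
        return TaxonomyIndex.from_dataframe(self.species_table())


def leviviricetes_fixture() -> ClassScaleFixture:
    """Load the frozen class-scale fixture shipped with the package.

    420 genera in two orders and six families; 883 species of which 12 are
    manually named and 871 are metagenome-derived placeholders awaiting
    batch naming. Synthetic portions (all genus names beyond the four
    published ones, and nine of the manual species epithets) were generated
    once with this package's own forge/latinizer and frozen.
    """
    data = resources.files("virnomina.data")
    genus_table = pd.read_csv(data.joinpath("leviviricetes_genera.csv"))
    manual: list[BinomialName] = []
    with data.joinpath("leviviricetes_manual_species.csv").open(encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            manual.append(BinomialName(genus=row["genus"], epithet=row["epithet"]))
    counts = {
        rec.Genus: int(rec.NMetagenomic) for rec in genus_table.itertuples(index=False)
    }
    return ClassScaleFixture(
        genus_table=genus_table,
        manual_species=tuple(manual),
        metagenomic_counts=counts,
    )


def make_class_scale_tables(
    seed: int = 2020,
    n_genera: int = 420,
    n_manual: int = 12,
    n_metagenomic: int = 871,
) -> tuple[pd.DataFrame, list[tuple[str, str, str]]]:
    """Build the class-scale genus table deterministically (used once to
    freeze the packaged fixture; kept as tested, reusable code).

    The four published genera keep their real names and hold the 12 manual
    species (three each); the remaining genera are forged from sampled terms
    with this package's own pipeline. Per-genus metagenome-derived species
    counts follow a truncated geometric (long-tailed) distribution adjusted
    to sum exactly to ``n_metagenomic``.
    """
    rng = np.random.default_rng(seed)
    manual_genera = ["Emesvirus", "Qubevirus", "Pepevirus", "Apeevirus"]
    manual_epithets = {
        "Emesvirus": [("zinderi", "published"), ("bostonense", "synthetic"),
                      ("vulpis", "synthetic")],
        "Qubevirus": [("durum", "published"), ("delbrucki", "synthetic"),
                      ("hominidae", "synthetic")],
        "Pepevirus": [("tritici", "synthetic"), ("zairense", "synthetic"),
                      ("vespertilionis", "synthetic")],
        "Apeevirus": [("quebecense", "published"), ("tonsillitidis", "synthetic"),
                      ("unicefi", "synthetic")],
    }
    if sum(len(v) for v in manual_epithets.values()) != n_manual:
        raise ValueError("manual epithet table must hold exactly n_manual names")

    n_forged = n_genera - len(manual_genera)
    seed_taxo = TaxonomyIndex.empty().with_names(manual_genera)
    config = MutationConfig(seed=int(rng.integers(0, 2**31)))
    forged: list[str] = []
    guard = 0
    while len(forged) < n_forged and guard < 20:
        need = n_forged - len(forged)
        terms = [t.text for t in sample_terms(
            TermSamplerConfig(seed=int(rng.integers(0, 2**31)), n_terms=2 * need)
        )]
        report = forge_genus_names(terms, config, taxonomy=seed_taxo)
        fresh = [n for n in report.names if n not in forged][:need]
        forged.extend(fresh)
        seed_taxo = seed_taxo.with_names(fresh)
        guard += 1
    if len(forged) < n_forged:
        raise RuntimeError("could not forge enough unique genus names")

    genera = manual_genera + forged
    # long-tailed per-genus placeholder counts over the forged genera only
    counts = np.minimum(rng.geometric(p=0.45, size=n_forged), 20)
    diff = n_metagenomic - int(counts.sum())
    while diff != 0:
        i = int(rng.integers(0, n_forged))
        if diff > 0 and counts[i] < 20:
            counts[i] += 1
            diff -= 1
        elif diff < 0 and counts[i] > 1:
            counts[i] -= 1
            diff += 1

    orders = ["Primolevirales", "Duolevirales"]
    families = ["Fluviviridae", "Stagnoviridae", "Litoviridae",
                "Pelagoviridae", "Fontiviridae", "Caenoviridae"]
    fam_order = {f: orders[0] if i < 3 else orders[1] for i, f in enumerate(families)}
    fam_assign = [families[i % len(families)] for i in range(n_genera)]

    rows = []
    for i, genus in enumerate(genera):
        fam = fam_assign[i]
        rows.append({
            "Order": fam_order[fam], "Family": fam, "Genus": genus,
            "NManual": len(manual_epithets.get(genus, [])),
            "NMetagenomic": 0 if genus in manual_genera else int(counts[i - len(manual_genera)]),
        })
    genus_table = pd.DataFrame(rows)
    manual_rows = [
        (genus, epithet, provenance)
        for genus in manual_genera
        for epithet, provenance in manual_epithets[genus]
    ]
    return genus_table, manual_rows
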