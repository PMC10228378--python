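"""Formulaic creation of individual Latinized species epithets.

Four naming routes are covered, matching how virologists actually name
species: after a geographical location (adjectival -ense), after a person or
organization (Latinized eponym declined to genitive), after a disease
(medical-suffix genitive), and after a host taxon (the host noun's genitive).
All virus genus suffixes (-virus, -satellite, -viriform, -viroid) are
grammatically neuter, so the geographic adjective always takes the neuter
-ense form and no gender agreement logic is needed downstream.
"""
from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass
from importlib import resources

from .errors import NoMatchingSuffixError, NotAeSuffixedError
from .orthography import LatinizedToken, join_with_elision, transliterate

audit_log = logging.getLogger("virnomina.audit")


class Gender(enum.Enum):
    """Grammatical gender of the Latinized base form of an eponym."""

    FEMININE = "feminine"
    MASCULINE = "masculine"
    NEUTER = "neuter"


#: Latin base endings appended when Latinizing an eponym, per gender.
_BASE_ENDING = {Gender.FEMININE: "a", Gender.MASCULINE: "us", Gender.NEUTER: "um"}
#: Genitive endings for the same declensions.
_GENITIVE_ENDING = {Gender.FEMININE: "ae", Gender.MASCULINE: "i", Gender.NEUTER: "i"}
#: Recognized Latin endings on an already-Latin-shaped name, with their
#: genitives. Checked longest-first; the ending wins over the declared gender.
_ENDING_TO_GENITIVE = (("us", "i"), ("um", "i"), ("a", "ae"))


@dataclass(frozen=True)
class SuffixRuleTable:
    """Ordered (match-suffix → replacement-suffix) rewrite rules.

    The first rule whose match-suffix ends the input word wins. Used for
    disease-name genitives and for guessing host-genus genitives.
    """

    name: str
    rules: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        matches = [m for m, _ in self.rules]
        if len(set(matches)) != len(matches):
            raise ValueError(f"duplicate match suffixes in table {self.name!r}")

    def apply(self, word: str) -> str | None:
        """Rewrite ``word`` by the first matching rule, or None if none match."""
        for match, replacement in self.rules:
            if word.endswith(match):
                return word[: len(word) - len(match)] + replacement
        return None

    @classmethod
    def from_csv(cls, path, name: str) -> "SuffixRuleTable":
        with open(path, encoding="utf-8") as handle:
            rows = [(r["match"], r["replacement"]) for r in csv.DictReader(handle)]
        return cls(name=name, rules=tuple(rows))


@dataclass(frozen=True)
class LatinNoun:
    """A dictionary Latin noun: nominative, its unique singular genitive, gloss."""

    nominative: LatinizedToken
    genitive: LatinizedToken
    gloss: str = ""

    @classmethod
    def make(cls, nominative: str, genitive: str, gloss: str = "") -> "LatinNoun":
        return cls(LatinizedToken(nominative.lower()), LatinizedToken(genitive.lower()), gloss)


def _packaged_table(filename: str, name: str) -> SuffixRuleTable:
    path = resources.files("virnomina.data").joinpath(filename)
    with path.open(encoding="utf-8") as handle:
        rows = [(r["match"], r["replacement"]) for r in csv.DictReader(handle)]
    return SuffixRuleTable(name=name, rules=tuple(rows))


def default_disease_table() -> SuffixRuleTable:
    """Medical-terminology suffix → genitive table (editable packaged data)."""
    return _packaged_table("disease_suffixes.csv", "disease")


def default_genitive_guess_table() -> SuffixRuleTable:
    """Nominative-ending → genitive-ending guesses for non-viral genus names."""
    return _packaged_table("genitive_guess.csv", "host-nominative")


def default_host_nouns() -> dict[str, LatinNoun]:
    """Small packaged Latin dictionary of common host nouns, by nominative."""
    path = resources.files("virnomina.data").joinpath("host_nouns.csv")
    nouns: dict[str, LatinNoun] = {}
    with path.open(encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            noun = LatinNoun.make(row["nominative"], row["genitive"], row["gloss"])
            nouns[noun.nominative.text] = noun
    return nouns


def geo_epithet(place: str) -> LatinizedToken:
    """Species epithet from a place name: transliterate and attach neuter -ense.

    One copy of a repeated junction vowel is elided (zaire → zairense), but a
    non-identical final vowel is retained (atlanta → atlantaense).
    """
    return join_with_elision(transliterate(place), "ense")


def eponym_epithet(name: str, gender: Gender) -> LatinizedToken:
    """Genitive epithet honoring a person, object, organization or institution.

    The name is transliterated, Latinized (base endings -a feminine, -us
    masculine, -um neuter) and declined to genitive (-ae / -i / -i). If the
    transliterated name already carries one of the Latin base endings, that
    ending is replaced by its genitive directly — the ending decides, the
    declared gender only selects the appended ending for names without one.
    A gender/ending conflict is flagged on the audit log.
    """
    token = transliterate(name)
    text = token.text
    for ending, genitive in _ENDING_TO_GENITIVE:
        if text.endswith(ending) and len(text) > len(ending):
            expected = _BASE_ENDING[gender]
            if ending != expected:
                audit_log.info(
                    "eponym %r: Latin ending -%s overrides declared gender %s",
                    name, ending, gender.value,
                )
            return LatinizedToken(text[: len(text) - len(ending)] + genitive)
    return join_with_elision(token, _GENITIVE_ENDING[gender])


def disease_epithet(disease: str, table: SuffixRuleTable | None = None) -> LatinizedToken:
    """Genitive epithet from a disease name by rewriting its medical suffix.

    Raises :class:`NoMatchingSuffixError` when the disease name carries no
    suffix known to the table; the caller must extend the table or take
    another naming route.
    """
    if table is None:
        table = default_disease_table()
    word = transliterate(disease).text
    result = table.apply(word)
    if result is None:
        raise NoMatchingSuffixError(word, table.name)
    return LatinizedToken(result)


def host_epithet(host: LatinNoun) -> LatinizedToken:
    """Epithet from a host taxon: the genitive form of the host's Latin noun."""
    return LatinizedToken(host.genitive.text.lower())


def suprageneric_epithet(taxon: str) -> LatinizedToken:
    """Epithet from a host taxon ranked above genus.

    Suprageneric taxa are plural; the only unambiguous ending is -ae, whose
    singular genitive is also -ae, so the (lowercased) taxon name is returned
    unchanged. Other endings raise :class:`NotAeSuffixedError`; route those
    through :func:`host_epithet` with a dictionary noun instead (e.g. the
    order Chiroptera via vespertilio/vespertilionis).
    """
    token = transliterate(taxon)
    if not token.text.endswith("ae"):
        raise NotAeSuffixedError(
            f"{taxon!r} does not end in -ae; use a dictionary noun via host_epithet"
        )
    return token


def guess_genitive(
    nominative: LatinizedToken | str, table: SuffixRuleTable | None = None
) -> LatinizedToken:
    """Guess the genitive of a host genus name from its nominative ending.

    The mapping is ambiguous (several declensions share nominative endings),
    so the result is flagged as a guess on the audit log and a name whose
    ending matches no rule raises :class:`NoMatchingSuffixError` — consult a
    Latin dictionary for those (third-declension nouns like vulpes/vulpis are
    not suffix-derivable).
    """
    if table is None:
        table = default_genitive_guess_table()
    word = nominative.text if isinstance(nominative, LatinizedToken) else LatinizedToken(nominative).text
    result = table.apply(word)
    if result is None:
        raise NoMatchingSuffixError(word, table.name)
    audit_log.info("genitive of %r guessed as %r from suffix table %r", word, result, table.name)
    return LatinizedToken(result)
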