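"""Seeded batch pipeline that mutates a term list into novel genus names.

The pipeline obfuscates each input term so that no generated genus name
points back at a person, place or object, while keeping the result
pronounceable: a random digit 1–3 is interleaved before every letter, three
ordered substitution maps rewrite specific (digit,letter) pairs to new
letters, the digits are stripped, and the mutated term is shaped into a stem
(consecutive duplicate letters collapsed, truncated, trailing consonants
trimmed so the stem ends in a vowel before the rank suffix). Stems must meet
minimum length/vowel/consonant constraints, must not collide with word stems
of established taxa and must not contain blocklisted words; survivors are
capitalized and suffixed with the genus rank suffix (-virus by default).

The whole run is reproducible from the seed in the configuration.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .errors import (
    EmptyInputError,
    InvalidTokenError,
    NoVowelError,
    StructuralError,
    UnmappableCharacterError,
)
from .orthography import (
    VOWELS,
    LatinizedToken,
    count_consonants,
    count_vowels,
    transliterate,
)

#: Genus rank suffixes the nomenclature code treats as neuter.
NEUTER_RANK_SUFFIXES = ("virus", "satellite", "viriform", "viroid")

_DIGITS = "123"


def default_substitution_steps() -> list[dict[str, str]]:
    """The packaged three-step substitution table (phonetically conservative)."""
    path = resources.files("virnomina.data").joinpath("substitution_steps.yaml")
    with path.open(encoding="utf-8") as handle:
        return list(yaml.safe_load(handle)["steps"])


@dataclass(frozen=True)
class MutationConfig:
    """Configuration of the genus-forge pipeline.

    Parameters
    ----------
    seed
        Seed for the digit-interleaving RNG stream; fixes the whole run.
    substitution_steps
        Exactly three ordered maps from a (digit,letter) pair, written as a
        two-character key like ``"2o"``, to a replacement letter.
    max_stem_chars
        Stems are truncated after this many characters (default 7).
    min_name_chars, min_vowels, min_consonants
        Acceptance constraints on the shaped stem (defaults 5 / 2 / 2).
    rank_suffix
        Appended to accepted capitalized stems; must be one of the neuter
        genus suffixes (virus, satellite, viriform, viroid).
    """

    seed: int = 0
    substitution_steps: tuple[Mapping[str, str], ...] = field(
        default_factory=lambda: tuple(default_substitution_steps())
    )
    max_stem_chars: int = 7
    min_name_chars: int = 5
    min_vowels: int = 2
    min_consonants: int = 2
    rank_suffix: str = "virus"

    def __post_init__(self) -> None:
        if len(self.substitution_steps) != 3:
            raise ValueError("exactly 3 substitution steps are required")
        object.__setattr__(self, "substitution_steps", tuple(
            dict(step) for step in self.substitution_steps
        ))
        for step in self.substitution_steps:
            for key, val in step.items():
                if len(key) != 2 or key[0] not in _DIGITS or not key[1].isalpha():
                    raise ValueError(f"substitution key {key!r} is not digit+letter")
                if len(val) != 1 or not ("a" <= val <= "z"):
                    raise ValueError(f"substitution value {val!r} is not a letter")
        for name in ("max_stem_chars", "min_name_chars", "min_vowels", "min_consonants"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.rank_suffix not in NEUTER_RANK_SUFFIXES:
            raise ValueError(
                f"rank_suffix must be one of {NEUTER_RANK_SUFFIXES}, got {self.rank_suffix!r}"
            )

    def with_seed(self, seed: int) -> "MutationConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class ForgeRecord:
    """Fate of one input term: accepted with a trace, or rejected with a reason."""

    term: str
    status: str  # "accepted" | "rejected"
    name: str | None = None  # final genus name if accepted
    reason: str | None = None  # rejection reason if rejected
    trace: tuple[str, ...] = ()  # per-step intermediate strings


@dataclass(frozen=True)
class ForgeReport:
    """Partition of the input terms into accepted genus names and rejections."""

    accepted: tuple[ForgeRecord, ...]
    rejected: tuple[ForgeRecord, ...]

    @property
    def names(self) -> list[str]:
        return [rec.name for rec in self.accepted]

    def records(self) -> list[ForgeRecord]:
        order = {rec.term: rec for rec in self.accepted}
        order.update({rec.term: rec for rec in self.rejected})
        return list(self.accepted) + list(self.rejected)


def interleave_digits(term: LatinizedToken | str, rng: np.random.Generator) -> str:
    """Interleave a random digit from {1,2,3} before every letter of the term.

    The output alternates digit,letter,digit,letter,... and has twice the
    length of the input; stripping the digits recovers the term exactly.
    """
    text = term.text if isinstance(term, LatinizedToken) else LatinizedToken(term).text
    digits = rng.integers(1, 4, size=len(text))
    return "".join(f"{d}{c}" for d, c in zip(digits, text))


def _pairs(alphanum: str) -> list[str]:
    if not alphanum or len(alphanum) % 2 != 0:
        raise StructuralError(f"{alphanum!r} is not an alternating digit/letter string")
    pairs = [alphanum[i : i + 2] for i in range(0, len(alphanum), 2)]
    for pair in pairs:
        if pair[0] not in _DIGITS or not pair[1].isalpha():
            raise StructuralError(f"{alphanum!r} is not an alternating digit/letter string")
    return pairs


def apply_substitution_steps(alphanum: str, config: MutationConfig) -> str:
    """Apply the three ordered substitution maps to the interleaved string.

    Each (digit,letter) pair is either rewritten to its mapped letter (the
    digit tag is retained until stripping) or left intact. The first letter
    of a term is never mutated.
    """
    pairs = _pairs(alphanum)
    for step in config.substitution_steps:
        for i in range(1, len(pairs)):  # position 0 is immutable
            replacement = step.get(pairs[i])
            if replacement is not None:
                pairs[i] = pairs[i][0] + replacement
    return "".join(pairs)


def strip_digits(alphanum: str) -> LatinizedToken:
    """Remove the digit tags, preserving letter order."""
    if not alphanum:
        raise EmptyInputError("cannot strip digits from an empty string")
    letters = "".join(c for c in alphanum if c not in _DIGITS)
    return LatinizedToken(letters)


def shape_stem(token: LatinizedToken | str, config: MutationConfig) -> LatinizedToken:
    """Shape a mutated term into a genus stem.

    Three steps, in order: collapse each run of a repeated letter to a single
    occurrence; truncate after ``max_stem_chars`` characters; trim trailing
    consonants so the stem ends in a vowel (avoiding a hard consonant before
    the rank suffix).

    Raises
    ------
    NoVowelError
        If the truncated stem contains no vowel at all.
    """
    text = token.text if isinstance(token, LatinizedToken) else LatinizedToken(token).text
    collapsed: list[str] = []
    for char in text:
        if not collapsed or collapsed[-1] != char:
            collapsed.append(char)
    stem = "".join(collapsed)[: config.max_stem_chars]
    while stem and stem[-1] not in VOWELS:
        stem = stem[:-1]
    if not stem:
        raise NoVowelError(f"stem of {text!r} contains no vowel")
    return LatinizedToken(stem)


def forge_genus_names(
    terms: Sequence[str],
    config: MutationConfig,
    taxonomy: "TaxonomyIndex | None" = None,
    blocklist: Iterable[str] = (),
) -> ForgeReport:
    """Run the full seeded pipeline over a term list.

    Per term: transliterate → interleave digits → substitution steps → strip
    digits → shape stem → constraint checks (length, vowels, consonants) →
    taxonomy stem-uniqueness check → blocklist check → capitalize and append
    the rank suffix. Duplicate final names keep the first occurrence; later
    ones are rejected as ``duplicate-output``. The run is fully reproducible
    from the configuration seed.
    """
    if not terms:
        raise EmptyInputError("term list is empty")
    rng = np.random.default_rng(config.seed)
    block = tuple(w.lower() for w in blocklist)
    taxo_stems = taxonomy.stem_set if taxonomy is not None else frozenset()
    accepted: list[ForgeRecord] = []
    rejected: list[ForgeRecord] = []
    seen_names: set[str] = set()

    def reject(term: str, reason: str, trace: list[str]) -> None:
        rejected.append(ForgeRecord(term=term, status="rejected", reason=reason, trace=tuple(trace)))

    for term in terms:
        trace: list[str] = []
        try:
            token = transliterate(term)
        except (UnmappableCharacterError, InvalidTokenError):
            reject(term, "unmappable", trace)
            continue
        trace.append(token.text)
        interleaved = interleave_digits(token, rng)
        trace.append(interleaved)
        substituted = apply_substitution_steps(interleaved, config)
        trace.append(substituted)
        mutated = strip_digits(substituted)
        trace.append(mutated.text)
        try:
            stem = shape_stem(mutated, config)
        except NoVowelError:
            reject(term, "no-vowel", trace)
            continue
        trace.append(stem.text)
        if len(stem) < config.min_name_chars:
            reject(term, "too-short", trace)
            continue
        if count_vowels(stem) < config.min_vowels:
            reject(term, "vowel-count", trace)
            continue
        if count_consonants(stem) < config.min_consonants:
            reject(term, "consonant-count", trace)
            continue
        if stem.text in taxo_stems:
            reject(term, "stem-collision", trace)
            continue
        if any(word and word in stem.text for word in block):
            reject(term, "blocklist", trace)
            continue
        name = LatinizedToken(stem.text + config.rank_suffix, first_upper=True).render()
        if name in seen_names:
            reject(term, "duplicate-output", trace)
            continue
        seen_names.add(name)
        trace.append(name)
        accepted.append(ForgeRecord(term=term, status="accepted", name=name, trace=tuple(trace)))
    return ForgeReport(accepted=tuple(accepted), rejected=tuple(rejected))
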