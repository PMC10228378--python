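"""Taxonomy indexing, stem uniqueness and binomial validation.

New genus names must have word stems that are unique across every
established taxon name, from realm down to species. This module builds a
per-rank index from a Master-Species-List-shaped table (one row per species,
one column per rank), derives the stem set by stripping rank suffixes
(longest suffix first, so "virus" never matches inside "viriform"-type
names), and provides binomial assembly plus code-compliance validation.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DuplicateBinomialError, EmptyInputError
from .orthography import LatinizedToken

#: Rank suffixes recognized when deriving word stems, realm down to genus,
#: plus the neuter genus-level suffixes. Stripping is longest-suffix-first.
DEFAULT_RANK_SUFFIXES = (
    "viria", "virae", "viricota", "viricotina", "viricetes", "viricetidae",
    "virales", "virineae", "viridae", "virinae", "virus",
    "satellitidae", "satellitinae", "satellite",
    "viriformidae", "viriform", "viroidae", "viroid",
)

#: Genus names must end in one of these (all grammatically neuter).
NEUTER_GENUS_SUFFIXES = ("virus", "satellite", "viriform", "viroid")

_EPITHET_RE = re.compile(r"^[a-z]([a-z-]*[a-z])?$")
_GENUS_RE = re.compile(r"^[A-Z][a-z-]*[a-z]$")

#: Rank column names recognized in MSL-style tables, in rank order.
MSL_RANKS = (
    "Realm", "Subrealm", "Kingdom", "Subkingdom", "Phylum", "Subphylum",
    "Class", "Subclass", "Order", "Suborder", "Family", "Subfamily",
    "Genus", "Subgenus", "Species",
)


def extract_stem(name: str, suffixes: Sequence[str] = DEFAULT_RANK_SUFFIXES) -> LatinizedToken:
    """Strip the longest matching rank suffix and return the lowercased stem.

    If no suffix matches (host taxa like Hominidae, legacy free-form names),
    the whole lowercased name is the stem.
    """
    lower = name.strip().lower()
    if not lower:
        raise EmptyInputError("cannot extract a stem from an empty name")
    for suffix in sorted(suffixes, key=len, reverse=True):
        if lower.endswith(suffix) and len(lower) > len(suffix):
            return LatinizedToken(lower[: -len(suffix)])
    return LatinizedToken(lower)


@dataclass(frozen=True)
class TaxonomyIndex:
    """Per-rank name sets plus the derived word-stem set for uniqueness checks."""

    names_by_rank: Mapping[str, frozenset[str]]
    stem_set: frozenset[str]
    rank_suffixes: tuple[str, ...] = DEFAULT_RANK_SUFFIXES

    @classmethod
    def empty(cls) -> "TaxonomyIndex":
        return cls(names_by_rank={}, stem_set=frozenset())

    @classmethod
    def from_dataframe(
        cls,
        table: pd.DataFrame,
        rank_columns: Sequence[str] | None = None,
        rank_suffixes: Sequence[str] = DEFAULT_RANK_SUFFIXES,
    ) -> "TaxonomyIndex":
        """Index an MSL-shaped table (one row per species, one column per rank).

        Legacy species names that are not single Latinized words (multi-word,
        digits) are indexed verbatim for collision purposes; each of their
        whitespace-separated alphabetic words also contributes a stem.
        """
        if rank_columns is None:
            lower_ranks = {r.lower() for r in MSL_RANKS}
            rank_columns = [c for c in table.columns if c.lower() in lower_ranks]
        names_by_rank: dict[str, frozenset[str]] = {}
        stems: set[str] = set()
        for col in rank_columns:
            values = {
                str(v).strip()
                for v in table[col].dropna().unique()
                if str(v).strip() and str(v).strip().lower() != "nan"
            }
            names_by_rank[col] = frozenset(values)
            for name in values:
                for word in name.split():
                    cleaned = "".join(c for c in word.lower() if c.isalpha() or c == "-").strip("-")
                    if cleaned:
                        stems.add(extract_stem(cleaned, rank_suffixes).text)
        return cls(
            names_by_rank=names_by_rank,
            stem_set=frozenset(stems),
            rank_suffixes=tuple(rank_suffixes),
        )

    @classmethod
    def from_csv(cls, path, sep: str | None = None, **kwargs) -> "TaxonomyIndex":
        if sep is None:
            sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
        return cls.from_dataframe(pd.read_csv(path, sep=sep), **kwargs)

    def with_names(self, names: Iterable[str], rank: str = "Genus") -> "TaxonomyIndex":
        """Return a new index augmented with additional taxon names."""
        extra = {str(n).strip() for n in names}
        merged = dict(self.names_by_rank)
        merged[rank] = frozenset(merged.get(rank, frozenset()) | extra)
        stems = set(self.stem_set)
        for name in extra:
            stems.add(extract_stem(name, self.rank_suffixes).text)
        return TaxonomyIndex(
            names_by_rank=merged,
            stem_set=frozenset(stems),
            rank_suffixes=self.rank_suffixes,
        )


def is_stem_unique(
    candidate: LatinizedToken | str,
    index: TaxonomyIndex,
    mode: str = "exact",
) -> tuple[bool, list[str]]:
    """Check a candidate stem against the taxonomy stem set.

    ``exact`` mode flags only an identical established stem; ``substring``
    mode additionally flags any established stem that contains, or is
    contained by, the candidate. Returns (unique?, colliding stems).
    """
    if mode not in ("exact", "substring"):
        raise ValueError(f"mode must be 'exact' or 'substring', got {mode!r}")
    stem = str(candidate).lower()
    if mode == "exact":
        collisions = [stem] if stem in index.stem_set else []
    else:
        collisions = sorted(s for s in index.stem_set if stem in s or s in stem)
    return (not collisions, collisions)


@dataclass(frozen=True)
class BinomialName:
    """A two-part virus species name: capitalized genus + lowercase epithet."""

    genus: str
    epithet: str

    def render(self) -> str:
        return f"{self.genus} {self.epithet}"

    def __str__(self) -> str:
        return self.render()


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of binomial validation; an empty violation list means valid."""

    name: str
    violations: tuple[str, ...] = ()

    @property
    def is_valid(self) -> bool:
        return not self.violations


def validate_binomial(name: BinomialName) -> ValidationReport:
    """Check a binomial against the nomenclature-code constraints.

    Checks charset (basic Latin letters plus internal hyphens), genus
    capitalization and neuter rank suffix, epithet lower-casing, and minimum
    length of both parts. Validation never raises; every violated rule is
    listed in the report.
    """
    violations: list[str] = []
    genus, epithet = name.genus, name.epithet
    if not genus:
        violations.append("genus-empty")
    else:
        if not _GENUS_RE.match(genus):
            violations.append("genus-charset")
        if genus[0].islower():
            violations.append("genus-capitalization")
        if not genus.lower().endswith(NEUTER_GENUS_SUFFIXES):
            violations.append("genus-suffix")
    if not epithet:
        violations.append("epithet-empty")
    else:
        if any(c.isupper() for c in epithet):
            violations.append("epithet-uppercase")
        if not _EPITHET_RE.match(epithet.lower()):
            violations.append("epithet-charset")
    return ValidationReport(name=name.render(), violations=tuple(violations))


def assemble(
    genera: Sequence[str],
    allocation: Mapping[str, Sequence[str]],
) -> list[BinomialName]:
    """Cross-join each genus with its allocated epithets into binomials.

    Epithet reuse across genera is legal; a repeated rendered binomial
    raises :class:`DuplicateBinomialError`. Every output passes
    :func:`validate_binomial` clean or an AssertionError is raised (the
    inputs were supposed to be forged/validated upstream).
    """
    unknown = set(allocation) - set(genera)
    if unknown:
        raise ValueError(f"allocation contains genera not in the genus list: {sorted(unknown)}")
    seen: set[str] = set()
    out: list[BinomialName] = []
    for genus in genera:
        for epithet in allocation.get(genus, ()):
            binomial = BinomialName(genus=genus, epithet=str(epithet))
            rendered = binomial.render()
            if rendered in seen:
                raise DuplicateBinomialError(rendered)
            seen.add(rendered)
            report = validate_binomial(binomial)
            if not report.is_valid:
                raise AssertionError(
                    f"assembled binomial {rendered!r} violates {report.violations}"
                )
            out.append(binomial)
    return out
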