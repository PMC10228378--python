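"""Combinatorial generator for Latinized species epithets.

Species epithets for large batches of metagenome-derived viruses are built
by crossing habitat roots (aqua-, limno-, thermo-, ...) with second elements
meaning "living in" (-cola, -bius, -incola, ...), optionally multiplied by a
prefix set for species-rich genera. A few dozen roots yield hundreds of
well-formed epithets; because all virus genus names are neuter, the epithets
are fixed strings reusable across genera, and the allocator hands each genus
a distinct subset from the shared pool.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import DemandExceedsPoolError, EmptyInputError
from .genus_forge import MutationConfig
from .orthography import (
    LatinizedToken,
    count_consonants,
    count_vowels,
    join_with_elision,
)


@dataclass(frozen=True)
class RootSet:
    """Root lists the combinatorial generator crosses.

    ``prefixes`` may (and by default does) include the empty string, which
    keeps the unprefixed habitat+dweller forms in the pool.
    """

    habitat_roots: tuple[str, ...]
    dweller_roots: tuple[str, ...]
    prefixes: tuple[str, ...] = ("",)

    def __post_init__(self) -> None:
        object.__setattr__(self, "habitat_roots", _dedup_validate(self.habitat_roots, "habitat"))
        object.__setattr__(self, "dweller_roots", _dedup_validate(self.dweller_roots, "dweller"))
        prefixes = tuple(dict.fromkeys(self.prefixes))
        for p in prefixes:
            if p:
                LatinizedToken(p)
        object.__setattr__(self, "prefixes", prefixes)
        for root in self.dweller_roots:
            if root[-1] not in "aeiou" and not root.endswith(("um", "us")):
                raise ValueError(
                    f"dweller root {root!r} must end in a vowel or a Latin -us/-um ending"
                )


def _dedup_validate(roots: Sequence[str], label: str) -> tuple[str, ...]:
    if not roots:
        raise EmptyInputError(f"{label} root list is empty")
    out = tuple(dict.fromkeys(roots))
    for root in out:
        LatinizedToken(root)
    return out


def default_roots() -> RootSet:
    """The packaged illustrative root sets (24 habitat, 12 dweller, 4 prefixes)."""
    path = resources.files("virnomina.data").joinpath("roots_default.yaml")
    with path.open(encoding="utf-8") as handle:
        raw = yaml.safe_load(handle)
    return RootSet(
        habitat_roots=tuple(raw["habitat_roots"]),
        dweller_roots=tuple(raw["dweller_roots"]),
        prefixes=tuple(raw["prefixes"]),
    )


def load_roots(path) -> RootSet:
    """Load a RootSet from a YAML file with keys habitat_roots/dweller_roots/prefixes."""
    with open(path, encoding="utf-8") as handle:
        raw = yaml.safe_load(handle)
    return RootSet(
        habitat_roots=tuple(raw["habitat_roots"]),
        dweller_roots=tuple(raw["dweller_roots"]),
        prefixes=tuple(raw.get("prefixes", [""])),
    )


def enumerate_epithets(
    roots: RootSet, constraints: MutationConfig | None = None
) -> list[LatinizedToken]:
    """Enumerate all prefix+habitat+dweller epithets passing the constraints.

    Junction elision is applied at each join (aqua + arum → aquarum), then
    each candidate is filtered by the same character/vowel/consonant
    constraints used for genus stems, deduplicated and returned sorted.
    The output size is at most |prefixes| × |habitat| × |dweller|.
    """
    if constraints is None:
        constraints = MutationConfig()
    seen: set[str] = set()
    for prefix in roots.prefixes:
        for habitat in roots.habitat_roots:
            body = join_with_elision(prefix, habitat) if prefix else LatinizedToken(habitat)
            for dweller in roots.dweller_roots:
                epithet = join_with_elision(body, dweller)
                if len(epithet) < constraints.min_name_chars:
                    continue
                if count_vowels(epithet) < constraints.min_vowels:
                    continue
                if count_consonants(epithet) < constraints.min_consonants:
                    continue
                seen.add(epithet.text)
    return [LatinizedToken(text) for text in sorted(seen)]


def allocate_epithets(
    genera: Sequence[str],
    species_per_genus: Mapping[str, int],
    epithets: Sequence[LatinizedToken | str],
    rng: np.random.Generator | int,
) -> dict[str, list[str]]:
    """Assign each genus the requested number of distinct epithets.

    Within a genus the assigned epithets are pairwise distinct (species-name
    uniqueness within a genus); the same epithet may recur across genera.
    Genera are processed in input order, sampling without replacement per
    genus from the seeded stream, so the assignment is deterministic given
    the seed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    pool = [str(e) for e in epithets]
    allocation: dict[str, list[str]] = {}
    for genus in genera:
        demand = int(species_per_genus.get(genus, 0))
        if demand > len(pool):
            raise DemandExceedsPoolError(genus, demand, len(pool))
        if demand == 0:
            allocation[genus] = []
            continue
        picks = rng.choice(len(pool), size=demand, replace=False)
        allocation[genus] = [pool[i] for i in picks]
    return allocation
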