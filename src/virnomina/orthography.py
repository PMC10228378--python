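"""Character-level plumbing for Latinized taxon names.

Virus taxon names are restricted to the ISO basic Latin alphabet (lowercase
a–z plus, at most, internal hyphens); diacritics and any other characters are
disallowed by the nomenclature code. This module supplies the primitives the
rest of the engine builds on: transliteration of arbitrary Unicode input to
that alphabet, vowel/consonant accounting, and suffix joining with elision of
a repeated junction vowel.
"""
from __future__ import annotations

import csv
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources

from .errors import InvalidTokenError, UnmappableCharacterError

#: Letters counted as vowels. 'y' deliberately counts as a consonant; the
#: naming guidance never relies on vocalic y and a conservative reading keeps
#: the constraint checks predictable. Override at call sites if needed.
VOWELS = frozenset("aeiou")

_TOKEN_RE = re.compile(r"^[a-z]([a-z-]*[a-z])?$")

# Characters dropped silently during transliteration (word separators and
# typographic marks that carry no letter content).
_DROPPED = set(" \t '’ʼ.·")


def _load_fold_table() -> dict[str, str]:
    table: dict[str, str] = {}
    path = resources.files("virnomina.data").joinpath("fold_table.csv")
    with path.open(encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            table[row["character"]] = row["replacement"]
    return table


_FOLDS = _load_fold_table()


@dataclass(frozen=True)
class LatinizedToken:
    """A lowercase ISO-basic-Latin string, the unit all rules operate on.

    Parameters
    ----------
    text
        Lowercase letters a–z with optional internal hyphens. No digits, no
        diacritics, no leading or trailing hyphen.
    first_upper
        Render with a capitalized first letter (used for genus names).
    """

    text: str
    first_upper: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not _TOKEN_RE.match(self.text):
            raise InvalidTokenError(
                f"{self.text!r} is not a valid Latinized token "
                "(expected lowercase a-z with optional internal hyphens)"
            )

    def render(self) -> str:
        if self.first_upper:
            return self.text[0].upper() + self.text[1:]
        return self.text

    def __str__(self) -> str:
        return self.text

    def __len__(self) -> int:
        return len(self.text)


def _coerce(token: "LatinizedToken | str") -> str:
    if isinstance(token, LatinizedToken):
        return token.text
    # validate strings passed directly
    return LatinizedToken(token).text


def transliterate(raw: str, keep_hyphens: bool = False) -> LatinizedToken:
    """Fold arbitrary Unicode text to a lowercase Latinized token.

    Diacritics are stripped by canonical decomposition (ü→u, é→e, ñ→n);
    a small fold table handles letters without a decomposition (ß→ss, æ→ae,
    œ→oe, ø→o, ...). Spaces, apostrophes and periods are removed; hyphens are
    removed unless ``keep_hyphens`` is set.

    Raises
    ------
    UnmappableCharacterError
        For characters with no fold to a–z (Greek, CJK, digits, ...). They
        are never silently dropped.
    EmptyInputError-like ValueError
        If the input is empty after whitespace trimming.
    """
    raw = raw.strip()
    if not raw:
        raise InvalidTokenError("cannot transliterate an empty string")
    out: list[str] = []
    for char in raw:
        lower = char.lower()
        if lower in _DROPPED:
            continue
        if char in _FOLDS or lower in _FOLDS:
            out.append(_FOLDS.get(char, _FOLDS.get(lower, "")))
            continue
        if lower in ("-", "‐", "‑", "–", "—"):
            if keep_hyphens:
                out.append("-")
            continue
        if "a" <= lower <= "z":
            out.append(lower)
            continue
        # strip combining marks from the decomposition
        decomposed = unicodedata.normalize("NFKD", lower)
        base = "".join(c for c in decomposed if not unicodedata.combining(c))
        if base and all("a" <= c <= "z" for c in base):
            out.append(base)
            continue
        raise UnmappableCharacterError(char, raw)
    text = "".join(out).strip("-")
    # collapse hyphen runs that arise from dropped neighbours
    text = re.sub(r"-{2,}", "-", text)
    if not text:
        raise InvalidTokenError(f"{raw!r} transliterates to an empty token")
    return LatinizedToken(text)


def count_vowels(token: "LatinizedToken | str") -> int:
    """Number of vowels ({a,e,i,o,u}) in the token; hyphens count as neither."""
    return sum(1 for c in _coerce(token) if c in VOWELS)


def count_consonants(token: "LatinizedToken | str") -> int:
    """Number of consonant letters in the token (letters that are not vowels)."""
    return sum(1 for c in _coerce(token) if c != "-" and c not in VOWELS)


def join_with_elision(
    stem: "LatinizedToken | str", suffix: "LatinizedToken | str"
) -> LatinizedToken:
    """Concatenate stem and suffix, eliding one copy of a repeated junction vowel.

    The repeated letter is dropped only when the stem's final letter equals
    the suffix's first letter AND that letter is a vowel: zaire + ense →
    zairense, but atlanta + ense → atlantaense (non-identical junction vowels
    are retained).
    """
    s, suf = _coerce(stem), _coerce(suffix)
    if s[-1] == suf[0] and s[-1] in VOWELS:
        return LatinizedToken(s + suf[1:])
    return LatinizedToken(s + suf)
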