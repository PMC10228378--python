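"""Exception hierarchy for the nomenclature engine.

Every rule failure raises a subclass of :class:`VirnominaError`, so callers
(notably the CLI) can distinguish rule violations from programming errors.
"""


class VirnominaError(Exception):
    """Base class for all nomenclature-rule errors."""


class UnmappableCharacterError(VirnominaError):
    """A character has no fold to the ISO basic Latin alphabet."""

    def __init__(self, char: str, source: str):
        self.char = char
        self.source = source
        super().__init__(
            f"character {char!r} (U+{ord(char):04X}) in {source!r} has no "
            "fold to the ISO basic Latin alphabet"
        )


class InvalidTokenError(VirnominaError):
    """A string violates the Latinized-token charset invariant."""


class NoMatchingSuffixError(VirnominaError):
    """No rule of a suffix table matches the end of the input word."""

    def __init__(self, word: str, table_name: str):
        self.word = word
        self.table_name = table_name
        super().__init__(
            f"no suffix rule in table {table_name!r} matches {word!r}; "
            "extend the table or use another naming route"
        )


class NotAeSuffixedError(VirnominaError):
    """A suprageneric host taxon does not carry the unambiguous -ae ending."""


class NoVowelError(VirnominaError):
    """Stem shaping removed every character (the term had no usable vowel)."""


class StructuralError(VirnominaError):
    """A digit-interleaved string does not alternate digit,letter,..."""


class EmptyInputError(VirnominaError):
    """An operation requires a non-empty input list or string."""


class DemandExceedsPoolError(VirnominaError):
    """A genus requests more distinct epithets than the pool holds."""

    def __init__(self, genus: str, requested: int, pool: int):
        self.genus = genus
        super().__init__(
            f"genus {genus!r} requests {requested} distinct epithets but the "
            f"pool holds only {pool}"
        )


class DuplicateBinomialError(VirnominaError):
    """Assembling binomials produced the same rendered name twice."""

    def __init__(self, name: str):
        self.name = name
        super().__init__(f"duplicate binomial {name!r}")
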