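"""Exception hierarchy shared across the package."""


class MetoriginError(Exception):
    """Base class for all package errors."""


class KeggParseError(MetoriginError):
    """A KEGG flat-file block could not be parsed (names the record index)."""


class EquationParseError(KeggParseError):
    """A reaction EQUATION string violated the expected grammar."""


class UnknownIdError(MetoriginError, KeyError):
    """Lookup of an identifier not present in the database."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message plain
        return Exception.__str__(self)


class DomainError(MetoriginError, ValueError):
    """A numeric argument violated a stated constraint."""


class ConfigError(MetoriginError):
    """Invalid run configuration (duplicate labels, empty universe, ...)."""


class FetchError(MetoriginError):
    """A network fetch failed after exhausting retries."""
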