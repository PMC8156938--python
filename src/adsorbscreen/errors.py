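"""Exception hierarchy shared across the package.

Every error raised on user input derives from :class:`AdsorbScreenError`,
so pipeline drivers can fail soft per complex without catching ``Exception``.
"""


class AdsorbScreenError(Exception):
    """Base class for all package-specific errors."""


class ParseError(AdsorbScreenError):
    """A text input could not be parsed (carries a line reference)."""


class SchemaError(AdsorbScreenError):
    """A record is missing a mandatory field."""


class ValidationError(AdsorbScreenError):
    """A parsed value violates a domain invariant (e.g. HOMO >= LUMO)."""


class ParameterError(AdsorbScreenError):
    """Force-field parameters (charge, sigma, epsilon) are missing."""


class DegenerateGeometryError(AdsorbScreenError):
    """An atom pair sits below the clash floor; the pair is named."""


class MissingInputError(AdsorbScreenError):
    """An energy component required by an identity is absent (never imputed)."""


class InconsistencyError(AdsorbScreenError):
    """Two redundant input routes disagree beyond tolerance."""


class DegeneracyError(AdsorbScreenError):
    """A formula denominator vanishes (equal hardness, equal orbital energies)."""


class DomainError(AdsorbScreenError):
    """An input is outside the domain where the quantity is defined."""


class GenerationError(AdsorbScreenError):
    """A synthetic fixture could not be constructed under its constraints."""


class PackagingError(AdsorbScreenError):
    """A packaged reference table failed its checksum."""
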