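"""Exception hierarchy for droplet digital PCR analysis."""


class DropgateError(Exception):
    """Base class for all package errors."""


class RegistryError(DropgateError):
    """Unknown assay type, cycle in the inheritance chain, or duplicate registration."""


class InputError(DropgateError):
    """Unusable input data (no parsable amplitude files, empty directory, ...)."""


class SelectionError(DropgateError):
    """A well selector matched nothing or named an absent well."""


class ParseError(DropgateError):
    """A CSV cell or filename could not be parsed."""


class SchemaError(DropgateError):
    """A metadata table is missing a required column."""


class AmbiguityError(DropgateError):
    """A bundle directory mixes more than one amplitude-file prefix."""


class VersionError(DropgateError):
    """A saved plate archive is newer than this package supports."""


class InsufficientDataError(DropgateError):
    """Too few droplets for a density estimate."""


class DegenerateFitError(DropgateError):
    """Zero-variance input to the mixture fit."""


class SaturationError(DropgateError):
    """All droplets positive: Poisson occupancy is unbounded."""


class InternalContradictionError(DropgateError):
    """A well passed QC but the empty/filled valley vanished downstream."""
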