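"""Exception types shared across the toolkit."""


class EsmacsError(Exception):
    """Base class for all toolkit errors."""


class TableFormatError(EsmacsError, ValueError):
    """Energy table structurally invalid (e.g. a required column is missing)."""


class TableParseError(EsmacsError, ValueError):
    """A cell in an energy table could not be parsed; message carries the line number."""


class DuplicateRecordError(EsmacsError, ValueError):
    """Two records share the same (ligand, kind, source, replica, frame) key."""


class ProtocolInputError(EsmacsError, ValueError):
    """The ensemble table lacks a data source the requested protocol needs."""


class UndefinedStatisticError(EsmacsError, ValueError):
    """A ranking statistic is undefined for the given data (e.g. zero variance)."""


class RadiusLookupError(EsmacsError, KeyError):
    """No radius available for an atom's type or element."""


class WeightLookupError(EsmacsError, KeyError):
    """No WSAS weight available for an atom type."""


class ConfigurationError(EsmacsError, ValueError):
    """A configuration object is incomplete (e.g. missing unit declaration)."""
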