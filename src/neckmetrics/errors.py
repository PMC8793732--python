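"""Exception hierarchy for neckmetrics."""


class NeckmetricsError(Exception):
    """Base class for all package errors."""


class ValidationError(NeckmetricsError):
    """A measurement, series or parameter set violates its invariants."""


class FixtureLookupError(NeckmetricsError, KeyError):
    """An unknown bundled-fixture name was requested."""


class InsufficientDataError(NeckmetricsError):
    """A series is too short for the requested computation (need >= 2)."""


class SerialGapError(NeckmetricsError):
    """A series has missing serial positions under the strict gap policy."""
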