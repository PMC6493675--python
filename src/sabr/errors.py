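"""Exception hierarchy for the sabr pipeline."""


class SabrError(Exception):
    """Base class for all sabr errors."""


class InvalidParameterError(SabrError, ValueError):
    """A parameter or specification violates its documented invariants."""


class MissingPolarityError(SabrError, ValueError):
    """An operation requiring both stimulus polarities found only one."""


class AllEpochsRejectedError(SabrError, RuntimeError):
    """Artifact rejection removed every epoch."""


class DegenerateInputError(SabrError, ValueError):
    """Input is degenerate for the requested statistic (e.g. zero variance)."""


class CorruptArchiveError(SabrError, IOError):
    """Epoch archive payload does not match its sidecar metadata."""
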