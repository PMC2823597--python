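"""Exception hierarchy shared across the pipeline."""


class MirnaPrepError(ValueError):
    """Base class for all package errors."""


class FormatError(MirnaPrepError):
    """A file does not conform to the expected AFE dialect."""


class IntegrityError(MirnaPrepError):
    """Internally inconsistent data (duplicates, missing probes, NaNs)."""


class DesignConflictError(MirnaPrepError):
    """Arrays in one experiment disagree on the probe/gene layout."""


class EstimationError(MirnaPrepError):
    """A statistical estimate cannot be formed from the data given."""
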