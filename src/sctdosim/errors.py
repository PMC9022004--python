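"""Exception hierarchy for the sctdosim pipeline."""


class SctDosimError(Exception):
    """Base class for all errors raised by sctdosim."""


class HeaderError(SctDosimError):
    """A volume file header is missing or carries invalid geometry."""


class VolumeFormatError(SctDosimError):
    """A file could not be parsed as a supported volume format."""


class UsageError(SctDosimError):
    """An operation was called with arguments that violate its contract."""


class ConfigError(SctDosimError):
    """A configuration object (curve, table, plan, study) is invalid."""


class PhantomSpecError(SctDosimError):
    """A phantom specification places a primitive outside the grid or is
    otherwise unbuildable."""


class InputError(SctDosimError):
    """Input data violate a precondition (e.g. empty body mask)."""


class DegenerateSampleError(SctDosimError):
    """A paired sample admits no test statistic (all differences zero)."""
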