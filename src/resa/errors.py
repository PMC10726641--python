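"""Exception hierarchy for the resa package."""


class ResaError(Exception):
    """Base class for all resa-specific errors."""


class ConfigError(ResaError):
    """Invalid or inconsistent configuration."""


class VcfFormatError(ResaError):
    """A VCF/TSV input lacks a required field or contains a malformed row."""


class ReferenceMismatchError(ResaError):
    """The reference base at a variant position disagrees with the call."""


class ConsistencyError(ResaError):
    """Internally inconsistent data (e.g. more carriers than cells)."""


class ModelingError(ResaError):
    """The classifier cannot be trained or applied as requested."""
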