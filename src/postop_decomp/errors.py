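"""Exception hierarchy shared across the pipeline."""


class PostopDecompError(Exception):
    """Base class for all package errors."""


class ArgumentError(PostopDecompError, ValueError):
    """A caller supplied an argument outside the documented domain."""


class ConfigError(PostopDecompError, ValueError):
    """A configuration value is internally inconsistent (e.g. band vs. fs)."""


class DataError(PostopDecompError, ValueError):
    """Input data violate a precondition (non-finite samples, short records, ...)."""


class IncompleteSignal(PostopDecompError):
    """A window could not be analysed (e.g. too few R-peaks).

    Raising this marks the subject for exclusion: subjects without complete
    signals in every channel/window are dropped from cohorts rather than
    imputed.
    """


class SubjectExcluded(PostopDecompError):
    """Subject-level exclusion signal (missing channel or incomplete window)."""
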