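"""Exception and warning types shared across the pipeline."""


class EEGEntropyError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(EEGEntropyError, ValueError):
    """An argument is outside its documented domain."""


class DegenerateInputError(EEGEntropyError, ValueError):
    """The input series is degenerate for the requested estimator
    (e.g. all-zero for SVDEn, monotone for AttnEn)."""


class ShortageError(EEGEntropyError, ValueError):
    """A record does not contain enough usable samples for the requested
    segmentation; the message names the deficit."""


class AssemblyError(EEGEntropyError, ValueError):
    """Feature-matrix assembly hit a missing/undefined value; the message
    names the offending (segment, channel, variant)."""


class ProtocolError(EEGEntropyError, ValueError):
    """The cross-validation protocol cannot be honoured on these data
    (e.g. fewer samples per class than folds)."""


class UndefinedEntropyWarning(UserWarning):
    """An entropy value is undefined on this input (e.g. SampEn with zero
    template matches); the estimator returns NaN."""
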