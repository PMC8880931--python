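"""Exception types raised across the package.

Every contract violation gets a named error so callers can distinguish
malformed inputs from genuine bugs.
"""


class PCLRError(Exception):
    """Base class for all package-specific errors."""


class InvalidSamplingRateError(PCLRError, ValueError):
    """Sampling rate outside the supported {250, 500} Hz set."""


class MissingLeadError(PCLRError, ValueError):
    """A 12-lead record lacks one of the required leads."""


class NonFiniteSignalError(PCLRError, ValueError):
    """A lead contains NaN or infinite amplitudes."""


class CohortFormatError(PCLRError, ValueError):
    """A stored cohort file is malformed or internally inconsistent."""


class UnfilteredCohortError(PCLRError, ValueError):
    """Pair sampling was asked to run on a cohort containing a
    single-record patient (eligibility filtering was skipped)."""


class PairingError(PCLRError, ValueError):
    """Invalid batch-sampling request or inconsistent pair structure."""


class ArchitectureError(PCLRError, ValueError):
    """Encoder/projection configuration that cannot be built, e.g. an
    input length not divisible through the downsampling chain."""


class ZeroVectorError(PCLRError, ValueError):
    """Cosine similarity requested for a zero vector."""


class TrainingError(PCLRError, RuntimeError):
    """Pre-training or supervised training could not proceed."""


class TrainingDivergedError(TrainingError):
    """A non-finite loss was encountered; carries diagnostics."""


class DegenerateLabelsError(PCLRError, ValueError):
    """Classification labels contain a single class."""


class FeatureTableError(PCLRError, ValueError):
    """Feature-table width/row mismatch in linear evaluation."""


class PipelineConfigError(PCLRError, ValueError):
    """Pipeline configuration failed validation before any compute."""
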