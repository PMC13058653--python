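"""Exception types shared across the pipeline."""


class MindgradError(Exception):
    """Base class for all pipeline errors."""


class DegenerateInputError(MindgradError, ValueError):
    """Input is structurally valid but statistically degenerate
    (zero-variance feature, constant map, all-zero connectivity row)."""


class InsufficientSampleError(MindgradError, ValueError):
    """Too few observations for the requested estimator."""


class IncompleteParcellationError(MindgradError, ValueError):
    """A vertex table does not cover every region of its parcellation."""


class DimensionError(MindgradError, ValueError):
    """Shapes of two pipeline objects do not agree."""


class ConnectivityError(MindgradError, ValueError):
    """Affinity graph is disconnected; a diffusion embedding is undefined."""


class DesignError(MindgradError, ValueError):
    """Regression design matrix is rank deficient or contrast-free."""
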