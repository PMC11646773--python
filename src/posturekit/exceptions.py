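"""Exception and warning types used across posturekit."""


class ParameterError(ValueError):
    """An argument or configuration field is outside its valid range."""


class GenerationError(RuntimeError):
    """Synthetic-data generation hit an infeasible parameter combination."""


class IngestError(ValueError):
    """A trial file does not conform to the documented layout."""


class AlignmentError(ValueError):
    """Two trajectories do not share the same rate / time base."""


class EmptyTrajectoryError(ValueError):
    """No sample of a trial carries enough vertical load to define a COP."""


class MetricError(ValueError):
    """A target-error metric cannot be computed from the given samples."""


class NoLandingError(ValueError):
    """No sustained force-plate contact found when searching for a landing."""


class DesignError(ValueError):
    """A model design cannot be built from the supplied outcome table."""


class FitConvergenceError(RuntimeError):
    """A mixed-model fit failed to converge; message carries diagnostics."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; message names the stage."""


class OutlierCapWarning(UserWarning):
    """The outlier screen removed more than the configured fraction of data."""
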