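"""Exception hierarchy for the timegen pipeline.

Every stage raises a subclass of :class:`TimegenError` so the CLI can map
failures to a non-zero exit with a stage-tagged message.
"""


class TimegenError(Exception):
    """Base class for all timegen errors."""


class InvalidDesignError(TimegenError, ValueError):
    """Experiment-design parameters are inconsistent (e.g. even ladder size)."""


class InvalidInputError(TimegenError, ValueError):
    """A value outside an operation's domain (non-positive duration, bad alpha...)."""


class InvalidSpecError(TimegenError, ValueError):
    """A cohort or power specification is degenerate."""


class FitFailureError(TimegenError, RuntimeError):
    """The bounded multi-start optimizer failed to converge from every start."""


class IncompleteCurveError(TimegenError, ValueError):
    """A generalization curve is missing trials for one or more ladder durations."""

    def __init__(self, missing_durations):
        self.missing_durations = list(missing_durations)
        super().__init__(
            "no trials for duration level(s): "
            + ", ".join(f"{d:g}" for d in self.missing_durations)
        )


class DegenerateDataError(TimegenError, ValueError):
    """Zero-variance or otherwise degenerate data handed to a statistical test."""
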