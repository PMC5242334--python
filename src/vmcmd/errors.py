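"""Exception hierarchy for the vmcmd package."""


class VmcmdError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(VmcmdError, ValueError):
    """A parameter violates its documented precondition."""


class IncompatibleModelError(VmcmdError, ValueError):
    """Two potential models cannot be combined (e.g. dimension mismatch)."""


class InvalidSelectionError(VmcmdError, ValueError):
    """A site selection is empty or refers to nonexistent sites."""


class InvalidStateError(VmcmdError, ValueError):
    """A virtual-state index is outside the ladder."""


class InvalidStartError(VmcmdError, ValueError):
    """A start conformation is inconsistent with the requested run."""


class IntegrationFailureError(VmcmdError, RuntimeError):
    """The trajectory diverged (non-finite energy or force)."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"non-finite energy/force at step {step}")


class CoverageGapError(VmcmdError, RuntimeError):
    """Adjacent energy histograms do not overlap; names the gap interval."""

    def __init__(self, gap: tuple[float, float] | None = None, message: str | None = None):
        self.gap = gap
        if message is None:
            if gap is not None:
                message = f"energy histograms leave a coverage gap in [{gap[0]:g}, {gap[1]:g}] kcal/mol"
            else:
                message = "energy histograms do not overlap"
        super().__init__(message)


class InsufficientSamplingError(VmcmdError, RuntimeError):
    """A histogram-based operation lacks counts; lists the empty bins."""

    def __init__(self, empty_bins=None, message: str | None = None):
        self.empty_bins = list(empty_bins) if empty_bins is not None else []
        if message is None:
            message = f"insufficient sampling: {len(self.empty_bins)} empty bins"
        super().__init__(message)


class DegenerateInputError(VmcmdError, ValueError):
    """Input has too little variation for the requested statistic."""


class TemperatureRangeError(VmcmdError, ValueError):
    """Requested temperature lies outside the multicanonical design range."""


class FormatError(VmcmdError, ValueError):
    """A serialized file is malformed; names the first bad record."""


class ConfigError(VmcmdError, ValueError):
    """A run configuration is invalid; names the offending key."""
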