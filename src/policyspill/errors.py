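"""Exception types shared across the pipeline."""


class PolicySpillError(Exception):
    """Base class for all package errors."""


class ConfigError(PolicySpillError):
    """Invalid simulation or pipeline configuration."""


class ConsistencyError(PolicySpillError):
    """Inputs that should describe the same counties/states/dates do not."""


class SchemaError(PolicySpillError):
    """A table is missing columns or contains unparseable/invalid values."""


class RankDeficiencyError(PolicySpillError):
    """Design matrix is rank deficient after fixed-effect absorption."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"collinear design columns after demeaning: {self.columns}")


class ConvergenceError(PolicySpillError):
    """Alternating-projection demeaning failed to converge."""

    def __init__(self, trace):
        self.trace = list(trace)
        super().__init__(
            f"two-way demeaning did not converge in {len(self.trace)} sweeps; "
            f"last max change {self.trace[-1]:.3e}"
        )
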