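"""Exception hierarchy shared across the package."""


class SwarmcastError(Exception):
    """Base class for all package errors."""


class PanelValidationError(SwarmcastError):
    """A panel violates a structural invariant (negative value, bad years...)."""


class IncompletePanelError(PanelValidationError):
    """One or more (year, stratum) cells are missing from a long-format table."""

    def __init__(self, missing):
        self.missing = list(missing)
        shown = ", ".join(f"{y}/{sex}/{age}" for y, sex, age in self.missing[:10])
        more = "" if len(self.missing) <= 10 else f" (+{len(self.missing) - 10} more)"
        super().__init__(f"incomplete panel: missing cells {shown}{more}")


class DuplicateRecordError(PanelValidationError):
    """The same (year, sex, age_group) cell appears more than once."""


class ZeroVarianceError(SwarmcastError):
    """A stratum is constant over the normalization fit range."""


class StratumMismatchError(SwarmcastError):
    """Normalization params and panel disagree on the stratum set/order."""


class SeriesTooShortError(SwarmcastError):
    """Panel has fewer years than a window + horizon requires."""


class TrainingDivergedError(SwarmcastError):
    """Loss became non-finite during training."""

    def __init__(self, epoch):
        self.epoch = epoch
        super().__init__(f"training diverged: non-finite loss at epoch {epoch}")


class ConfigError(SwarmcastError):
    """Invalid user-supplied configuration."""
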