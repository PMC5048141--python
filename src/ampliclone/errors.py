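"""Exception hierarchy for the ampliclone pipeline."""


class AmplicloneError(Exception):
    """Base class for all pipeline errors."""


class PanelError(AmplicloneError):
    """Invalid amplicon panel, MID set or manifest."""


class SimulationError(AmplicloneError):
    """Invalid simulation specification."""


class CalibrationError(AmplicloneError):
    """Replicate calibration cannot be performed or yields no usable threshold."""


class StatsError(AmplicloneError):
    """Invalid contingency table or infeasible exact test."""


class ConfigError(AmplicloneError):
    """Invalid run configuration."""
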