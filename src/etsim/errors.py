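"""Exception hierarchy for etsim."""


class EtsimError(Exception):
    """Base class for all etsim errors."""


class ConfigurationError(EtsimError):
    """Invalid parameter file, scenario, or solver configuration."""


class NumericalError(EtsimError):
    """Integration produced a non-finite or impossibly negative state."""


class FitError(EtsimError):
    """A calibration routine failed to produce any converged estimate."""


class PresetError(KeyError, EtsimError):
    """Unknown scenario preset name."""
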