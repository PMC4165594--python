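"""Exception hierarchy for the lipidmr pipeline."""


class LipidMRError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(LipidMRError):
    """A simulation or run configuration is internally inconsistent."""


class ValidationError(LipidMRError):
    """Input data violate a precondition (units, signs, shapes)."""


class SamplingError(LipidMRError):
    """Case-control rejection sampling could not reach the requested counts."""


class WeakInstrumentError(LipidMRError):
    """First-stage coefficient too close to zero for a ratio estimate."""


class ConvergenceError(LipidMRError):
    """A regression fit failed (e.g. perfect separation in the logistic model)."""
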