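"""Exception hierarchy for model construction, sensing and filtering."""


class CRNObserverError(Exception):
    """Base class for all package errors."""


class ModelError(CRNObserverError):
    """Invalid reaction network: bad propensity, stoichiometry or cap."""


class StateSpaceSizeError(ModelError):
    """Truncated state space would exceed the configured hard limit."""


class SchemaError(CRNObserverError):
    """Malformed configuration file (model, sensor, observations, lineage)."""


class SensorError(CRNObserverError):
    """Observation model misuse (unknown symbol, unsupported kind)."""


class ZeroLikelihoodError(CRNObserverError):
    """An observation (or output jump) has probability zero under the model.

    For a single model this signals misfit between data, sensor and prior.
    During composed multi-model filtering a per-block zero is *not* an error:
    the block is zeroed and the remaining models renormalized.
    """

    def __init__(self, message, index=None, time=None):
        super().__init__(message)
        self.index = index
        self.time = time


class IdentifiabilityError(CRNObserverError):
    """The truncated chain has no unique stationary distribution."""
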