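"""Exception hierarchy for the effectome package."""


class EffectomeError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(EffectomeError):
    """A configuration problem: missing column, bad mapping, unknown key."""


class DataError(EffectomeError):
    """Malformed input data (for example an unparseable synapse count)."""


class IntegrityError(EffectomeError):
    """Persisted artifacts disagree with each other (matrix vs. sidecar)."""


class StabilityError(EffectomeError):
    """A dynamics matrix is unstable for the requested simulation."""


class RankError(EffectomeError):
    """A design or covariance matrix is rank deficient beyond tolerance."""


class SolverError(EffectomeError):
    """An iterative solver failed to converge to the requested tolerance."""


class DefectiveMatrixError(EffectomeError):
    """A matrix is too close to non-diagonalizable for eigen-based methods."""
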