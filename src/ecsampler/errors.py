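"""Exception hierarchy for ecsampler.

Every module raises subclasses of :class:`ECSamplerError` so callers can
catch toolkit failures with a single except clause while still being able
to distinguish input-format problems from numerical ones.
"""


class ECSamplerError(Exception):
    """Base class for all ecsampler errors."""


class FormatError(ECSamplerError):
    """A file or table could not be parsed; the message names the location."""


class EmptyInputError(ECSamplerError):
    """An input that must be non-empty (table, structure, cluster) was empty."""


class PairingError(ECSamplerError):
    """Two per-pair vectors disagree in length or ordering."""


class DomainError(ECSamplerError):
    """A numeric argument lies outside its mathematical domain."""


class MappingError(ECSamplerError):
    """A residue referenced by a coupling pair cannot be resolved in a structure."""


class SelectionError(ECSamplerError):
    """An atom selection produced mismatched or empty atom lists."""


class FeaturizationError(ECSamplerError):
    """A featurization scheme could not be applied (missing atoms, degenerate basis)."""


class LagError(ECSamplerError):
    """The requested lag time is invalid for the given trajectories."""


class CardinalityError(ECSamplerError):
    """More clusters requested than data points available."""


class ConnectivityError(ECSamplerError):
    """A matrix or network is not connected/irreducible where required."""


class EstimationError(ECSamplerError):
    """An iterative estimator failed to converge; the message reports the residual."""


class MatrixError(ECSamplerError):
    """A transition matrix violates row-stochasticity."""


class InstabilityError(ECSamplerError):
    """An integrator diverged; usually cured by a smaller timestep."""


class DegenerateInputError(ECSamplerError):
    """A degenerate configuration (e.g. start state inside the stop set)."""
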