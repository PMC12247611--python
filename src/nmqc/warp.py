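"""Sinh-arcsinh likelihood warping.

A monotone map from the observation scale of a phenotype to a latent scale
on which residuals are (approximately) Gaussian.  The family is the
sinh-arcsinh transform of Jones & Pewsey composed with an affine
pre-standardization:

    phi(y) = sinh( delta * asinh((y - a0) / b0) - epsilon )

``epsilon`` controls skew (positive epsilon pushes mass to the left on the
latent scale), ``delta`` controls tail weight (delta < 1 heavier than
Gaussian, delta > 1 lighter), and ``(a0, b0)`` center and scale the input.
With ``epsilon = 0, delta = 1, a0 = 0, b0 = 1`` the map is the identity, so
a Gaussian model is nested exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["WarpParams", "warp_forward", "warp_inverse", "warp_log_derivative"]

_LOG2 = float(np.log(2.0))


@dataclass(frozen=True)
class WarpParams:
    """Parameters of the sinh-arcsinh warp.

    Attributes
    ----------
    a0, b0 : float
        Affine pre-standardization: location and (positive) scale.
    epsilon : float
        Skew parameter; 0 means symmetric.
    delta : float
        Tail-weight parameter; must be positive, 1 means Gaussian tails.
    """

    a0: float = 0.0
    b0: float = 1.0
    epsilon: float = 0.0
    delta: float = 1.0

    def __post_init__(self) -> None:
        if not self.b0 > 0:
            raise ValueError(f"b0 must be positive, got {self.b0}")
        if not self.delta > 0:
            raise ValueError(f"delta must be positive, got {self.delta}")

    @property
    def is_identity(self) -> bool:
        return (
            self.a0 == 0.0
            and self.b0 == 1.0
            and self.epsilon == 0.0
            and self.delta == 1.0
        )


def warp_forward(y, w: WarpParams):
    """phi(y): observation scale -> latent (Gaussianized) scale."""
    u = (np.asarray(y, dtype=float) - w.a0) / w.b0
    return np.sinh(w.delta * np.arcsinh(u) - w.epsilon)


def warp_inverse(t, w: WarpParams):
    """Exact analytic inverse of :func:`warp_forward`."""
    t = np.asarray(t, dtype=float)
    return w.a0 + w.b0 * np.sinh((np.arcsinh(t) + w.epsilon) / w.delta)


def _log_cosh(x):
    # stable log(cosh(x)) for large |x|
    ax = np.abs(x)
    return ax + np.log1p(np.exp(-2.0 * ax)) - _LOG2


def warp_log_derivative(y, w: WarpParams):
    """log d(phi)/dy, the Jacobian term of the warped likelihood.

    d(phi)/dy = delta * cosh(delta * asinh(u) - epsilon) / (b0 * sqrt(1+u^2))
    with u = (y - a0)/b0; always positive, so phi is strictly increasing.
    """
    u = (np.asarray(y, dtype=float) - w.a0) / w.b0
    arg = w.delta * np.arcsinh(u) - w.epsilon
    return (
        np.log(w.delta)
        - np.log(w.b0)
        + _log_cosh(arg)
        - 0.5 * np.log1p(u * u)
    )
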