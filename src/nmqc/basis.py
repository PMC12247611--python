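"""Cubic B-spline basis over age with evenly spaced knots.

The covariate model is a clamped cubic (order 4) B-spline with five evenly
spaced knots spanning the training age range.  The clamped boundary knots
repeat the endpoints, which gives 7 basis functions that form a partition
of unity on the training domain, so no separate intercept column is needed.
Test ages outside the training range are clamped to the nearest boundary
(with a warning) rather than extrapolated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

logger = logging.getLogger(__name__)

__all__ = ["BSplineBasis", "build_basis"]


@dataclass(frozen=True)
class BSplineBasis:
    """A clamped cubic B-spline basis on a fixed age domain.

    Attributes
    ----------
    knots : tuple of float
        The evenly spaced knots (endpoints included).
    order : int
        Spline order (degree + 1); 4 for cubic.
    """

    knots: tuple
    order: int = 4

    full_knots: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        knots = np.asarray(self.knots, dtype=float)
        if knots.size < 2:
            raise ValueError("need at least 2 knots")
        deg = self.order - 1
        full = np.concatenate(
            [np.repeat(knots[0], deg), knots, np.repeat(knots[-1], deg)]
        )
        object.__setattr__(self, "full_knots", full)

    @property
    def domain(self) -> tuple:
        return (self.knots[0], self.knots[-1])

    @property
    def n_functions(self) -> int:
        """Number of basis functions M = len(full_knots) - order."""
        return len(self.full_knots) - self.order

    def design_matrix(self, x) -> np.ndarray:
        """Evaluate all basis functions at ``x`` (n x M matrix).

        Values outside the domain are clamped to the boundary, matching the
        policy of holding the normative curve flat beyond the observed ages.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        lo, hi = self.domain
        if np.any((x < lo) | (x > hi)):
            logger.warning(
                "ages outside training domain [%g, %g] clamped to boundary",
                lo,
                hi,
            )
            x = np.clip(x, lo, hi)
        dm = BSpline.design_matrix(
            x, self.full_knots, self.order - 1, extrapolate=False
        )
        return dm.toarray()

    def to_dict(self) -> dict:
        return {"knots": [float(k) for k in self.knots], "order": self.order}

    @classmethod
    def from_dict(cls, d: dict) -> "BSplineBasis":
        return cls(knots=tuple(d["knots"]), order=int(d["order"]))


def build_basis(ages, n_knots: int = 5, order: int = 4) -> BSplineBasis:
    """Build the basis from training ages: ``n_knots`` evenly spaced knots
    on [min(age), max(age)].

    Raises
    ------
    ValueError
        If fewer than two distinct ages are supplied.
    """
    ages = np.asarray(ages, dtype=float)
    lo, hi = float(np.min(ages)), float(np.max(ages))
    if not hi > lo:
        raise ValueError("ages must contain at least 2 distinct values")
    knots = np.linspace(lo, hi, n_knots)
    return BSplineBasis(knots=tuple(knots), order=order)
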