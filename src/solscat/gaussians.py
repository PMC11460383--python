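"""Closed algebra of Gaussian sums in momentum transfer.

A :class:`GaussianSum` represents a function of the momentum transfer q of
the form ``f(q) = sum_l c_l * exp(-d_l * q**2)`` with ``d_l >= 0`` in units
of Å².  Atomic form factors, dummy-atom (excluded solvent) factors and their
combinations are all of this shape, and the shape is closed under addition
and multiplication.  The product rule is what makes the pair distance
distribution function of the Debye sum analytically integrable: every product
of two form factors is again a short Gaussian sum, and each Gaussian term has
a closed-form inverse sine transform (see :mod:`solscat.debye`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GaussianSum", "gaussian_sum_product"]


@dataclass(frozen=True)
class GaussianSum:
    """Sum of Gaussians in q: ``sum_l c[l] * exp(-d[l] * q**2)``.

    Parameters
    ----------
    c : amplitudes (electrons, or electrons² for products).
    d : exponents in Å² (multiply q² directly; all must be >= 0).
    """

    c: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        c = np.atleast_1d(np.asarray(self.c, dtype=float))
        d = np.atleast_1d(np.asarray(self.d, dtype=float))
        if c.shape != d.shape or c.ndim != 1:
            raise ValueError("c and d must be 1-D arrays of equal length")
        if c.size == 0:
            raise ValueError("empty Gaussian sum")
        if np.any(d < 0):
            raise ValueError("Gaussian exponents must be non-negative")
        object.__setattr__(self, "c", c)
        object.__setattr__(self, "d", d)

    @property
    def n_terms(self) -> int:
        return self.c.size

    def __call__(self, q) -> np.ndarray:
        """Evaluate at momentum transfer q (Å⁻¹, scalar or array)."""
        q = np.asarray(q, dtype=float)
        q2 = np.square(q)
        return np.exp(-np.multiply.outer(q2, self.d)) @ self.c

    def at_zero(self) -> float:
        """Value at q = 0, i.e. the total amplitude ``sum(c)``."""
        return float(self.c.sum())

    def __add__(self, other: "GaussianSum") -> "GaussianSum":
        return GaussianSum(np.concatenate([self.c, other.c]),
                           np.concatenate([self.d, other.d]))

    def __neg__(self) -> "GaussianSum":
        return GaussianSum(-self.c, self.d)

    def __sub__(self, other: "GaussianSum") -> "GaussianSum":
        return self + (-other)

    def __mul__(self, other: "GaussianSum") -> "GaussianSum":
        return gaussian_sum_product(self, other)


def gaussian_sum_product(a: GaussianSum, b: GaussianSum) -> GaussianSum:
    """Pointwise product of two Gaussian sums, again as a Gaussian sum.

    ``(c_a e^{-d_a q²}) (c_b e^{-d_b q²}) = c_a c_b e^{-(d_a+d_b) q²}``
    applied to every cross pair, so a product of sums with m and n terms has
    exactly m·n terms.
    """
    c = np.multiply.outer(a.c, b.c).ravel()
    d = np.add.outer(a.d, b.d).ravel()
    return GaussianSum(c, d)
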