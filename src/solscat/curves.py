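"""Sampled PDDF and scattering-intensity curves plus their plain-text forms.

A PDDF is stored as a density ``p(r)`` on a uniform r grid starting at 0
(bin centres for histogram methods), with the zero-distance self-pair mass
kept separately in ``self_mass`` so that both the area identity

    area = sum(p) * dr + self_mass = (sum ΔZ)²

and the constant offset it contributes to I(q) are exact.  Intensities are
in effective-electron² units on a q grid in Å⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["PDDFCurve", "XSCurve", "sinc", "default_q_grid", "default_r_grid"]


def sinc(x: np.ndarray) -> np.ndarray:
    """sin(x)/x with sinc(0) = 1 (the orientational-average kernel)."""
    return np.sinc(np.asarray(x) / np.pi)


def default_q_grid(q_max: float = 3.0, n_q: int = 300) -> np.ndarray:
    """Default scattering grid: n_q points on (0, q_max], plus q=0 sits fine."""
    return np.linspace(0.0, q_max, n_q)


def default_r_grid(r_max: float, dr: float = 0.5) -> np.ndarray:
    """Uniform distance grid from 0 covering r_max (default Δr = 0.5 Å)."""
    n = int(np.ceil(r_max / dr)) + 1
    return np.arange(n) * dr


def _check_uniform(r: np.ndarray) -> float:
    r = np.asarray(r, dtype=float)
    if r.ndim != 1 or r.size < 2:
        raise ValueError("grid must be 1-D with at least two points")
    if abs(r[0]) > 1e-12:
        raise ValueError("r grid must start at 0")
    dr = r[1] - r[0]
    if dr <= 0 or not np.allclose(np.diff(r), dr, rtol=1e-9, atol=1e-12):
        raise ValueError("r grid must be strictly increasing and uniform")
    return float(dr)


@dataclass
class PDDFCurve:
    """Pair distance distribution function P(r) on a uniform grid."""

    r: np.ndarray
    p: np.ndarray
    method: str = ""                  # PC | DD | DH | partial
    self_mass: float = 0.0            # weight at r = 0 (self pairs), PC/DH
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        self._dr = _check_uniform(self.r)
        if self.p.shape != self.r.shape:
            raise ValueError("p and r must have the same shape")

    @property
    def dr(self) -> float:
        return self._dr

    def area(self) -> float:
        """Total pair weight: rectangle-rule integral plus the self mass."""
        return float(self.p.sum() * self._dr + self.self_mass)

    def scaled(self, factor: float, method: str | None = None) -> "PDDFCurve":
        return replace(self, p=self.p * factor, self_mass=self.self_mass * factor,
                       method=method or self.method)

    def write(self, path) -> None:
        lines = ["# r(A) P(r)", f"# method {self.method}",
                 f"# self_mass {self.self_mass!r}"]
        lines += [f"{r:.6e} {p:.6e}" for r, p in zip(self.r, self.p)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path) -> "PDDFCurve":
        method, self_mass, r, p = "", 0.0, [], []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                f = line[1:].split()
                if f[:1] == ["method"] and len(f) > 1:
                    method = f[1]
                elif f[:1] == ["self_mass"]:
                    self_mass = float(f[1])
                continue
            a, b = line.split()
            r.append(float(a))
            p.append(float(b))
        return cls(np.array(r), np.array(p), method=method, self_mass=self_mass)


@dataclass
class XSCurve:
    """Solution scattering intensity I(q) on a q grid (Å⁻¹)."""

    q: np.ndarray
    i: np.ndarray
    method: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.i = np.asarray(self.i, dtype=float)
        if self.q.shape != self.i.shape or self.q.ndim != 1:
            raise ValueError("q and i must be 1-D arrays of equal length")
        if np.any(self.q < 0):
            raise ValueError("negative q")

    def write(self, path) -> None:
        lines = ["# q(1/A) I(q)", f"# method {self.method}"]
        lines += [f"{q:.6e} {i:.6e}" for q, i in zip(self.q, self.i)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path) -> "XSCurve":
        method, q, i = "", [], []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                f = line[1:].split()
                if f[:1] == ["method"] and len(f) > 1:
                    method = f[1]
                continue
            a, b = line.split()
            q.append(float(a))
            i.append(float(b))
        return cls(np.array(q), np.array(i), method=method)
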