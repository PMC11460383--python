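"""Atomic and atom-group X-ray form factors with excluded-solvent contrast.

Scattering sites are non-hydrogen atoms (or heavy atoms carrying implicit
hydrogens, e.g. CH2).  Each site type has

* a vacuum form factor ``f(q)`` stored as five Gaussians,
* a dummy-atom factor ``g(q) = rho_s * V * exp(-q^2 * V^(2/3) / (4 pi))``
  describing the solvent volume ``V`` it displaces in a solvent of electron
  density ``rho_s`` (e/Å³),

and the combined, contrast-corrected factor is ``A(q) = f(q) - g(q)``, with
``A(0) = Z - rho_s * V``, the site's effective (contrast) electron number.

The shipped coefficient table (``data/atom_groups.json``) can be regenerated
with ``scripts/make_formfactor_table.py`` and extended by the user; its
schema is one entry per group label with fields ``element``, ``n_h``, ``z``,
``volume`` (Å³), ``a`` (5 amplitudes, electrons) and ``b`` (5 exponents, Å²,
multiplying q²).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np

from .gaussians import GaussianSum, gaussian_sum_product

__all__ = [
    "FiveGaussianFF",
    "DummyAtomFF",
    "AtomGroupTable",
    "UnknownGroupError",
    "combined_form_factor",
    "gaussian_sum_product",
    "DEFAULT_SOLVENT_ED",
]

DEFAULT_SOLVENT_ED = 0.334  # e/Å³, pure water


class UnknownGroupError(KeyError):
    """Raised when a group label is not present in the form-factor table."""

    def __init__(self, label: str):
        super().__init__(label)
        self.label = label

    def __str__(self) -> str:
        return f"unknown atom-group label: {self.label!r}"


@dataclass(frozen=True)
class FiveGaussianFF:
    """Vacuum form factor of one site type as five Gaussians in q."""

    label: str
    a: np.ndarray          # amplitudes, electrons
    b: np.ndarray          # exponents, Å² (multiply q²)
    n_electrons: float     # total electrons incl. implicit hydrogens

    def __post_init__(self):
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.shape != (5,) or b.shape != (5,):
            raise ValueError("five amplitudes and five exponents required")
        if np.any(b < 0):
            raise ValueError("form-factor exponents must be non-negative")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    def as_gaussian_sum(self) -> GaussianSum:
        return GaussianSum(self.a, self.b)

    def __call__(self, q) -> np.ndarray:
        return self.as_gaussian_sum()(q)


@dataclass(frozen=True)
class DummyAtomFF:
    """Gaussian dummy-atom factor of the displaced solvent volume."""

    volume: float        # Å³
    solvent_ed: float    # e/Å³

    def __post_init__(self):
        if self.volume <= 0:
            raise ValueError("displaced volume must be positive")
        if self.solvent_ed < 0:
            raise ValueError("solvent electron density must be non-negative")

    @property
    def exponent(self) -> float:
        return self.volume ** (2.0 / 3.0) / (4.0 * np.pi)

    def as_gaussian_sum(self) -> GaussianSum:
        return GaussianSum([self.solvent_ed * self.volume], [self.exponent])

    def __call__(self, q) -> np.ndarray:
        return self.as_gaussian_sum()(q)


@dataclass(frozen=True)
class GroupEntry:
    ff: FiveGaussianFF
    volume: float
    z: float
    element: str
    n_h: int


class AtomGroupTable:
    """Registry of scattering-site types (form factor, volume, electrons).

    The default table covers the frequently occurring biomolecular heavy-atom
    groups (C, CH, CH2, CH3, N, NH, NH2, NH3, O, OH, S, SH, P), explicit
    water, and bare-element/ion fallbacks.
    """

    def __init__(self, entries: dict[str, GroupEntry]):
        self.entries = dict(entries)

    def __contains__(self, label: str) -> bool:
        return label in self.entries

    def __getitem__(self, label: str) -> GroupEntry:
        try:
            return self.entries[label]
        except KeyError:
            raise UnknownGroupError(label) from None

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def labels(self) -> list[str]:
        return list(self.entries)

    @classmethod
    def from_json(cls, path) -> "AtomGroupTable":
        data = json.loads(Path(path).read_text())
        return cls._from_dict(data)

    @classmethod
    def _from_dict(cls, data: dict) -> "AtomGroupTable":
        entries = {}
        for label, g in data["groups"].items():
            ff = FiveGaussianFF(label=label, a=np.array(g["a"]),
                                b=np.array(g["b"]), n_electrons=float(g["z"]))
            entries[label] = GroupEntry(ff=ff, volume=float(g["volume"]),
                                        z=float(g["z"]), element=g["element"],
                                        n_h=int(g["n_h"]))
        return cls(entries)

    @classmethod
    @lru_cache(maxsize=1)
    def default(cls) -> "AtomGroupTable":
        text = resources.files("solscat").joinpath("data/atom_groups.json").read_text()
        return cls._from_dict(json.loads(text))


def combined_form_factor(group: str, solvent_ed: float = DEFAULT_SOLVENT_ED,
                         table: AtomGroupTable | None = None) -> GaussianSum:
    """Contrast form factor ``A(q) = f(q) - g(q)`` as a Gaussian sum.

    ``A(0) = Z - solvent_ed * V``, the group's effective electron number.
    For ``solvent_ed == 0`` (vacuum) the dummy term is omitted and the result
    has five terms; otherwise six (five positive-ish, one negative).
    """
    if solvent_ed < 0:
        raise ValueError("solvent electron density must be non-negative")
    table = table or AtomGroupTable.default()
    entry = table[group]
    f = entry.ff.as_gaussian_sum()
    if solvent_ed == 0:
        return f
    g = DummyAtomFF(volume=entry.volume, solvent_ed=solvent_ed).as_gaussian_sum()
    return f - g
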