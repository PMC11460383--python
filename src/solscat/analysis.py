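"""Dmax diagnostics and PDDF normalization utilities.

The true maximum dimension of an assembly (largest pair distance) is often
carried by only a handful of atom pairs, so a simulated PDDF decays into a
long shallow tail and the visually/experimentally accessible "apparent"
Dmax — the largest r where P(r) still exceeds a small fraction (default
0.1%) of the peak maximum — sits several Å short of the true value.

Normalization: coordinate-based PDDFs are per particle (molar-concentration
scaling in experimental terms).  Dividing by molecular weight reproduces the
per-mass (mass-concentration) scaling that makes curves of differently sized
assemblies artificially comparable and can mislead interpretation; it is
provided for exactly that demonstration.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .curves import PDDFCurve
from .structure import StructureModel, max_pair_distance, molecular_weight

__all__ = ["DmaxReport", "apparent_dmax", "normalize_pddf"]


@dataclass(frozen=True)
class DmaxReport:
    true_dmax: float       # Å, largest pair distance of the structure
    apparent_dmax: float   # Å, threshold crossing of the PDDF
    threshold: float       # fraction of the PDDF peak maximum
    gap: float             # true − apparent, Å
    method: str = ""
    dr: float = 0.0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def apparent_dmax(p: PDDFCurve, true_dmax: float | StructureModel,
                  threshold: float = 0.001) -> DmaxReport:
    """Apparent Dmax: largest grid point with P(r) ≥ threshold·max(P).

    The self mass (zero-distance pairs) is excluded from the peak maximum;
    the crossing is located on the stored grid without interpolation, so the
    result carries the grid's Δr precision.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if isinstance(true_dmax, StructureModel):
        true_dmax = max_pair_distance(true_dmax)
    peak = float(p.p.max())
    if peak <= 0:
        raise ValueError("PDDF has no positive values")
    above = np.nonzero(p.p >= threshold * peak)[0]
    apparent = float(p.r[above[-1]])
    apparent = min(apparent, float(true_dmax))
    return DmaxReport(true_dmax=float(true_dmax), apparent_dmax=apparent,
                      threshold=threshold, gap=float(true_dmax) - apparent,
                      method=p.method, dr=p.dr)


def normalize_pddf(p: PDDFCurve, mode: str = "per_particle",
                   mw: float | None = None) -> PDDFCurve:
    """Return the PDDF in per-particle (identity) or per-mass scaling.

    ``mw`` is the molecular weight in kDa (required for ``per_mass``; use
    :func:`solscat.structure.molecular_weight`).
    """
    if mode == "per_particle":
        return p.scaled(1.0)
    if mode == "per_mass":
        if mw is None or mw <= 0:
            raise ValueError("per_mass normalization requires mw > 0 (kDa)")
        return p.scaled(1.0 / mw)
    raise ValueError(f"mode must be per_particle or per_mass, got {mode!r}")
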