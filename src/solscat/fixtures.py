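"""Synthetic point-set generators with known pair-distance structure.

Every engine is testable without downloaded structures: the generators
produce models whose geometry (exact pair distances, Dmax, subunit
partition) is known by construction —

* ``two_atom``    — the minimal closed-form case;
* ``ladder``      — two rails of regularly spaced rungs (the layered repeat
  of a nucleic-acid duplex), giving an oscillatory PDDF at the rise period;
* ``helix``       — a double helix of point sites;
* ``sphere``      — uniform solid ball (compact globule);
* ``shell``       — hollow spherical shell (virus-capsid-like PDDF);
* ``ring``        — N rigid subunit clusters on a circle (cyclodextrin-like)
  with a ready-made subunit partition for PDDF decomposition.

Coordinates are rounded to 0.001 Å so fixtures round-trip exactly through
PDB files.  All randomness comes from one seeded generator per call.
"""

from __future__ import annotations

import numpy as np

from .formfactors import AtomGroupTable, DEFAULT_SOLVENT_ED
from .structure import StructureModel, assign_atom_types

__all__ = ["make_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = ("two_atom", "ladder", "helix", "sphere", "shell", "ring")


def _model(points: np.ndarray, labels, solvent_ed: float,
           res_seqs=None) -> StructureModel:
    n = points.shape[0]
    labels = np.asarray(labels if not isinstance(labels, str)
                        else [labels] * n)
    table = AtomGroupTable.default()
    elements = np.array([table[str(l)].element.upper() for l in labels])
    m = StructureModel(
        positions=np.round(points, 3),
        group_labels=labels,
        type_index=np.zeros(n, dtype=np.int32),
        type_labels=[],
        chain_ids=np.full(n, "A"),
        res_names=np.full(n, "FIX"),
        res_seqs=(np.arange(n, dtype=np.int64) + 1 if res_seqs is None
                  else np.asarray(res_seqs, dtype=np.int64)),
        atom_names=labels.astype("U4"),   # atom name carries the group label
        elements=elements,
        solvent_ed=solvent_ed,
        source={"fixture": True},
    )
    return assign_atom_types(m)


def _cycle_labels(labels, n, rng=None):
    labels = [labels] if isinstance(labels, str) else list(labels)
    if rng is None:
        return [labels[i % len(labels)] for i in range(n)]
    return list(rng.choice(labels, size=n))


def make_fixture(kind: str, seed: int | None = None,
                 solvent_ed: float = DEFAULT_SOLVENT_ED,
                 labels="C", **params):
    """Build a synthetic model; returns (StructureModel, ground_truth dict).

    ``labels`` is a single group label or a mix cycled over the atoms.
    Ground truth holds exact geometric facts (Dmax bounds or exact pair
    distances, subunit index ranges) for use as test oracles.
    """
    rng = np.random.default_rng(seed)
    if kind == "two_atom":
        d = float(params.get("d", 5.0))
        pts = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, d]])
        gt = {"dmax": d, "distances": [d]}
        m = _model(pts, _cycle_labels(labels, 2), solvent_ed)

    elif kind == "ladder":
        n_rungs = int(params.get("n_rungs", 10))
        rise = float(params.get("rise", 3.4))
        width = float(params.get("width", 10.0))
        rails = int(params.get("rails", 2))   # 1 = collinear chain
        z = np.arange(n_rungs) * rise
        xs = [0.0] if rails == 1 else [-width / 2, width / 2]
        pts = np.concatenate([
            np.column_stack([np.full(n_rungs, x), np.zeros(n_rungs), z])
            for x in xs])
        dmax = float(np.hypot(width if rails == 2 else 0.0,
                              (n_rungs - 1) * rise))
        gt = {"dmax": dmax, "rise": rise, "width": width, "n_rungs": n_rungs,
              "rails": rails}
        m = _model(pts, _cycle_labels(labels, rails * n_rungs), solvent_ed)

    elif kind == "helix":
        n_per_strand = int(params.get("n", 20))
        radius = float(params.get("radius", 9.0))
        rise = float(params.get("rise", 3.4))
        twist = float(params.get("twist", np.deg2rad(36.0)))
        offset = float(params.get("strand_offset", np.pi * 0.75))
        pts = []
        for s_phase in (0.0, offset):
            for i in range(n_per_strand):
                a = i * twist + s_phase
                pts.append([radius * np.cos(a), radius * np.sin(a), i * rise])
        pts = np.array(pts)
        gt = {"rise": rise, "radius": radius}
        m = _model(pts, _cycle_labels(labels, len(pts)), solvent_ed)

    elif kind == "sphere":
        n = int(params.get("n", 500))
        radius = float(params.get("radius", 20.0))
        aspect = float(params.get("aspect", 1.0))  # c/a ratio: >1 = prolate
        u = rng.random(n)
        pts = rng.normal(size=(n, 3))
        pts *= (radius * u ** (1 / 3) / np.linalg.norm(pts, axis=1))[:, None]
        pts[:, 2] *= aspect
        gt = {"radius": radius, "aspect": aspect,
              "dmax_upper": 2 * radius * max(aspect, 1.0)}
        m = _model(pts, _cycle_labels(labels, n, rng if
                                      not isinstance(labels, str) else None),
                   solvent_ed)

    elif kind == "shell":
        n = int(params.get("n", 2000))
        radius = float(params.get("radius", 80.0))
        thickness = float(params.get("thickness", 15.0))
        r_in, r_out = radius - thickness / 2, radius + thickness / 2
        u = rng.random(n)
        rr = (r_in ** 3 + u * (r_out ** 3 - r_in ** 3)) ** (1 / 3)
        pts = rng.normal(size=(n, 3))
        pts *= (rr / np.linalg.norm(pts, axis=1))[:, None]
        gt = {"radius": radius, "thickness": thickness,
              "dmax_lower": 2 * radius - thickness, "dmax_upper": 2 * r_out}
        m = _model(pts, _cycle_labels(labels, n), solvent_ed)

    elif kind == "ring":
        n_sub = int(params.get("n_subunits", 8))
        ring_radius = float(params.get("ring_radius", 7.5))
        sub_n = int(params.get("atoms_per_subunit", 11))
        sub_size = float(params.get("subunit_radius", 2.2))
        # one rigid random cluster, copied around the ring
        local = rng.normal(size=(sub_n, 3))
        local *= (sub_size * rng.random(sub_n) ** (1 / 3)
                  / np.linalg.norm(local, axis=1))[:, None]
        pts, seqs = [], []
        for s in range(n_sub):
            a = 2 * np.pi * s / n_sub
            rot = np.array([[np.cos(a), -np.sin(a), 0],
                            [np.sin(a), np.cos(a), 0], [0, 0, 1.0]])
            centre = np.array([ring_radius * np.cos(a),
                               ring_radius * np.sin(a), 0.0])
            pts.append(local @ rot.T + centre)
            seqs.extend([s + 1] * sub_n)
        pts = np.concatenate(pts)
        lab = _cycle_labels(labels, sub_n) * n_sub
        gt = {"n_subunits": n_sub, "ring_radius": ring_radius,
              "subunits": [list(range(s * sub_n, (s + 1) * sub_n))
                           for s in range(n_sub)],
              "chord_distances": [
                  2 * ring_radius * np.sin(np.pi * k / n_sub)
                  for k in range(1, n_sub // 2 + 1)]}
        m = _model(pts, lab, solvent_ed, res_seqs=seqs)

    else:
        raise ValueError(f"unknown fixture kind {kind!r}; "
                         f"choose from {FIXTURE_KINDS}")
    return m, gt
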