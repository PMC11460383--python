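"""Shared fixtures: small models, oracles, numba warm-up."""

import numpy as np
import pytest

import solscat as ss
from solscat.fixtures import _model

MIXED_LABELS = ["C", "CH", "CH2", "N", "NH", "O", "OH", "S"]
PROTEIN_LABELS = ["C", "CH", "CH2", "CH3", "N", "NH", "NH2", "NH3",
                  "O", "OH", "S", "SH"]


@pytest.fixture(scope="session", autouse=True)
def _warm_kernels():
    """Trigger numba JIT once on tiny inputs so timings elsewhere are clean."""
    m, _ = ss.make_fixture("two_atom", d=3.0)
    q = np.linspace(0, 1, 5)
    ss.dd_xs(m, q)
    ss.pc_pddf(m, dr=0.1)
    h = ss.build_histograms(m, dr=0.1)
    ss.dh_xs(h, q)
    ss.dh_pddf(h, r_grid=np.arange(120) * 0.1)
    ss.dd_pddf(m, r_grid=np.arange(120) * 0.1)


def model_from_points(points, labels, solvent_ed=0.334, res_seqs=None):
    """Public-ish helper: build a typed model straight from coordinates."""
    return _model(np.asarray(points, dtype=float), labels, solvent_ed,
                  res_seqs=res_seqs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_mixed_model(rng):
    """50 random sites, 8 group types, water contrast."""
    pts = rng.uniform(-12, 12, size=(50, 3)).round(3)
    labels = [MIXED_LABELS[i % len(MIXED_LABELS)] for i in range(50)]
    return model_from_points(pts, labels)


def naive_debye_xs(model, q):
    """Independent O(N²) Debye sum with per-atom form factors (oracle)."""
    from solscat.formfactors import combined_form_factor
    A = np.stack([combined_form_factor(l, model.solvent_ed, model.table)(q)
                  for l in model.group_labels])          # (N, nq)
    pos = model.positions
    i = np.zeros_like(q, dtype=float)
    for j in range(model.n_atoms):
        for k in range(model.n_atoms):
            r = np.linalg.norm(pos[j] - pos[k])
            x = q * r
            s = np.where(np.abs(x) < 1e-12, 1.0, np.sin(x) / np.maximum(x, 1e-300))
            i += A[j] * A[k] * s
    return i


def naive_typed_histogram(model, dr):
    """Independent double-loop typed histogram (oracle)."""
    nt = model.n_types
    pos = model.positions
    tidx = model.type_index
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    bins = np.round(d / dr).astype(int)
    n_bins = bins.max() + 1
    H = np.zeros((nt, nt, n_bins))
    self_counts = np.zeros(nt)
    n = model.n_atoms
    for j in range(n):
        self_counts[tidx[j]] += 1
        for k in range(n):
            if j != k:
                H[tidx[j], tidx[k], bins[j, k]] += 1
    return H, self_counts
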