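"""Direct-Debye engine: brute-force oracles, analytic PDDF, round trips."""

import time

import numpy as np
import pytest
from scipy.integrate import quad

import solscat as ss
from solscat.kernels import deposit_gaussian_terms, deposit_self_terms

from conftest import model_from_points, naive_debye_xs


def test_single_atom_intensity_is_squared_form_factor():
    m, _ = ss.make_fixture("two_atom", d=5.0)
    m1 = m.subset(np.array([0]))
    q = np.linspace(0, 3, 40)
    A = ss.combined_form_factor("C", m.solvent_ed)
    np.testing.assert_allclose(ss.dd_xs(m1, q).i, A(q) ** 2, rtol=1e-12)


def test_two_atom_closed_form():
    m, _ = ss.make_fixture("two_atom", d=5.0, labels=["C", "O"])
    q = np.linspace(0, 3, 90)
    A1 = ss.combined_form_factor("C", m.solvent_ed)(q)
    A2 = ss.combined_form_factor("O", m.solvent_ed)(q)
    ref = A1**2 + A2**2 + 2 * A1 * A2 * np.sinc(q * 5.0 / np.pi)
    assert np.abs(ss.dd_xs(m, q).i - ref).max() / ref[0] < 1e-12


def test_debye_sum_matches_naive_double_loop(small_mixed_model):
    q = np.linspace(0, 3, 31)
    got = ss.dd_xs(small_mixed_model, q).i
    ref = naive_debye_xs(small_mixed_model, q)
    assert np.abs(got - ref).max() / np.abs(ref).max() < 1e-12


def test_nonuniform_q_grid_agrees_with_uniform_path(small_mixed_model):
    q = np.linspace(0, 3, 61)
    qn = np.ascontiguousarray(q[[0, 3, 7, 20, 40, 60]])
    got = ss.dd_xs(small_mixed_model, qn).i
    ref = ss.dd_xs(small_mixed_model, q).i[[0, 3, 7, 20, 40, 60]]
    np.testing.assert_allclose(got, ref, rtol=1e-12)


def test_pair_kernel_matches_quadrature_of_sine_integral():
    """One pair, one Gaussian term, against direct numerical quadrature of
    (2 r c / π a) ∫ exp(−d q²) sin(qa) sin(qr) dq."""
    a, c, d, dr = 6.2, 1.7, 0.31, 0.05
    out = np.zeros(400)
    deposit_gaussian_terms(np.array([a]), np.array([1.0]),
                           np.array([c]), np.array([d]), dr, out)
    r = np.arange(400) * dr
    ref = np.array([
        (2 * ri * c / (np.pi * a)) * quad(
            lambda q: np.exp(-d * q * q) * np.sin(q * a) * np.sin(q * ri),
            0, 60, limit=400)[0]
        for ri in r])
    l2 = np.linalg.norm(out - ref) / np.linalg.norm(ref)
    assert l2 < 1e-6
    # peak at the pair distance up to the r-weighting shift (~2d/a) + grid
    assert abs(r[np.argmax(out)] - a) <= 2 * d / a + dr + 1e-12


def test_self_kernel_integrates_to_amplitude():
    c, d, dr = 2.3, 0.12, 0.01
    out = np.zeros(1500)
    deposit_self_terms(1.0, np.array([c]), np.array([d]), dr, out)
    assert out.sum() * dr == pytest.approx(c, rel=1e-9)
    assert out[0] == 0.0


def test_delta_width_limit_recovers_point_charge_binning():
    """As d → 0 the kernel mass collapses onto the pair distance, recovering
    the point-charge histogram weight (grid kept finer than the width)."""
    a, c, d, dr = 5.0, 1.0, 2.5e-5, 0.001
    out = np.zeros(6000)
    deposit_gaussian_terms(np.array([a]), np.array([1.0]),
                           np.array([c]), np.array([d]), dr, out)
    assert out.sum() * dr == pytest.approx(c, rel=1e-9)
    r = np.arange(out.size) * dr
    near = np.abs(r - a) <= 0.05
    assert out[near].sum() * dr == pytest.approx(c, rel=1e-9)


def test_analytic_pddf_area_equals_forward_scattering(small_mixed_model):
    p = ss.dd_pddf(small_mixed_model, dr=0.1)
    i0 = ss.dd_xs(small_mixed_model, np.array([0.0])).i[0]
    assert abs(p.area() - i0) / abs(i0) < 5e-3


def test_analytic_pddf_matches_numeric_inverse_transform():
    m, _ = ss.make_fixture("sphere", n=10, radius=6, seed=9,
                           labels=["C", "N", "O"])
    q = np.linspace(0, 50, 20001)
    xs = ss.dd_xs(m, q)
    r = np.arange(0, 180) * 0.1
    p_ref = ss.xs_to_pddf_numeric(xs, r)
    p = ss.dd_pddf(m, r_grid=r)
    l2 = np.linalg.norm(p.p - p_ref.p) / np.linalg.norm(p.p)
    assert l2 < 1e-4


def test_truncated_inverse_transform_warns_and_ripples():
    m, _ = ss.make_fixture("sphere", n=10, radius=6, seed=9)
    q = np.linspace(0, 3, 600)
    xs = ss.dd_xs(m, q)
    r = np.arange(0, 180) * 0.1
    with pytest.warns(UserWarning, match="truncat"):
        p_trunc = ss.xs_to_pddf_numeric(xs, r)
    p = ss.dd_pddf(m, r_grid=r)
    # Fourier truncation at q=3 leaves visible ripples (incl. negative lobes)
    assert p_trunc.p.min() < -0.01 * p.p.max()


def test_inverse_transform_of_sinc_peaks_at_distance():
    d = 8.0
    q = np.linspace(0, 60, 24001)
    xs = ss.XSCurve(q, np.sinc(q * d / np.pi), method="synthetic")
    r = np.arange(0, 150) * 0.1
    p = ss.xs_to_pddf_numeric(xs, r)
    assert abs(r[np.argmax(p.p)] - d) <= 0.1 + 1e-12


@pytest.mark.parametrize("kind,params,labels", [
    ("two_atom", dict(d=5.0), ["C", "O"]),
    ("ladder", dict(n_rungs=6), ["C", "N"]),
    ("ring", dict(seed=1), ["C", "O", "CH"]),
    ("sphere", dict(n=60, radius=9, seed=2), ["C", "NH", "OH"]),
])
def test_round_trip_pddf_to_xs_reproduces_debye(kind, params, labels):
    m, _ = ss.make_fixture(kind, labels=labels, **params)
    q = np.linspace(0, 3, 120)
    ref = ss.dd_xs(m, q)
    p = ss.dd_pddf(m, dr=0.1)
    got = ss.pddf_to_xs(p, q)
    assert np.abs(got.i / ref.i - 1).max() < 5e-3


def test_quadratic_cost_scaling(rng):
    """Debye double-sum cost grows ~quadratically with atom count."""
    q = np.linspace(0, 3, 60)
    times = {}
    for n in (100, 400):
        pts = rng.uniform(-20, 20, size=(n, 3))
        m = model_from_points(pts, "C")
        ss.dd_xs(m, q)                      # warm
        t = min(_timed(lambda: ss.dd_xs(m, q)) for _ in range(3))
        times[n] = t
    assert times[400] / times[100] > 4     # ideal 16; generous floor


def _timed(fn):
    t0 = time.perf_counter()
    fn()
    return time.perf_counter() - t0
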