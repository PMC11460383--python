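"""Subunit PDDF decomposition: exact additivity and cross-term structure."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

import solscat as ss
from solscat import Selection, SubunitError

from conftest import model_from_points


def index_selections(groups):
    return [Selection(name=f"sub{i}", indices=tuple(g))
            for i, g in enumerate(groups)]


def rel_residual(dec):
    return dec.residual() / (np.abs(dec.total.p).max() + dec.total.self_mass)


def test_two_single_atom_subunits_enumeration():
    m, _ = ss.make_fixture("two_atom", d=5.0, labels="H", solvent_ed=0.0)
    dec = ss.decompose_pddf(m, index_selections([[0], [1]]), method="PC",
                            dr=0.1)
    assert dec.parts[0].self_mass == pytest.approx(1.0)
    assert dec.parts[1].self_mass == pytest.approx(1.0)
    assert np.all(dec.parts[0].p == 0)
    corr = dec.correlations[(0, 1)]
    k = int(round(5.0 / 0.1))
    assert corr.p[k] * corr.dr == pytest.approx(2.0)   # both ordered directions
    np.testing.assert_allclose(dec.summed().p, ss.pc_pddf(m, dr=0.1).p[:dec.total.p.size])
    assert rel_residual(dec) < 1e-12


def test_correlation_support_bounded_by_cross_distances(rng):
    a = rng.uniform(-3, 3, size=(15, 3))
    b = rng.uniform(-3, 3, size=(12, 3)) + np.array([30.0, 0, 0])
    m = model_from_points(np.vstack([a, b]).round(3), "C")
    dec = ss.decompose_pddf(m, index_selections([range(15), range(15, 27)]),
                            method="PC", dr=0.5)
    corr = dec.correlations[(0, 1)]
    dmin = cdist(m.positions[:15], m.positions[15:]).min()
    dmax = cdist(m.positions[:15], m.positions[15:]).max()
    nz = np.nonzero(corr.p)[0]
    assert corr.r[nz[0]] >= dmin - corr.dr
    assert corr.r[nz[-1]] <= dmax + corr.dr


@pytest.mark.parametrize("method,tol", [("PC", 1e-12), ("DH", 1e-12),
                                        ("DD", 1e-9)])
def test_ring_additivity_all_methods(method, tol):
    m, gt = ss.make_fixture("ring", seed=5, labels=["C", "O", "CH"])
    subs = index_selections(gt["subunits"])
    dec = ss.decompose_pddf(m, subs, method=method, dr=0.25, hist_dr=0.1)
    assert rel_residual(dec) < tol


def test_ring_cross_pairs_match_brute_force_oracle():
    m, gt = ss.make_fixture("ring", seed=5, labels=["C", "O", "CH"])
    subs = index_selections(gt["subunits"])
    dec = ss.decompose_pddf(m, subs, method="PC", dr=0.25)
    ia, ib = gt["subunits"][0], gt["subunits"][3]
    w = m.delta_z
    d = cdist(m.positions[ia], m.positions[ib])
    ww = np.multiply.outer(w[ia], w[ib])
    nbins = dec.total.p.size
    ref = np.bincount(np.round(d / 0.25).astype(int).ravel(),
                      weights=2 * ww.ravel(), minlength=nbins)
    got = dec.correlations[(0, 3)].p * 0.25
    np.testing.assert_allclose(got, ref[:nbins], atol=1e-12 * np.abs(ww).max())


def test_ring_intra_short_range_and_neighbour_chords():
    """Distances inside one subunit dominate short r; neighbour correlations
    peak near the ring chord distances."""
    m, gt = ss.make_fixture("ring", seed=5, labels=["C", "O", "CH"],
                            subunit_radius=1.5, ring_radius=7.5)
    subs = index_selections(gt["subunits"])
    dec = ss.decompose_pddf(m, subs, method="PC", dr=0.25)
    sub_diameter = 2 * 1.5
    intra = sum(p.p for p in dec.parts)
    short = dec.total.r <= sub_diameter
    np.testing.assert_allclose(dec.total.p[short],
                               intra[short] + sum(
                                   c.p[short] for c in dec.correlations.values()))
    # nearest-neighbour correlation concentrated around the first chord
    chord = gt["chord_distances"][0]
    corr01 = dec.correlations[(0, 1)]
    peak_r = corr01.r[np.argmax(corr01.p)]
    assert abs(peak_r - chord) < sub_diameter


def test_permutation_of_subunits_leaves_total_unchanged():
    m, gt = ss.make_fixture("ring", seed=2, labels=["C", "N"])
    subs = index_selections(gt["subunits"])
    dec1 = ss.decompose_pddf(m, subs, method="PC", dr=0.5)
    dec2 = ss.decompose_pddf(m, subs[::-1], method="PC", dr=0.5)
    np.testing.assert_array_equal(dec1.total.p, dec2.total.p)
    s1 = sorted(tuple(np.round(p.p, 12)) for p in dec1.parts)
    s2 = sorted(tuple(np.round(p.p, 12)) for p in dec2.parts)
    assert s1 == s2
    np.testing.assert_allclose(dec1.summed().p, dec2.summed().p, atol=1e-12)


def test_overlapping_and_incomplete_partitions_rejected():
    m, gt = ss.make_fixture("ring", seed=1)
    subs = index_selections(gt["subunits"])
    with pytest.raises(SubunitError, match="overlap"):
        ss.decompose_pddf(m, subs + [subs[0]], method="PC")
    with pytest.raises(SubunitError, match="not covered"):
        ss.decompose_pddf(m, subs[:-1], method="PC")
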