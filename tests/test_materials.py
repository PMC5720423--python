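"""Material registry, mixture rule, interpolation and coefficient queries."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import brachyresponse as br
from brachyresponse.materials import (CrossSectionTable, MaterialError,
                                      _element_table)
from brachyresponse.toy import make_toy_material

TABLE1 = [
    # name, z_eff, z_over_a, density (tabulated reference constants)
    ("water", 7.5, 0.555, 1.0),
    ("LiF", 8.27, 0.462, 2.635),
    ("Li2B4O7", 7.4, 0.485, 2.44),
    ("Al2O3", 10.2, 0.491, 3.97),
    ("diamond", 6.0, 0.496, 3.5),
    ("silicon", 14.0, 0.499, 2.33),
    ("air", 7.6, 0.499, 0.0012),
]


@pytest.mark.parametrize("name,z_eff,z_over_a,density", TABLE1)
def test_registry_carries_tabulated_constants(name, z_eff, z_over_a, density):
    m = br.get_material(name)
    assert m.z_eff == z_eff
    assert m.z_over_a == z_over_a
    assert m.density == density
    total = sum(w for _, w in m.elements)
    assert total == pytest.approx(1.0, abs=1e-6)
    assert all(w > 0 for _, w in m.elements)


def test_make_material_renormalizes_small_deviation():
    m = br.make_material("w2", [(1, 0.1119), (8, 0.8884)], 1.0)
    assert sum(w for _, w in m.elements) == pytest.approx(1.0, abs=1e-12)
    ref = br.get_material("water")
    assert br.coefficient(m, "total", 50.0) == pytest.approx(
        br.coefficient(ref, "total", 50.0), rel=5e-4)


@pytest.mark.parametrize("elements,density", [
    ([(1, 0.5), (8, 0.3)], 1.0),       # fractions far from 1
    ([(99, 1.0)], 1.0),                # unknown element
    ([(8, 1.0)], -2.0),                # non-positive density
    ([], 1.0),                         # empty composition
    ([(1, -0.1), (8, 1.1)], 1.0),      # negative fraction
])
def test_make_material_rejects_invalid_input(elements, density):
    with pytest.raises(MaterialError):
        br.make_material("bad", elements, density)


def test_single_element_mixture_is_identity():
    si = br.get_material("silicon")
    elem = _element_table(14)
    assert np.allclose(si.xs.mu_pe, elem.mu_pe)
    assert np.allclose(si.xs.mu_en, elem.mu_en)


def test_mixture_rule_is_linear_in_composition():
    w = br.get_material("water")
    split = br.make_material(
        "water_split", [(1, 0.055947), (1, 0.055947), (8, 0.888106)], 1.0)
    for kind in ("pe", "incoh", "coh", "en", "total"):
        assert np.allclose(split.xs.interp(kind, [10.0, 30.0, 300.0]),
                           w.xs.interp(kind, [10.0, 30.0, 300.0]))


def test_coefficient_exact_at_grid_points(water):
    idx = np.searchsorted(water.xs.energy_keV, 30.0)
    e = water.xs.energy_keV[idx]
    assert br.coefficient(water, "en", e) == pytest.approx(
        water.xs.mu_en[idx], rel=1e-12)


def test_coefficient_loglog_midpoint(water):
    # hand-evaluated two-point log-log interpolant between bracketing rows
    grid = water.xs.energy_keV
    i = np.searchsorted(grid, 100.0)
    e1, e2 = grid[i], grid[i + 1]
    y1, y2 = water.xs.mu_total[i], water.xs.mu_total[i + 1]
    e_mid = np.sqrt(e1 * e2)  # midway in log space
    expected = np.exp(np.log(y1) + (np.log(e_mid) - np.log(e1))
                      / (np.log(e2) - np.log(e1))
                      * (np.log(y2) - np.log(y1)))
    assert br.coefficient(water, "total", e_mid) == pytest.approx(
        expected, rel=1e-12)


def test_coefficient_rejects_out_of_range_and_unknown_kind(water):
    with pytest.raises(MaterialError):
        br.coefficient(water, "total", 0.5)
    with pytest.raises(MaterialError):
        br.coefficient(water, "total", 2000.0)
    with pytest.raises(MaterialError):
        br.coefficient(water, "pair", 100.0)


@pytest.mark.parametrize("name", [row[0] for row in TABLE1])
def test_interaction_fractions_sum_to_one(name):
    m = br.get_material(name)
    energies = m.xs.energy_keV[::7]
    f_pe, f_in, f_coh = br.interaction_fractions(m, energies)
    assert np.allclose(f_pe + f_in + f_coh, 1.0, atol=1e-9)


def test_interaction_fractions_water_27keV(water):
    f_pe, f_in, f_coh = br.interaction_fractions(water, 27.0)
    assert f_pe == pytest.approx(0.464, abs=0.01)
    assert f_in == pytest.approx(0.41, abs=0.01)
    assert f_coh == pytest.approx(0.126, abs=0.01)


def test_interaction_fractions_degenerate_toy():
    toy = make_toy_material(mu_incoh=0.2, density=1.0)
    assert br.interaction_fractions(toy, 50.0) == (0.0, 1.0, 0.0)


@pytest.mark.parametrize("name", [row[0] for row in TABLE1])
def test_muen_ratio_self_is_unity(name):
    m = br.get_material(name)
    assert br.muen_ratio(m, m, 70.0) == 1.0


def test_muen_ratio_at_co60_energy(water):
    assert br.muen_ratio(br.get_material("LiF"), water, 1250.0) == \
        pytest.approx(0.833, abs=0.005)
    assert br.muen_ratio(br.get_material("silicon"), water, 1250.0) == \
        pytest.approx(0.894, abs=0.005)


@pytest.mark.parametrize("name", [r[0] for r in TABLE1 if r[0] != "water"])
def test_compton_regime_ratio_tracks_electron_density(name, water):
    """Above 500 keV the mu_en ratio reduces to the <Z/A> ratio (2%)."""
    det = br.get_material(name)
    za_ratio = det.z_over_a / water.z_over_a
    for e in (600.0, 1000.0, 1250.0, 1500.0):
        assert br.muen_ratio(det, water, e) == pytest.approx(
            za_ratio, rel=0.02)


def test_corrupted_table_fails_consistency_check(water):
    xs = water.xs
    corrupt = CrossSectionTable(
        energy_keV=xs.energy_keV.copy(),
        mu_pe=xs.mu_pe * 0.2,  # tampered channel: mu_en now exceeds the sum
        mu_incoh=xs.mu_incoh.copy(), mu_coh=xs.mu_coh.copy(),
        mu_en=xs.mu_en.copy())
    with pytest.raises(MaterialError, match="mu_en exceeds"):
        corrupt.validate()


def test_packaged_form_factors_match_upstream_it92():
    """The packaged Gaussian coefficients are verbatim IT92 (via gemmi)."""
    gemmi = pytest.importorskip("gemmi")
    from brachyresponse.materials import _form_factor_coeffs

    symbols = {1: "H", 6: "C", 8: "O", 9: "F", 14: "Si"}
    coeffs = _form_factor_coeffs()
    for z, sym in symbols.items():
        it = gemmi.Element(sym).it92
        a, b, c = coeffs[z]
        assert np.allclose(a, it.a, rtol=1e-4)
        assert np.allclose(b, it.b, rtol=1e-4)
        assert c == pytest.approx(it.c, rel=1e-3, abs=1e-4)


@settings(max_examples=25, deadline=None)
@given(w_h=st.floats(0.05, 0.95),
       e=st.floats(1.0, 1500.0))
def test_fractions_sum_for_arbitrary_mixture(w_h, e):
    m = br.make_material("mix", [(1, w_h), (8, 1.0 - w_h)], 1.0)
    f = br.interaction_fractions(m, e)
    assert np.isclose(sum(f), 1.0, atol=1e-9)
    assert all(fi >= 0 for fi in f)
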