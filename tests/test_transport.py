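"""Transport engine: interaction samplers, boundary logic, oracles."""
import dataclasses

import numpy as np
import pytest
from scipy import stats

import brachyresponse as br
from brachyresponse.toy import (analytic_uncollided_fluence, kn_reference_pdf,
                                make_toy_material, thomson_pdf)
from brachyresponse.transport import (TransportError, _compton_scatter,
                                      _rotate_directions)
from brachyresponse.validation import (check_absorber, check_error_scaling,
                                       check_inverse_square)

ME_C2 = 510.99895


def _mono_point_source(energy=100.0):
    return br.SourceModel(kind="point", spectrum=br.PhotonSpectrum(
        energies=np.array([energy]), intensities=np.array([1.0])))


# ----------------------------------------------------------------------
# Compton
# ----------------------------------------------------------------------
def test_compton_kinematics_consistency(rng):
    e0 = np.full(20_000, 200.0)
    e1, cost = _compton_scatter(e0, rng)
    expected = e0 / (1.0 + (e0 / ME_C2) * (1.0 - cost))
    assert np.allclose(e1, expected, rtol=1e-12)
    assert np.all(e1 < e0)  # Compton always lowers the energy
    assert np.all(e1 > 0)


def test_compton_backscatter_floor(rng):
    # closed form E/(1 + 2E/511) at cos(theta) = -1
    e1, _cost = _compton_scatter(np.full(50_000, 1000.0), rng)
    floor = 1000.0 / (1.0 + 2.0 * 1000.0 / ME_C2)
    assert floor == pytest.approx(203.5, abs=0.05)
    assert e1.min() >= floor - 1e-9


def test_compton_forward_scatter_identity():
    # cos(theta) = 1 forces E' = E in the kinematic relation
    e = 80.0
    assert e / (1.0 + (e / ME_C2) * (1.0 - 1.0)) == e


def test_compton_angles_match_klein_nishina_pdf(rng):
    n = 100_000
    _e, cost = _compton_scatter(np.full(n, 30.0), rng)
    grid, pdf = kn_reference_pdf(30.0, 20001)
    cdf = np.concatenate([[0.0], np.cumsum(
        0.5 * (pdf[1:] + pdf[:-1]) * np.diff(grid))])
    cdf /= cdf[-1]
    edges = np.linspace(-1, 1, 41)
    probs = np.diff(np.interp(edges, grid, cdf))
    observed, _ = np.histogram(cost, bins=edges)
    _c, p = stats.chisquare(observed, probs * n)
    assert p > 0.01


def test_sample_compton_scalar_api(rng):
    e1, cost = br.sample_compton(30.0, rng)
    assert 0 < e1 <= 30.0
    assert -1.0 <= cost <= 1.0


# ----------------------------------------------------------------------
# Rayleigh
# ----------------------------------------------------------------------
def test_rayleigh_flat_form_factor_reduces_to_thomson(rng):
    toy = make_toy_material(mu_coh=0.5, density=1.0)
    n = 100_000
    cost = br.sample_rayleigh(toy, np.full(n, 60.0), rng)
    grid, pdf = thomson_pdf(4001)
    cdf = np.concatenate([[0.0], np.cumsum(
        0.5 * (pdf[1:] + pdf[:-1]) * np.diff(grid))])
    cdf /= cdf[-1]
    edges = np.linspace(-1, 1, 41)
    observed, _ = np.histogram(cost, bins=edges)
    _c, p = stats.chisquare(observed, np.diff(np.interp(edges, grid, cdf)) * n)
    assert p > 0.01


def test_rayleigh_forward_peaked_at_high_energy(rng, water):
    cost = br.sample_rayleigh(water, np.full(20_000, 300.0), rng)
    assert cost.mean() > 0.9


def test_rayleigh_scalar_api(rng, water):
    c = br.sample_rayleigh(water, 60.0, rng)
    assert -1.0 <= c <= 1.0


def test_rotation_preserves_scattering_angle(rng):
    u = np.tile([0.0, 0.0, 1.0], (1000, 1))
    cost = rng.uniform(-1, 1, 1000)
    phi = rng.uniform(0, 2 * np.pi, 1000)
    v = _rotate_directions(u, cost, phi)
    assert np.allclose(np.einsum("ij,ij->i", u, v), cost, atol=1e-10)
    assert np.allclose(np.linalg.norm(v, axis=1), 1.0)


# ----------------------------------------------------------------------
# transport oracles
# ----------------------------------------------------------------------
def test_pure_absorber_matches_attenuated_inverse_square():
    ok, detail = check_absorber(150_000, seed=101)
    assert ok, detail


def test_vacuum_limit_matches_inverse_square():
    ok, detail = check_inverse_square(150_000, seed=102)
    assert ok, detail


def test_batch_error_scales_as_inverse_sqrt_n():
    ok, detail = check_error_scaling(seed=103)
    assert ok, detail


def test_two_region_attenuation_with_scattering_disabled():
    """Piecewise-constant pure absorbers: the tally must equal the
    analytic exp(-mu1 r1 - mu2 (r - r1)) / (4 pi r^2) at three radii."""
    mu1, mu2, r_split = 0.4, 0.1, 3.0
    t1 = make_toy_material(mu_pe=mu1, mu_en=mu1, density=1.0, name="t1")
    t2 = make_toy_material(mu_pe=mu2, mu_en=mu2, density=1.0, name="t2")
    geom = br.build_rz_geometry([r_split, 20.0], [-20.0, 20.0],
                                {(0, 0): t1, (1, 0): t2})
    radii = (4.0, 6.0, 9.0)
    cfg = br.RunConfig(n_histories=400_000, seed=104,
                       source=_mono_point_source(), geometry=geom,
                       distances=radii)
    tally = br.run_transport(cfg)
    for k, r in enumerate(radii):
        mu_path = mu1 * r_split + mu2 * (r - r_split)
        expected = np.exp(-mu_path) / (4 * np.pi * r * r)
        got = tally.total_fluence(k)
        sigma = tally.rel_unc_total(k) * got
        assert got == pytest.approx(expected, abs=3.2 * sigma)


def test_embedded_ring_of_same_material_changes_nothing():
    toy = make_toy_material(mu_pe=0.1, mu_incoh=0.15, mu_en=0.1,
                            density=1.0, name="t")
    homo = br.homogeneous_cylinder(toy)
    ring = br.phantom_with_rings(toy, [(1.9, 2.1, toy)],
                                 ring_half_height=0.05)
    out = {}
    for label, geom in (("homo", homo), ("ring", ring)):
        cfg = br.RunConfig(n_histories=300_000, seed=105,
                           source=_mono_point_source(), geometry=geom,
                           distances=(2.0, 5.0))
        out[label] = br.run_transport(cfg)
    for k in range(2):
        a, b = out["homo"], out["ring"]
        diff = abs(a.total_fluence(k) - b.total_fluence(k))
        sigma = np.hypot(a.rel_unc_total(k) * a.total_fluence(k),
                         b.rel_unc_total(k) * b.total_fluence(k))
        assert diff < 3.5 * sigma


def test_transport_is_deterministic():
    cfg = br.load_preset("i125_water", n_histories=30_000, seed=42)
    a = br.run_transport(cfg)
    b = br.run_transport(cfg)
    assert np.array_equal(a.batch_fluence, b.batch_fluence)


def test_scored_energies_within_physical_bounds(i125_water_tally):
    """No fluence below the cutoff or above the highest source line."""
    tally = i125_water_tally
    centers = tally.energy_centers
    spectrum_max = br.get_spectrum("I125_TG43U1").max_energy
    populated = tally.fluence.sum(axis=0) > 0
    assert centers[populated].min() >= 1.0
    assert centers[populated].max() <= spectrum_max


def test_config_validation():
    src = _mono_point_source()
    geom = br.homogeneous_cylinder(
        make_toy_material(mu_pe=0.1, density=1.0))
    with pytest.raises(TransportError):
        br.RunConfig(n_histories=5, seed=1, source=src, geometry=geom,
                     distances=(1.0,), batches=10)
    with pytest.raises(TransportError):
        br.RunConfig(n_histories=100, seed=1, source=src, geometry=geom,
                     distances=(25.0,))
    with pytest.raises(TransportError):
        br.RunConfig(n_histories=100, seed=1, source=src, geometry=geom,
                     distances=(1.0,), pcut=0.5)


def test_tally_csv_roundtrip(tmp_path):
    cfg = br.load_preset("i125_water", n_histories=20_000, seed=3)
    cfg = dataclasses.replace(cfg, distances=(1.0, 5.0))
    tally = br.run_transport(cfg)
    path = tmp_path / "tally.csv"
    tally.to_csv(path)
    back = br.FluenceTally.from_csv(path)
    assert back.labels == tally.labels
    # align the reconstructed (trimmed) bin grid with the original one
    offset = int(round((back.energy_edges[0] - tally.energy_edges[0])
                       / (tally.energy_edges[1] - tally.energy_edges[0])))
    n_back = back.batch_fluence.shape[2]
    orig = tally.batch_fluence[:, :, offset:offset + n_back]
    assert np.allclose(back.batch_fluence, orig, rtol=1e-6)
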