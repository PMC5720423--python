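"""Kerma conversion, response correction and mean energies."""
import numpy as np
import pytest

import brachyresponse as br
from brachyresponse.analysis import (AnalysisError, CO60_REFERENCE_KEV,
                                     collision_kerma, fluence_mean_energy,
                                     kerma_from_tally,
                                     kerma_weighted_mean_energy)
from brachyresponse.toy import make_toy_material
from brachyresponse.transport import FluenceTally


def _synthetic_tally(batch_fluence, edges, labels=None, distances=None):
    n_b, n_s, _ = batch_fluence.shape
    labels = labels or [f"s{i}" for i in range(n_s)]
    return FluenceTally(labels=labels,
                        shells=np.tile([1.0, 1.1, -0.5, 0.5], (n_s, 1)),
                        distances=distances or [None] * n_s,
                        energy_edges=edges,
                        batch_fluence=batch_fluence, n_histories=1)


def test_collision_kerma_single_bin_identity(water):
    e = np.array([30.25])
    phi = np.array([2.5e-3])
    expected = 2.5e-3 * 30.25 * br.coefficient(water, "en", 30.25)
    assert collision_kerma(e, phi, water) == pytest.approx(expected,
                                                           rel=1e-12)


def test_collision_kerma_zero_fluence(water):
    assert collision_kerma([30.0], [0.0], water) == 0.0


def test_collision_kerma_two_line_hand_sum():
    toy = make_toy_material(mu_pe=0.1, mu_en=(0.2, -1.0), density=1.0)
    e = np.array([50.0, 200.0])
    phi = np.array([3.0, 1.0])
    # hand evaluation: mu_en(E) = 0.2 (E/100)^-1 -> 0.4 and 0.1
    expected = 3.0 * 50.0 * 0.4 + 1.0 * 200.0 * 0.1
    assert collision_kerma(e, phi, toy) == pytest.approx(expected, rel=1e-12)


def test_fluence_mean_energy_identities():
    assert fluence_mean_energy([40.0], [1.0]) == 40.0
    assert fluence_mean_energy([20.0, 60.0], [1.0, 1.0]) == 40.0
    with pytest.raises(AnalysisError):
        fluence_mean_energy([20.0], [0.0])


def test_kerma_weighted_mean_energy_identities(water):
    assert kerma_weighted_mean_energy([40.0], [1.0], water) == 40.0
    # constant mu_en cancels: reduces to the fluence-weighted mean of E^2
    toy = make_toy_material(mu_pe=0.1, mu_en=0.05, density=1.0)
    e = np.array([20.0, 60.0])
    phi = np.array([3.0, 1.0])
    expected = np.average(e, weights=phi * e * 0.05)
    assert kerma_weighted_mean_energy(e, phi, toy) == pytest.approx(expected)


def test_kerma_weighted_two_line_hand_value():
    toy = make_toy_material(mu_pe=0.1, mu_en=(0.2, -1.0), density=1.0)
    e = np.array([50.0, 200.0])
    phi = np.array([3.0, 1.0])
    w = phi * e * np.array([0.4, 0.1])
    assert kerma_weighted_mean_energy(e, phi, toy) == pytest.approx(
        float(np.average(e, weights=w)))


def test_response_of_water_is_exactly_one(water, rng):
    edges = np.arange(1.0, 36.0, 0.5)
    batch = rng.random((10, 4, len(edges) - 1))
    tally = _synthetic_tally(batch, edges)
    k = kerma_from_tally(tally, water)
    table = br.response_correction(k, k, water, water)
    assert np.all(table.r == 1.0)


def test_toy_detector_with_doubled_muen_gives_unit_response(water, rng):
    doubled = make_toy_material(
        mu_pe=0.1, density=1.0, name="2xwater",
        mu_en=lambda e: 2.0 * np.asarray(water.coefficient("en", e)))
    edges = np.arange(1.0, 36.0, 0.5)
    batch = rng.random((10, 3, len(edges) - 1))
    tally = _synthetic_tally(batch, edges)
    table = br.response_correction(kerma_from_tally(tally, doubled),
                                   kerma_from_tally(tally, water),
                                   doubled, water)
    assert np.allclose(table.r, 1.0, rtol=1e-10)


def test_monoenergetic_large_cavity_closed_form(water, detector_materials):
    """A delta spectrum reduces R to the closed-form mu_en ratio curve."""
    det = detector_materials["LiF"]
    edges = np.array([1.0, 1.5])  # one bin; kerma evaluated at its center
    e_center = 1.25
    batch = np.full((10, 1, 1), 3.0e-4)
    # place the bin at 60 keV by shifting the edges
    edges = np.array([59.75, 60.25])
    tally = _synthetic_tally(batch, edges)
    table = br.response_correction(kerma_from_tally(tally, det),
                                   kerma_from_tally(tally, water),
                                   det, water)
    expected = (br.muen_ratio(det, water, 60.0)
                / br.muen_ratio(det, water, CO60_REFERENCE_KEV))
    assert table.r[0] == pytest.approx(expected, rel=1e-10)


def test_mismatched_kerma_grids_rejected(water, rng):
    edges = np.arange(1.0, 36.0, 0.5)
    t1 = _synthetic_tally(rng.random((10, 2, len(edges) - 1)), edges,
                          labels=["a", "b"])
    t2 = _synthetic_tally(rng.random((10, 2, len(edges) - 1)), edges,
                          labels=["a", "c"])
    with pytest.raises(AnalysisError):
        br.response_correction(kerma_from_tally(t1, water),
                               kerma_from_tally(t2, water), water, water)


def test_phantom_response_ratio_identity_and_mismatch(water, rng):
    edges = np.arange(1.0, 36.0, 0.5)
    tally = _synthetic_tally(rng.random((10, 3, len(edges) - 1)), edges)
    k = kerma_from_tally(tally, water)
    table = br.response_correction(k, k, water, water)
    ratio = br.phantom_response_ratio(table, table)
    assert np.allclose(ratio["ratio"], 1.0)
    other = br.response_correction(k, k, water, water)
    other.detector = "LiF"
    with pytest.raises(AnalysisError):
        br.phantom_response_ratio(table, other)


def test_self_attenuation_identity(water, rng):
    edges = np.arange(1.0, 36.0, 0.5)
    tally = _synthetic_tally(rng.random((10, 1, len(edges) - 1)), edges)
    k = kerma_from_tally(tally, water)
    df = br.self_attenuation(k, k)
    assert df["factor"].iloc[0] == pytest.approx(1.0)


def test_kerma_uncertainty_from_batch_spread(water):
    edges = np.array([29.75, 30.25])
    batch = np.array([[[1.0]], [[1.1]], [[0.9]], [[1.0]], [[1.05]],
                      [[0.95]], [[1.0]], [[1.02]], [[0.98]], [[1.0]]])
    tally = _synthetic_tally(batch, edges)
    k = kerma_from_tally(tally, water)
    per_batch = batch[:, 0, 0]
    expected = per_batch.std(ddof=1) / np.sqrt(10) / per_batch.mean()
    assert k.rel_unc[0] == pytest.approx(expected, rel=1e-9)
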