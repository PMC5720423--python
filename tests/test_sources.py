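"""Emission spectra and primary sampling."""
import numpy as np
import pytest
from scipy import stats

import brachyresponse as br
from brachyresponse.sources import SourceError


def test_i125_spectrum_lines_and_mean():
    s = br.get_spectrum("I125_TG43U1")
    assert len(s.energies) == 5
    assert s.energies.min() > 27.0 and s.energies.max() < 36.0
    assert s.mean_energy == pytest.approx(28.37, abs=0.05)


def test_co60_spectrum_mean_is_reference_energy():
    s = br.get_spectrum("CO60")
    assert s.mean_energy == pytest.approx(1250.0)
    assert np.allclose(s.probabilities, 0.5)


def test_yb169_spectrum_span():
    s = br.get_spectrum("YB169")
    assert s.energies.min() >= 49.0
    assert s.energies.max() <= 308.0
    assert 50 < s.mean_energy < 200


def test_unknown_source_id():
    with pytest.raises(SourceError, match="unknown source id"):
        br.get_spectrum("PD103")


@pytest.mark.parametrize("energies,intensities", [
    ([0.5, 30.0], [1.0, 1.0]),   # below 1 keV
    ([30.0], [-1.0]),            # negative intensity
    ([], []),                    # empty
])
def test_spectrum_invariants(energies, intensities):
    with pytest.raises(SourceError):
        br.PhotonSpectrum(energies=np.asarray(energies, dtype=float),
                          intensities=np.asarray(intensities, dtype=float))


def test_emission_is_reproducible():
    model = br.SourceModel(kind="bare_line",
                           spectrum=br.get_spectrum("I125_TG43U1"))
    a = br.sample_emission(model, np.random.default_rng(7), 1000)
    b = br.sample_emission(model, np.random.default_rng(7), 1000)
    for x, y in zip(a, b):
        assert np.array_equal(x, y)


def test_line_source_positions_uniform_on_segment(rng):
    model = br.SourceModel(kind="bare_line",
                           spectrum=br.get_spectrum("I125_TG43U1"),
                           active_length=0.3)
    pos, _d, _e, w = br.sample_emission(model, rng, 100_000)
    z = pos[:, 2]
    assert np.all(np.abs(z) <= 0.15)
    assert abs(z.mean()) < 3 * 0.15 / np.sqrt(3 * len(z))
    assert np.allclose(pos[:, :2], 0.0)
    assert np.all(w == 1.0)


def test_isotropic_directions_have_zero_mean_cosine(rng):
    model = br.SourceModel(kind="point",
                           spectrum=br.get_spectrum("I125_TG43U1"))
    _p, direc, _e, _w = br.sample_emission(model, rng, 100_000)
    n = len(direc)
    assert np.allclose(np.linalg.norm(direc, axis=1), 1.0)
    for axis in range(3):
        assert abs(direc[:, axis].mean()) < 3 / np.sqrt(3 * n)


def test_energy_draw_frequencies_match_intensities(rng):
    s = br.get_spectrum("I125_TG43U1")
    model = br.SourceModel(kind="point", spectrum=s)
    _p, _d, e, _w = br.sample_emission(model, rng, 100_000)
    observed = np.array([(e == line).sum() for line in s.energies])
    _chi2, p = stats.chisquare(observed, s.probabilities * len(e))
    assert p > 0.01


def test_parallel_beam_within_radius_and_field_area(rng):
    model = br.SourceModel(kind="parallel_beam",
                           spectrum=br.get_spectrum("CO60"),
                           beam_radius=5.64, beam_z=-20.0)
    pos, direc, _e, _w = br.sample_emission(model, rng, 20_000)
    r = np.hypot(pos[:, 0], pos[:, 1])
    assert np.all(r <= 5.64)
    assert np.allclose(pos[:, 2], -20.0)
    assert np.allclose(direc, [0.0, 0.0, 1.0])
    assert np.pi * 5.64**2 == pytest.approx(100.0, rel=0.01)


@pytest.mark.parametrize("kwargs", [
    {"kind": "ring"},
    {"kind": "bare_line", "active_length": 0.0},
    {"kind": "parallel_beam", "beam_radius": None},
])
def test_source_model_validation(kwargs):
    with pytest.raises(SourceError):
        br.SourceModel(spectrum=br.get_spectrum("CO60"), **kwargs)
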