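"""Emission spectra and primary-photon samplers.

Packaged spectra:

* ``I125_TG43U1`` -- the five-line bare I-125 spectrum of the TG-43U1
  consensus dataset (27.2-35.5 keV).
* ``YB169`` -- principal gamma and Tm K x-ray lines of Yb-169 decay
  (49.8-307.7 keV) with standard emission probabilities.
* ``CO60`` -- the two-line reference spectrum, stored as 1170/1330 keV
  with equal weights (reference energy 1250 keV).

Source geometries are deliberately bare: an isotropic line source on the
cylinder axis, an isotropic point source, or a parallel circular beam.
Encapsulated clinical source models are out of scope.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np

DATA_DIR = Path(__file__).parent / "data" / "spectra"

_SPECTRUM_FILES = {
    "I125_TG43U1": "i125_tg43u1.csv",
    "YB169": "yb169.csv",
    "CO60": "co60.csv",
}


class SourceError(ValueError):
    pass


@dataclass(frozen=True)
class PhotonSpectrum:
    """Discrete emission lines (keV, relative intensity per decay)."""

    energies: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        e = np.asarray(self.energies, dtype=float)
        w = np.asarray(self.intensities, dtype=float)
        if e.shape != w.shape or e.ndim != 1 or len(e) == 0:
            raise SourceError("energies/intensities must be equal-length 1-D")
        if np.any(e <= 1.0) or np.any(e > 1500.0):
            raise SourceError("line energies must lie in (1, 1500] keV")
        if np.any(w <= 0):
            raise SourceError("line intensities must be positive")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "intensities", w)

    @property
    def normalization(self) -> float:
        """Total intensity (photons per decay for nuclide spectra)."""
        return float(self.intensities.sum())

    @property
    def probabilities(self) -> np.ndarray:
        return self.intensities / self.intensities.sum()

    @property
    def mean_energy(self) -> float:
        """Intensity-weighted mean line energy, keV."""
        return float(np.average(self.energies, weights=self.intensities))

    @property
    def max_energy(self) -> float:
        return float(self.energies.max())

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        cum = np.cumsum(self.probabilities)
        idx = np.searchsorted(cum, rng.random(n), side="right")
        return self.energies[np.minimum(idx, len(cum) - 1)]


@lru_cache(maxsize=8)
def get_spectrum(source_id: str) -> PhotonSpectrum:
    """Load a packaged spectrum by id (I125_TG43U1, YB169, CO60)."""
    key = source_id.upper()
    if key not in _SPECTRUM_FILES:
        raise SourceError(
            f"unknown source id {source_id!r}; "
            f"known: {', '.join(sorted(_SPECTRUM_FILES))}")
    raw = np.genfromtxt(DATA_DIR / _SPECTRUM_FILES[key], delimiter=",",
                        names=True)
    return PhotonSpectrum(energies=np.atleast_1d(raw["energy_keV"]),
                          intensities=np.atleast_1d(raw["intensity"]))


@dataclass(frozen=True)
class SourceModel:
    """Emission geometry plus spectrum.

    kind: 'bare_line' (uniform on the axis segment of ``active_length``
    centered at the origin, isotropic), 'point' (origin, isotropic) or
    'parallel_beam' (uniform on a disc of ``beam_radius`` at axial
    position ``beam_z``, travelling toward +z).
    """

    kind: str
    spectrum: PhotonSpectrum
    active_length: float = 0.3  # cm, bare_line only
    beam_radius: float | None = None  # cm, parallel_beam only
    beam_z: float = 0.0

    def __post_init__(self):
        if self.kind not in ("bare_line", "point", "parallel_beam"):
            raise SourceError(f"unknown source kind {self.kind!r}")
        if self.kind == "bare_line" and not self.active_length > 0:
            raise SourceError("active_length must be positive")
        if self.kind == "parallel_beam" and not (self.beam_radius or 0) > 0:
            raise SourceError("beam_radius must be positive")


def _isotropic_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    cost = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    sint = np.sqrt(1.0 - cost * cost)
    return np.column_stack([sint * np.cos(phi), sint * np.sin(phi), cost])


def sample_emission(model: SourceModel, rng: np.random.Generator,
                    n: int = 1):
    """Draw primary photons: (positions, unit directions, energies, weights)."""
    pos = np.zeros((n, 3))
    if model.kind == "bare_line":
        half = model.active_length / 2.0
        pos[:, 2] = rng.uniform(-half, half, n)
        direc = _isotropic_directions(rng, n)
    elif model.kind == "point":
        direc = _isotropic_directions(rng, n)
    else:  # parallel_beam
        r = model.beam_radius * np.sqrt(rng.random(n))
        phi = rng.uniform(0.0, 2.0 * np.pi, n)
        pos[:, 0] = r * np.cos(phi)
        pos[:, 1] = r * np.sin(phi)
        pos[:, 2] = model.beam_z
        direc = np.tile([0.0, 0.0, 1.0], (n, 1))
    energies = model.spectrum.sample(rng, n)
    return pos, direc, energies, np.ones(n)
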