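"""Materials, photon cross sections and mass energy-absorption coefficients.

Elemental mass interaction coefficients (photoelectric, incoherent,
coherent, energy absorption; cm^2/g on a common 1-1500 keV grid) are
packaged as CSV files and combined with the additive mixture rule

    (mu/rho)_mix = sum_i w_i (mu/rho)_i

where w_i are mass fractions.  All interpolation between grid points is
log-log linear, the standard choice for photon cross sections.

The material registry (``data/materials.yaml``) carries the phantom and
detector materials with their tabulated effective atomic numbers,
electron densities <Z/A> and mass densities; those constants are stored
values, never recomputed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import yaml

DATA_DIR = Path(__file__).parent / "data"

ENERGY_MIN_KEV = 1.0
ENERGY_MAX_KEV = 1500.0

_KINDS = ("pe", "incoh", "coh", "total", "en")
_COLS = {"pe": "mu_pe", "incoh": "mu_incoh", "coh": "mu_coh", "en": "mu_en"}

ATOMIC_WEIGHT = {
    1: 1.008, 3: 6.941, 5: 10.811, 6: 12.011, 7: 14.007,
    8: 15.999, 9: 18.998, 13: 26.982, 14: 28.085, 18: 39.948,
}

#: Bohr radius in Angstrom, used by the form-factor model
_A0 = 0.529177210903


class MaterialError(ValueError):
    """Raised for unknown elements/materials or invalid compositions."""


@dataclass
class CrossSectionTable:
    """Per-material mass interaction coefficients on an energy grid."""

    energy_keV: np.ndarray
    mu_pe: np.ndarray
    mu_incoh: np.ndarray
    mu_coh: np.ndarray
    mu_en: np.ndarray

    @property
    def mu_total(self) -> np.ndarray:
        # pair/triplet production is excluded (below ~1% of the total for
        # these materials at 1.5 MeV), so the stored channels are exhaustive
        return self.mu_pe + self.mu_incoh + self.mu_coh

    def validate(self) -> None:
        e = self.energy_keV
        if e.ndim != 1 or len(e) < 2 or np.any(np.diff(e) <= 0):
            raise MaterialError("energy grid must be strictly increasing")
        if e[0] > ENERGY_MIN_KEV or e[-1] < ENERGY_MAX_KEV:
            raise MaterialError(
                f"energy grid must span [{ENERGY_MIN_KEV}, {ENERGY_MAX_KEV}] keV")
        for name in ("mu_pe", "mu_incoh", "mu_coh", "mu_en"):
            if np.any(getattr(self, name) < 0):
                raise MaterialError(f"{name} has negative entries")
        if np.all(self.mu_total <= 0):
            raise MaterialError("all interaction channels vanish")
        if np.any(self.mu_en > self.mu_total * (1 + 1e-9)):
            raise MaterialError("mu_en exceeds mu_total: corrupt table")

    def interp(self, kind: str, energy_keV) -> np.ndarray:
        """Log-log interpolated coefficient; exact at grid points."""
        if kind not in _KINDS:
            raise MaterialError(f"unknown coefficient kind {kind!r}")
        e = np.asarray(energy_keV, dtype=float)
        if np.any(e < ENERGY_MIN_KEV) or np.any(e > ENERGY_MAX_KEV):
            raise MaterialError(
                f"energy outside [{ENERGY_MIN_KEV}, {ENERGY_MAX_KEV}] keV")
        y = self.mu_total if kind == "total" else getattr(self, _COLS[kind])
        with np.errstate(divide="ignore"):
            out = np.exp(np.interp(np.log(e), np.log(self.energy_keV),
                                   np.log(np.maximum(y, 1e-300))))
        out = np.where(out < 1e-290, 0.0, out)
        return out if out.ndim else float(out)


@dataclass
class Material:
    """A named mixture with density and linked cross-section table.

    ``z_eff`` and ``z_over_a`` are tabulated constants (stored, not
    computed).  ``elements`` holds (atomic number, mass fraction) pairs
    with fractions summing to one.
    """

    name: str
    elements: list[tuple[int, float]]
    density: float  # g/cm^3
    xs: CrossSectionTable
    z_eff: float | None = None
    z_over_a: float | None = None
    _ff2_coeffs: list[tuple[float, np.ndarray, np.ndarray, float]] = field(
        default_factory=list, repr=False)
    _s_coeffs: list = field(default_factory=list, repr=False)

    def coefficient(self, kind: str, energy_keV):
        return self.xs.interp(kind, energy_keV)

    def ff2(self, x) -> np.ndarray:
        """Squared coherent form factor per gram, sum_i (w_i/A_i) F_i(x)^2.

        ``x = sin(theta/2)/lambda`` in 1/Angstrom.  Drives the angular
        distribution of Rayleigh scattering.
        """
        x = np.asarray(x, dtype=float)
        total = np.zeros_like(x)
        for wa, a, b, c in self._ff2_coeffs:
            total += wa * _form_factor(a, b, c, x) ** 2
        return total

    def sfunc(self, x) -> np.ndarray:
        """Incoherent scattering function per gram, sum_i (w_i/A_i) S_i(x).

        Monotone from 0 at x = 0 toward the free-electron limit; weights
        the Klein-Nishina angular law for bound-Compton sampling.  The
        same per-element model that generated the packaged incoherent
        cross sections (exact 1 - f^2 for hydrogen, Gaussian electron
        groups otherwise).
        """
        x = np.asarray(x, dtype=float)
        total = np.zeros_like(x)
        for wa, z, a, b, c in self._s_coeffs:
            total += wa * _incoherent_func(z, a, b, c, x)
        return total


def _form_factor(a, b, c_pair, x):
    """IT92 Gaussian sum with a hydrogenic core replacing the constant."""
    c, zk = c_pair
    f = np.zeros_like(x)
    xx = x * x
    for ai, bi in zip(a, b):
        f = f + ai * np.exp(-bi * xx)
    core = (1.0 + (2.0 * np.pi * _A0 * x / zk) ** 2) ** -2
    return f + c * core


@lru_cache(maxsize=1)
def _s_gamma() -> float:
    """Calibration exponent of the incoherent scattering function (the
    same one used to generate the packaged incoherent cross sections)."""
    path = DATA_DIR / "incoherent_gamma.csv"
    if not path.exists():
        return 1.0
    return float(np.genfromtxt(path, names=True)["gamma"])


def _incoherent_func(z, a, b, c_pair, x):
    """Incoherent scattering function S(x) for one element."""
    c, zk = c_pair
    gamma = _s_gamma()
    if z == 1:
        f = (1.0 + (2.0 * np.pi * _A0 * x) ** 2) ** -2
        return (1.0 - f * f) ** gamma
    xx = x * x
    core = (1.0 + (2.0 * np.pi * _A0 * x / zk) ** 2) ** -2
    s = np.zeros_like(x)
    for ai, bi in zip(a, b):
        s = s + ai * (1.0 - np.exp(-2.0 * bi * xx))
    s = s + c * (1.0 - core * core)
    s = np.clip(s / (a.sum() + c), 0.0, 1.0)
    return z * s ** gamma


@lru_cache(maxsize=1)
def _form_factor_coeffs() -> dict[int, tuple[np.ndarray, np.ndarray, float]]:
    raw = np.genfromtxt(DATA_DIR / "formfactors.csv", delimiter=",",
                        names=True)
    out = {}
    for row in np.atleast_1d(raw):
        z = int(row["Z"])
        a = np.array([row[f"a{i}"] for i in range(1, 5)])
        b = np.array([row[f"b{i}"] for i in range(1, 5)])
        out[z] = (a, b, float(row["c"]))
    return out


def _element_ff_terms(z: int) -> list[tuple[float, np.ndarray, np.ndarray, tuple]]:
    """(weight_multiplier, a, b, (c, z_k)) terms for one element's F(x)."""
    coeffs = _form_factor_coeffs()
    if z == 7:
        # pathological IT92 fit for N: geometric mean of C and O is used in
        # the packaged tables; for sampling, average of C and O F^2 shapes
        # scaled to Z=7 is an adequate stand-in
        a6, b6, c6 = coeffs[6]
        a8, b8, c8 = coeffs[8]
        return [(0.5 * (49.0 / 36.0), a6, b6, (c6, 5.7)),
                (0.5 * (49.0 / 64.0), a8, b8, (c8, 7.7))]
    a, b, c = coeffs[z]
    return [(1.0, a, b, (c, max(z - 0.3, 1.0)))]


def _element_s_terms(z: int):
    """(multiplier, z_source, a, b, (c, z_k)) terms for one element's S(x)."""
    coeffs = _form_factor_coeffs()
    if z == 1:
        return [(1.0, 1, None, None, (0.0, 1.0))]
    if z == 7:
        a6, b6, c6 = coeffs[6]
        a8, b8, c8 = coeffs[8]
        return [(3.5 / 6.0, 6, a6, b6, (c6, 5.7)),
                (3.5 / 8.0, 8, a8, b8, (c8, 7.7))]
    a, b, c = coeffs[z]
    return [(1.0, z, a, b, (c, max(z - 0.3, 1.0)))]


@lru_cache(maxsize=32)
def _element_table(z: int) -> CrossSectionTable:
    matches = sorted((DATA_DIR / "elements").glob(f"Z{z:02d}_*.csv"))
    if not matches:
        raise MaterialError(f"no packaged cross sections for element Z={z}")
    raw = np.genfromtxt(matches[0], delimiter=",", names=True)
    table = CrossSectionTable(
        energy_keV=raw["energy_keV"].copy(), mu_pe=raw["mu_pe"].copy(),
        mu_incoh=raw["mu_incoh"].copy(), mu_coh=raw["mu_coh"].copy(),
        mu_en=raw["mu_en"].copy())
    table.validate()
    return table


def make_material(name: str, elements, density: float,
                  z_eff: float | None = None,
                  z_over_a: float | None = None) -> Material:
    """Build a Material from (Z, mass fraction) pairs via the mixture rule.

    Fractions are renormalized when their sum deviates from one by less
    than 1e-3; larger deviations raise :class:`MaterialError`.
    """
    if density <= 0:
        raise MaterialError(f"non-positive density for {name!r}")
    elements = [(int(z), float(w)) for z, w in elements]
    if not elements:
        raise MaterialError("at least one element is required")
    if any(w <= 0 for _, w in elements):
        raise MaterialError("mass fractions must be positive")
    total = sum(w for _, w in elements)
    if abs(total - 1.0) >= 1e-3:
        raise MaterialError(
            f"mass fractions of {name!r} sum to {total:.6f}, not 1")
    elements = [(z, w / total) for z, w in elements]

    tables = {z: _element_table(z) for z, _ in elements}
    grid = tables[elements[0][0]].energy_keV
    for z, _ in elements:
        if not np.array_equal(tables[z].energy_keV, grid):
            raise MaterialError("element tables are on mismatched grids")
    mixed = {}
    for kind, col in _COLS.items():
        mixed[col] = sum(w * getattr(tables[z], col) for z, w in elements)
    xs = CrossSectionTable(energy_keV=grid.copy(), **mixed)
    xs.validate()

    ff2_terms = []
    s_terms = []
    for z, w in elements:
        wa = w / ATOMIC_WEIGHT[z]
        for mult, a, b, cz in _element_ff_terms(z):
            ff2_terms.append((wa * mult, a, b, cz))
        for mult, z_src, a, b, cz in _element_s_terms(z):
            s_terms.append((wa * mult, z_src, a, b, cz))
    return Material(name=name, elements=elements, density=density, xs=xs,
                    z_eff=z_eff, z_over_a=z_over_a, _ff2_coeffs=ff2_terms,
                    _s_coeffs=s_terms)


@lru_cache(maxsize=1)
def _registry() -> dict:
    with open(DATA_DIR / "materials.yaml") as fh:
        return yaml.safe_load(fh)


def list_materials() -> list[str]:
    return sorted(_registry())


@lru_cache(maxsize=32)
def get_material(name: str) -> Material:
    """Fetch a registered material (water, LiF, silicon, ...)."""
    reg = _registry()
    if name not in reg:
        raise MaterialError(
            f"unknown material {name!r}; registered: {', '.join(sorted(reg))}")
    entry = reg[name]
    return make_material(name, [(int(z), w) for z, w in
                                entry["elements"].items()],
                         entry["density"], z_eff=entry.get("z_eff"),
                         z_over_a=entry.get("z_over_a"))


def coefficient(material: Material, kind: str, energy_keV):
    """Mass interaction coefficient (cm^2/g) at the given energy."""
    return material.coefficient(kind, energy_keV)


def interaction_fractions(material: Material, energy_keV):
    """(photoelectric, incoherent, coherent) shares of the total."""
    pe = material.coefficient("pe", energy_keV)
    inc = material.coefficient("incoh", energy_keV)
    coh = material.coefficient("coh", energy_keV)
    total = pe + inc + coh
    return pe / total, inc / total, coh / total


def muen_ratio(detector: Material, reference: Material, energy_keV):
    """Ratio of mass energy-absorption coefficients detector/reference."""
    return (detector.coefficient("en", energy_keV)
            / reference.coefficient("en", energy_keV))
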