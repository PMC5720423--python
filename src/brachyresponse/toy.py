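"""Synthetic materials with closed-form transport solutions, plus the
independent oracles used to validate the engine.

Toy materials expose the same duck-typed surface as real materials
(``coefficient``, ``density``, ``ff2``) but with user-chosen constant or
power-law channel coefficients, so every transport and analysis stage
can be exercised against hand-computable answers: a pure absorber gives
the attenuated inverse-square fluence exp(-mu r)/(4 pi r^2), a
near-vacuum gives 1/(4 pi r^2), a material with mu_en exactly twice
water's gives R = 1 by cancellation.

The oracles here are written independently of the transport code (direct
formula evaluation and numeric integration, no shared samplers), so
agreement between the two is evidence rather than tautology.
"""
from __future__ import annotations

import numpy as np

ME_C2 = 510.99895  # keV


class ToyError(ValueError):
    pass


def _as_channel(spec):
    """Channel spec: number (constant), (amplitude, exponent) power law
    amplitude*(E/100 keV)**exponent, or a callable of E."""
    if callable(spec):
        return spec
    if np.isscalar(spec):
        return lambda e, v=float(spec): np.full_like(
            np.asarray(e, dtype=float), v, dtype=float)
    amp, expo = spec
    return lambda e, a=float(amp), p=float(expo): a * (
        np.asarray(e, dtype=float) / 100.0) ** p


class ToyMaterial:
    """Material-compatible object with prescribed coefficients (cm^2/g)."""

    def __init__(self, name="toy", mu_pe=0.0, mu_incoh=0.0, mu_coh=0.0,
                 mu_en=None, density=1.0, form_factor_sq=None):
        self.name = name
        self.density = float(density)
        self._channels = {"pe": _as_channel(mu_pe),
                          "incoh": _as_channel(mu_incoh),
                          "coh": _as_channel(mu_coh)}
        self._mu_en = (_as_channel(mu_en) if mu_en is not None
                       else self._channels["pe"])
        self._ff2 = (_as_channel(form_factor_sq)
                     if form_factor_sq is not None else None)
        probe = np.array([10.0, 100.0, 1000.0])
        if all(np.all(self._channels[k](probe) == 0.0)
               for k in ("pe", "incoh", "coh")):
            raise ToyError("all interaction channels are zero")

    def coefficient(self, kind, energy_keV):
        e = np.asarray(energy_keV, dtype=float)
        if kind == "en":
            out = self._mu_en(e)
        elif kind == "total":
            out = sum(self._channels[k](e) for k in ("pe", "incoh", "coh"))
        elif kind in self._channels:
            out = self._channels[kind](e)
        else:
            raise ToyError(f"unknown coefficient kind {kind!r}")
        return out if out.ndim else float(out)

    def ff2(self, x):
        x = np.asarray(x, dtype=float)
        if self._ff2 is None:
            return np.ones_like(x)  # constant factor -> pure Thomson
        return self._ff2(x)

    def sfunc(self, x):
        # free electrons: flat incoherent function -> pure Klein-Nishina
        return np.ones_like(np.asarray(x, dtype=float))


def make_toy_material(mu_pe=0.0, mu_incoh=0.0, mu_coh=0.0, mu_en=None,
                      density=1.0, name="toy",
                      form_factor_sq=None) -> ToyMaterial:
    """Build a Material-compatible toy with the given channel functions."""
    return ToyMaterial(name=name, mu_pe=mu_pe, mu_incoh=mu_incoh,
                       mu_coh=mu_coh, mu_en=mu_en, density=density,
                       form_factor_sq=form_factor_sq)


def analytic_uncollided_fluence(mu_linear: float, r: float) -> float:
    """Uncollided point-source fluence exp(-mu r) / (4 pi r^2) per photon."""
    if r <= 0:
        raise ToyError("r must be positive")
    return float(np.exp(-mu_linear * r) / (4.0 * np.pi * r * r))


def kn_reference_pdf(energy_keV: float, n_points: int = 2001):
    """Normalized Klein-Nishina pdf over cos(theta), by direct formula.

    Returns (cos_grid, pdf); the pdf integrates to one (trapezoid) to
    better than 1e-6 on the returned grid.
    """
    if not 1.0 < energy_keV <= 1500.0:
        raise ToyError("energy outside (1, 1500] keV")
    cost = np.linspace(-1.0, 1.0, n_points)
    eps = energy_keV / ME_C2
    ratio = 1.0 / (1.0 + eps * (1.0 - cost))  # E'/E
    d = ratio ** 2 * (ratio + 1.0 / ratio - (1.0 - cost ** 2))
    pdf = d / np.trapezoid(d, cost)
    return cost, pdf


def thomson_pdf(n_points: int = 2001):
    """Normalized Thomson pdf proportional to 1 + cos^2."""
    cost = np.linspace(-1.0, 1.0, n_points)
    pdf = (1.0 + cost ** 2) * 3.0 / 8.0
    return cost, pdf
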