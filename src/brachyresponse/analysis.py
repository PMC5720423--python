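"""From fluence spectra to collision kerma, energy response R, and
mean energies.

The relative absorbed-dose energy response correction for a detector
material ``det`` at beam quality Q is

    R = (K_det / K_wat)_Q / [(mu_en/rho)_det / (mu_en/rho)_wat]_Co60

with collision kerma K = sum_E Phi(E) * E * (mu_en/rho)(E) computed from
the scored fluence spectrum, and the Co-60 denominator evaluated
analytically at 1250 keV (the simulated Co-60 dose ratios agree with the
mass energy-absorption ratio at the percent level, so the analytic ratio
stands in for the reference beam).

All uncertainties are 1-sigma, propagated to first order (relative
uncertainties added in quadrature for ratios); per-shell kerma
uncertainties come from the tally's batch spread.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .materials import Material, muen_ratio
from .transport import FluenceTally

CO60_REFERENCE_KEV = 1250.0


class AnalysisError(ValueError):
    pass


def collision_kerma(energies_keV, fluence, material) -> float:
    """Collision kerma per source photon from a binned fluence spectrum.

    K = sum_bins Phi(E) * E * (mu_en/rho)(E) at bin centers; units
    keV * cm^2/g per source photon (only ratios are ever used).
    """
    e = np.asarray(energies_keV, dtype=float)
    phi = np.asarray(fluence, dtype=float)
    if e.shape != phi.shape:
        raise AnalysisError("energy and fluence grids differ in shape")
    live = phi > 0
    if not live.any():
        return 0.0
    muen = material.coefficient("en", e[live])
    return float(np.sum(phi[live] * e[live] * muen))


@dataclass
class KermaResult:
    """Collision kerma per source photon at each scoring shell."""

    material: str
    labels: list
    distances: list
    kerma: np.ndarray
    rel_unc: np.ndarray
    batch_kerma: np.ndarray  # (n_batches, n_shells)
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"label": self.labels,
                             "distance_cm": self.distances,
                             "kerma": self.kerma,
                             "rel_unc": self.rel_unc})


def kerma_from_tally(tally: FluenceTally, material: Material,
                     shells=None) -> KermaResult:
    """Convert a fluence tally to collision kerma for one material."""
    idx = range(len(tally.labels)) if shells is None else shells
    idx = list(idx)
    centers = tally.energy_centers
    muen = np.asarray(material.coefficient("en", centers), dtype=float)
    weights = centers * muen
    batch = tally.batch_fluence[:, idx, :] @ weights
    mean = batch.mean(axis=0)
    sem = batch.std(axis=0, ddof=1) / np.sqrt(batch.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(mean > 0, sem / np.maximum(mean, 1e-300), np.inf)
    return KermaResult(material=getattr(material, "name", "material"),
                       labels=[tally.labels[i] for i in idx],
                       distances=[tally.distances[i] for i in idx],
                       kerma=mean, rel_unc=rel, batch_kerma=batch,
                       meta=dict(tally.meta))


@dataclass
class ResponseTable:
    """R with 1-sigma uncertainties per (detector, distance)."""

    detector: str
    reference_energy_keV: float
    labels: list
    distances: list
    r: np.ndarray
    rel_unc: np.ndarray
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"label": self.labels,
                             "distance_cm": self.distances,
                             "R": self.r, "rel_unc": self.rel_unc})


def response_correction(kerma_det: KermaResult, kerma_wat: KermaResult,
                        detector: Material, reference: Material,
                        reference_energy_keV: float = CO60_REFERENCE_KEV,
                        ) -> ResponseTable:
    """Energy response correction R per scoring shell.

    Divides the detector/water kerma ratio by the detector/water mass
    energy-absorption ratio at the reference (Co-60) energy.
    """
    if kerma_det.labels != kerma_wat.labels:
        raise AnalysisError("kerma results scored on different shells")
    denom = muen_ratio(detector, reference, reference_energy_keV)
    r = (kerma_det.kerma / kerma_wat.kerma) / denom
    rel = np.sqrt(kerma_det.rel_unc ** 2 + kerma_wat.rel_unc ** 2)
    return ResponseTable(detector=kerma_det.material,
                         reference_energy_keV=reference_energy_keV,
                         labels=list(kerma_det.labels),
                         distances=list(kerma_det.distances),
                         r=r, rel_unc=rel, meta=dict(kerma_det.meta))


def fluence_mean_energy(energies_keV, fluence) -> float:
    """Fluence-weighted mean energy, keV."""
    phi = np.asarray(fluence, dtype=float)
    if phi.sum() <= 0:
        raise AnalysisError("empty spectrum")
    return float(np.average(np.asarray(energies_keV, float), weights=phi))


def kerma_weighted_mean_energy(energies_keV, fluence, material) -> float:
    """Mean energy weighted by E * Phi(E) * (mu_en/rho)_material(E), keV."""
    e = np.asarray(energies_keV, dtype=float)
    phi = np.asarray(fluence, dtype=float)
    w = phi * e * np.asarray(material.coefficient("en", e), dtype=float)
    if w.sum() <= 0:
        raise AnalysisError("empty spectrum")
    return float(np.average(e, weights=w))


def mean_energies_from_tally(tally: FluenceTally,
                             materials: list[Material]) -> pd.DataFrame:
    """Per-shell fluence-weighted and kerma-weighted mean energies."""
    rows = []
    centers = tally.energy_centers
    for k, label in enumerate(tally.labels):
        phi = tally.spectrum(k)
        row = {"label": label, "distance_cm": tally.distances[k],
               "E_fluence_keV": fluence_mean_energy(centers, phi)}
        for m in materials:
            row[f"E_kerma_{m.name}_keV"] = kerma_weighted_mean_energy(
                centers, phi, m)
        rows.append(row)
    return pd.DataFrame(rows)


def phantom_response_ratio(r_solid: ResponseTable,
                           r_water: ResponseTable) -> pd.DataFrame:
    """Elementwise R_solid / R_water with propagated uncertainty."""
    if (r_solid.labels != r_water.labels
            or r_solid.detector != r_water.detector):
        raise AnalysisError("response tables are not comparable")
    ratio = r_solid.r / r_water.r
    rel = np.sqrt(r_solid.rel_unc ** 2 + r_water.rel_unc ** 2)
    return pd.DataFrame({"label": r_solid.labels,
                         "distance_cm": r_solid.distances,
                         "ratio": ratio, "rel_unc": rel})


def self_attenuation(kerma_with_detector: KermaResult,
                     kerma_reference: KermaResult) -> pd.DataFrame:
    """Detector self-attenuation: kerma with the detector modeled divided
    by the unperturbed (detector-absent) kerma at the same location."""
    if len(kerma_with_detector.kerma) != len(kerma_reference.kerma):
        raise AnalysisError("mismatched runs")
    factor = kerma_with_detector.kerma / kerma_reference.kerma
    rel = np.sqrt(kerma_with_detector.rel_unc ** 2
                  + kerma_reference.rel_unc ** 2)
    return pd.DataFrame({"label": kerma_with_detector.labels,
                         "distance_cm": kerma_with_detector.distances,
                         "factor": factor, "rel_unc": rel})
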