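"""Reusable experiment drivers mirroring the study's runs.

These functions are the single implementation behind the CLI, the
analysis scripts and the acceptance checks: bare-line-source response
runs in a phantom, and with/without-detector self-attenuation runs.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .analysis import (kerma_from_tally, mean_energies_from_tally,
                       response_correction, self_attenuation)
from .config import load_preset
from .geometry import homogeneous_cylinder, phantom_with_rings
from .materials import get_material
from .sources import SourceModel, get_spectrum
from .transport import RunConfig, run_transport

DETECTORS = ("LiF", "Li2B4O7", "Al2O3", "diamond", "silicon", "air")

#: detector models for the self-attenuation study: concentric shells on
#: the transverse plane.  The silicon diode is a 60 um sensitive shell
#: between 0.0225 cm substrate shells (1 mm height); LiF and Al2O3 are
#: 1 mm thick x 1 mm height shells.
_DETECTOR_STACKS = {
    "silicon": {"substrate": 0.0225, "sensitive": 0.006, "height": 0.1},
    "LiF": {"substrate": 0.0, "sensitive": 0.1, "height": 0.1},
    "Al2O3": {"substrate": 0.0, "sensitive": 0.1, "height": 0.1},
}


def response_run(preset_name: str, detectors=DETECTORS,
                 n_histories: int | None = None, seed: int | None = None):
    """Run a packaged preset and compute R for the requested detectors.

    Returns (tally, dict detector -> ResponseTable, mean-energy frame).
    """
    overrides = {}
    if n_histories is not None:
        overrides["n_histories"] = int(n_histories)
    if seed is not None:
        overrides["seed"] = int(seed)
    cfg = load_preset(preset_name, **overrides)
    tally = run_transport(cfg)
    water = get_material("water")
    k_wat = kerma_from_tally(tally, water)
    tables = {}
    for name in detectors:
        det = get_material(name)
        tables[name] = response_correction(
            kerma_from_tally(tally, det), k_wat, det, water)
    energies = mean_energies_from_tally(tally, [water])
    return tally, tables, energies


def self_attenuation_factor(detector: str, source_id: str = "I125_TG43U1",
                            distance: float = 1.0,
                            n_histories: int = 1_000_000, seed: int = 1,
                            phantom: str = "water") -> pd.DataFrame:
    """Self-attenuation of a shell-modeled detector at one distance.

    Runs the source twice -- detector modeled, and homogeneous phantom --
    and returns kerma(with detector) / kerma(without) scored in the
    sensitive shell, with 1-sigma uncertainty.
    """
    if detector not in _DETECTOR_STACKS:
        raise ValueError(f"no shell model for detector {detector!r}")
    stack = _DETECTOR_STACKS[detector]
    det_mat = get_material(detector)
    ph = get_material(phantom)
    spectrum = get_spectrum(source_id)
    src = SourceModel(kind="bare_line", spectrum=spectrum, active_length=0.3)

    half_sens = stack["sensitive"] / 2.0
    sub = stack["substrate"]
    half_h = stack["height"] / 2.0
    sens = (f"{detector}_sensitive", distance - half_sens,
            distance + half_sens, -half_h, half_h)
    rings = [(distance - half_sens, distance + half_sens, det_mat)]
    if sub > 0:
        rings = [(distance - half_sens - sub, distance - half_sens, det_mat),
                 rings[0],
                 (distance + half_sens, distance + half_sens + sub, det_mat)]

    det_cfg = RunConfig(
        n_histories=n_histories, seed=seed, source=src,
        geometry=phantom_with_rings(ph, rings, ring_half_height=half_h),
        extra_shells=(sens,))
    ref_cfg = RunConfig(
        n_histories=n_histories, seed=seed + 1, source=src,
        geometry=homogeneous_cylinder(ph), extra_shells=(sens,))

    k_det = kerma_from_tally(run_transport(det_cfg), det_mat)
    k_ref = kerma_from_tally(run_transport(ref_cfg), det_mat)
    df = self_attenuation(k_det, k_ref)
    df.insert(0, "detector", detector)
    df["distance_cm"] = distance
    return df


def phantom_ratio_run(source_id: str, detectors=DETECTORS,
                      n_histories: int = 500_000, seed: int = 1):
    """R in PMMA and polystyrene relative to water, per detector/distance."""
    prefix = "i125" if source_id.upper().startswith("I125") else "yb169"
    _t, r_wat, _e = response_run(f"{prefix}_water", detectors,
                                 n_histories, seed)
    out = {}
    for phantom in ("pmma", "polystyrene"):
        _t, r_sol, _e = response_run(f"{prefix}_{phantom}", detectors,
                                     n_histories, seed + 1)
        from .analysis import phantom_response_ratio

        out[phantom] = {d: phantom_response_ratio(r_sol[d], r_wat[d])
                        for d in detectors}
    return out
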