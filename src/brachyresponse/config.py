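"""YAML run configuration: one dialect for every experiment.

Schema (units in key names)::

    run:     {n_histories: int, seed: int, batches: 10, pcut_keV: 1.0}
    source:  {id: I125_TG43U1|YB169|CO60, kind: bare_line|point|parallel_beam,
              active_length_cm: 0.3, beam_radius_cm: null}
    phantom: {material: water, radius_cm: 20.0, height_cm: 40.0}
    detector_rings:            # optional heterogeneity on the transverse plane
      height_cm: 0.1
      rings: [{material: silicon, r_inner_cm: ..., r_outer_cm: ...}, ...]
    tally:   {distances_cm: [...], thickness_cm: 0.05, height_cm: 0.05,
              energy_bin_keV: 0.5,
              extra_shells: [{label: ..., r1: ..., r2: ..., z1: ..., z2: ...}]}

Packaged presets (water/PMMA/polystyrene phantoms for both sources) live
under ``data/presets`` and are loaded with :func:`load_preset`.
"""
from __future__ import annotations

from pathlib import Path

import yaml

from .geometry import homogeneous_cylinder, phantom_with_rings
from .materials import get_material
from .sources import SourceModel, get_spectrum
from .transport import RunConfig

PRESET_DIR = Path(__file__).parent / "data" / "presets"


class ConfigError(ValueError):
    pass


def _require(mapping, key, context):
    if not isinstance(mapping, dict) or key not in mapping:
        raise ConfigError(f"missing required field '{key}' in '{context}'")
    return mapping[key]


def config_from_dict(doc: dict) -> RunConfig:
    run = _require(doc, "run", "config")
    n_hist = int(_require(run, "n_histories", "run"))
    seed = _require(run, "seed", "run")
    if seed is None:
        raise ConfigError("missing required field 'seed' in 'run'")

    src = _require(doc, "source", "config")
    spectrum = get_spectrum(str(_require(src, "id", "source")))
    model = SourceModel(kind=str(src.get("kind", "bare_line")),
                        spectrum=spectrum,
                        active_length=float(src.get("active_length_cm", 0.3)),
                        beam_radius=src.get("beam_radius_cm"),
                        beam_z=float(src.get("beam_z_cm", 0.0)))

    ph = _require(doc, "phantom", "config")
    phantom = get_material(str(_require(ph, "material", "phantom")))
    radius = float(ph.get("radius_cm", 20.0))
    height = float(ph.get("height_cm", 40.0))
    rings_doc = doc.get("detector_rings")
    if rings_doc:
        rings = [(float(_require(r, "r_inner_cm", "detector_rings")),
                  float(_require(r, "r_outer_cm", "detector_rings")),
                  get_material(str(_require(r, "material", "detector_rings"))))
                 for r in _require(rings_doc, "rings", "detector_rings")]
        geom = phantom_with_rings(
            phantom, rings,
            ring_half_height=float(rings_doc.get("height_cm", 0.1)) / 2.0,
            radius=radius, height=height)
    else:
        geom = homogeneous_cylinder(phantom, radius=radius, height=height)

    tally = _require(doc, "tally", "config")
    distances = tuple(float(d) for d in tally.get("distances_cm", ()))
    extra = tuple((str(_require(s, "label", "extra_shells")),
                   float(s["r1"]), float(s["r2"]),
                   float(s["z1"]), float(s["z2"]))
                  for s in tally.get("extra_shells", ()))
    return RunConfig(
        n_histories=n_hist, seed=int(seed), source=model, geometry=geom,
        distances=distances, extra_shells=extra,
        pcut=float(run.get("pcut_keV", 1.0)),
        batches=int(run.get("batches", 10)),
        bin_width=float(tally.get("energy_bin_keV", 0.5)),
        shell_thickness=float(tally.get("thickness_cm", 0.05)),
        shell_height=float(tally.get("height_cm", 0.05)))


def load_config(path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"config file {path} is not a mapping")
    return config_from_dict(doc)


def list_presets() -> list[str]:
    return sorted(p.stem for p in PRESET_DIR.glob("*.yaml"))


def load_preset(name: str, **overrides) -> RunConfig:
    """Load a packaged preset; keyword overrides patch the 'run' block."""
    path = PRESET_DIR / f"{name}.yaml"
    if not path.exists():
        raise ConfigError(
            f"unknown preset {name!r}; available: {', '.join(list_presets())}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    doc.setdefault("run", {}).update(overrides)
    return config_from_dict(doc)


def preset_dict(name: str) -> dict:
    with open(PRESET_DIR / f"{name}.yaml") as fh:
        return yaml.safe_load(fh)
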