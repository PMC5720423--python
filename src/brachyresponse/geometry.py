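"""RZ (cylindrically symmetric) region geometry.

A geometry is a grid of nested cylindrical rings times axial slabs; each
(ring, slab) cell carries one material.  ``radial_bounds`` are the outer
radii of the rings (strictly increasing, first > 0) and ``z_bounds`` the
slab edges.  Photons outside the outermost radius or the z range have
left the phantom.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class GeometryError(ValueError):
    pass


@dataclass
class RZGeometry:
    radial_bounds: np.ndarray  # outer ring radii, cm
    z_bounds: np.ndarray  # slab edges, cm
    material_index: np.ndarray  # (n_rings, n_slabs) -> index into materials
    materials: list  # material objects (duck-typed; see transport)

    @property
    def n_rings(self) -> int:
        return len(self.radial_bounds)

    @property
    def n_slabs(self) -> int:
        return len(self.z_bounds) - 1

    @property
    def outer_radius(self) -> float:
        return float(self.radial_bounds[-1])

    def locate(self, x, y, z):
        """Region indices (ir, iz) for points; -1 marks outside."""
        r = np.hypot(np.asarray(x, float), np.asarray(y, float))
        ir = np.searchsorted(self.radial_bounds, r, side="right")
        iz = np.searchsorted(self.z_bounds, np.asarray(z, float),
                             side="right") - 1
        outside = (ir >= self.n_rings) | (iz < 0) | (iz >= self.n_slabs)
        return (np.where(outside, -1, ir).astype(np.int64),
                np.where(outside, -1, iz).astype(np.int64))

    def material_at(self, x, y, z):
        ir, iz = self.locate(x, y, z)
        if np.ndim(ir) == 0:
            if ir < 0:
                return None
            return self.materials[self.material_index[ir, iz]]
        raise GeometryError("material_at takes scalar coordinates")


def build_rz_geometry(radial_bounds, z_bounds, region_material) -> RZGeometry:
    """Validate bounds and the region->material map.

    ``region_material`` maps (ring index, slab index) to a material
    object; every cell must be assigned.
    """
    rb = np.asarray(radial_bounds, dtype=float)
    zb = np.asarray(z_bounds, dtype=float)
    if rb.ndim != 1 or len(rb) < 1 or rb[0] <= 0 or np.any(np.diff(rb) <= 0):
        raise GeometryError("radial_bounds must be strictly increasing, > 0")
    if zb.ndim != 1 or len(zb) < 2 or np.any(np.diff(zb) <= 0):
        raise GeometryError("z_bounds must be strictly increasing")
    n_r, n_z = len(rb), len(zb) - 1
    materials: list = []
    index = np.full((n_r, n_z), -1, dtype=np.int64)
    for ir in range(n_r):
        for iz in range(n_z):
            try:
                mat = region_material[(ir, iz)]
            except KeyError:
                raise GeometryError(f"region ({ir}, {iz}) has no material")
            for k, known in enumerate(materials):
                if known is mat:
                    index[ir, iz] = k
                    break
            else:
                materials.append(mat)
                index[ir, iz] = len(materials) - 1
    return RZGeometry(radial_bounds=rb, z_bounds=zb, material_index=index,
                      materials=materials)


def homogeneous_cylinder(material, radius: float = 20.0,
                         height: float = 40.0) -> RZGeometry:
    """Single-material phantom cylinder centered on the origin."""
    return build_rz_geometry([radius], [-height / 2.0, height / 2.0],
                             {(0, 0): material})


def phantom_with_rings(phantom, rings, ring_half_height: float,
                       radius: float = 20.0,
                       height: float = 40.0) -> RZGeometry:
    """Phantom with concentric material rings around the transverse plane.

    ``rings`` is a list of (r_inner, r_outer, material); the rings live in
    the axial slab |z| < ring_half_height and must be non-overlapping and
    inside the phantom radius.
    """
    edges = set()
    for r1, r2, _ in rings:
        if not (0 < r1 < r2 < radius):
            raise GeometryError("ring radii must satisfy 0 < r1 < r2 < R")
        edges.update((r1, r2))
    rb = sorted(edges) + [radius]
    zb = [-height / 2.0, -ring_half_height, ring_half_height, height / 2.0]
    region = {}
    for ir in range(len(rb)):
        r_hi = rb[ir]
        for iz in range(3):
            mat = phantom
            if iz == 1:
                for r1, r2, ring_mat in rings:
                    if r1 < r_hi <= r2:
                        mat = ring_mat
                        break
            region[(ir, iz)] = mat
    return build_rz_geometry(rb, zb, region)
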