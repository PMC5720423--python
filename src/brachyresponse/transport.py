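"""Analog photon Monte Carlo in RZ geometry with track-length tallies.

The engine transports photons only: at the source energies considered
(< 1.5 MeV) secondary electron ranges are short and collision kerma
approximates absorbed dose, so electrons are never followed.
Photoelectric absorption terminates a history; incoherent (Compton)
scattering redirects and degrades the photon using the free-electron
Klein-Nishina law; coherent (Rayleigh) scattering redirects it without
energy loss using a Thomson distribution modulated by the material's
atomic form factors.  Channel probabilities come from the packaged
partial cross sections.

Fluence is estimated with the track-length estimator: every flight
segment deposits its chord length through each thin scoring shell into
the shell's energy bin; dividing by shell volume and source photon count
gives fluence per source photon.  Histories are split into batches and
the batch spread provides the statistical uncertainty.

The free path is sampled from the residual optical depth, which is
carried across region boundaries (equivalent, by memorylessness, to
resampling at each boundary).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import RZGeometry
from .sources import SourceModel, sample_emission

ME_C2 = 510.99895  # keV
HC = 12.3984198  # keV * Angstrom
_EPS_PUSH = 1e-7  # cm, overshoot past region boundaries
_TINY = 1e-12


class TransportError(RuntimeError):
    pass


# ----------------------------------------------------------------------
# interaction samplers
# ----------------------------------------------------------------------
def _compton_scatter(energy_keV: np.ndarray, rng: np.random.Generator):
    """Vectorized Klein-Nishina sampling (Kahn-style two-branch rejection).

    Returns (scattered energy keV, scattering angle cosine).
    """
    e = np.asarray(energy_keV, dtype=float)
    alpha = e / ME_C2
    emin = 1.0 / (1.0 + 2.0 * alpha)
    a1 = np.log1p(2.0 * alpha)
    a2 = 0.5 * (1.0 - emin * emin)
    p1 = a1 / (a1 + a2)
    eps = np.empty_like(e)
    todo = np.ones(e.shape, dtype=bool)
    while todo.any():
        idx = np.nonzero(todo)[0]
        r1 = rng.random(idx.size)
        r2 = rng.random(idx.size)
        r3 = rng.random(idx.size)
        em, al = emin[idx], alpha[idx]
        trial = np.where(r1 < p1[idx],
                         em * np.exp(a1[idx] * r2),
                         np.sqrt(em * em + (1.0 - em * em) * r2))
        t = (1.0 - trial) / (al * trial)
        sin2 = t * (2.0 - t)
        accept = r3 <= 1.0 - trial * sin2 / (1.0 + trial * trial)
        ok = idx[accept]
        eps[ok] = trial[accept]
        todo[ok] = False
    cost = 1.0 - (1.0 - eps) / (alpha * eps)
    return e * eps, np.clip(cost, -1.0, 1.0)


def sample_compton(energy_keV: float, rng: np.random.Generator):
    """Sample one Compton scatter: (scattered energy keV, cos theta)."""
    e_out, cost = _compton_scatter(np.atleast_1d(float(energy_keV)), rng)
    return float(e_out[0]), float(cost[0])


class _RayleighSampler:
    """Inverse-CDF sampler for x^2 with density proportional to F^2(x).

    x = sin(theta/2)/lambda; sampling x^2 from F^2 and rejecting with the
    Thomson factor (1 + cos^2)/2 yields the form-factor-modulated
    coherent angular distribution.  With F constant the method reduces
    exactly to Thomson sampling.
    """

    def __init__(self, material, e_max_keV: float, n: int = 1024):
        y_max = (e_max_keV / HC) ** 2 * 1.0000001
        y = np.concatenate([[0.0], np.geomspace(y_max * 1e-9, y_max, n)])
        f2 = material.ff2(np.sqrt(y))
        cdf = np.concatenate([[0.0],
                              np.cumsum(0.5 * (f2[1:] + f2[:-1])
                                        * np.diff(y))])
        self._y = y
        self._cdf = cdf

    def sample(self, energy_keV: np.ndarray, rng: np.random.Generator):
        e = np.asarray(energy_keV, dtype=float)
        cost = np.empty_like(e)
        todo = np.ones(e.shape, dtype=bool)
        cap = np.interp((e / HC) ** 2, self._y, self._cdf)
        while todo.any():
            idx = np.nonzero(todo)[0]
            u = rng.random(idx.size) * cap[idx]
            y = np.interp(u, self._cdf, self._y)
            c = 1.0 - 2.0 * y * (HC / e[idx]) ** 2
            accept = rng.random(idx.size) <= 0.5 * (1.0 + c * c)
            ok = idx[accept]
            cost[ok] = c[accept]
            todo[ok] = False
        return np.clip(cost, -1.0, 1.0)


class _ComptonWeight:
    """Bound-Compton angular weight: the material's incoherent scattering
    function S(x), used to reject Klein-Nishina samples.  Materials
    without an ``sfunc`` (free electrons) get a flat weight."""

    def __init__(self, material, e_max_keV: float, n: int = 2048):
        x_hi = (e_max_keV / HC) * 1.0000001
        grid = np.linspace(0.0, x_hi, n)
        if hasattr(material, "sfunc"):
            w = np.asarray(material.sfunc(grid), dtype=float)
        else:
            w = np.ones_like(grid)
        self._x = grid
        self._w = w
        self._flat = np.allclose(w, w[0])

    def weight(self, x):
        return np.interp(x, self._x, self._w)

    def scatter(self, energy, rng):
        """Sample (scattered energy, cos theta) with the S(x) rejection."""
        if self._flat:
            return _compton_scatter(energy, rng)
        e_out = np.empty_like(energy)
        cost = np.empty_like(energy)
        cap = np.maximum(self.weight(energy / HC), _TINY)
        todo = np.ones(energy.shape, dtype=bool)
        while todo.any():
            idx = np.nonzero(todo)[0]
            e_new, c = _compton_scatter(energy[idx], rng)
            x = (energy[idx] / HC) * np.sqrt(0.5 * (1.0 - c))
            accept = rng.random(idx.size) * cap[idx] <= self.weight(x)
            ok = idx[accept]
            e_out[ok] = e_new[accept]
            cost[ok] = c[accept]
            todo[ok] = False
        return e_out, cost


def sample_rayleigh(material, energy_keV, rng: np.random.Generator):
    """Sample coherent-scatter angle cosine(s) for a material."""
    e = np.atleast_1d(np.asarray(energy_keV, dtype=float))
    sampler = _RayleighSampler(material, float(e.max()))
    out = sampler.sample(e, rng)
    return float(out[0]) if np.ndim(energy_keV) == 0 else out


def _rotate_directions(u: np.ndarray, cost: np.ndarray,
                       phi: np.ndarray) -> np.ndarray:
    """Rotate unit vectors by polar angle arccos(cost), azimuth phi."""
    sint = np.sqrt(np.maximum(0.0, 1.0 - cost * cost))
    # orthonormal frame around each direction
    swap = np.abs(u[:, 2]) > 0.9
    a = np.zeros_like(u)
    a[~swap, 2] = 1.0
    a[swap, 0] = 1.0
    e1 = np.cross(u, a)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(u, e1)
    out = (cost[:, None] * u
           + sint[:, None] * (np.cos(phi)[:, None] * e1
                              + np.sin(phi)[:, None] * e2))
    return out / np.linalg.norm(out, axis=1, keepdims=True)


# ----------------------------------------------------------------------
# configuration and tally containers
# ----------------------------------------------------------------------
@dataclass
class RunConfig:
    """Complete description of one transport run."""

    n_histories: int
    seed: int
    source: SourceModel
    geometry: RZGeometry
    distances: tuple = ()  # transverse-axis scoring distances, cm
    extra_shells: tuple = ()  # (label, r1, r2, z1, z2) additional tallies
    pcut: float = 1.0  # keV photon cutoff
    batches: int = 10
    bin_width: float = 0.5  # keV
    shell_thickness: float = 0.05  # cm
    shell_height: float = 0.05  # cm
    chunk_size: int = 200_000

    def __post_init__(self):
        if self.pcut < 1.0:
            raise TransportError("pcut below the 1 keV table floor")
        if self.n_histories < self.batches:
            raise TransportError("n_histories must be >= batches")
        for d in self.distances:
            if not 0 < d < self.geometry.outer_radius:
                raise TransportError(
                    f"tally distance {d} outside the phantom")

    def shell_bounds(self):
        """(labels, array of (r1, r2, z1, z2)) for all scoring shells."""
        labels, bounds = [], []
        t, h = self.shell_thickness, self.shell_height
        for d in self.distances:
            labels.append(f"d={d:g}cm")
            bounds.append((d - t / 2, d + t / 2, -h / 2, h / 2))
        for label, r1, r2, z1, z2 in self.extra_shells:
            labels.append(label)
            bounds.append((r1, r2, z1, z2))
        if not labels:
            raise TransportError("no scoring shells requested")
        return labels, np.asarray(bounds, dtype=float)


@dataclass
class FluenceTally:
    """Energy-binned track-length fluence per source photon, per shell."""

    labels: list
    shells: np.ndarray  # (n_shells, 4): r1, r2, z1, z2
    distances: list  # transverse distance per shell (None for custom)
    energy_edges: np.ndarray  # keV, len n_bins + 1
    batch_fluence: np.ndarray  # (n_batches, n_shells, n_bins)
    n_histories: int
    meta: dict = field(default_factory=dict)

    @property
    def energy_centers(self) -> np.ndarray:
        return 0.5 * (self.energy_edges[1:] + self.energy_edges[:-1])

    @property
    def fluence(self) -> np.ndarray:
        return self.batch_fluence.mean(axis=0)

    def spectrum(self, shell: int) -> np.ndarray:
        return self.fluence[shell]

    def total_fluence(self, shell: int) -> float:
        return float(self.fluence[shell].sum())

    def rel_unc_total(self, shell: int) -> float:
        """Relative 1-sigma standard error of the shell's total fluence."""
        per_batch = self.batch_fluence[:, shell, :].sum(axis=1)
        mean = per_batch.mean()
        if mean <= 0:
            return np.inf
        sem = per_batch.std(ddof=1) / np.sqrt(len(per_batch))
        return float(sem / mean)

    def shell_volume(self, shell: int) -> float:
        r1, r2, z1, z2 = self.shells[shell]
        return float(np.pi * (r2 * r2 - r1 * r1) * (z2 - z1))

    def to_csv(self, path) -> None:
        """Long-format CSV (nonzero bins only), batch-resolved."""
        with open(path, "w") as fh:
            fh.write("shell,label,distance_cm,batch,bin_low_keV,"
                     "bin_high_keV,fluence\n")
            edges = self.energy_edges
            for k in range(len(self.labels)):
                d = self.distances[k]
                dtxt = "" if d is None else f"{d:g}"
                for b in range(self.batch_fluence.shape[0]):
                    row = self.batch_fluence[b, k]
                    for i in np.nonzero(row)[0]:
                        fh.write(f"{k},{self.labels[k]},{dtxt},{b},"
                                 f"{edges[i]:g},{edges[i + 1]:g},"
                                 f"{row[i]:.9e}\n")

    @classmethod
    def from_csv(cls, path, shells=None, n_histories=0, meta=None):
        import pandas as pd

        df = pd.read_csv(path)
        labels = list(dict.fromkeys(df["label"]))
        width = float((df["bin_high_keV"] - df["bin_low_keV"]).iloc[0])
        e0 = float(df["bin_low_keV"].min())
        n_bins = int(round((df["bin_high_keV"].max() - e0) / width))
        edges = e0 + width * np.arange(n_bins + 1)
        n_batches = int(df["batch"].max()) + 1
        batch = np.zeros((n_batches, len(labels), n_bins))
        lab_idx = {lab: i for i, lab in enumerate(labels)}
        bins = np.round((df["bin_low_keV"].values - e0) / width).astype(int)
        for (lab, b, i, v) in zip(df["label"], df["batch"], bins,
                                  df["fluence"]):
            batch[int(b), lab_idx[lab], int(i)] = v
        distances = []
        for lab in labels:
            sub = df[df["label"] == lab]["distance_cm"]
            val = sub.iloc[0]
            distances.append(None if (isinstance(val, float) and np.isnan(val))
                             else float(val))
        return cls(labels=labels,
                   shells=shells if shells is not None else
                   np.zeros((len(labels), 4)),
                   distances=distances, energy_edges=edges,
                   batch_fluence=batch, n_histories=n_histories,
                   meta=meta or {})


# ----------------------------------------------------------------------
# per-material lookup tables
# ----------------------------------------------------------------------
class _MaterialLookup:
    def __init__(self, material, e_min: float, e_max: float, n: int = 2048):
        grid = np.geomspace(max(e_min, 1.0), min(e_max * 1.001, 1500.0), n)
        self.log_e = np.log(grid)
        mu_pe = np.asarray(material.coefficient("pe", grid), dtype=float)
        mu_in = np.asarray(material.coefficient("incoh", grid), dtype=float)
        mu_co = np.asarray(material.coefficient("coh", grid), dtype=float)
        total = mu_pe + mu_in + mu_co
        if np.any(total <= 0):
            raise TransportError(
                f"zero total cross section for {getattr(material, 'name', material)}")
        self.log_mu_lin = np.log(total * material.density)
        self.cum_pe = mu_pe / total
        self.cum_incoh = (mu_pe + mu_in) / total

    def mu_lin(self, energy: np.ndarray) -> np.ndarray:
        return np.exp(np.interp(np.log(energy), self.log_e, self.log_mu_lin))

    def channel_cums(self, energy: np.ndarray):
        le = np.log(energy)
        return (np.interp(le, self.log_e, self.cum_pe),
                np.interp(le, self.log_e, self.cum_incoh))


# ----------------------------------------------------------------------
# scoring
# ----------------------------------------------------------------------
def _interval_in_cylinder(r02, b, a, radius):
    """Parametric interval [tl, th] with r(t) < radius along a segment."""
    c = r02 - radius * radius
    axial = a < _TINY
    disc = b * b - a * c
    with np.errstate(invalid="ignore", divide="ignore"):
        sq = np.sqrt(np.maximum(disc, 0.0))
        tl = (-b - sq) / np.where(axial, 1.0, a)
        th = (-b + sq) / np.where(axial, 1.0, a)
    inside_axial = axial & (c < 0)
    miss = (~axial & (disc <= 0)) | (axial & (c >= 0))
    tl = np.where(inside_axial, -np.inf, np.where(miss, np.inf, tl))
    th = np.where(inside_axial, np.inf, np.where(miss, -np.inf, th))
    return tl, th


def _score_segments(batch_tally, shells, inv_volumes, zspan, rspan,
                    pos, u, s, ebin):
    """Add track lengths of segments pos -> pos + s*u to the shell tallies."""
    x0, y0, z0 = pos[:, 0], pos[:, 1], pos[:, 2]
    ux, uy, uz = u[:, 0], u[:, 1], u[:, 2]
    z_end = z0 + s * uz
    cand = (np.minimum(z0, z_end) <= zspan[1]) & \
           (np.maximum(z0, z_end) >= zspan[0])
    if not cand.any():
        return
    idx = np.nonzero(cand)[0]
    x0, y0, z0 = x0[idx], y0[idx], z0[idx]
    ux, uy, uz = ux[idx], uy[idx], uz[idx]
    s = s[idx]
    ebin = ebin[idx]
    a = ux * ux + uy * uy
    b = x0 * ux + y0 * uy
    r02 = x0 * x0 + y0 * y0
    # radial reach of each segment
    t_perp = np.clip(np.where(a > _TINY, -b / np.where(a > _TINY, a, 1.0),
                              0.0), 0.0, s)
    rmin2 = r02 + t_perp * (2 * b + t_perp * a)
    r_end2 = r02 + s * (2 * b + s * a)
    rmax2 = np.maximum(r02, r_end2)
    reach = (rmin2 <= rspan[1] ** 2) & (rmax2 >= rspan[0] ** 2)
    if not reach.any():
        return
    keep = np.nonzero(reach)[0]
    x0, y0, z0 = x0[keep], y0[keep], z0[keep]
    ux, uy, uz = ux[keep], uy[keep], uz[keep]
    s, ebin = s[keep], ebin[keep]
    a, b, r02 = a[keep], b[keep], r02[keep]

    vertical = np.abs(uz) < _TINY
    safe_uz = np.where(vertical, 1.0, uz)
    n_bins = batch_tally.shape[1]
    for k in range(len(shells)):
        r1, r2, zlo, zhi = shells[k]
        t1 = (zlo - z0) / safe_uz
        t2 = (zhi - z0) / safe_uz
        tz_lo = np.minimum(t1, t2)
        tz_hi = np.maximum(t1, t2)
        in_slab = (z0 >= zlo) & (z0 < zhi)
        tz_lo = np.where(vertical, np.where(in_slab, -np.inf, np.inf), tz_lo)
        tz_hi = np.where(vertical, np.where(in_slab, np.inf, -np.inf), tz_hi)
        ol, oh = _interval_in_cylinder(r02, b, a, r2)
        l_out = np.maximum(0.0, np.minimum(np.minimum(oh, tz_hi), s)
                           - np.maximum(np.maximum(ol, tz_lo), 0.0))
        il, ih = _interval_in_cylinder(r02, b, a, r1)
        l_in = np.maximum(0.0, np.minimum(np.minimum(ih, tz_hi), s)
                          - np.maximum(np.maximum(il, tz_lo), 0.0))
        track = l_out - l_in
        hit = track > 0
        if hit.any():
            batch_tally[k] += np.bincount(ebin[hit],
                                          weights=track[hit] * inv_volumes[k],
                                          minlength=n_bins)


# ----------------------------------------------------------------------
# main driver
# ----------------------------------------------------------------------
def run_transport(config: RunConfig) -> FluenceTally:
    """Run the analog photon transport and return the fluence tally."""
    geom = config.geometry
    e_max = config.source.spectrum.max_energy
    lookups = [_MaterialLookup(m, config.pcut, e_max)
               for m in geom.materials]
    ray_samplers = [_RayleighSampler(m, e_max) for m in geom.materials]
    compton_weights = [_ComptonWeight(m, e_max) for m in geom.materials]

    labels, shells = config.shell_bounds()
    distances = list(config.distances) + [None] * len(config.extra_shells)
    inv_volumes = 1.0 / (np.pi * (shells[:, 1] ** 2 - shells[:, 0] ** 2)
                         * (shells[:, 3] - shells[:, 2]))
    zspan = (shells[:, 2].min(), shells[:, 3].max())
    rspan = (shells[:, 0].min(), shells[:, 1].max())

    n_bins = int(np.ceil((e_max - config.pcut) / config.bin_width))
    edges = config.pcut + config.bin_width * np.arange(n_bins + 1)

    rng = np.random.default_rng(config.seed)
    per_batch = config.n_histories // config.batches
    batch_fluence = np.zeros((config.batches, len(labels), n_bins))

    for ib in range(config.batches):
        n_b = per_batch + (config.n_histories % config.batches
                           if ib == config.batches - 1 else 0)
        tally = batch_fluence[ib]
        remaining = n_b
        while remaining > 0:
            n = min(remaining, config.chunk_size)
            remaining -= n
            _run_chunk(n, config, geom, lookups, ray_samplers,
                       compton_weights, shells, inv_volumes, zspan, rspan,
                       tally, edges, rng)
        tally /= n_b

    return FluenceTally(labels=labels, shells=shells, distances=distances,
                        energy_edges=edges, batch_fluence=batch_fluence,
                        n_histories=config.n_histories,
                        meta={"seed": config.seed,
                              "n_histories": config.n_histories,
                              "batches": config.batches,
                              "pcut_keV": config.pcut,
                              "source_kind": config.source.kind})


def _run_chunk(n, config, geom, lookups, ray_samplers, compton_weights,
               shells, inv_volumes, zspan, rspan, tally, edges, rng):
    pos, u, energy, _w = sample_emission(config.source, rng, n)
    tau = rng.exponential(size=n)
    rb = geom.radial_bounds
    zb = geom.z_bounds
    mat_index = geom.material_index
    n_mat = len(geom.materials)
    e_lo, width = edges[0], edges[1] - edges[0]
    n_bins = len(edges) - 1

    while len(energy):
        x, y, z = pos[:, 0], pos[:, 1], pos[:, 2]
        r = np.hypot(x, y)
        ir = np.searchsorted(rb, r, side="right")
        iz = np.searchsorted(zb, z, side="right") - 1
        inside = (ir < len(rb)) & (iz >= 0) & (iz < len(zb) - 1)
        if not inside.all():
            pos, u, energy, tau = (arr[inside] for arr in
                                   (pos, u, energy, tau))
            if not len(energy):
                break
            x, y, z = pos[:, 0], pos[:, 1], pos[:, 2]
            r = np.hypot(x, y)
            ir, iz = ir[inside], iz[inside]
        midx = mat_index[ir, iz]

        mu = np.empty(len(energy))
        c_pe = np.empty(len(energy))
        c_in = np.empty(len(energy))
        for m in range(n_mat):
            sel = midx == m
            if sel.any():
                mu[sel] = lookups[m].mu_lin(energy[sel])
                c_pe[sel], c_in[sel] = lookups[m].channel_cums(energy[sel])

        s_int = tau / np.maximum(mu, _TINY)

        # distance to the nearest region boundary
        ux, uy, uz = u[:, 0], u[:, 1], u[:, 2]
        a = ux * ux + uy * uy
        b = x * ux + y * uy
        r_out = rb[ir]
        disc = b * b - a * (r * r - r_out * r_out)
        with np.errstate(invalid="ignore", divide="ignore"):
            t_out = np.where(a > _TINY,
                             (-b + np.sqrt(np.maximum(disc, 0.0)))
                             / np.where(a > _TINY, a, 1.0), np.inf)
        t_bound = np.where(t_out > 0, t_out, np.inf)
        has_inner = ir > 0
        if has_inner.any():
            r_in = np.where(has_inner, rb[np.maximum(ir - 1, 0)], 0.0)
            disc_in = b * b - a * (r * r - r_in * r_in)
            with np.errstate(invalid="ignore", divide="ignore"):
                t_in = np.where(
                    has_inner & (a > _TINY) & (disc_in > 0) & (b < 0),
                    (-b - np.sqrt(np.maximum(disc_in, 0.0)))
                    / np.where(a > _TINY, a, 1.0), np.inf)
            t_bound = np.minimum(t_bound, np.where(t_in > 0, t_in, np.inf))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_z = np.where(uz > _TINY, (zb[iz + 1] - z) / uz,
                           np.where(uz < -_TINY, (zb[iz] - z) / uz, np.inf))
        t_bound = np.minimum(t_bound, np.where(t_z > 0, t_z, np.inf))
        t_bound = np.maximum(t_bound, 0.0) + _EPS_PUSH

        interact = s_int < t_bound
        step = np.where(interact, s_int, t_bound)

        ebin = np.minimum(((energy - e_lo) / width).astype(np.int64),
                          n_bins - 1)
        _score_segments(tally, shells, inv_volumes, zspan, rspan,
                        pos, u, step, ebin)
        pos = pos + step[:, None] * u
        tau = np.where(interact, tau, tau - t_bound * mu)

        if interact.any():
            ii = np.nonzero(interact)[0]
            xi = rng.random(ii.size)
            pe_sel = xi < c_pe[ii]
            compton_sel = ~pe_sel & (xi < c_in[ii])
            ray_sel = ~pe_sel & ~compton_sel

            dead = np.zeros(len(energy), dtype=bool)
            dead[ii[pe_sel]] = True

            if compton_sel.any():
                ci = ii[compton_sel]
                for m in range(n_mat):
                    sel = ci[midx[ci] == m]
                    if not sel.size:
                        continue
                    e_new, cost = compton_weights[m].scatter(energy[sel], rng)
                    phi = rng.uniform(0.0, 2.0 * np.pi, sel.size)
                    u[sel] = _rotate_directions(u[sel], cost, phi)
                    energy[sel] = e_new
                    dead[sel] |= e_new < config.pcut
            if ray_sel.any():
                rix = ii[ray_sel]
                for m in range(n_mat):
                    sel = rix[midx[rix] == m]
                    if sel.size:
                        cost = ray_samplers[m].sample(energy[sel], rng)
                        phi = rng.uniform(0.0, 2.0 * np.pi, sel.size)
                        u[sel] = _rotate_directions(u[sel], cost, phi)
            tau[ii] = rng.exponential(size=ii.size)
            keep = ~dead
            pos, u, energy, tau = (arr[keep] for arr in
                                   (pos, u, energy, tau))
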