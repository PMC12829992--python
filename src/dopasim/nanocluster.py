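"""Transporter-nanocluster uptake on a single varicosity surface.

An ellipsoidal axonal varicosity (1.5 µm x 800 nm) is unfolded to a flat
1.8 µm square membrane; the extracellular box above it is 3.52 µm tall so
that the simulated extracellular volume is seven times the varicosity
volume.  Transporter capacity lives only in the membrane-adjacent voxel
layer, either dispersed over the whole surface or concentrated into eight
non-overlapping circular nanoclusters (20-160 nm diameter).  The volume-mean
uptake capacity is held at 4 µM/s in every scenario, so clustering changes
only where the same number of transporters sits, not how many there are.

Two protocols probe the consequence of clustering: a constant volumetric
drive (the space-averaged quantal release rate, ~224-228 nM/s) integrated
to steady state, and clearance of a uniform 100 nM load with no drive.
Dense clusters locally deplete dopamine, and because uptake is
concentration-dependent this lowers the effective clearance rate of the
whole box — the diffusion-limited-uptake mechanism.

Lateral boundaries are periodic (the unfolded surface is closed); top and
bottom are reflecting.  The default time step sits just below the explicit
stability bound dx²/(6 Da).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.constants import Avogadro

from . import _kernels
from .errors import ParameterError, StabilityError

__all__ = [
    "VaricositySurface",
    "ClusterLayout",
    "DriveParams",
    "NanoRecording",
    "build_layout",
    "steady_drive_run",
    "clearance_run",
    "CLUSTER_DIAMETERS_NM",
]

CLUSTER_DIAMETERS_NM = (20.0, 40.0, 80.0, 160.0)


@dataclass(frozen=True)
class VaricositySurface:
    """Unfolded varicosity membrane and its extracellular box."""

    side_um: float = 1.8
    height_um: float = 3.52
    granularity_um: float = 0.02
    Da: float = 321.7            # tortuosity-corrected diffusion, µm²/s

    def __post_init__(self):
        if min(self.side_um, self.height_um, self.granularity_um, self.Da) <= 0:
            raise ParameterError("surface dimensions must be positive")

    @property
    def nx(self) -> int:
        return int(round(self.side_um / self.granularity_um))

    @property
    def nz(self) -> int:
        return int(round(self.height_um / self.granularity_um))

    @property
    def shape(self) -> tuple:
        return (self.nx, self.nx, self.nz)

    @property
    def voxel_volume_um3(self) -> float:
        return self.granularity_um**3

    @property
    def total_volume_um3(self) -> float:
        return self.nx * self.nx * self.nz * self.voxel_volume_um3

    @property
    def max_stable_dt(self) -> float:
        return self.granularity_um**2 / (6.0 * self.Da)

    def default_dt(self) -> float:
        """90 % of the stability bound (1.86e-7 s at 20 nm grain)."""
        return 0.9 * self.max_stable_dt


@dataclass
class ClusterLayout:
    """Per-voxel transporter capacity map on the membrane layer."""

    surface: VaricositySurface
    vmax_map: np.ndarray          # (nx, nx) µM/s, membrane-adjacent layer
    centres_um: np.ndarray        # (n, 2) cluster centres, empty if dispersed
    diameter_nm: float | None     # None = dispersed
    mean_vmax_uM_s: float
    km_nM: float = 210.0

    @property
    def dispersed(self) -> bool:
        return self.diameter_nm is None

    def volume_mean_vmax(self) -> float:
        """Capacity averaged over the whole box; invariant across layouts."""
        s = self.surface
        return float(self.vmax_map.sum()) / (s.nx * s.nx * s.nz)

    def centre_voxel(self) -> tuple:
        """Surface-layer voxel under the first cluster centre (or the box
        centre when dispersed); used for the local-depletion trace."""
        s = self.surface
        if self.dispersed or not len(self.centres_um):
            return (s.nx // 2, s.nx // 2)
        i, j = np.unravel_index(int(np.argmax(self.vmax_map)),
                                self.vmax_map.shape)
        return (int(i), int(j))


def _disk_weights(surface: VaricositySurface, centres, radius_um, supersample=5):
    """Sub-voxel area-overlap weights of disks on the surface grid.

    Each voxel footprint is supersampled; the weight is the fraction of the
    footprint covered by any disk (with periodic wrap), which keeps the
    effective sink size faithful for clusters near or below the grid grain.
    """
    nx = surface.nx
    dx = surface.granularity_um
    w = np.zeros((nx, nx))
    span = int(np.ceil(radius_um / dx)) + 1
    offs = (np.arange(supersample) + 0.5) / supersample
    ox, oy = np.meshgrid(offs, offs, indexing="ij")
    for cx, cy in centres:
        i0 = int(np.floor(cx / dx))
        j0 = int(np.floor(cy / dx))
        for di in range(-span, span + 1):
            for dj in range(-span, span + 1):
                i, j = i0 + di, j0 + dj
                x = (i + ox) * dx - cx
                y = (j + oy) * dx - cy
                frac = np.count_nonzero(x**2 + y**2 <= radius_um**2) \
                    / supersample**2
                if frac:
                    w[i % nx, j % nx] += frac
    return np.minimum(w, 1.0)


def build_layout(surface: VaricositySurface | None = None,
                 diameter_nm: float | str | None = "dispersed", *,
                 n_clusters: int = 8, mean_vmax_uM_s: float = 4.0,
                 km_nM: float = 210.0, seed=0,
                 max_tries: int = 1000) -> ClusterLayout:
    """Build a capacity layout: dispersed or ``n_clusters`` non-overlapping
    disks of the given diameter, at fixed volume-mean capacity.

    The total transporter capacity (volume-mean Vmax times box volume) is
    identical for every layout; shrinking the uptake-competent footprint
    raises the per-voxel density accordingly.
    """
    surface = surface or VaricositySurface()
    nx = surface.nx
    total_capacity = mean_vmax_uM_s * nx * nx * surface.nz  # µM/s voxel units
    if diameter_nm in ("dispersed", None):
        vmax_map = np.full((nx, nx), total_capacity / (nx * nx))
        return ClusterLayout(surface, vmax_map, np.zeros((0, 2)), None,
                             mean_vmax_uM_s, km_nM)
    d_um = float(diameter_nm) * 1e-3
    if d_um > surface.side_um / np.sqrt(n_clusters):
        raise ParameterError("clusters cannot fit on the surface")
    rng = np.random.default_rng(seed)
    side = surface.side_um
    centres = []
    for _ in range(max_tries):
        c = rng.random(2) * side
        ok = True
        for p in centres:
            d = np.abs(c - p)
            d = np.minimum(d, side - d)  # periodic distance
            if np.hypot(*d) < d_um:
                ok = False
                break
        if ok:
            centres.append(c)
            if len(centres) == n_clusters:
                break
    else:
        raise ParameterError(
            f"could not place {n_clusters} non-overlapping clusters")
    centres = np.asarray(centres)
    w = _disk_weights(surface, centres, d_um / 2.0)
    vmax_map = total_capacity * w / w.sum()
    return ClusterLayout(surface, vmax_map, centres, float(diameter_nm),
                         mean_vmax_uM_s, km_nM)


@dataclass(frozen=True)
class DriveParams:
    """Constant volumetric dopamine addition emulating pacemaker release.

    The rate is the product of the quantal voxel increment (one vesicle of
    ``vesicle_molecules`` diluted into a voxel's extracellular compartment),
    firing rate, release probability and active-terminal density — the
    space-average of the stochastic release process of the tissue model.
    """

    vesicle_radius_nm: float = 25.0
    vesicle_molecules: float = 3000.0
    evf: float = 0.21
    f_rate_hz: float = 4.0
    r_pct: float = 0.06
    at_density_per_um3: float = 0.04

    @property
    def vesicle_volume_um3(self) -> float:
        return 4.0 / 3.0 * np.pi * (self.vesicle_radius_nm * 1e-3) ** 3

    def vesicle_conc_nM(self) -> float:
        litres = self.vesicle_volume_um3 * 1e-15
        return self.vesicle_molecules / Avogadro / litres * 1e9

    def q_conc_nM(self, voxel_volume_um3: float) -> float:
        """Voxel concentration increment of one fusion event."""
        return (self.vesicle_volume_um3 / voxel_volume_um3
                * self.vesicle_conc_nM() / self.evf)

    def rate_nM_s(self) -> float:
        """Volumetric addition rate (nM/s); ~228 nM/s at defaults.

        ``Q_conc * voxel_volume`` is voxel-size independent, so the rate is
        an intensive property of the tissue parameters."""
        return (self.q_conc_nM(1.0) * self.f_rate_hz * self.r_pct
                * self.at_density_per_um3)


@dataclass
class NanoRecording:
    """Volume-mean and cluster-centre traces of a varicosity run."""

    layout: ClusterLayout
    dt: float
    times: np.ndarray
    mean_trace: np.ndarray
    centre_trace: np.ndarray       # membrane voxel under a cluster centre
    final_field: np.ndarray
    time_to_target_s: float | None = None

    def surface_profile(self) -> np.ndarray:
        """Concentration along the surface-layer row through the recorded
        centre voxel (cross-section through a cluster)."""
        i, _ = self.layout.centre_voxel()
        return self.final_field[i, :, 0].copy()


def _integrate(layout: ClusterLayout, drive_nM_s: float, field, dt,
               duration_s, record_every_s, target_mean_nM=None,
               max_t_s=None):
    s = layout.surface
    if dt is None:
        dt = s.default_dt()
    if dt > s.max_stable_dt:
        raise StabilityError(
            f"dt={dt:g}s exceeds the stability bound {s.max_stable_dt:g}s "
            f"at {s.granularity_um * 1e3:.0f} nm grain")
    alpha = s.Da * dt / s.granularity_um**2
    C = np.ascontiguousarray(field, dtype=np.float64)
    buf = np.empty_like(C)
    vmax_dt = np.ascontiguousarray(layout.vmax_map * 1e3 * dt)
    ci, cj = layout.centre_voxel()
    record_every = max(1, int(round(record_every_s / dt)))
    horizon = duration_s if target_mean_nM is None else max_t_s
    n_steps = int(round(horizon / dt))
    n_rec = n_steps // record_every
    out_mean = np.zeros(n_rec)
    out_centre = np.zeros(n_rec)
    chunk = max(record_every, int(round(5e-3 / dt)) // record_every * record_every)
    rec_idx = 0
    prev = 0
    t_target = None
    while prev < n_steps:
        nsub = min(chunk, n_steps - prev)
        C, buf, rec_idx = _kernels.run_nano_chunk(
            C, buf, vmax_dt, layout.km_nM, drive_nM_s * dt, alpha,
            prev, nsub, record_every, ci, cj, out_mean, out_centre, rec_idx)
        prev += nsub
        if target_mean_nM is not None and rec_idx \
                and out_mean[rec_idx - 1] <= target_mean_nM:
            break
    times = (np.arange(rec_idx) + 1) * record_every * dt
    mean_trace = out_mean[:rec_idx]
    if target_mean_nM is not None:
        below = np.nonzero(mean_trace <= target_mean_nM)[0]
        if len(below):
            i = below[0]
            if i == 0:
                t_target = float(times[0])
            else:  # linear interpolation between records
                t0, t1 = times[i - 1], times[i]
                v0, v1 = mean_trace[i - 1], mean_trace[i]
                t_target = float(t0 + (v0 - target_mean_nM) / (v0 - v1) * (t1 - t0))
    return NanoRecording(layout, dt, times, mean_trace,
                         out_centre[:rec_idx], C, t_target)


def steady_drive_run(layout: ClusterLayout, drive: DriveParams | float | None = None,
                     duration_s: float = 0.4, *, dt: float | None = None,
                     init_nM: float | np.ndarray | None = None,
                     record_every_s: float = 1e-3) -> NanoRecording:
    """Constant uniform drive against the layout's uptake map.

    ``init_nM`` may be a scalar or a full field — passing the final field of
    a previous run switches layouts mid-experiment (e.g. unclustered
    equilibrium, then clustered).  ``drive`` defaults to the pacemaker
    rate; a plain number is taken as nM/s.
    """
    if drive is None:
        drive = DriveParams()
    rate = drive.rate_nM_s() if isinstance(drive, DriveParams) else float(drive)
    if init_nM is None:
        init_nM = 0.0
    field = init_nM if isinstance(init_nM, np.ndarray) \
        else np.full(layout.surface.shape, float(init_nM))
    return _integrate(layout, rate, field, dt, duration_s, record_every_s)


def clearance_run(layout: ClusterLayout, c0_nM: float = 100.0, *,
                  target_mean_nM: float = 5.0, max_t_s: float = 1.5,
                  dt: float | None = None,
                  record_every_s: float = 1e-3) -> NanoRecording:
    """Clear a uniform load with no drive; stops once the volume mean
    reaches ``target_mean_nM`` (or ``max_t_s``).

    ``time_to_target_s`` is the interpolated first-crossing time; it grows
    as capacity is packed into smaller, denser clusters.
    """
    field = np.full(layout.surface.shape, float(c0_nM))
    return _integrate(layout, 0.0, field, dt, None, record_every_s,
                      target_mean_nM=target_mean_nM, max_t_s=max_t_s)
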