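"""Region-level simulation experiments and summary statistics.

The central entry point is :func:`simulate`, which advances the coupled
release / uptake / diffusion (and optionally receptor-occupancy) system on a
periodic lattice and records traces, pooled percentile statistics and
threshold volumes.  The named experiments — pacemaker runs for dorsal (DS)
and ventral striatum (VS), locally induced bursts with spill-over metrics, a
firing pause with receptor read-out, parameter sweeps, and the granularity
consistency check — are thin configurations of that engine.

Region parameter sets: DS uses 4 Hz tonic firing, 6 % release probability,
3000 molecules per vesicle, D = 763 µm²/s at tortuosity 1.54, Vmax 6 µM/s,
Km 210 nM, one site per 25 µm³ from 150 neurons, EVF 0.21.  VS lowers the
site density to one per 27.8 µm³ (90 %) and the uptake capacity to 2 µM/s
(33 %), all else equal.

"Tonic" and "peak" concentrations are the 50th and 99.5th percentiles of
the pooled voxel distribution; focality is their ratio.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd

from . import _kernels
from .analytic import mean_field_steady_state
from .errors import ParameterError, StabilityError
from .lattice import DiffusionParams, UptakeParams, apparent_diffusion
from .receptors import D1, D2, ReceptorParams, occupancy_equilibrium
from .release import (
    BurstSegment,
    FiringProtocol,
    PauseSegment,
    ReleaseParams,
    build_release_events,
    place_sites,
    sample_spikes,
)

__all__ = [
    "RegionParams",
    "SummaryStats",
    "RunRecording",
    "BurstResult",
    "PauseResult",
    "GranularityResult",
    "simulate",
    "run_region",
    "burst_experiment",
    "pause_experiment",
    "sweep",
    "granularity_check",
    "DEFAULT_PERCENTILES",
]

DEFAULT_PERCENTILES = np.concatenate([np.arange(0.5, 100.0, 0.5), [99.9]])


@dataclass(frozen=True)
class RegionParams:
    """All physiological constants of one striatal subregion."""

    name: str = "DS"
    f_rate_hz: float = 4.0
    r_pct: float = 0.06
    q_molecules: float = 3000.0
    D: float = 763.0
    lam: float = 1.54
    vmax_uM_s: float = 6.0
    km_nM: float = 210.0
    density_per_um3: float = 0.04
    evf: float = 0.21
    n_neurons: int = 150

    def __post_init__(self):
        if self.f_rate_hz < 0 or not 0 <= self.r_pct <= 1 \
                or self.q_molecules <= 0 or self.vmax_uM_s < 0 \
                or self.km_nM <= 0 or self.density_per_um3 < 0 \
                or not 0 < self.evf <= 1 or self.n_neurons < 1:
            raise ParameterError(f"invalid region parameters: {self}")
        apparent_diffusion(self.D, self.lam)

    @classmethod
    def dorsal(cls, **overrides) -> "RegionParams":
        return cls(name="DS", **overrides)

    @classmethod
    def ventral(cls, **overrides) -> "RegionParams":
        """VS: terminal density reduced to 90 % (one site per 27.8 µm³) and
        uptake capacity to 33 % (2 µM/s)."""
        kw = dict(name="VS", density_per_um3=1.0 / 27.8, vmax_uM_s=2.0)
        kw.update(overrides)
        return cls(**kw)

    def replace(self, **changes) -> "RegionParams":
        return dataclasses.replace(self, **changes)

    @property
    def Da(self) -> float:
        return apparent_diffusion(self.D, self.lam)

    @property
    def k_lin(self) -> float:
        """Linearised uptake rate Vmax/Km (1/s), valid for C << Km."""
        return self.vmax_uM_s * 1e3 / self.km_nM

    def release_flux_nM_s(self) -> float:
        """Expected volumetric release rate: Q_conc * f * R * density * v."""
        rp = ReleaseParams(self.r_pct, self.q_molecules, self.evf)
        # Q_conc * voxel_volume is voxel-size independent
        return rp.q_conc_nM(1.0) * self.f_rate_hz * self.r_pct \
            * self.density_per_um3

    def mean_field_nM(self) -> float:
        """Spatially homogeneous steady state; 0 if flux exceeds capacity."""
        try:
            return mean_field_steady_state(
                self.release_flux_nM_s(), self.vmax_uM_s, self.km_nM)
        except ParameterError:
            return 0.0


@dataclass
class SummaryStats:
    """Pooled concentration statistics of a steady-state run."""

    percentiles: np.ndarray       # percent levels
    values: np.ndarray            # nM, averaged over post-burn-in snapshots
    spatial_mean: float           # nM, pooled over space and time
    volume_above_um3: float       # mean volume above threshold
    threshold_nM: float
    n_snapshots: int

    def percentile(self, p: float) -> float:
        i = int(np.argmin(np.abs(self.percentiles - p)))
        return float(self.values[i])

    @property
    def p50(self) -> float:
        return self.percentile(50.0)

    @property
    def p99_5(self) -> float:
        return self.percentile(99.5)

    @property
    def focality(self) -> float:
        """Peak-to-tonic ratio p99.5 / p50 (heterogeneity of the field)."""
        p50 = self.p50
        return float("inf") if p50 == 0 else self.p99_5 / p50


@dataclass
class RunRecording:
    """Traces and statistics of one lattice simulation."""

    params: RegionParams
    dt: float
    voxel_size: float
    shape: tuple
    burn_in_s: float
    times: np.ndarray
    mean_trace: np.ndarray
    probe_voxels: np.ndarray
    probe_conc: np.ndarray              # (n_rec, n_probes)
    stats: SummaryStats | None = None
    occ_mean: dict = dfield(default_factory=dict)     # receptor name -> trace
    probe_occ: dict = dfield(default_factory=dict)    # receptor name -> (n_rec, n_probes)
    special: dict = dfield(default_factory=dict)      # time -> snapshot metrics
    final_field: np.ndarray | None = None
    final_occ: dict = dfield(default_factory=dict)
    site_count: int = 0

    def window(self, t0: float, t1: float | None = None) -> np.ndarray:
        m = self.times >= t0
        if t1 is not None:
            m &= self.times < t1
        return m

    def mean_after(self, t0: float) -> float:
        return float(self.mean_trace[self.window(t0)].mean())

    def probe_occ_mean(self, receptor: str, t0: float) -> float:
        """Time-average of probe-voxel occupancy after ``t0``."""
        return float(self.probe_occ[receptor][self.window(t0)].mean())


_SEED_STREAMS = ("placement", "firing", "release", "burst")


def _rng_streams(seed):
    """Independent RNG streams for placement, firing, release and bursts.

    ``seed`` is an int (streams spawned from one sequence) or a dict with a
    ``base`` entry plus optional per-stream overrides, so sweeps can vary
    one source of randomness at a time.
    """
    if isinstance(seed, dict):
        base = seed.get("base", 0)
        spawned = np.random.SeedSequence(base).spawn(len(_SEED_STREAMS))
        return [
            np.random.default_rng(
                np.random.SeedSequence(seed[name]) if name in seed else s)
            for name, s in zip(_SEED_STREAMS, spawned)
        ]
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(len(_SEED_STREAMS))]


def _special_metrics(C, voxel_volume, threshold_nM):
    above = int(np.count_nonzero(C > threshold_nM))
    return {
        "mean_nM": float(C.mean()),
        "volume_above_um3": above * voxel_volume,
        "max_nM": float(C.max(initial=0.0)),
    }


def simulate(params: RegionParams, protocol: FiringProtocol, *,
             domain_um: float = 50.0, voxel_size: float = 1.0,
             dt: float = 1e-4, seed=0, receptors: bool = False,
             burn_in_s: float = 0.0, snapshot_every_s: float = 0.01,
             trace_every_s: float = 1e-3, n_probes: int = 8,
             init: str | float = "mean-field",
             percentiles: np.ndarray | None = None,
             threshold_nM: float = 100.0,
             special_times=(), keep_final: bool = False,
             active_fraction: float = 1.0,
             track_exposure_from: float | None = None,
             cube_metrics: tuple | None = None,
             d1: ReceptorParams = D1, d2: ReceptorParams = D2) -> RunRecording:
    """Advance the full model and collect statistics.

    ``special_times`` lists times (s) at which threshold-volume metrics are
    captured exactly; ``cube_metrics=(center_um, side_um)`` additionally
    records the running mean concentration of that cube at the snapshot
    cadence.  ``init`` seeds the field at the mean-field steady state
    (default), at zero, or at an explicit value, so that burn-in only has to
    absorb the heterogeneous structure, not the absolute level.
    """
    if percentiles is None:
        percentiles = DEFAULT_PERCENTILES
    shape = (max(1, int(round(domain_um / voxel_size))),) * 3
    diff = DiffusionParams(params.D, params.lam)
    bound = voxel_size**2 / (6.0 * diff.Da)
    if dt > bound:
        raise StabilityError(
            f"dt={dt:g} s exceeds the stability bound dx^2/(6 Da) = {bound:g} s")
    alpha = diff.Da * dt / voxel_size**2
    vox_vol = voxel_size**3
    rp = ReleaseParams(params.r_pct, params.q_molecules, params.evf)
    q_conc = rp.q_conc_nM(vox_vol)

    s_place, s_fire, s_release, s_burst = _rng_streams(seed)

    sites = place_sites(shape, voxel_size, params.density_per_um3,
                        params.n_neurons, s_place, active_fraction)
    spike_steps, spike_neurons = sample_spikes(
        protocol, params.n_neurons, dt, s_fire)
    ev_steps, ev_vox = build_release_events(
        sites, spike_steps, spike_neurons, params.r_pct, s_release)

    n_steps = int(round(protocol.duration_s / dt))
    # site-level burst pulses: every active site inside the cube receives the
    # pulse train on top of tonic firing
    for seg in protocol.bursts():
        mask = sites.sites_in_cube(seg.cube_center_um, seg.cube_side_um)
        mask &= sites.active_mask
        flat = sites.flat_indices()[mask]
        for t_pulse in seg.pulse_times():
            step = int(round(t_pulse / dt))
            if step >= n_steps:
                continue
            fire = s_burst.random(len(flat)) < seg.release_probability
            vox = flat[fire]
            ev_steps = np.concatenate([ev_steps, np.full(len(vox), step, dtype=np.int64)])
            ev_vox = np.concatenate([ev_vox, vox])
    order = np.argsort(ev_steps, kind="stable")
    ev_steps, ev_vox = np.ascontiguousarray(ev_steps[order]), \
        np.ascontiguousarray(ev_vox[order])

    if init == "mean-field":
        c0 = params.mean_field_nM()
    elif init == "zeros":
        c0 = 0.0
    else:
        c0 = float(init)
    C = np.full(shape, c0, dtype=np.float64)
    buf = np.empty_like(C)

    flat_sites = sites.flat_indices()
    probe_vox = flat_sites[:n_probes] if len(flat_sites) else np.zeros(1, np.int64)

    trace_every = max(1, int(round(trace_every_s / dt)))
    n_rec = n_steps // trace_every
    out_mean = np.zeros(n_rec)
    out_probe = np.zeros((n_rec, len(probe_vox)))
    if receptors:
        occ1 = occupancy_equilibrium(C, d1)
        occ2 = occupancy_equilibrium(C, d2)
        out_o1m, out_o2m = np.zeros(n_rec), np.zeros(n_rec)
        out_p1 = np.zeros((n_rec, len(probe_vox)))
        out_p2 = np.zeros((n_rec, len(probe_vox)))

    snap_every = max(1, int(round(snapshot_every_s / dt)))
    boundaries = set(range(snap_every, n_steps + 1, snap_every)) | {n_steps}
    special_steps = {}
    for t in special_times:
        st = min(max(1, int(round(t / dt))), n_steps)
        special_steps[st] = t
        boundaries.add(st)
    cube_mask = None
    if cube_metrics is not None:
        center, side = cube_metrics
        idx = np.indices(shape)
        pos = (idx + 0.5) * voxel_size
        cube_mask = np.all(
            np.abs(pos - np.asarray(center)[:, None, None, None]) <= side / 2.0,
            axis=0)
    cube_trace_t, cube_trace_v = [], []

    pct_sum = np.zeros(len(percentiles))
    vol_above_sum = 0.0
    n_snap = 0
    burn_step = int(round(burn_in_s / dt))
    special_out = {}
    exposure = None
    if track_exposure_from is not None:
        exposure = np.zeros(shape, dtype=bool)
        exposure_step = int(round(track_exposure_from / dt))

    prev = 0
    ev_ptr = 0
    rec_idx = 0
    for b in sorted(boundaries):
        nsub = b - prev
        if nsub > 0:
            if receptors:
                C, buf, ev_ptr, rec_idx = _kernels.run_lattice_chunk_occ(
                    C, buf, occ1, occ2, alpha,
                    params.vmax_uM_s * 1e3 * dt, params.km_nM, q_conc,
                    d1.kon * dt, d1.koff_s * dt, d2.kon * dt, d2.koff_s * dt,
                    ev_steps, ev_vox, ev_ptr, prev, nsub, trace_every,
                    probe_vox, out_mean, out_o1m, out_o2m,
                    out_probe, out_p1, out_p2, rec_idx)
            else:
                C, buf, ev_ptr, rec_idx = _kernels.run_lattice_chunk(
                    C, buf, alpha, params.vmax_uM_s * 1e3 * dt, params.km_nM,
                    q_conc, ev_steps, ev_vox, ev_ptr, prev, nsub, trace_every,
                    probe_vox, out_mean, out_probe, rec_idx)
        prev = b
        if exposure is not None and b >= exposure_step:
            np.logical_or(exposure, C > threshold_nM, out=exposure)
        if b in special_steps:
            m = _special_metrics(C, vox_vol, threshold_nM)
            if exposure is not None:
                m["exposed_volume_um3"] = int(np.count_nonzero(exposure)) * vox_vol
            special_out[special_steps[b]] = m
        if b % snap_every == 0 and b > burn_step:
            pct_sum += np.percentile(C, percentiles)
            vol_above_sum += np.count_nonzero(C > threshold_nM) * vox_vol
            n_snap += 1
        if cube_mask is not None:
            cube_trace_t.append(b * dt)
            cube_trace_v.append(float(C[cube_mask].mean()))

    times = (np.arange(n_rec) + 1) * trace_every * dt
    stats = None
    if n_snap:
        post = times > burn_in_s
        stats = SummaryStats(
            percentiles=percentiles, values=pct_sum / n_snap,
            spatial_mean=float(out_mean[post].mean()),
            volume_above_um3=vol_above_sum / n_snap,
            threshold_nM=threshold_nM, n_snapshots=n_snap)

    rec = RunRecording(
        params=params, dt=dt, voxel_size=voxel_size, shape=shape,
        burn_in_s=burn_in_s, times=times, mean_trace=out_mean,
        probe_voxels=probe_vox, probe_conc=out_probe, stats=stats,
        special=special_out, site_count=sites.n_sites)
    if cube_mask is not None:
        rec.special["cube_trace"] = (np.asarray(cube_trace_t),
                                     np.asarray(cube_trace_v))
    if receptors:
        rec.occ_mean = {"D1": out_o1m, "D2": out_o2m}
        rec.probe_occ = {"D1": out_p1, "D2": out_p2}
        if keep_final:
            rec.final_occ = {"D1": occ1, "D2": occ2}
    if keep_final:
        rec.final_field = C
    return rec


def run_region(params: RegionParams, duration_s: float = 10.0, *,
               domain_um: float = 50.0, burn_in_s: float = 5.0,
               seed=0, receptors: bool = False, **kw) -> RunRecording:
    """Pacemaker (tonic) run with steady-state statistics after burn-in.

    ``duration_s`` is the total simulated time; statistics pool all voxels
    over all post-burn-in snapshots.
    """
    if duration_s <= burn_in_s:
        raise ParameterError(
            f"duration {duration_s}s must exceed the burn-in {burn_in_s}s")
    protocol = FiringProtocol(params.f_rate_hz, duration_s)
    return simulate(params, protocol, domain_um=domain_um, seed=seed,
                    receptors=receptors, burn_in_s=burn_in_s, **kw)


@dataclass
class BurstResult:
    """Spill-over metrics of a locally induced burst."""

    n_pulses: int
    rate_hz: float
    cube_volume_um3: float
    burst_end_s: float
    peak_cube_mean_nM: float
    spill_ratio_end: float        # volume above threshold / cube volume
    spill_ratio_100ms: float
    baseline_ratio: float         # same metric just before the burst
    cube_times: np.ndarray
    cube_mean_trace: np.ndarray
    recording: RunRecording


def burst_experiment(params: RegionParams, n_pulses: int, rate_hz: float, *,
                     cube_side_um: float = 10.0, domain_um: float = 50.0,
                     equilibrate_s: float = 2.0, seed=0,
                     burst_release_probability: float = 1.0,
                     threshold_nM: float = 100.0, **kw) -> BurstResult:
    """Locally induced burst: every active site in a central cube receives
    ``n_pulses`` extra pulses at ``rate_hz`` on top of tonic firing.

    Spill-over is quantified as the domain volume with concentration above
    ``threshold_nM`` at the end of the burst (and 100 ms later), divided by
    the cube volume.
    """
    if domain_um < cube_side_um + 2 * 20.0:
        raise ParameterError("cube needs >= 20 µm margin inside the domain")
    center = (domain_um / 2.0,) * 3
    dt = kw.get("dt", 1e-4)
    burst_end = equilibrate_s + ((n_pulses - 1) / rate_hz if n_pulses else 0.0) + 2 * dt
    duration = burst_end + 0.15
    segs = []
    if n_pulses:
        segs = [BurstSegment(equilibrate_s, n_pulses, rate_hz, center,
                             cube_side_um, burst_release_probability)]
    protocol = FiringProtocol(params.f_rate_hz, duration, segs)
    baseline_t = max(equilibrate_s - 0.01, dt)
    rec = simulate(params, protocol, domain_um=domain_um, seed=seed,
                   burn_in_s=equilibrate_s, threshold_nM=threshold_nM,
                   special_times=(baseline_t, burst_end, burst_end + 0.1),
                   cube_metrics=(center, cube_side_um), **kw)
    cube_v = cube_side_um**3
    ct, cv = rec.special.pop("cube_trace")
    return BurstResult(
        n_pulses=n_pulses, rate_hz=rate_hz, cube_volume_um3=cube_v,
        burst_end_s=burst_end,
        peak_cube_mean_nM=float(cv.max()),
        spill_ratio_end=rec.special[burst_end]["volume_above_um3"] / cube_v,
        spill_ratio_100ms=rec.special[burst_end + 0.1]["volume_above_um3"] / cube_v,
        baseline_ratio=rec.special[baseline_t]["volume_above_um3"] / cube_v,
        cube_times=ct, cube_mean_trace=cv, recording=rec)


@dataclass
class PauseResult:
    """Mean concentration and receptor occupancy through a firing pause."""

    pause_start_s: float
    pause_end_s: float
    times: np.ndarray
    mean_trace: np.ndarray
    d1_probe: np.ndarray          # probe-site mean occupancy trace
    d2_probe: np.ndarray
    d1_domain: np.ndarray
    d2_domain: np.ndarray
    d2_baseline: float            # time-avg probe D2 occupancy pre-pause
    d2_pause_end: float           # probe D2 occupancy at pause end
    d1_baseline: float
    recording: RunRecording


def pause_experiment(params: RegionParams, pause_s: float = 1.0, *,
                     equilibrate_s: float = 10.0, recovery_s: float = 2.0,
                     domain_um: float = 50.0, seed=0, **kw) -> PauseResult:
    """Complete pause in firing after pacemaker equilibration.

    All neurons are silenced for ``pause_s``; the spatial-mean concentration
    and D1/D2 occupancies (domain mean and probe-site mean) are recorded
    through recovery.
    """
    duration = equilibrate_s + pause_s + recovery_s
    segs = [PauseSegment(equilibrate_s, pause_s)] if pause_s > 0 else []
    protocol = FiringProtocol(params.f_rate_hz, duration, segs)
    rec = simulate(params, protocol, domain_um=domain_um, seed=seed,
                   receptors=True, burn_in_s=min(equilibrate_s, 5.0), **kw)
    d1p = rec.probe_occ["D1"].mean(axis=1)
    d2p = rec.probe_occ["D2"].mean(axis=1)
    pre = rec.window(max(0.0, equilibrate_s - 2.0), equilibrate_s)
    end_i = int(np.argmin(np.abs(rec.times - (equilibrate_s + pause_s))))
    return PauseResult(
        pause_start_s=equilibrate_s, pause_end_s=equilibrate_s + pause_s,
        times=rec.times, mean_trace=rec.mean_trace,
        d1_probe=d1p, d2_probe=d2p,
        d1_domain=rec.occ_mean["D1"], d2_domain=rec.occ_mean["D2"],
        d2_baseline=float(d2p[pre].mean()), d2_pause_end=float(d2p[end_i]),
        d1_baseline=float(d1p[pre].mean()), recording=rec)


_SWEEP_AXES = ("vmax", "q", "km", "r_pct", "f_rate", "active_fraction")


def sweep(params: RegionParams, axis: str, grid, *,
          domain_um: float = 20.0, duration_s: float = 8.0,
          burn_in_s: float = 2.0, seed=0, common_random_numbers: bool = True,
          **kw) -> pd.DataFrame:
    """Summary statistics across a one-parameter grid.

    ``axis`` is one of vmax (µM/s), q (molecules), km (nM), r_pct
    (fraction), f_rate (Hz) or active_fraction; the latter fixes the
    varicosity density at one site per 9 µm³ and varies the release-capable
    fraction.  With ``common_random_numbers`` every grid point reuses the
    same seed so that only the swept factor varies.  The Km sweep also
    reports values normalised to the point closest to the region default
    (the read-out used for competitive-inhibition comparisons).
    """
    if axis not in _SWEEP_AXES:
        raise ParameterError(f"unknown sweep axis {axis!r}; one of {_SWEEP_AXES}")
    rows = []
    for i, g in enumerate(np.asarray(grid, dtype=float)):
        p = params
        frac = 1.0
        if axis == "vmax":
            p = p.replace(vmax_uM_s=g)
        elif axis == "q":
            p = p.replace(q_molecules=g)
        elif axis == "km":
            p = p.replace(km_nM=g)
        elif axis == "r_pct":
            p = p.replace(r_pct=g)
        elif axis == "f_rate":
            p = p.replace(f_rate_hz=g)
        else:
            p = p.replace(density_per_um3=1.0 / 9.0)
            frac = g
        run_seed = seed if common_random_numbers else (seed, i)
        rec = run_region(p, duration_s, domain_um=domain_um,
                         burn_in_s=burn_in_s, seed=run_seed,
                         active_fraction=frac, **kw)
        st = rec.stats
        rows.append({axis: g, "p50_nM": st.p50, "p99_5_nM": st.p99_5,
                     "focality": st.focality, "mean_nM": st.spatial_mean,
                     "volume_above_um3": st.volume_above_um3})
    df = pd.DataFrame(rows)
    if axis == "km":
        base = int(np.argmin(np.abs(df["km"] - params.km_nM)))
        for col in ("p50_nM", "p99_5_nM"):
            df[col + "_ratio"] = df[col] / df[col].iloc[base]
    return df


@dataclass
class GranularityResult:
    """Percentile agreement across voxel sizes."""

    voxel_sizes: tuple
    reference: float                       # finest voxel size
    percentiles: np.ndarray
    curves: dict                           # voxel size -> percentile curve
    deviation: dict                        # voxel size -> |rel dev| curve
    median_abs_deviation: dict             # over percentiles 5-99, as fraction


def granularity_check(params: RegionParams, voxel_sizes=(0.5, 1.0), *,
                      domain_um: float = 25.0, duration_s: float = 10.0,
                      burn_in_s: float = 4.0, seed=0, dt: float = 1e-4,
                      **kw) -> GranularityResult:
    """Run matched pacemaker simulations at several voxel sizes and compare
    pooled percentile curves against the finest one.

    The physical domain, densities and firing statistics are identical; the
    time step is reduced where the stability bound at a finer grain requires
    it.  Deviations are |relative| per percentile; the headline number is
    the median over percentiles 5-99.
    """
    voxel_sizes = tuple(sorted(voxel_sizes))
    ref = voxel_sizes[0]
    Da = apparent_diffusion(params.D, params.lam)
    curves = {}
    pct = DEFAULT_PERCENTILES
    for v in voxel_sizes:
        bound = v**2 / (6.0 * Da)
        dt_v = min(dt, 0.9 * bound)
        rec = run_region(params, duration_s, domain_um=domain_um,
                         burn_in_s=burn_in_s, seed=seed, voxel_size=v,
                         dt=dt_v, percentiles=pct, **kw)
        curves[v] = rec.stats.values
    refc = curves[ref]
    band = (pct >= 5.0) & (pct <= 99.0)
    deviation, mad = {}, {}
    for v in voxel_sizes:
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.abs(curves[v] - refc) / np.where(refc > 0, refc, np.nan)
        deviation[v] = d
        mad[v] = float(np.nanmedian(d[band]))
    return GranularityResult(voxel_sizes, ref, pct, curves, deviation, mad)
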