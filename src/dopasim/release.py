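"""Release-site geometry, stochastic firing, and quantal release.

Release sites are uniformly distributed discrete points on the lattice (at
most one per voxel), each assigned to one of ``n_neurons`` parent neurons.
Neurons fire independent Poisson spike trains at the tonic rate; on each
action potential every active site of the spiking neuron releases one
vesicle with probability ``R``.  A release event raises the concentration of
the site's voxel by the quantal increment

    Q_conc = Q / (N_A * voxel_volume * EVF)

i.e. the content of one vesicle diluted into the extracellular compartment
of a single voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd
from scipy.constants import Avogadro

from .errors import ParameterError

__all__ = [
    "ReleaseParams",
    "ReleaseSiteMap",
    "FiringProtocol",
    "PauseSegment",
    "TrainSegment",
    "BurstSegment",
    "quantal_concentration",
    "place_sites",
    "sample_spikes",
    "apply_release",
    "build_release_events",
]


def quantal_concentration(q_molecules: float, voxel_volume_um3: float,
                          evf: float) -> float:
    """Concentration increment (nM) of one fusion event in one voxel.

    ``q_molecules`` vesicle content, ``voxel_volume_um3`` the geometric voxel
    volume, ``evf`` the extracellular volume fraction that the released
    molecules actually occupy.
    """
    if q_molecules <= 0 or voxel_volume_um3 <= 0 or not 0 < evf <= 1:
        raise ParameterError("Q, voxel volume must be positive and 0 < EVF <= 1")
    litres = voxel_volume_um3 * evf * 1e-15
    return q_molecules / Avogadro / litres * 1e9  # mol/L -> nM


@dataclass(frozen=True)
class ReleaseParams:
    """Per-event release parameters."""

    r_pct: float = 0.06        # release probability per AP per site (fraction)
    q_molecules: float = 3000  # DA molecules per vesicle
    evf: float = 0.21          # extracellular volume fraction

    def __post_init__(self):
        if not 0 <= self.r_pct <= 1:
            raise ParameterError(f"release probability must be in [0,1], got {self.r_pct}")
        if self.q_molecules <= 0:
            raise ParameterError("Q must be positive")
        if not 0 < self.evf <= 1:
            raise ParameterError("EVF must be in (0,1]")

    def q_conc_nM(self, voxel_volume_um3: float) -> float:
        """Quantal concentration increment for the given voxel volume."""
        return quantal_concentration(self.q_molecules, voxel_volume_um3, self.evf)


@dataclass
class ReleaseSiteMap:
    """Voxel positions of release sites with neuron assignment."""

    site_voxels: np.ndarray    # (n, 3) int voxel indices
    neuron_of_site: np.ndarray  # (n,) int
    active_mask: np.ndarray    # (n,) bool
    density: float             # sites per µm³
    shape: tuple               # lattice shape
    voxel_size: float          # µm

    @property
    def n_sites(self) -> int:
        return self.site_voxels.shape[0]

    @property
    def n_neurons(self) -> int:
        return int(self.neuron_of_site.max()) + 1 if self.n_sites else 0

    def flat_indices(self) -> np.ndarray:
        """Flat (C-order) voxel index of each site."""
        if self.n_sites == 0:
            return np.zeros(0, dtype=np.int64)
        return np.ravel_multi_index(
            (self.site_voxels[:, 0], self.site_voxels[:, 1], self.site_voxels[:, 2]),
            self.shape,
        ).astype(np.int64)

    def sites_in_cube(self, center_um, side_um) -> np.ndarray:
        """Boolean mask of sites inside an axis-aligned cube (µm units)."""
        pos = (self.site_voxels + 0.5) * self.voxel_size
        half = side_um / 2.0
        return np.all(np.abs(pos - np.asarray(center_um)) <= half, axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "x": self.site_voxels[:, 0], "y": self.site_voxels[:, 1],
            "z": self.site_voxels[:, 2],
            "neuron": self.neuron_of_site, "active": self.active_mask.astype(int),
        })


def place_sites(shape, voxel_size: float, density: float, n_neurons: int,
                rng, active_fraction: float = 1.0) -> ReleaseSiteMap:
    """Place release sites uniformly at random, at most one per voxel.

    The number of sites is binomial with mean ``density * volume``; each site
    is assigned a parent neuron uniformly at random and is active with
    probability ``active_fraction``.
    """
    rng = np.random.default_rng(rng)
    shape = tuple(int(s) for s in shape)
    n_vox = int(np.prod(shape))
    p = density * voxel_size**3
    if p < 0:
        raise ParameterError("density must be non-negative")
    if p > 1:
        raise ParameterError(
            f"density {density}/µm³ exceeds one site per voxel at "
            f"voxel size {voxel_size} µm"
        )
    if n_neurons < 1:
        raise ParameterError("need at least one neuron")
    n_sites = int(rng.binomial(n_vox, p)) if p > 0 else 0
    flat = rng.choice(n_vox, size=n_sites, replace=False)
    vox = np.stack(np.unravel_index(flat, shape), axis=1).astype(np.int64)
    neurons = rng.integers(0, n_neurons, size=n_sites, dtype=np.int64)
    active = rng.random(n_sites) < active_fraction
    return ReleaseSiteMap(vox, neurons, active, density, shape, voxel_size)


@dataclass(frozen=True)
class PauseSegment:
    """Complete silencing of all tonic firing in [start, start+length)."""
    start: float
    length: float


@dataclass(frozen=True)
class TrainSegment:
    """Deterministic stimulation train delivered to every neuron (field
    stimulation): ``n_pulses`` pulses at ``rate_hz`` starting at ``start``."""
    start: float
    n_pulses: int
    rate_hz: float


@dataclass(frozen=True)
class BurstSegment:
    """Extra pulses delivered to all sites inside a cube, on top of tonic
    firing.  Handled at the site level by the simulation engine, not through
    the neuron raster."""
    start: float
    n_pulses: int
    rate_hz: float
    cube_center_um: tuple
    cube_side_um: float
    release_probability: float = 1.0  # synchronous, locally induced release

    def pulse_times(self) -> np.ndarray:
        return self.start + np.arange(self.n_pulses) / self.rate_hz


@dataclass
class FiringProtocol:
    """Tonic Poisson firing plus optional pause / train / burst segments."""

    tonic_rate_hz: float = 4.0
    duration_s: float = 10.0
    segments: list = dfield(default_factory=list)

    def __post_init__(self):
        if self.tonic_rate_hz < 0 or self.duration_s <= 0:
            raise ParameterError("rate must be >= 0 and duration > 0")
        for seg in self.segments:
            rate = getattr(seg, "rate_hz", 0.0)
            if rate < 0:
                raise ParameterError("segment rates must be non-negative")
        pauses = sorted(
            (s for s in self.segments if isinstance(s, PauseSegment)),
            key=lambda s: s.start,
        )
        for a, b in zip(pauses, pauses[1:]):
            if a.start + a.length > b.start:
                raise ParameterError("pause segments overlap")

    def pauses(self):
        return [s for s in self.segments if isinstance(s, PauseSegment)]

    def trains(self):
        return [s for s in self.segments if isinstance(s, TrainSegment)]

    def bursts(self):
        return [s for s in self.segments if isinstance(s, BurstSegment)]


def sample_spikes(protocol: FiringProtocol, n_neurons: int, dt: float, rng):
    """Sample the neuron-level spike raster.

    Tonic spikes are a homogeneous Poisson process per neuron, thinned to
    zero inside pause segments; train segments add one deterministic spike
    per neuron per pulse.  Burst segments act on sites, not neurons, and are
    not part of the raster.

    Returns ``(steps, neurons)`` int64 arrays sorted by step.
    """
    rng = np.random.default_rng(rng)
    if dt <= 0 or dt * protocol.tonic_rate_hz > 0.5:
        raise ParameterError("need dt > 0 and dt * rate << 1")
    n_steps = int(round(protocol.duration_s / dt))
    counts = rng.poisson(protocol.tonic_rate_hz * protocol.duration_s, size=n_neurons)
    total = int(counts.sum())
    times = rng.random(total) * protocol.duration_s
    neurons = np.repeat(np.arange(n_neurons, dtype=np.int64), counts)
    keep = np.ones(total, dtype=bool)
    for seg in protocol.pauses():
        keep &= ~((times >= seg.start) & (times < seg.start + seg.length))
    times, neurons = times[keep], neurons[keep]
    for seg in protocol.trains():
        pt = seg.start + np.arange(seg.n_pulses) / seg.rate_hz
        pt = pt[pt < protocol.duration_s]
        times = np.concatenate([times, np.tile(pt, n_neurons)])
        neurons = np.concatenate([
            neurons, np.repeat(np.arange(n_neurons, dtype=np.int64), len(pt))])
    steps = np.minimum((times / dt).astype(np.int64), n_steps - 1)
    order = np.argsort(steps, kind="stable")
    return steps[order], neurons[order]


def build_release_events(sites: ReleaseSiteMap, spike_steps, spike_neurons,
                         r_pct: float, rng):
    """Turn a spike raster into a step-sorted list of quantal events.

    For every spike of neuron ``n``, each *active* site of ``n`` releases
    independently with probability ``r_pct``.  Returns ``(steps, flat_voxel)``
    int64 arrays sorted by step.
    """
    rng = np.random.default_rng(rng)
    if sites.n_sites == 0 or len(spike_steps) == 0 or r_pct == 0:
        z = np.zeros(0, dtype=np.int64)
        return z, z.copy()
    order = np.argsort(sites.neuron_of_site, kind="stable")
    act = order[sites.active_mask[order]]
    neuron_sorted = sites.neuron_of_site[act]
    flat_sorted = sites.flat_indices()[act]
    n_neurons = int(max(sites.neuron_of_site.max(),
                        np.max(spike_neurons))) + 1
    offsets = np.searchsorted(neuron_sorted, np.arange(n_neurons + 1))
    counts = (offsets[spike_neurons + 1] - offsets[spike_neurons])
    ev_steps = np.repeat(spike_steps, counts)
    starts = offsets[spike_neurons]
    # flat site index for every (spike, site-of-neuron) pair
    idx = np.concatenate([np.arange(s, s + c) for s, c in zip(starts, counts)]) \
        if len(starts) else np.zeros(0, dtype=np.int64)
    ev_vox = flat_sorted[idx]
    fire = rng.random(len(ev_vox)) < r_pct
    ev_steps, ev_vox = ev_steps[fire], ev_vox[fire]
    order = np.argsort(ev_steps, kind="stable")
    return ev_steps[order].astype(np.int64), ev_vox[order].astype(np.int64)


def apply_release(field, sites: ReleaseSiteMap, spike_neurons,
                  params: ReleaseParams, rng):
    """Apply one step's releases to a concentration field (returns a copy).

    ``spike_neurons`` lists the neurons that spiked this step (with
    multiplicity).  Each active site of a spiking neuron independently
    releases with probability ``params.r_pct`` and deposits the quantal
    increment into its own voxel.
    """
    rng = np.random.default_rng(rng)
    out = field.copy()
    if len(spike_neurons) == 0:
        return out
    steps = np.zeros(len(spike_neurons), dtype=np.int64)
    _, vox = build_release_events(sites, steps, np.asarray(spike_neurons),
                                  params.r_pct, rng)
    if len(vox):
        q = params.q_conc_nM(field.voxel_volume)
        np.add.at(out.values.reshape(-1), vox, q)
    return out
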