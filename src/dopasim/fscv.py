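"""Fast-scan cyclic voltammetry (FSCV) read-out model.

FSCV does not observe the true concentration time course: adsorption to and
desorption from the carbon-fibre electrode low-pass filter it.  The read-out
is modelled as a causal convolution of the simulated trace with a discrete
impulse response

    IF[t] = exp(-(t + 1) * (k1 * t_s + k2 * t_o)),   t = 0, 1, 2, ...

where ``t`` counts voltammetric scans (one every ``t_s`` seconds), ``t_o``
is the oxidation time within a scan and ``k1``/``k2`` are desorption
constants.  The kernel is truncated once its tail falls below 1e-6 of the
first tap and normalised to unit sum, so steady concentrations read out
unchanged and regional comparisons are unaffected by the overall gain.

``stim_train_experiment`` reproduces electrical-stimulation train
experiments: every release site receives every pulse (field stimulation)
with the tonic per-pulse release probability, and the region-mean response
is convolved to a pseudo-FSCV trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .experiments import RegionParams, RunRecording, simulate
from .release import FiringProtocol, TrainSegment

__all__ = [
    "FSCVKernelParams",
    "impulse_kernel",
    "fscv_readout",
    "StimTrainResult",
    "stim_train_experiment",
]


@dataclass(frozen=True)
class FSCVKernelParams:
    """Scan timing and desorption constants of the recording set-up."""

    t_s: float = 0.1        # scan interval, s
    t_o: float = 0.004      # oxidation time, s
    k_minus1: float = 1.2   # desorption constant, 1/s
    k_minus2: float = 12.0  # desorption constant, 1/s

    def __post_init__(self):
        if min(self.t_s, self.t_o, self.k_minus1, self.k_minus2) <= 0:
            raise ParameterError("all FSCV kernel parameters must be positive")

    @property
    def tap_decay(self) -> float:
        """Per-scan decay factor exp(-(k1*t_s + k2*t_o))."""
        return float(np.exp(-(self.k_minus1 * self.t_s
                              + self.k_minus2 * self.t_o)))


def impulse_kernel(params: FSCVKernelParams, n_taps: int = 200) -> np.ndarray:
    """Discrete, unit-sum impulse response sampled at the scan interval.

    Taps follow ``exp(-(t+1)*(k1*t_s + k2*t_o))`` for scan index t, are
    truncated where the tail drops below 1e-6 of the first tap, and are
    normalised to unit sum (identity DC gain).
    """
    if n_taps < 1:
        raise ParameterError("need at least one tap")
    t = np.arange(n_taps)
    k = np.exp(-(t + 1) * (params.k_minus1 * params.t_s
                           + params.k_minus2 * params.t_o))
    keep = k >= 1e-6 * k[0]
    k = k[: int(np.nonzero(keep)[0].max()) + 1]
    return k / k.sum()


def fscv_readout(times: np.ndarray, trace: np.ndarray,
                 params: FSCVKernelParams | None = None):
    """Convolve a concentration trace to the FSCV scan grid.

    The trace (sampled on a uniform grid whose spacing divides the scan
    interval) is box-averaged to one sample per scan and causally convolved
    with the normalised kernel.  Returns ``(scan_times, readout)``.
    """
    params = params or FSCVKernelParams()
    times = np.asarray(times, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if len(times) < 2 or len(times) != len(trace):
        raise ParameterError("need matching time and value arrays")
    dt = times[1] - times[0]
    per_scan = params.t_s / dt
    if abs(per_scan - round(per_scan)) > 1e-6:
        raise ParameterError(
            f"trace sampling {dt:g}s must divide the scan interval "
            f"{params.t_s:g}s")
    per_scan = int(round(per_scan))
    n_scans = len(trace) // per_scan
    scans = trace[: n_scans * per_scan].reshape(n_scans, per_scan).mean(axis=1)
    kernel = impulse_kernel(params)
    out = np.convolve(scans, kernel)[:n_scans]
    scan_times = times[0] + (np.arange(n_scans) + 0.5) * params.t_s
    return scan_times, out


@dataclass
class StimTrainResult:
    """Raw and convolved region-mean response to a stimulation train."""

    region: str
    rate_hz: float
    n_pulses: int
    times: np.ndarray
    raw: np.ndarray
    scan_times: np.ndarray
    convolved: np.ndarray
    peak_raw_nM: float
    peak_convolved_nM: float
    recording: RunRecording


def stim_train_experiment(params: RegionParams, *, n_pulses: int = 120,
                          rate_hz: float = 60.0, domain_um: float = 25.0,
                          pre_s: float = 1.0, tail_s: float = 2.0, seed=0,
                          kernel: FSCVKernelParams | None = None,
                          **kw) -> StimTrainResult:
    """Field-stimulation train with pseudo-FSCV read-out.

    Every pulse is delivered to every neuron simultaneously; each site then
    releases with the region's per-action-potential probability.  Tonic
    pacemaker firing continues throughout.
    """
    kernel = kernel or FSCVKernelParams()
    train_len = (n_pulses / rate_hz) if n_pulses else 0.0
    duration = pre_s + train_len + tail_s
    segs = [TrainSegment(pre_s, n_pulses, rate_hz)] if n_pulses else []
    protocol = FiringProtocol(params.f_rate_hz, duration, segs)
    rec = simulate(params, protocol, domain_um=domain_um, seed=seed,
                   burn_in_s=min(pre_s, 1.0), **kw)
    scan_t, conv = fscv_readout(rec.times, rec.mean_trace, kernel)
    return StimTrainResult(
        region=params.name, rate_hz=rate_hz, n_pulses=n_pulses,
        times=rec.times, raw=rec.mean_trace, scan_times=scan_t,
        convolved=conv, peak_raw_nM=float(rec.mean_trace.max()),
        peak_convolved_nM=float(conv.max()), recording=rec)
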