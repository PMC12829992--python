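"""D1/D2 receptor occupancy kinetics.

Per-voxel fractional occupancy follows the bimolecular binding ODE

    d occ/dt = [DA] * kon * (1 - occ) - koff * occ

with ``kon = koff / EC50`` implied by the equilibrium constant.  Receptor
binding does not buffer the concentration field (GPCRs are expressed at low
copy number relative to transmitter).

D1 receptors are low-affinity/fast (EC50 1000 nM, koff 19.5 /s; occupancy
halves in ~36 ms after transmitter washout) and D2 receptors high-affinity/
slow (EC50 7 nM, koff 0.2 /s; halving time ~3.5 s), which is why D2
occupancy integrates dopamine over seconds while D1 tracks it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .errors import ParameterError, StabilityError

__all__ = [
    "ReceptorParams",
    "OccupancyField",
    "D1",
    "D2",
    "kon_from",
    "occupancy_equilibrium",
    "occupancy_step",
]


def kon_from(ec50_nM: float, koff_s: float) -> float:
    """Forward rate constant (nM⁻¹ s⁻¹) implied by EC50 and koff."""
    if ec50_nM <= 0 or koff_s <= 0:
        raise ParameterError("EC50 and koff must be positive")
    return koff_s / ec50_nM


@dataclass(frozen=True)
class ReceptorParams:
    """Equilibrium affinity and dissociation rate of a receptor."""

    ec50_nM: float
    koff_s: float
    name: str = "receptor"

    def __post_init__(self):
        kon_from(self.ec50_nM, self.koff_s)  # validates

    @property
    def kon(self) -> float:
        """Association rate constant, nM⁻¹ s⁻¹."""
        return kon_from(self.ec50_nM, self.koff_s)

    def with_affinity(self, ec50_nM: float) -> "ReceptorParams":
        """Same receptor at a different affinity, keeping koff fixed.

        Affinity sweeps rescale kon through the equilibrium relation while
        the measured dissociation rate is held."""
        return ReceptorParams(ec50_nM, self.koff_s, self.name)


D1 = ReceptorParams(ec50_nM=1000.0, koff_s=19.5, name="D1")
D2 = ReceptorParams(ec50_nM=7.0, koff_s=0.2, name="D2")


def occupancy_equilibrium(C_nM, params: ReceptorParams):
    """Steady-state occupancy ``C / (C + EC50)`` at constant concentration."""
    C = np.asarray(C_nM, dtype=float)
    if np.any(C < 0):
        raise ParameterError("concentration must be non-negative")
    return C / (C + params.ec50_nM)


@dataclass
class OccupancyField:
    """Per-voxel fractional occupancy of one receptor type."""

    values: np.ndarray
    receptor: ReceptorParams

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ParameterError("occupancy must lie in [0, 1]")

    @classmethod
    def zeros(cls, shape, receptor: ReceptorParams) -> "OccupancyField":
        return cls(np.zeros(shape, dtype=np.float64), receptor)

    @classmethod
    def equilibrated(cls, concentration, receptor: ReceptorParams) -> "OccupancyField":
        """Occupancy field initialised at the local equilibrium of a
        concentration field (array or :class:`ConcentrationField`)."""
        values = getattr(concentration, "values", concentration)
        return cls(occupancy_equilibrium(values, receptor), receptor)

    def copy(self) -> "OccupancyField":
        return OccupancyField(self.values.copy(), self.receptor)


def occupancy_step(occ: OccupancyField, concentration, dt: float) -> OccupancyField:
    """One explicit-Euler step of the occupancy ODE against a concentration
    field; occupancy stays in [0, 1]."""
    values = getattr(concentration, "values", concentration)
    values = np.asarray(values, dtype=np.float64)
    p = occ.receptor
    if dt * (p.kon * float(values.max(initial=0.0)) + p.koff_s) >= 1.0:
        raise StabilityError(
            "dt too large for explicit occupancy update: "
            "dt * (kon*max[DA] + koff) must be < 1"
        )
    out = occ.copy()
    _kernels.occupancy_update(out.values, values, p.kon * dt, p.koff_s * dt)
    return out
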