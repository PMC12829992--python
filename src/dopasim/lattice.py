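"""Voxelised concentration field and the deterministic physics operators.

The extracellular dopamine concentration lives on a regular 3-D lattice with
periodic boundaries on all axes.  Two operators act on it:

* explicit finite-difference diffusion with the standard 7-point Laplacian
  stencil, using the apparent diffusion coefficient ``Da = D / lambda**2``
  that corrects the free coefficient for extracellular tortuosity, and
* Michaelis-Menten reuptake, ``dC = -Vmax * C / (Km + C) * dt``, floored at
  zero so that an explicit step can never drive a voxel negative.

Units: concentrations nM, lengths µm, time s, D in µm²/s, Vmax in µM/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .errors import ParameterError, StabilityError

__all__ = [
    "ConcentrationField",
    "DiffusionParams",
    "UptakeParams",
    "apparent_diffusion",
    "max_stable_dt",
    "diffusion_step",
    "uptake_step",
]


def apparent_diffusion(D: float, lam: float) -> float:
    """Apparent diffusion coefficient ``D / lam**2`` in a tortuous medium.

    Parameters
    ----------
    D : free diffusion coefficient (µm²/s), must be positive.
    lam : tortuosity, dimensionless, >= 1.
    """
    if D <= 0:
        raise ParameterError(f"diffusion coefficient must be positive, got {D}")
    if lam < 1:
        raise ParameterError(f"tortuosity must be >= 1, got {lam}")
    return D / lam**2


@dataclass(frozen=True)
class DiffusionParams:
    """Free diffusion coefficient and tortuosity of the extracellular space."""

    D: float = 763.0      # µm²/s
    lam: float = 1.54     # dimensionless

    def __post_init__(self):
        apparent_diffusion(self.D, self.lam)  # validates

    @property
    def Da(self) -> float:
        """Apparent (tortuosity-corrected) diffusion coefficient, µm²/s."""
        return apparent_diffusion(self.D, self.lam)


@dataclass(frozen=True)
class UptakeParams:
    """Michaelis-Menten transporter kinetics.

    ``vmax_uM_s`` may be a scalar (spatially uniform capacity) or an array
    broadcastable to the field shape (per-voxel capacity map).
    """

    vmax_uM_s: float | np.ndarray = 6.0
    km_nM: float = 210.0

    def __post_init__(self):
        if np.any(np.asarray(self.vmax_uM_s) < 0):
            raise ParameterError("Vmax must be non-negative everywhere")
        if self.km_nM <= 0:
            raise ParameterError(f"Km must be positive, got {self.km_nM}")

    @property
    def uniform(self) -> bool:
        return np.ndim(self.vmax_uM_s) == 0


@dataclass
class ConcentrationField:
    """3-D extracellular concentration lattice (nM) with periodic topology."""

    values: np.ndarray
    voxel_size: float           # µm
    boundary: str = field(default="periodic")

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ParameterError("concentration field must be 3-D")
        if self.voxel_size <= 0:
            raise ParameterError("voxel size must be positive")
        if self.boundary != "periodic":
            raise ParameterError("only periodic boundaries are supported")
        if np.any(self.values < 0):
            raise ParameterError("concentrations must be non-negative")

    @classmethod
    def zeros(cls, shape, voxel_size: float) -> "ConcentrationField":
        return cls(np.zeros(shape, dtype=np.float64), voxel_size)

    @classmethod
    def uniform(cls, shape, voxel_size: float, value: float) -> "ConcentrationField":
        return cls(np.full(shape, float(value), dtype=np.float64), voxel_size)

    @property
    def shape(self):
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel, µm³."""
        return self.voxel_size**3

    @property
    def total_volume(self) -> float:
        return self.values.size * self.voxel_volume

    def copy(self) -> "ConcentrationField":
        return ConcentrationField(self.values.copy(), self.voxel_size)


def max_stable_dt(field: ConcentrationField, params: DiffusionParams) -> float:
    """Largest stable explicit-Euler step, ``dx**2 / (6 * Da)`` in 3-D."""
    return field.voxel_size**2 / (6.0 * params.Da)


def diffusion_step(field: ConcentrationField, params: DiffusionParams,
                   dt: float) -> ConcentrationField:
    """One explicit diffusion step; conserves total concentration.

    Raises :class:`StabilityError` if ``dt`` exceeds the 3-D stability bound
    ``dx**2 / (6 Da)``.
    """
    bound = max_stable_dt(field, params)
    if dt > bound:
        raise StabilityError(
            f"dt={dt:g} s exceeds the explicit-Euler stability bound "
            f"dx^2/(6 Da) = {bound:g} s"
        )
    alpha = params.Da * dt / field.voxel_size**2
    out = np.empty_like(field.values)
    _kernels.diffuse_periodic(field.values, out, alpha)
    return ConcentrationField(out, field.voxel_size)


def uptake_step(field: ConcentrationField, params: UptakeParams,
                dt: float) -> ConcentrationField:
    """One Michaelis-Menten uptake step, floored at zero."""
    if dt <= 0:
        raise ParameterError("dt must be positive")
    out = np.empty_like(field.values)
    km = float(params.km_nM)
    if params.uniform:
        _kernels.mm_uptake(field.values, out, float(params.vmax_uM_s) * 1e3 * dt, km)
    else:
        vmax_dt = np.broadcast_to(
            np.asarray(params.vmax_uM_s, dtype=np.float64) * 1e3 * dt,
            field.values.shape,
        ).copy()
        _kernels.mm_uptake_map(field.values, out, vmax_dt, km)
    return ConcentrationField(out, field.voxel_size)
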