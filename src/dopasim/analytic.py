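"""Closed-form references used to validate the lattice simulator.

``point_source_solution`` is the classical volume-transmission solution for
an instantaneous point source in a tortuous medium with linear uptake: a
free-space Gaussian with the apparent diffusion coefficient, scaled by the
extracellular volume fraction and damped by a first-order clearance factor.
``mean_field_steady_state`` balances a spatially uniform volumetric release
flux against Michaelis-Menten uptake, ignoring diffusion (which has zero net
effect on the spatial mean under periodic boundaries).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.constants import Avogadro

from .errors import ParameterError

__all__ = ["PointSourceParams", "point_source_solution", "mean_field_steady_state"]


@dataclass(frozen=True)
class PointSourceParams:
    """Quantal point source in a tortuous medium with linear uptake."""

    q_molecules: float = 3000.0
    Da: float = 321.7        # apparent diffusion coefficient, µm²/s
    evf: float = 0.21
    k_lin: float = 0.0       # linearised uptake rate Vmax/Km, 1/s

    def __post_init__(self):
        if self.q_molecules <= 0 or self.Da <= 0 or not 0 < self.evf <= 1 \
                or self.k_lin < 0:
            raise ParameterError("invalid point-source parameters")


def point_source_solution(r_um, t_s, params: PointSourceParams):
    """Concentration (nM) at radius ``r`` and time ``t`` after one quantal
    release of ``Q`` molecules at the origin.

        C(r, t) = (Q/N_A) / (EVF * (4 pi Da t)^{3/2})
                  * exp(-r^2 / (4 Da t)) * exp(-k_lin * t)

    ``r`` and ``t`` broadcast; requires ``t > 0``.
    """
    r = np.asarray(r_um, dtype=float)
    t = np.asarray(t_s, dtype=float)
    if np.any(t <= 0):
        raise ParameterError("time must be positive")
    mol = params.q_molecules / Avogadro
    denom_um3 = params.evf * (4.0 * np.pi * params.Da * t) ** 1.5
    conc_mol_per_L = mol / (denom_um3 * 1e-15)
    out = conc_mol_per_L * 1e9 * np.exp(-r**2 / (4.0 * params.Da * t)) \
        * np.exp(-params.k_lin * t)
    return out if out.shape else float(out)


def mean_field_steady_state(flux_nM_s: float, vmax_uM_s: float,
                            km_nM: float) -> float:
    """Spatial-mean steady state of flux-in vs Michaelis-Menten uptake.

    Solves ``Vmax * C / (Km + C) = flux`` for C (nM).  Requires the flux to
    stay below the uptake capacity, otherwise no steady state exists.
    """
    vmax = vmax_uM_s * 1e3
    if flux_nM_s < 0 or vmax <= 0 or km_nM <= 0:
        raise ParameterError("flux must be >= 0; Vmax, Km positive")
    if flux_nM_s >= vmax:
        raise ParameterError(
            f"flux {flux_nM_s} nM/s >= uptake capacity {vmax} nM/s: "
            "no steady state"
        )
    return flux_nM_s * km_nM / (vmax - flux_nM_s)
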