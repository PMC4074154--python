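"""Dimensionless current analysis and Nicholson-Shain inversion for D.

For a planar electrode and a linear sweep, the current obeys

    pi*chi = i / (n F A c0 * sqrt(D * a)),      a = n F v / (R T),

and for a reversible one-electron transfer the forward-peak value of the
dimensionless current approaches pi*chi_p = 0.4463 independently of every
system parameter (Randles-Sevcik).  Solving this relation at the peak for D
gives the classical estimate implemented by
:func:`estimate_D_nicholson_shain`.  The estimate is biased whenever the
mechanism deviates from simple reversible transfer (quasi-reversible
kinetics, chemical follow-up steps), because the peak value of pi*chi then
depends on the rate constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._constants import FARADAY, GAS_CONSTANT
from .conditions import ExperimentConditions, Voltammogram
from .errors import InvalidInputError, NoPeakError

__all__ = [
    "PI_CHI_PEAK_REVERSIBLE",
    "DimensionlessQuantities",
    "sweep_rate_constant",
    "dimensionless_current",
    "rate_to_dimensionless",
    "peak_current_from_D",
    "estimate_D_nicholson_shain",
]

PI_CHI_PEAK_REVERSIBLE = 0.4463
"""Reversible-limit forward-peak value of the dimensionless current pi*chi."""


@dataclass(frozen=True)
class DimensionlessQuantities:
    """Dimensionless descriptors of a voltammetric experiment."""

    pi_chi: float
    a: float  # sweep rate constant nFv/RT, 1/s
    kappa1: float  # dimensionless follow-up rate k1/a

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise InvalidInputError("a must be positive")
        if self.kappa1 < 0:
            raise InvalidInputError("kappa1 must be nonnegative")


def sweep_rate_constant(cond: ExperimentConditions) -> float:
    """a = n F v / (R T), the characteristic sweep rate in 1/s."""
    return cond.n_electrons * FARADAY * cond.scan_rate / (GAS_CONSTANT * cond.temperature)


def dimensionless_current(i, D: float, cond: ExperimentConditions):
    """Convert current(s) in A to the dimensionless form pi*chi.

    Parameters
    ----------
    i : scalar or array of currents in A.
    D : diffusion coefficient in cm^2/s.
    cond : experimental conditions supplying n, A, c0, v, T.
    """
    if D <= 0:
        raise InvalidInputError("D must be positive")
    prefactor = (
        cond.n_electrons
        * FARADAY
        * cond.electrode_area
        * cond.bulk_concentration
        * math.sqrt(D * sweep_rate_constant(cond))
    )
    return np.asarray(i, dtype=float) / prefactor if np.ndim(i) else float(i) / prefactor


def rate_to_dimensionless(k1: float, cond: ExperimentConditions) -> float:
    """kappa1 = k1 / a with a = nFv/RT."""
    if k1 < 0:
        raise InvalidInputError("k1 must be nonnegative")
    return k1 / sweep_rate_constant(cond)


def peak_current_from_D(D: float, cond: ExperimentConditions,
                        pi_chi_p: float = PI_CHI_PEAK_REVERSIBLE) -> float:
    """Forward peak current in A implied by D under the reversible assumption."""
    if D <= 0:
        raise InvalidInputError("D must be positive")
    return pi_chi_p * (
        cond.n_electrons
        * FARADAY
        * cond.electrode_area
        * cond.bulk_concentration
        * math.sqrt(D * sweep_rate_constant(cond))
    )


def forward_peak_current(cv: Voltammogram) -> float:
    """Forward-branch peak current relative to the zero-current baseline.

    Raises :class:`NoPeakError` when the forward branch has no interior
    maximum (monotone branch).
    """
    _, i_for = cv.forward
    k = int(np.argmax(i_for))
    if k == 0 or k == len(i_for) - 1:
        raise NoPeakError("forward branch of the voltammogram is monotone")
    return float(i_for[k])


def estimate_D_nicholson_shain(cv: Voltammogram) -> float:
    """Estimate D (cm^2/s) from the forward peak current of a voltammogram.

    Inverts the dimensionless-current relation at the peak assuming the
    reversible value pi*chi_p = 0.4463.  No baseline subtraction is applied:
    the peak current is taken relative to zero.
    """
    cond = cv.conditions
    ip = forward_peak_current(cv)
    a = sweep_rate_constant(cond)
    denom = (
        PI_CHI_PEAK_REVERSIBLE
        * cond.n_electrons
        * FARADAY
        * cond.electrode_area
        * cond.bulk_concentration
    )
    return (ip / denom) ** 2 / a
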