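"""Least-squares fitting of mechanism parameters to voltammograms.

The fitted parameters are (E0, ks, D) for the quasi-reversible mechanism
and (E0, ks, k1, D) when a follow-up reaction is present.  The objective is
the sum over all target voltammograms of the squared difference between the
simulated and target currents after both traces of a pair are mapped with
the affine transformation that sends the *target* trace to [-1, 1] (its
minimum to -1, its maximum to +1).  The per-curve scaling gives small- and
large-amplitude voltammograms equal weight in the fit; deriving the map
from the target alone preserves the amplitude mismatch between simulation
and target, which is essential for identifiability: the shape of a
voltammogram depends only on dimensionless groups such as ks/sqrt(D), so a
fully amplitude-invariant objective could not pin down D at all, whereas
the peak amplitude scales with sqrt(D).  Minimization uses a bounded
quasi-Newton optimizer with Latin-hypercube multistarts; rate constants
and D are searched on a log10 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.optimize
from scipy.stats import qmc

from .conditions import Mechanism, MechanismSpec, NumericsConfig, Voltammogram
from .cvsim import simulate_cv
from .errors import (
    DegenerateTraceError,
    GridMismatchError,
    InvalidInputError,
    NumericalFailureError,
)

__all__ = ["FitResult", "scaled_sse", "fit_parameters", "fit_report"]

_LOG_PARAMS = {"ks", "k1", "D"}
_PARAM_ORDER = {
    Mechanism.E_REV: ("e0", "D"),
    Mechanism.EC: ("e0", "k1", "D"),
    Mechanism.E_QR: ("e0", "ks", "D"),
    Mechanism.E_QR_C: ("e0", "ks", "k1", "D"),
}

DEFAULT_BOUNDS = {
    "e0": (0.0, 0.7),
    "ks": (1e-4, 10.0),
    "k1": (1e-4, 1e4),
    "D": (5e-7, 1e-4),
}


def scaled_sse(sim: Voltammogram, target: Voltammogram) -> float:
    """Sum of squared current differences in the target's [-1, 1] scale.

    Both traces are transformed with the affine map that sends the target
    trace to [-1, 1] (min -> -1, max -> +1) before the squared differences
    are summed, so every target curve contributes on the same unit scale
    regardless of its raw amplitude, while an amplitude mismatch between
    simulation and target still registers as error.  Requires identical
    potential grids.
    """
    if len(sim) != len(target) or not np.allclose(
        sim.potentials, target.potentials, atol=1e-9
    ):
        raise GridMismatchError("voltammograms are not on the same potential grid")
    lo, hi = target.currents.min(), target.currents.max()
    if hi == lo:
        raise DegenerateTraceError("target current trace is constant; cannot scale to [-1, 1]")
    diff = 2.0 * (sim.currents - target.currents) / (hi - lo)
    return float(np.sum(diff**2))


@dataclass
class FitResult:
    """Outcome of a mechanism-parameter fit."""

    fitted: MechanismSpec
    objective: float
    mean_abs_error_current: float
    n_evaluations: int
    converged: bool
    per_curve_objective: np.ndarray


def _spec_from_vector(kind: Mechanism, names, z) -> MechanismSpec:
    values = {}
    for name, zi in zip(names, z):
        values[name] = 10.0**zi if name in _LOG_PARAMS else zi
    return MechanismSpec(
        kind=kind,
        e0=values["e0"],
        D=values["D"],
        ks=values.get("ks"),
        k1=values.get("k1"),
    )


def fit_parameters(
    targets: Sequence[Voltammogram],
    kind: Mechanism,
    bounds: Optional[dict] = None,
    n_starts: int = 6,
    seed: int = 0,
    numerics: Optional[NumericsConfig] = None,
    initial: Optional[MechanismSpec] = None,
) -> FitResult:
    """Fit mechanism parameters to one or more target voltammograms.

    Parameters
    ----------
    targets : voltammograms sharing one mechanism (possibly different
        concentrations and scan rates).
    kind : mechanism to fit; determines the parameter set.
    bounds : dict mapping parameter name to (low, high) in natural units;
        missing entries fall back to :data:`DEFAULT_BOUNDS`.
    n_starts : number of Latin-hypercube initializations (seeded).
    numerics : solver settings used for every trial simulation.
    initial : optional explicit starting point, run in addition to the
        Latin-hypercube starts.

    Returns the best local optimum over all starts; if the optimizer failed
    to converge everywhere, the best iterate found is still returned with
    ``converged=False``.
    """
    if not targets:
        raise InvalidInputError("need at least one target voltammogram")
    names = _PARAM_ORDER[kind]
    merged = dict(DEFAULT_BOUNDS)
    if bounds:
        merged.update(bounds)
    lo = np.array([
        math.log10(merged[p][0]) if p in _LOG_PARAMS else merged[p][0] for p in names
    ])
    hi = np.array([
        math.log10(merged[p][1]) if p in _LOG_PARAMS else merged[p][1] for p in names
    ])

    n_eval = 0

    def objective(z: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        try:
            spec = _spec_from_vector(kind, names, z)
        except Exception:
            return 1e12
        total = 0.0
        for tgt in targets:
            try:
                sim = simulate_cv(spec, tgt.conditions, numerics)
                total += scaled_sse(sim, tgt)
            except (NumericalFailureError, DegenerateTraceError):
                return 1e12
        return total

    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    starts = lo + sampler.random(n_starts) * (hi - lo)
    if initial is not None:
        z_init = np.array([
            math.log10(getattr(initial, p)) if p in _LOG_PARAMS else getattr(initial, p)
            for p in names
        ])
        starts = np.vstack([z_init, starts])

    best_z, best_obj, any_converged = None, math.inf, False
    for z0 in starts:
        res = scipy.optimize.minimize(
            objective,
            z0,
            method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
            options={"maxiter": 60, "eps": 1e-4},
        )
        if res.fun < best_obj:
            best_z, best_obj = res.x, float(res.fun)
            any_converged = bool(res.success)

    assert best_z is not None
    spec = _spec_from_vector(kind, names, best_z)
    per_curve = []
    abs_errs = []
    for tgt in targets:
        sim = simulate_cv(spec, tgt.conditions, numerics)
        per_curve.append(scaled_sse(sim, tgt))
        abs_errs.append(np.mean(np.abs(sim.currents - tgt.currents)))
    return FitResult(
        fitted=spec,
        objective=best_obj,
        mean_abs_error_current=float(np.mean(abs_errs)),
        n_evaluations=n_eval,
        converged=any_converged,
        per_curve_objective=np.asarray(per_curve),
    )


def fit_report(result: FitResult) -> str:
    """Human-readable summary of a fit, one parameter per line."""
    spec = result.fitted
    lines = [
        f"mechanism: {spec.kind.value}",
        f"E0 = {spec.e0:.6g} V",
    ]
    if spec.ks is not None:
        lines.append(f"ks = {spec.ks:.6g} cm/s")
    if spec.k1 is not None:
        lines.append(f"k1 = {spec.k1:.6g} 1/s")
    lines += [
        f"D = {spec.D:.6g} cm^2/s",
        f"objective (scaled SSE) = {result.objective:.6g}",
        f"mean |i_sim - i_target| = {result.mean_abs_error_current:.6g} A",
        f"evaluations = {result.n_evaluations}",
        f"converged = {result.converged}",
        "per-curve scaled SSE: "
        + ", ".join(f"{v:.4g}" for v in result.per_curve_objective),
    ]
    return "\n".join(lines)
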