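"""Finite-difference simulation of cyclic voltammograms.

Solves 1-D semi-infinite diffusion for the species of an electrode reaction

    A  =  B + n e-      (electron transfer at the electrode, x = 0)
    B  ->  C            (first-order homogeneous follow-up, rate k1)

with equal diffusion coefficients, a Crank-Nicolson scheme in time and an
exponentially expanding spatial grid.  The electrode boundary condition is
either a Nernst equilibrium (reversible kinds) or Butler-Volmer kinetics
(quasi-reversible kinds); the homogeneous follow-up reaction is treated
fully implicitly inside the same linear system, which keeps the scheme
stable up to k1 of order 10^3 s^-1 at the default time step.

Sign convention: the oxidation current on the forward (anodic) sweep is
positive.
"""

from __future__ import annotations

import math

import numpy as np
import scipy.sparse
from scipy.linalg import solve_banded

from ._constants import FARADAY, GAS_CONSTANT
from .conditions import (
    ExperimentConditions,
    MechanismSpec,
    NumericsConfig,
    Voltammogram,
    potential_waveform,
)
from .errors import NumericalFailureError

__all__ = ["simulate_cv", "SimulationState"]

_PHI_CLIP = 60.0  # dimensionless overpotential clip; exp(60) is far past any physical window


def _spatial_grid(num: NumericsConfig, width: float) -> tuple[np.ndarray, np.ndarray]:
    """Node positions and spacings of the expanding grid on [0, width]."""
    n = num.n_space_nodes
    g = num.grid_expansion
    if g == 1.0:
        h = np.full(n - 1, width / (n - 1))
    else:
        h0 = width * (g - 1.0) / (g ** (n - 1) - 1.0)
        h = h0 * g ** np.arange(n - 1)
    x = np.concatenate([[0.0], np.cumsum(h)])
    return x, h


class SimulationState:
    """Concentration profiles retained after a simulation (for diagnostics).

    Attributes
    ----------
    x : node positions (cm)
    profiles : array (n_times, n_species, n_nodes) of concentrations, stored
        only when ``keep_profiles`` is requested from :func:`simulate_cv`.
    species : tuple of species labels
    """

    def __init__(self, x: np.ndarray, species: tuple[str, ...]):
        self.x = x
        self.species = species
        self.profiles: list[np.ndarray] = []

    def total_moles(self) -> np.ndarray:
        """Trapezoidal integral of the summed concentrations at each stored time."""
        out = []
        for p in self.profiles:
            out.append(np.trapezoid(p.sum(axis=0), self.x))
        return np.asarray(out)


def simulate_cv(
    mech: MechanismSpec,
    cond: ExperimentConditions,
    num: NumericsConfig | None = None,
    keep_profiles: bool = False,
) -> Voltammogram | tuple[Voltammogram, SimulationState]:
    """Simulate a cyclic voltammogram for the given mechanism and conditions.

    Parameters
    ----------
    mech : mechanism kind and physical parameters (E0, ks, alpha, k1, D).
    cond : experimental conditions (scan rate, temperature, area, ...).
    num : discretization settings; defaults pass the refinement-convergence
        check (forward peak changes by < 0.1 % under grid doubling).
    keep_profiles : additionally return concentration profiles at every
        waveform sample for diagnostic use (mass-balance checks).

    Returns
    -------
    Voltammogram, with the current sampled at every waveform potential and
    ``currents[0] = 0`` (no charge has flowed at t = 0).
    """
    if num is None:
        num = NumericsConfig()
    E = potential_waveform(cond)
    n_pts = len(E)
    D = mech.D
    c_bulk = cond.bulk_concentration
    k1 = float(mech.k1) if mech.kind.has_followup and mech.k1 else 0.0
    n_species = 3 if k1 > 0.0 else 2
    nernstian = not mech.kind.quasireversible

    width = num.domain_factor * math.sqrt(D * cond.t_total)
    x, h = _spatial_grid(num, width)
    n_nodes = num.n_space_nodes
    n_unk = n_species * n_nodes
    h0 = h[0]

    dt = cond.e_step / cond.scan_rate / num.time_substeps
    nF_over_RT = cond.n_electrons * FARADAY / (GAS_CONSTANT * cond.temperature)

    # Diffusion operator on the non-uniform grid (interior nodes).
    j = np.arange(1, n_nodes - 1)
    hw, he = h[j - 1], h[j]
    aW = 2.0 * D / (hw * (hw + he))
    aE = 2.0 * D / (he * (hw + he))
    aC = -(aW + aE)

    ns = n_species
    half = 0.5 * dt
    # LHS band template: rows for interior nodes and the far (bulk) boundary;
    # electrode rows (indices 0..ns-1) are filled per time step.
    ab_template = np.zeros((2 * ns + 1, n_unk))
    u = ns  # upper bandwidth

    def band_set(i: np.ndarray, jj: np.ndarray, val: np.ndarray, ab: np.ndarray) -> None:
        ab[u + i - jj, jj] = val

    rows = ns * j  # species-A row index at interior node j
    for s in range(ns):
        i_rows = rows + s
        diag = 1.0 + half * (aW + aE)
        if s == 1:  # species B loses to C at rate k1 (fully implicit)
            diag = diag + dt * k1
        band_set(i_rows, i_rows, diag, ab_template)
        band_set(i_rows, i_rows - ns, -half * aW, ab_template)
        band_set(i_rows, i_rows + ns, -half * aE, ab_template)
        if s == 2:  # species C gains from B
            band_set(i_rows, i_rows - 1, np.full(len(i_rows), -dt * k1), ab_template)
    far = ns * (n_nodes - 1) + np.arange(ns)
    band_set(far, far, np.ones(ns), ab_template)

    # Explicit (RHS) operator as a sparse matrix: I + dt/2 * L on interior rows.
    ri, ci, vi = [], [], []
    for s in range(ns):
        i_rows = rows + s
        ri += [i_rows, i_rows, i_rows]
        ci += [i_rows, i_rows - ns, i_rows + ns]
        vi += [1.0 - half * (aW + aE), half * aW, half * aE]
    B_rhs = scipy.sparse.csr_matrix(
        (np.concatenate(vi), (np.concatenate(ri), np.concatenate(ci))),
        shape=(n_unk, n_unk),
    )

    c = np.zeros(n_unk)
    c[0::ns] = c_bulk  # species A at bulk concentration everywhere

    bulk_rhs = np.zeros(ns)
    bulk_rhs[0] = c_bulk

    beta = D / h0
    currents = np.empty(n_pts)
    currents[0] = 0.0
    nFA = cond.n_electrons * FARADAY * cond.electrode_area

    state = SimulationState(x, ("A", "B", "C")[:ns]) if keep_profiles else None
    if state is not None:
        state.profiles.append(c.reshape(n_nodes, ns).T.copy())

    for kstep in range(1, n_pts):
        e_prev, e_next = E[kstep - 1], E[kstep]
        for sub in range(1, num.time_substeps + 1):
            e_here = e_prev + (e_next - e_prev) * sub / num.time_substeps
            phi = np.clip(nF_over_RT * (e_here - mech.e0), -_PHI_CLIP, _PHI_CLIP)
            ab = ab_template.copy()
            if nernstian:
                theta = math.exp(phi)
                scale = 1.0 / (1.0 + theta)
                # cB0 - theta*cA0 = 0  (row scaled for conditioning)
                ab[u + 0 - 0, 0] = -theta * scale
                ab[u + 0 - 1, 1] = scale
                # flux balance: cA0 + cB0 - cA1 - cB1 = 0
                ab[u + 1 - 0, 0] = 1.0
                ab[u + 1 - 1, 1] = 1.0
                ab[u + 1 - ns, ns] = -1.0
                ab[u + 1 - (ns + 1), ns + 1] = -1.0
            else:
                kf = mech.ks * math.exp(mech.alpha * phi)
                kb = mech.ks * math.exp(-(1.0 - mech.alpha) * phi)
                # beta*(cA1 - cA0) - kf*cA0 + kb*cB0 = 0
                ab[u + 0 - 0, 0] = -beta - kf
                ab[u + 0 - 1, 1] = kb
                ab[u + 0 - ns, ns] = beta
                # beta*(cB1 - cB0) + kf*cA0 - kb*cB0 = 0
                ab[u + 1 - 0, 0] = kf
                ab[u + 1 - 1, 1] = -beta - kb
                ab[u + 1 - (ns + 1), ns + 1] = beta
            if ns == 3:
                # zero flux for the electro-inactive product C
                ab[u + 2 - 2, 2] = 1.0
                ab[u + 2 - (ns + 2), ns + 2] = -1.0

            rhs = B_rhs @ c
            rhs[:ns] = 0.0
            rhs[-ns:] = bulk_rhs
            try:
                c = solve_banded((ns, ns), ab, rhs)
            except Exception as exc:  # pragma: no cover - LAPACK failure path
                raise NumericalFailureError(f"banded solve failed at step {kstep}") from exc
            if not np.all(np.isfinite(c)):
                raise NumericalFailureError(f"non-finite concentrations at step {kstep}")

        if nernstian:
            flux = beta * (c[ns] - c[0])
        else:
            flux = kf * c[0] - kb * c[1]
        currents[kstep] = nFA * flux
        if state is not None:
            state.profiles.append(c.reshape(n_nodes, ns).T.copy())

    if not np.all(np.isfinite(currents)):
        raise NumericalFailureError("non-finite current in simulated voltammogram")
    cv = Voltammogram(E, currents, cond, provenance=mech)
    if keep_profiles:
        return cv, state
    return cv
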