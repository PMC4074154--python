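"""Domain types for cyclic voltammetry experiments.

The controlled experimental variables (scan rate, temperature, electrode
area, bulk concentration, electron count and the potential window) are
collected in :class:`ExperimentConditions`; the electrode-reaction model and
its physical parameters in :class:`MechanismSpec`; a simulated or measured
current/potential trace in :class:`Voltammogram`.

Units follow electrochemical convention: potentials in V, scan rate in
V s^-1, temperature in K, electrode area in cm^2, concentration in
mol cm^-3 (0.4 mmol/L == 4e-7 mol cm^-3), rate constants in cm s^-1
(heterogeneous) and s^-1 (homogeneous), diffusion coefficients in
cm^2 s^-1, currents in A.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import InvalidConditionsError, InvalidMechanismError

__all__ = [
    "Mechanism",
    "ExperimentConditions",
    "MechanismSpec",
    "NumericsConfig",
    "Voltammogram",
    "potential_waveform",
]


class Mechanism(enum.Enum):
    """Electrode reaction mechanisms.

    E_REV   reversible (Nernstian) electron transfer  A = B + e-
    E_QR    quasi-reversible electron transfer (Butler-Volmer kinetics)
    EC      reversible transfer with irreversible first-order follow-up B -> C
    E_QR_C  quasi-reversible transfer with follow-up B -> C
    """

    E_REV = "E_rev"
    E_QR = "Eqr"
    EC = "EC"
    E_QR_C = "EqrC"

    @property
    def quasireversible(self) -> bool:
        return self in (Mechanism.E_QR, Mechanism.E_QR_C)

    @property
    def has_followup(self) -> bool:
        return self in (Mechanism.EC, Mechanism.E_QR_C)


@dataclass(frozen=True)
class ExperimentConditions:
    """Controlled variables of a cyclic voltammetry experiment."""

    scan_rate: float  # V/s
    temperature: float  # K
    electrode_area: float  # cm^2
    bulk_concentration: float  # mol/cm^3
    n_electrons: int
    e_start: float  # V
    e_reverse: float  # V
    e_step: float  # V

    def __post_init__(self) -> None:
        if self.scan_rate <= 0:
            raise InvalidConditionsError("scan_rate must be positive")
        if self.temperature <= 0:
            raise InvalidConditionsError("temperature must be positive")
        if self.electrode_area <= 0:
            raise InvalidConditionsError("electrode_area must be positive")
        if self.bulk_concentration <= 0:
            raise InvalidConditionsError("bulk_concentration must be positive")
        if int(self.n_electrons) != self.n_electrons or self.n_electrons < 1:
            raise InvalidConditionsError("n_electrons must be a positive integer")
        if self.e_step <= 0:
            raise InvalidConditionsError("e_step must be positive")
        if self.e_reverse == self.e_start:
            raise InvalidConditionsError("e_reverse must differ from e_start")

    @property
    def half_steps(self) -> int:
        """Number of potential increments in one sweep direction."""
        return int(round(abs(self.e_reverse - self.e_start) / self.e_step))

    @property
    def n_points(self) -> int:
        """Number of samples in the triangular waveform (switching point once)."""
        return 2 * self.half_steps + 1

    @property
    def t_total(self) -> float:
        """Total sweep duration in seconds."""
        return 2 * abs(self.e_reverse - self.e_start) / self.scan_rate


@dataclass(frozen=True)
class MechanismSpec:
    """Mechanism kind plus its physical parameters.

    ``ks`` (heterogeneous rate constant, cm/s) is required for the
    quasi-reversible kinds; ``k1`` (first-order follow-up rate, 1/s) for the
    kinds with a chemical follow-up step.  All species share one diffusion
    coefficient ``D``.
    """

    kind: Mechanism
    e0: float  # formal potential, V
    D: float  # cm^2/s
    ks: Optional[float] = None  # cm/s
    alpha: float = 0.5
    k1: Optional[float] = None  # 1/s

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise InvalidMechanismError("D must be positive")
        if not 0 < self.alpha < 1:
            raise InvalidMechanismError("alpha must lie in (0, 1)")
        if self.kind.quasireversible:
            if self.ks is None or self.ks <= 0:
                raise InvalidMechanismError(
                    f"{self.kind.value} requires a positive heterogeneous rate ks"
                )
        if self.kind.has_followup:
            if self.k1 is None or self.k1 < 0:
                raise InvalidMechanismError(
                    f"{self.kind.value} requires a nonnegative follow-up rate k1"
                )


@dataclass(frozen=True)
class NumericsConfig:
    """Discretization settings for the diffusion solver.

    The spatial grid expands geometrically away from the electrode so the
    first node spacing is far below the diffusion-layer thickness; the domain
    extends ``domain_factor * sqrt(D * t_total)`` into solution, where the
    semi-infinite boundary is represented by bulk concentrations.  One time
    step per potential increment by default, optionally sub-stepped.
    """

    n_space_nodes: int = 140
    grid_expansion: float = 1.08
    domain_factor: float = 6.0
    time_substeps: int = 1

    def __post_init__(self) -> None:
        if self.n_space_nodes < 10:
            raise InvalidConditionsError("n_space_nodes must be >= 10")
        if self.grid_expansion < 1.0:
            raise InvalidConditionsError("grid_expansion must be >= 1")
        if self.domain_factor <= 1.0:
            raise InvalidConditionsError("domain_factor must exceed 1")
        if self.time_substeps < 1:
            raise InvalidConditionsError("time_substeps must be >= 1")

    def refined(self, factor: int = 2) -> "NumericsConfig":
        """A configuration with ``factor`` times more space nodes and substeps."""
        return NumericsConfig(
            n_space_nodes=self.n_space_nodes * factor,
            grid_expansion=self.grid_expansion ** (1.0 / factor),
            domain_factor=self.domain_factor,
            time_substeps=self.time_substeps * factor,
        )


def potential_waveform(cond: ExperimentConditions) -> np.ndarray:
    """Triangular potential sweep for the given conditions.

    The sweep runs from ``e_start`` to ``e_reverse`` in uniform steps of
    ``e_step`` and back; the switching-potential sample appears exactly once.

    Raises
    ------
    InvalidConditionsError
        If ``e_step`` does not evenly divide the potential window
        (tolerance 1e-9 V).
    """
    window = abs(cond.e_reverse - cond.e_start)
    m = cond.half_steps
    if m < 1 or abs(m * cond.e_step - window) > 1e-9:
        raise InvalidConditionsError(
            f"e_step={cond.e_step} does not evenly divide the window {window}"
        )
    sign = 1.0 if cond.e_reverse > cond.e_start else -1.0
    forward = cond.e_start + sign * cond.e_step * np.arange(m + 1)
    backward = forward[-2::-1]
    return np.concatenate([forward, backward])


@dataclass
class Voltammogram:
    """A triangular potential sweep paired with its current response."""

    potentials: np.ndarray
    currents: np.ndarray
    conditions: ExperimentConditions
    provenance: Optional[MechanismSpec] = None

    def __post_init__(self) -> None:
        self.potentials = np.asarray(self.potentials, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.potentials.shape != self.currents.shape:
            raise InvalidConditionsError("potentials and currents must have equal length")
        expected = potential_waveform(self.conditions)
        if self.potentials.shape != expected.shape or not np.allclose(
            self.potentials, expected, atol=1e-9
        ):
            raise InvalidConditionsError(
                "potentials do not form the triangular sweep implied by conditions"
            )

    def __len__(self) -> int:
        return len(self.potentials)

    @property
    def switching_index(self) -> int:
        return self.conditions.half_steps

    @property
    def forward(self) -> tuple[np.ndarray, np.ndarray]:
        """(potentials, currents) of the forward branch, switching point included."""
        k = self.switching_index
        return self.potentials[: k + 1], self.currents[: k + 1]

    @property
    def reverse(self) -> tuple[np.ndarray, np.ndarray]:
        """(potentials, currents) of the reverse branch, switching point included."""
        k = self.switching_index
        return self.potentials[k:], self.currents[k:]
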