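"""Ready-made network scenarios: a three-qubit dephasing chain and the
seven-site Fenna-Matthews-Olson (FMO) monomer.

The chain couples qubit 1 to qubit 3 through a middle qubit that may
suffer phase damping -- a minimal model of a damaged network link.  Times
and rates are in units of the hopping strength J.

The FMO monomer is the pigment-protein wire connecting the light-harvesting
antenna of green sulfur bacteria to the reaction center.  It is modelled as
seven coupled chromophore sites with the standard site-basis Hamiltonian
(in cm^-1), Markovian pure dephasing on every site and an irreversible sink
from site 3 into the reaction center.  The eighth, more recently resolved
site is not included.  Times are in picoseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assemblage import MeasurementAssembly, Scenario, pauli_measurement_set
from .dynamics import (
    LindbladModel,
    Operator,
    QuantumState,
    StateSpace,
    build_state_space,
    embed_site_operator,
)
from .units import wavenumber_to_angular_frequency

__all__ = [
    "ChainParameters",
    "FmoParameters",
    "three_qubit_chain_scenario",
    "fmo_site_hamiltonian",
    "fmo_model",
    "fmo_scenario",
    "gamma_dp_from_temperature",
]

#: Dephasing rate at the 15 K reference temperature, in cm^-1.
GAMMA_DP_AT_15K = 7.7
#: Site-3 -> reaction-center transfer rate, in cm^-1.
DEFAULT_SINK_RATE = 5.3

# 7x7 site-basis Hamiltonian of the FMO monomer in cm^-1: site energies on
# the diagonal (relative to site 3; the large ground-state offset is
# omitted), excitonic couplings off the diagonal.
_FMO_H = np.array(
    [
        [215.0, -104.1, 5.1, -4.3, 4.7, -15.1, -7.8],
        [-104.1, 220.0, 32.6, 7.1, 5.4, 8.3, 0.8],
        [5.1, 32.6, 0.0, -46.8, 1.0, -8.1, 5.1],
        [-4.3, 7.1, -46.8, 125.0, -70.7, -14.7, -61.5],
        [4.7, 5.4, 1.0, -70.7, 450.0, 89.7, -2.5],
        [-15.1, 8.3, -8.1, -14.7, 89.7, 330.0, 32.7],
        [-7.8, 0.8, 5.1, -61.5, -2.5, 32.7, 280.0],
    ]
)


@dataclass
class ChainParameters:
    """Couplings and middle-qubit dephasing of the three-qubit chain (units of J)."""

    J12: float = 1.0
    J23: float = 1.0
    gamma: float = 0.0

    def __post_init__(self):
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass
class FmoParameters:
    """FMO monomer parameters; energies and rates in cm^-1, temperature in K."""

    hamiltonian_cm1: np.ndarray = field(default_factory=lambda: _FMO_H.copy())
    gamma_dp_cm1: float = GAMMA_DP_AT_15K
    sink_rate_cm1: float = DEFAULT_SINK_RATE
    temperature: float | None = None
    convert_rates_with_2pic: bool = True

    def __post_init__(self):
        self.hamiltonian_cm1 = np.asarray(self.hamiltonian_cm1, dtype=float)
        if self.hamiltonian_cm1.shape != (7, 7):
            raise ValueError("FMO Hamiltonian must be 7x7")
        if np.abs(self.hamiltonian_cm1 - self.hamiltonian_cm1.T).max() > 0:
            raise ValueError("coupling matrix must be symmetric")
        if self.temperature is not None:
            self.gamma_dp_cm1 = gamma_dp_from_temperature(self.temperature)
        if self.gamma_dp_cm1 < 0 or self.sink_rate_cm1 < 0:
            raise ValueError("rates must be >= 0")


def three_qubit_chain_scenario(
    J12: float = 1.0,
    J23: float = 1.0,
    gamma: float = 0.0,
    target: int = 3,
) -> Scenario:
    """Chain scenario: qubit 1 excited and measured (Pauli set), qubit 2 dephased.

    The hopping Hamiltonian J12 (sigma+^1 sigma-^2 + h.c.) + J23 (...) acts
    on the 0/1-excitation sector of three qubits; phase damping of the
    middle qubit enters as a sigma_z dissipator at rate ``gamma``.
    """
    params = ChainParameters(J12, J23, gamma)
    space = build_state_space(3)
    d = space.dimension
    H = np.zeros((d, d), dtype=complex)
    i1, i2, i3 = (space.site_index(s) for s in (1, 2, 3))
    H[i1, i2] = H[i2, i1] = params.J12
    H[i2, i3] = H[i3, i2] = params.J23
    dissipators = []
    if params.gamma > 0:
        dissipators.append((params.gamma, embed_site_operator("sigma_z", 2, space)))
    model = LindbladModel(Operator(space, H), dissipators)

    rho0 = np.zeros((d, d), dtype=complex)
    rho0[i1, i1] = 1.0
    return Scenario(
        rho0=QuantumState(space, rho0),
        measured_site=1,
        target_site=int(target),
        assembly=pauli_measurement_set(),
        channel=model,
        description=f"three-qubit chain J12={params.J12} J23={params.J23} gamma={params.gamma}",
    )


def fmo_site_hamiltonian() -> np.ndarray:
    """The 7x7 FMO site-basis Hamiltonian in cm^-1 (copy)."""
    return _FMO_H.copy()


def gamma_dp_from_temperature(T: float) -> float:
    """Dephasing rate in cm^-1 at temperature T (kelvin).

    Born-Markov treatment of an Ohmic environment gives a pure-dephasing
    rate proportional to temperature; the proportionality constant is
    anchored at the 15 K reference point of 7.7 cm^-1.
    """
    if T < 0:
        raise ValueError("temperature must be >= 0")
    return GAMMA_DP_AT_15K / 15.0 * float(T)


def fmo_model(params: FmoParameters | None = None) -> LindbladModel:
    """Haken-Strobl model of the FMO monomer on the 9-dimensional sector.

    Seven sites plus vacuum plus reaction center; vacuum and reaction-center
    energies are set to zero.  One sink dissipator (rate Gamma, jump
    operator sigma+^R sigma-^3) and seven sigma_z dephasers (rate gamma_dp).
    All cm^-1 inputs are converted to rad/ps; time is in picoseconds.
    """
    if params is None:
        params = FmoParameters()
    space = build_state_space(7, include_reaction_center=True)
    d = space.dimension
    H = np.zeros((d, d), dtype=complex)
    for n in range(7):
        for npr in range(7):
            H[space.site_index(n + 1), space.site_index(npr + 1)] = (
                wavenumber_to_angular_frequency(params.hamiltonian_cm1[n, npr])
            )

    conv = wavenumber_to_angular_frequency if params.convert_rates_with_2pic else float
    dissipators = []
    if params.sink_rate_cm1 > 0:
        s = (
            embed_site_operator("raise", "R", space).matrix
            @ embed_site_operator("lower", 3, space).matrix
        )
        dissipators.append((conv(params.sink_rate_cm1), Operator(space, s)))
    if params.gamma_dp_cm1 > 0:
        for n in range(1, 8):
            dissipators.append((conv(params.gamma_dp_cm1), embed_site_operator("sigma_z", n, space)))
    return LindbladModel(Operator(space, H), dissipators)


def fmo_scenario(
    target_site: int,
    T: float = 15.0,
    sink_rate: float = DEFAULT_SINK_RATE,
    assembly: MeasurementAssembly | None = None,
) -> Scenario:
    """FMO steering scenario: site 6 maximally mixed and measured at time 0.

    The initial state is completely mixed at site 6 with every other site in
    its ground state, i.e. (|vac><vac| + |e6><e6|)/2 in the sector; the
    Pauli set X, Y, Z is measured on site 6 and the assemblage of
    ``target_site`` (any site but 6) is followed in time.
    """
    target_site = int(target_site)
    if target_site == 6:
        raise ValueError("target_site must differ from the measured site 6")
    if not 1 <= target_site <= 7:
        raise ValueError("target_site must be one of 1..5, 7")
    params = FmoParameters(temperature=T, sink_rate_cm1=sink_rate)
    model = fmo_model(params)
    space = model.space
    d = space.dimension
    rho0 = np.zeros((d, d), dtype=complex)
    rho0[0, 0] = 0.5
    i6 = space.site_index(6)
    rho0[i6, i6] = 0.5
    return Scenario(
        rho0=QuantumState(space, rho0),
        measured_site=6,
        target_site=target_site,
        assembly=assembly or pauli_measurement_set(),
        channel=model,
        description=f"FMO site-6 -> site-{target_site}, T={T} K, Gamma={sink_rate} cm^-1",
    )
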