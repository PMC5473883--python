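"""Spatio-temporal assemblages.

An assemblage is the table of subnormalized conditional states
``sigma_{a|x}(t)`` of a target qubit B, indexed by the outcome ``a`` and
setting ``x`` of a measurement performed on node A at time 0:

    sigma_{a|x}(t) = tr_A{ Lambda[ (sqrt(F_{a|x}) (x) 1) rho_0 (sqrt(F_{a|x}) (x) 1) ] }

where Lambda is the network channel.  With an identity channel and a
bipartite initial state this reduces to the familiar EPR steering
assemblage; with a single system measured and then evolved it reduces to
the temporal assemblage.  Unlike the EPR special case, the general
assemblage may be *signalling* across settings -- the measurement
disturbance propagates through the channel -- and that is part of the
phenomenon, so validation reports but never rejects signalling.

Convention: outcome "+" is the +1 eigenvector of the measured Pauli, and
the sigma_z +1 eigenstate is the excited state |e>.  Qubit basis ordering
is (g, e).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dynamics import (
    LindbladModel,
    Operator,
    QuantumState,
    QubitPairSpace,
    StateSpace,
    evolve,
)

__all__ = [
    "PAULI",
    "MeasurementAssembly",
    "Scenario",
    "Assemblage",
    "AssemblageReport",
    "IdentityChannel",
    "DiscardChannel",
    "pauli_measurement_set",
    "post_measurement_branches",
    "assemblage_at",
    "assemblage_trajectory",
    "reduce_to_site_qubit",
    "validate_assemblage",
]

# Qubit basis (g, e); sigma_z = |e><e| - |g><g|.
PAULI = {
    "X": np.array([[0.0, 1.0], [1.0, 0.0]], dtype=complex),
    "Y": np.array([[0.0, -1.0j], [1.0j, 0.0]], dtype=complex),
    "Z": np.array([[-1.0, 0.0], [0.0, 1.0]], dtype=complex),
}
_I2 = np.eye(2, dtype=complex)


@dataclass
class MeasurementAssembly:
    """POVMs {F_{a|x}} on the measured node's qubit, indexed [x][a]."""

    elements: np.ndarray  # (n_settings, n_outcomes, 2, 2)
    setting_labels: tuple[str, ...] = ()
    tol: float = 1e-10

    def __post_init__(self):
        self.elements = np.asarray(self.elements, dtype=complex)
        if self.elements.ndim != 4 or self.elements.shape[2:] != (2, 2):
            raise ValueError("elements must have shape (settings, outcomes, 2, 2)")
        if not self.setting_labels:
            self.setting_labels = tuple(f"x{i}" for i in range(self.n_settings))
        for x in range(self.n_settings):
            tot = self.elements[x].sum(axis=0)
            if np.abs(tot - _I2).max() > self.tol:
                raise ValueError(f"POVM for setting {x} does not sum to identity")
            for a in range(self.n_outcomes):
                F = self.elements[x, a]
                if np.abs(F - F.conj().T).max() > self.tol:
                    raise ValueError("POVM element not Hermitian")
                if np.linalg.eigvalsh(F).min() < -self.tol:
                    raise ValueError("POVM element not positive semidefinite")

    @property
    def n_settings(self) -> int:
        return self.elements.shape[0]

    @property
    def n_outcomes(self) -> int:
        return self.elements.shape[1]


def pauli_measurement_set() -> MeasurementAssembly:
    """Projective X, Y, Z measurements; outcomes ordered (+, -)."""
    els = np.empty((3, 2, 2, 2), dtype=complex)
    for x, w in enumerate("XYZ"):
        els[x, 0] = 0.5 * (_I2 + PAULI[w])
        els[x, 1] = 0.5 * (_I2 - PAULI[w])
    return MeasurementAssembly(els, setting_labels=("X", "Y", "Z"))


class IdentityChannel:
    """The do-nothing channel (EPR reduction of spatio-temporal steering)."""


@dataclass
class DiscardChannel:
    """Channel that discards its input and outputs a fixed target state.

    Null model for a fully broken network link: whatever happened at the
    measured node, the target ends up in ``rho_fixed``, so the assemblage
    carries only the classical data table p(a|x) and is never steerable.
    """

    rho_fixed: np.ndarray

    def __post_init__(self):
        self.rho_fixed = np.asarray(self.rho_fixed, dtype=complex)
        st = QuantumState(QubitSpace2(), self.rho_fixed)
        st.validate()


@dataclass(frozen=True)
class QubitSpace2:
    """A bare qubit space used for 2x2 target states."""

    basis_labels: tuple[str, ...] = ("g", "e")

    @property
    def dimension(self) -> int:
        return 2


@dataclass
class Scenario:
    """Initial state + measurement on node A + channel + target node B."""

    rho0: QuantumState
    measured_site: object
    target_site: object
    assembly: MeasurementAssembly
    channel: object  # LindbladModel | IdentityChannel | DiscardChannel
    description: str = ""
    temporal: bool = False  # measured_site == target_site allowed when True
    solver_options: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.measured_site == self.target_site and not self.temporal:
            raise ValueError(
                "measured_site equals target_site; flag the scenario as a temporal reduction"
            )
        self.rho0.validate()

    @property
    def space(self):
        return self.rho0.space


def _embed_qubit_operator(M: np.ndarray, site, space) -> np.ndarray:
    """Embed a 2x2 operator acting on one node's qubit into the full space.

    For the 0/1-excitation sector the operator acts on the (vac, e_site)
    block, while on every other basis state the site is in its ground
    state, so only the (g,g) matrix element survives (raising components
    would leave the sector).  Exact for scenarios whose initial states have
    no excitation outside the measured site.
    """
    M = np.asarray(M, dtype=complex)
    if isinstance(space, QubitPairSpace):
        return np.kron(M, _I2)
    if isinstance(space, StateSpace):
        d = space.dimension
        i = space.site_index(site)
        E = M[0, 0] * np.eye(d, dtype=complex)
        E[0, 0] = M[0, 0]
        E[i, i] = M[1, 1]
        E[0, i] = M[0, 1]
        E[i, 0] = M[1, 0]
        return E
    raise TypeError(f"cannot embed a qubit operator into {type(space).__name__}")


def _psd_sqrt(F: np.ndarray, clip: float = 1e-12) -> np.ndarray:
    """Hermitian spectral square root with eigenvalue clipping at zero."""
    F = 0.5 * (F + F.conj().T)
    w, V = np.linalg.eigh(F)
    if w.min() < -1e-8:
        raise ValueError(f"operator has negative eigenvalue {w.min():.3e}; no PSD square root")
    w = np.sqrt(np.clip(w, 0.0, None))
    return (V * w) @ V.conj().T


def post_measurement_branches(
    rho0: QuantumState, assembly: MeasurementAssembly, measured_site
) -> np.ndarray:
    """Subnormalized branches rho_{a|x} = (sqrtF (x) 1) rho_0 (sqrtF (x) 1).

    Returns an array of shape (n_settings, n_outcomes, d, d); the trace of
    branch (a|x) is the outcome probability p(a|x).
    """
    rho0.validate()
    d = rho0.space.dimension
    out = np.empty((assembly.n_settings, assembly.n_outcomes, d, d), dtype=complex)
    for x in range(assembly.n_settings):
        for a in range(assembly.n_outcomes):
            K = _embed_qubit_operator(_psd_sqrt(assembly.elements[x, a]), measured_site, rho0.space)
            out[x, a] = K @ rho0.matrix @ K.conj().T
    return out


def reduce_to_site_qubit(state: QuantumState, site) -> QuantumState:
    """Trace out everything except one site's qubit (0/1-excitation sector).

    The excited population is ``<e_site|rho|e_site>``; every other sector
    state has the site in its ground state, so the ground population is the
    remaining trace, and the only coherence surviving the partial trace is
    the one with all other subsystems matched: ``<e|rho_B|g> = <e_site|rho|vac>``.
    """
    space = state.space
    if isinstance(space, QubitPairSpace):
        rho = state.matrix
        red = rho[:2, :2] + rho[2:, 2:]  # trace over the first (measured) qubit
        return QuantumState(QubitSpace2(), red, expected_trace=None)
    if not isinstance(space, StateSpace):
        raise TypeError(f"cannot reduce a state on {type(space).__name__}")
    i = space.site_index(site)
    rho = state.matrix
    pe = rho[i, i]
    coh = rho[i, 0]
    red = np.array([[np.trace(rho) - pe, np.conj(coh)], [coh, pe]], dtype=complex)
    return QuantumState(QubitSpace2(), red, expected_trace=None)


@dataclass
class Assemblage:
    """Subnormalized target-qubit states sigma_{a|x}, indexed [x][a]."""

    members: np.ndarray  # (n_settings, n_outcomes, 2, 2)
    time: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.members = np.asarray(self.members, dtype=complex)
        if self.members.ndim != 4 or self.members.shape[2:] != (2, 2):
            raise ValueError("members must have shape (settings, outcomes, 2, 2)")

    @property
    def n_settings(self) -> int:
        return self.members.shape[0]

    @property
    def n_outcomes(self) -> int:
        return self.members.shape[1]

    def probabilities(self) -> np.ndarray:
        """p(a|x) = tr sigma_{a|x}, shape (settings, outcomes)."""
        return np.real(np.trace(self.members, axis1=2, axis2=3))

    def conditional_state(self, x: int, a: int, tol: float = 1e-12) -> Optional[np.ndarray]:
        p = float(np.real(np.trace(self.members[x, a])))
        if p <= tol:
            return None
        return self.members[x, a] / p

    # -- JSON interchange ---------------------------------------------------
    def to_json(self) -> dict:
        return {
            "n_settings": self.n_settings,
            "n_outcomes": self.n_outcomes,
            "time": float(self.time),
            "members": [
                [
                    [[{"re": float(v.real), "im": float(v.imag)} for v in row] for row in self.members[x, a]]
                    for a in range(self.n_outcomes)
                ]
                for x in range(self.n_settings)
            ],
            "metadata": dict(self.metadata),
        }

    @classmethod
    def from_json(cls, payload: dict, validate: bool = True) -> "Assemblage":
        members = np.array(
            [
                [
                    [[complex(v["re"], v["im"]) for v in row] for row in mat]
                    for mat in setting
                ]
                for setting in payload["members"]
            ],
            dtype=complex,
        )
        asm = cls(members, time=float(payload.get("time", 0.0)), metadata=dict(payload.get("metadata", {})))
        if validate:
            report = validate_assemblage(asm)
            if not report.members_psd or not report.trace_sums_ok:
                raise ValueError(f"invalid assemblage on load: {report}")
        return asm


@dataclass
class AssemblageReport:
    """Validation report; signalling is reported, never enforced."""

    min_eigenvalue: float
    members_psd: bool
    trace_sums: np.ndarray
    trace_sums_ok: bool
    non_signalling: bool
    signalling_deviation: float

    def __str__(self):
        return (
            f"AssemblageReport(min_eig={self.min_eigenvalue:.2e}, psd={self.members_psd}, "
            f"trace_sums_ok={self.trace_sums_ok}, non_signalling={self.non_signalling}, "
            f"signalling_dev={self.signalling_deviation:.2e})"
        )


def validate_assemblage(assemblage: Assemblage, tol: float = 1e-8) -> AssemblageReport:
    """Check PSD members, per-setting trace sums and the no-signalling property."""
    mem = assemblage.members
    herm = 0.5 * (mem + np.conj(np.swapaxes(mem, -1, -2)))
    min_eig = float(np.linalg.eigvalsh(herm).min())
    herm_dev = float(np.abs(mem - herm).max())
    trace_sums = np.real(np.trace(mem, axis1=2, axis2=3)).sum(axis=1)
    reduced = mem.sum(axis=1)  # sum over outcomes, per setting
    sig_dev = float(np.abs(reduced - reduced[0]).max()) if assemblage.n_settings > 1 else 0.0
    return AssemblageReport(
        min_eigenvalue=min_eig,
        members_psd=(min_eig >= -tol and herm_dev <= tol),
        trace_sums=trace_sums,
        trace_sums_ok=bool(np.abs(trace_sums - 1.0).max() <= tol),
        non_signalling=(sig_dev <= tol),
        signalling_deviation=sig_dev,
    )


def _reduce_branch(scenario: Scenario, branch: np.ndarray) -> np.ndarray:
    st = QuantumState(scenario.space, branch, expected_trace=None)
    return reduce_to_site_qubit(st, scenario.target_site).matrix


def assemblage_trajectory(scenario: Scenario, time_grid, **evolve_opts) -> list[Assemblage]:
    """Assemblages at every point of ``time_grid`` (branches evolved once)."""
    grid = np.asarray(time_grid, dtype=float)
    branches = post_measurement_branches(scenario.rho0, scenario.assembly, scenario.measured_site)
    m, o = branches.shape[:2]
    d = scenario.space.dimension
    evolve_opts = {**scenario.solver_options, **evolve_opts}

    if isinstance(scenario.channel, DiscardChannel):
        members = np.empty((grid.size, m, o, 2, 2), dtype=complex)
        for x in range(m):
            for a in range(o):
                members[:, x, a] = np.real(np.trace(branches[x, a])) * scenario.channel.rho_fixed
    elif isinstance(scenario.channel, IdentityChannel):
        base = np.empty((m, o, 2, 2), dtype=complex)
        for x in range(m):
            for a in range(o):
                base[x, a] = _reduce_branch(scenario, branches[x, a])
        members = np.broadcast_to(base, (grid.size, m, o, 2, 2)).copy()
    elif isinstance(scenario.channel, LindbladModel):
        members = np.empty((grid.size, m, o, 2, 2), dtype=complex)
        for x in range(m):
            for a in range(o):
                st = QuantumState(scenario.space, branches[x, a], expected_trace=None)
                traj = evolve(st, scenario.channel, grid, **evolve_opts)
                for k, point in enumerate(traj):
                    members[k, x, a] = reduce_to_site_qubit(point, scenario.target_site).matrix
    else:
        raise TypeError(f"unsupported channel type {type(scenario.channel).__name__}")

    meta = {"scenario": scenario.description, "target": str(scenario.target_site)}
    return [Assemblage(members[k], time=float(grid[k]), metadata=dict(meta)) for k in range(grid.size)]


def assemblage_at(scenario: Scenario, t: float, **evolve_opts) -> Assemblage:
    """The spatio-temporal assemblage of the scenario's target at time ``t``."""
    if t < 0:
        raise ValueError("t must be >= 0")
    grid = np.array([0.0]) if t == 0 else np.array([0.0, float(t)])
    return assemblage_trajectory(scenario, grid, **evolve_opts)[-1]
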