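"""State spaces, operator embedding and Lindblad evolution.

Excitation transport through a network of two-level sites conserves the
number of excitations whenever the Hamiltonian is of hopping type and the
dissipators are diagonal in the site basis (dephasing) or move the
excitation between sites (a sink).  Every scenario shipped with this
package starts in the span of the vacuum and the single-excitation states,
so instead of the full ``2**n`` tensor space we work in the
(n_sites + 1)-dimensional 0/1-excitation sector (plus one level for the
reaction center when present).  The restriction is exact for these
scenarios and is cross-checked against full tensor-space propagation in the
test suite.

The dissipator convention is the prefactor-free form

    rate * (2 A rho A^dag - A^dag A rho - rho A^dag A)

with no extra factor 1/2.  A sigma_z dephaser at rate ``g`` therefore damps
the coherence between an excited site and the vacuum at ``4 g`` and the
coherence between two excited sites at ``8 g``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "StateSpace",
    "QubitPairSpace",
    "Operator",
    "QuantumState",
    "LindbladModel",
    "build_state_space",
    "embed_site_operator",
    "lindblad_rhs",
    "liouvillian",
    "evolve",
]

_SITE_OPS = ("raise", "lower", "sigma_z", "sigma_x", "sigma_y")


@dataclass(frozen=True)
class StateSpace:
    """The 0/1-excitation sector of a network of two-level sites.

    Basis ordering: the vacuum (all sites in the ground state) at index 0,
    then one excitation at each site in site order, then optionally the
    excited reaction center.
    """

    n_sites: int
    include_reaction_center: bool = False
    basis_labels: tuple[str, ...] = ()

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError(f"n_sites must be >= 1, got {self.n_sites}")
        if not self.basis_labels:
            labels = ["vac"] + [f"e{i}" for i in range(1, self.n_sites + 1)]
            if self.include_reaction_center:
                labels.append("eR")
            object.__setattr__(self, "basis_labels", tuple(labels))
        if len(self.basis_labels) != self.dimension:
            raise ValueError("basis_labels inconsistent with dimension")

    @property
    def dimension(self) -> int:
        return self.n_sites + 1 + (1 if self.include_reaction_center else 0)

    def site_index(self, site) -> int:
        """Basis index of the single-excitation state of ``site`` (1-based or 'R')."""
        if site == "R":
            if not self.include_reaction_center:
                raise ValueError("space has no reaction center")
            return self.dimension - 1
        site = int(site)
        if not 1 <= site <= self.n_sites:
            raise ValueError(f"site {site} not in 1..{self.n_sites}")
        return site


@dataclass(frozen=True)
class QubitPairSpace:
    """A plain two-qubit tensor space (measured qubit first), basis gg, ge, eg, ee.

    Used by the EPR reduction of spatio-temporal steering, where node A and
    node B are independent qubits and the channel acts on their joint state.
    """

    basis_labels: tuple[str, ...] = ("g;g", "g;e", "e;g", "e;e")

    @property
    def dimension(self) -> int:
        return 4


@dataclass
class Operator:
    """A matrix together with the space it acts on."""

    space: object
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=complex)
        d = self.space.dimension
        if self.matrix.shape != (d, d):
            raise ValueError(f"matrix shape {self.matrix.shape} != space dimension {d}")

    def dagger(self) -> "Operator":
        return Operator(self.space, self.matrix.conj().T)


@dataclass
class QuantumState:
    """A (possibly subnormalized) density operator on a space.

    ``expected_trace`` declares the normalization (1.0 for proper states,
    the branch probability for post-measurement branches, or None to skip
    the check).
    """

    space: object
    matrix: np.ndarray
    trace_tol: float = 1e-8
    expected_trace: float | None = 1.0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=complex)
        d = self.space.dimension
        if self.matrix.shape != (d, d):
            raise ValueError(f"matrix shape {self.matrix.shape} != space dimension {d}")

    def validate(self) -> None:
        """Raise ValueError if not Hermitian / PSD / correctly normalized."""
        m = self.matrix
        if np.abs(m - m.conj().T).max() > self.trace_tol:
            raise ValueError("state is not Hermitian within tolerance")
        w = np.linalg.eigvalsh(0.5 * (m + m.conj().T))
        if w.min() < -self.trace_tol:
            raise ValueError(f"state has negative eigenvalue {w.min():.3e}")
        if self.expected_trace is not None:
            tr = float(np.real(np.trace(m)))
            if abs(tr - self.expected_trace) > self.trace_tol:
                raise ValueError(f"trace {tr} != declared normalization {self.expected_trace}")

    @property
    def trace(self) -> float:
        return float(np.real(np.trace(self.matrix)))


@dataclass
class LindbladModel:
    """Hamiltonian plus dissipators, all in angular-frequency units (hbar = 1).

    The dissipators are ``(rate, jump_operator)`` pairs applied in the
    prefactor-free convention ``rate*(2 A rho A^dag - A^dag A rho - rho A^dag A)``.
    """

    hamiltonian: Operator
    dissipators: list[tuple[float, Operator]] = field(default_factory=list)
    hermiticity_tol: float = 1e-10

    def __post_init__(self):
        H = self.hamiltonian.matrix
        if np.abs(H - H.conj().T).max() > self.hermiticity_tol:
            raise ValueError("Hamiltonian is not Hermitian within tolerance")
        for rate, op in self.dissipators:
            if rate < 0:
                raise ValueError(f"dissipator rate must be >= 0, got {rate}")
            if op.space.dimension != self.space.dimension:
                raise ValueError("dissipator operator lives in a different space")

    @property
    def space(self):
        return self.hamiltonian.space


def build_state_space(n_sites: int, include_reaction_center: bool = False) -> StateSpace:
    """Construct the 0/1-excitation sector space for ``n_sites`` two-level sites."""
    return StateSpace(n_sites=int(n_sites), include_reaction_center=bool(include_reaction_center))


def embed_site_operator(op_name: str, site, space: StateSpace) -> Operator:
    """Single-site Pauli/ladder operator restricted to the 0/1-excitation sector.

    In the sector, every basis state other than ``e_site`` has the given
    site in its ground state, so ``sigma_z`` acts as +1 on ``e_site`` and -1
    on everything else; ``raise`` maps the vacuum to ``e_site`` (any other
    sector state is annihilated, since raising an already-excited network
    would leave the sector).
    """
    if op_name not in _SITE_OPS:
        raise ValueError(f"unknown op_name {op_name!r}; expected one of {_SITE_OPS}")
    d = space.dimension
    i = space.site_index(site)
    M = np.zeros((d, d), dtype=complex)
    if op_name == "raise":
        M[i, 0] = 1.0
    elif op_name == "lower":
        M[0, i] = 1.0
    elif op_name == "sigma_z":
        M = -np.eye(d, dtype=complex)
        M[i, i] = 1.0
    elif op_name == "sigma_x":
        M[i, 0] = 1.0
        M[0, i] = 1.0
    elif op_name == "sigma_y":
        M[i, 0] = 1.0j
        M[0, i] = -1.0j
    return Operator(space, M)


def lindblad_rhs(state: QuantumState, model: LindbladModel) -> np.ndarray:
    """Right-hand side of the master equation for ``state`` under ``model``."""
    if state.space.dimension != model.space.dimension:
        raise ValueError("state and model live in different spaces")
    rho = state.matrix
    H = model.hamiltonian.matrix
    out = -1j * (H @ rho - rho @ H)
    for rate, op in model.dissipators:
        A = op.matrix
        Ad = A.conj().T
        AdA = Ad @ A
        out += rate * (2.0 * (A @ rho @ Ad) - AdA @ rho - rho @ AdA)
    return out


def liouvillian(model: LindbladModel) -> np.ndarray:
    """The generator as a (d^2, d^2) matrix acting on row-major vectorized rho."""
    d = model.space.dimension
    H = model.hamiltonian.matrix
    Id = np.eye(d)
    # vec(A rho B) = (A kron B^T) vec(rho) for row-major vec.
    L = -1j * (np.kron(H, Id) - np.kron(Id, H.T))
    for rate, op in model.dissipators:
        A = op.matrix
        AdA = A.conj().T @ A
        L += rate * (
            2.0 * np.kron(A, A.conj())
            - np.kron(AdA, Id)
            - np.kron(Id, AdA.T)
        )
    return L


def evolve(
    state: QuantumState,
    model: LindbladModel,
    time_grid,
    *,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    method: str = "DOP853",
) -> list[QuantumState]:
    """Propagate ``state`` through the master equation over ``time_grid``.

    ``time_grid`` must start at 0 and be strictly increasing.  Works for
    subnormalized inputs (the generator is linear); the trajectory preserves
    the trace of the input within solver tolerance.
    """
    grid = np.asarray(time_grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise ValueError("time_grid must be a 1-d sequence of times")
    if abs(grid[0]) > 1e-15:
        raise ValueError("time_grid must start at 0")
    if grid.size > 1 and np.any(np.diff(grid) <= 0):
        raise ValueError("time_grid must be strictly increasing")
    if state.space.dimension != model.space.dimension:
        raise ValueError("state and model live in different spaces")

    d = state.space.dimension
    tr0 = state.trace
    if grid.size == 1:
        return [state]

    L = liouvillian(model)

    def rhs(_t, v):
        return L @ v

    sol = solve_ivp(
        rhs,
        (grid[0], grid[-1]),
        state.matrix.ravel(),
        t_eval=grid,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"Lindblad integration failed: {sol.message}")

    out = []
    for k in range(grid.size):
        rho = sol.y[:, k].reshape(d, d)
        rho = 0.5 * (rho + rho.conj().T)
        st = QuantumState(state.space, rho, trace_tol=state.trace_tol, expected_trace=None)
        out.append(st)
    # Trace preservation diagnostic: the generator is trace-free, so drift
    # beyond integrator tolerance signals a failed solve.
    drift = max(abs(st.trace - tr0) for st in out)
    if drift > 1e-6:
        raise RuntimeError(f"trace drift {drift:.3e} exceeds tolerance; integration unreliable")
    out[0] = state
    return out


# ---------------------------------------------------------------------------
# JSON interchange for models (energies/rates stored in cm^-1)

def model_to_json(
    n_sites: int,
    include_reaction_center: bool,
    hamiltonian_cm1: np.ndarray,
    dissipators: list[dict],
) -> dict:
    """Serializable description of a network model with entries in cm^-1."""
    H = np.asarray(hamiltonian_cm1)
    if np.iscomplexobj(H) and np.abs(H.imag).max() > 0:
        ham = [[{"re": float(v.real), "im": float(v.imag)} for v in row] for row in H]
    else:
        ham = [[float(np.real(v)) for v in row] for row in H]
    return {
        "n_sites": int(n_sites),
        "include_reaction_center": bool(include_reaction_center),
        "hamiltonian_cm1": ham,
        "dissipators": dissipators,
    }


def model_from_json(payload: dict):
    """Inverse of :func:`model_to_json`; returns the raw fields."""
    ham = payload["hamiltonian_cm1"]
    if ham and isinstance(ham[0][0], dict):
        H = np.array([[complex(v["re"], v["im"]) for v in row] for row in ham])
    else:
        H = np.array(ham, dtype=float)
    return (
        int(payload["n_sites"]),
        bool(payload["include_reaction_center"]),
        H,
        list(payload.get("dissipators", [])),
    )
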