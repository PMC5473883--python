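"""Steerability of spatio-temporal assemblages via semidefinite programming.

An assemblage {sigma_{a|x}} is unsteerable when it admits a hidden-state
model sigma_{a|x} = sum_lambda p(lambda) p(a|x,lambda) sigma_lambda.  The
response functions can be taken deterministic without loss of generality
(convex weights are absorbed into rho_lambda = p(lambda) sigma_lambda), so
with m settings and o outcomes the model is a finite sum over the o**m
deterministic strategies and its existence is an SDP feasibility problem.

Two quantifiers are implemented on top of the same enumeration:

* the STS weight, the minimal steerable fraction in a convex split of the
  assemblage into an unsteerable and an arbitrary part,

      STSW = min 1 - tr sum_l rho_l
             s.t. sigma_{a|x} - sum_l d_l(a|x) rho_l >= 0,  rho_l >= 0;

* the STS robustness, the minimal amount of noise assemblage that must be
  mixed in before the mixture becomes unsteerable,

      STSR = min tr sum_l rho_l - 1
             s.t. sum_l d_l(a|x) rho_l - sigma_{a|x} >= 0,  rho_l >= 0.

Both vanish exactly on the unsteerable set.  Each program can be solved in
two independent encodings ("conic": equality-constrained standard form
with explicit slack blocks; "lmi": inequality form over the Hermitian
components of rho_lambda), which is used as a cross-check in the tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from ._ipm import SDPSolution, solve_lmi, solve_sdp
from .assemblage import Assemblage

__all__ = [
    "DeterministicStrategy",
    "SteeringResult",
    "enumerate_strategies",
    "check_hidden_state_model",
    "sts_weight",
    "sts_robustness",
]

#: Hermitian operator basis of the qubit: diag projectors, real and
#: imaginary off-diagonal parts.  <B_k, M> recovers (M00, M11, 2 Re M01, 2 Im M01).
_HERM_BASIS = (
    np.array([[1.0, 0.0], [0.0, 0.0]], dtype=complex),
    np.array([[0.0, 0.0], [0.0, 1.0]], dtype=complex),
    np.array([[0.0, 1.0], [1.0, 0.0]], dtype=complex),
    np.array([[0.0, -1.0j], [1.0j, 0.0]], dtype=complex),
)
_I2 = np.eye(2, dtype=complex)
_Z2 = np.zeros((2, 2), dtype=complex)

#: Default declaration thresholds (configurable per call).
FEASIBILITY_TOL = 1e-7
STEERABLE_TOL = 1e-6


@dataclass(frozen=True)
class DeterministicStrategy:
    """A response function assigning one outcome to each setting."""

    index: int
    outcomes: tuple[int, ...]  # outcomes[x] is the answer to setting x
    n_outcomes: int

    def response(self, a: int, x: int) -> int:
        """d(a|x) in {0, 1}."""
        return 1 if self.outcomes[x] == a else 0

    def table(self) -> np.ndarray:
        """The full 0/1 response table, shape (n_settings, n_outcomes)."""
        t = np.zeros((len(self.outcomes), self.n_outcomes), dtype=int)
        for x, a in enumerate(self.outcomes):
            t[x, a] = 1
        return t


def enumerate_strategies(n_settings: int, n_outcomes: int, cap: int = 4096) -> list[DeterministicStrategy]:
    """All o**m deterministic strategies, lexicographically ordered."""
    if n_settings < 1 or n_outcomes < 1:
        raise ValueError("need at least one setting and one outcome")
    total = n_outcomes**n_settings
    if total > cap:
        raise ResourceWarning(
            f"{total} deterministic strategies exceed the cap {cap}; "
            "reduce the number of settings/outcomes or raise the cap"
        )
    return [
        DeterministicStrategy(i, outs, n_outcomes)
        for i, outs in enumerate(itertools.product(range(n_outcomes), repeat=n_settings))
    ]


@dataclass
class SteeringResult:
    """Value and optimality certificate of a steering program."""

    measure_name: str  # "weight" | "robustness" | "feasibility"
    value: float
    certificate: list[np.ndarray]
    solver_status: str
    strategies: list[DeterministicStrategy] = field(default_factory=list, repr=False)
    mu: float = 0.0  # tr sum_l rho_l (weight program); 1 + alpha (robustness)
    noise_assemblage: np.ndarray | None = None
    residuals: dict = field(default_factory=dict)

    @property
    def steerable(self) -> bool:
        return self.value > STEERABLE_TOL

    def model_members(self, n_settings: int, n_outcomes: int) -> np.ndarray:
        """Reconstruct sum_l d_l(a|x) rho_l from the certificate, indexed [x][a]."""
        out = np.zeros((n_settings, n_outcomes, 2, 2), dtype=complex)
        for lam, rho in zip(self.strategies, self.certificate):
            for x in range(n_settings):
                out[x, lam.outcomes[x]] += rho
        return out

    def to_json(self) -> dict:
        return {
            "measure": self.measure_name,
            "value": float(self.value),
            "solver_status": self.solver_status,
            "certificate": [
                [[{"re": float(v.real), "im": float(v.imag)} for v in row] for row in rho]
                for rho in self.certificate
            ],
            "residuals": {k: float(v) for k, v in self.residuals.items()},
        }


def _clean_members(assemblage: Assemblage, clip: float = 1e-10) -> np.ndarray:
    """Hermitize members and clip slightly negative eigenvalues (integrator noise)."""
    mem = np.asarray(assemblage.members, dtype=complex)
    herm = 0.5 * (mem + np.conj(np.swapaxes(mem, -1, -2)))
    w, V = np.linalg.eigh(herm)
    if w.min() < -1e-6:
        raise ValueError(f"assemblage member has eigenvalue {w.min():.3e}; not a valid assemblage")
    w = np.clip(w, 0.0, None)
    return np.einsum("...ij,...j,...kj->...ik", V, w, V.conj())


def _psd_clip(M: np.ndarray) -> np.ndarray:
    M = 0.5 * (M + M.conj().T)
    w, V = np.linalg.eigh(M)
    return (V * np.clip(w, 0.0, None)) @ V.conj().T


def _program_blocks(members, strategies, sign):
    """Conic-form data for the weight (sign=+1) / robustness (sign=-1) programs."""
    m, o = members.shape[:2]
    L = len(strategies)
    nslack = m * o
    c_rho = -_I2 if sign > 0 else _I2
    c_blocks = [c_rho] * L + [_Z2] * nslack
    a_blocks = []
    b = []
    for x in range(m):
        for a in range(o):
            j_slack = x * o + a
            for Bk in _HERM_BASIS:
                row = [Bk if lam.outcomes[x] == a else _Z2 for lam in strategies]
                row += [sign * Bk if j == j_slack else _Z2 for j in range(nslack)]
                a_blocks.append(row)
                b.append(float(np.real(np.trace(Bk.conj().T @ members[x, a]))))
    return c_blocks, a_blocks, np.array(b)


def _lmi_blocks(members, strategies, sign):
    """LMI-form data over the 4L Hermitian components of the rho_lambda."""
    m, o = members.shape[:2]
    L = len(strategies)
    nvar = 4 * L
    # objective: sum_l tr rho_l = sum_l (z_{l,0} + z_{l,1})
    c = np.zeros(nvar)
    for l in range(L):
        c[4 * l] = 1.0
        c[4 * l + 1] = 1.0
    nblocks = L + m * o
    f0 = [_Z2] * L + [
        (members[x, a] if sign > 0 else -members[x, a]) for x in range(m) for a in range(o)
    ]
    fs = []
    for l in range(L):
        for k, Bk in enumerate(_HERM_BASIS):
            row = [Bk if j == l else _Z2 for j in range(L)]
            for x in range(m):
                for a in range(o):
                    d = 1 if strategies[l].outcomes[x] == a else 0
                    row.append(-sign * d * Bk if d else _Z2)
            fs.append(row)
    # transpose: solve_lmi wants f_blocks[i][block]
    return c, f0, fs, nblocks


def _rho_from_z(z: np.ndarray, L: int) -> list[np.ndarray]:
    out = []
    for l in range(L):
        M = sum(z[4 * l + k] * _HERM_BASIS[k] for k in range(4))
        out.append(M)
    return out


def _certificate_residual(members, strategies, certificate, sign) -> float:
    """Worst violation of the program's semidefinite constraints by the certificate."""
    m, o = members.shape[:2]
    model = np.zeros_like(members)
    for lam, rho in zip(strategies, certificate):
        for x in range(m):
            model[x, lam.outcomes[x]] += rho
    viol = 0.0
    for x in range(m):
        for a in range(o):
            gap = sign * (members[x, a] - model[x, a])
            viol = max(viol, -float(np.linalg.eigvalsh(0.5 * (gap + gap.conj().T)).min()))
    for rho in certificate:
        viol = max(viol, -float(np.linalg.eigvalsh(0.5 * (rho + rho.conj().T)).min()))
    return viol


def _solve_measure(assemblage, name, sign, formulation, tol, strategy_cap):
    members = _clean_members(assemblage)
    m, o = members.shape[:2]
    strategies = enumerate_strategies(m, o, cap=strategy_cap)
    L = len(strategies)

    if formulation == "conic":
        c_blocks, a_blocks, b = _program_blocks(members, strategies, sign)
        sol = solve_sdp(c_blocks, a_blocks, b, tol=tol)
        rhos = [_psd_clip(sol.x_blocks[l]) for l in range(L)]
        raw = sol.primal_objective
    elif formulation == "lmi":
        c, f0, fs, _ = _lmi_blocks(members, strategies, sign)
        z, val, sol = solve_lmi(-sign * c, f0, fs, tol=tol)
        rhos = [_psd_clip(M) for M in _rho_from_z(z, L)]
        raw = val
    else:
        raise ValueError(f"unknown formulation {formulation!r}")

    if sol.status == "failed":
        raise RuntimeError(
            f"SDP solver failed on the {name} program "
            f"(gap={sol.gap:.2e}, pres={sol.primal_residual:.2e}, dres={sol.dual_residual:.2e})"
        )

    trsum = float(sum(np.real(np.trace(r)) for r in rhos))
    value = (1.0 + raw) if sign > 0 else (raw - 1.0)
    value = max(0.0, float(value))
    if sign > 0:
        value = min(1.0, value)

    result = SteeringResult(
        measure_name=name,
        value=value,
        certificate=rhos,
        solver_status=sol.status,
        strategies=strategies,
        mu=trsum,
        residuals={
            "gap": sol.gap,
            "primal": sol.primal_residual,
            "dual": sol.dual_residual,
            "certificate": _certificate_residual(members, strategies, rhos, sign),
        },
    )
    if name == "robustness" and value > STEERABLE_TOL:
        model = result.model_members(m, o)
        result.noise_assemblage = (model - members) / value
    return result


def sts_weight(
    assemblage: Assemblage,
    *,
    formulation: str = "conic",
    tol: float = 1e-9,
    strategy_cap: int = 4096,
) -> SteeringResult:
    """The STS weight of an assemblage (0 = unsteerable, up to 1)."""
    return _solve_measure(assemblage, "weight", +1, formulation, tol, strategy_cap)


def sts_robustness(
    assemblage: Assemblage,
    *,
    formulation: str = "conic",
    tol: float = 1e-9,
    strategy_cap: int = 4096,
) -> SteeringResult:
    """The STS robustness of an assemblage (0 = unsteerable)."""
    return _solve_measure(assemblage, "robustness", -1, formulation, tol, strategy_cap)


def check_hidden_state_model(
    assemblage: Assemblage,
    tol: float = FEASIBILITY_TOL,
    *,
    strategy_cap: int = 4096,
) -> tuple[bool, list[np.ndarray] | None]:
    """Does the assemblage admit a (spatio-temporal) hidden-state model?

    Solved as a two-phase feasibility problem independent of the weight and
    robustness programs: first the linear equality system
    ``sigma_{a|x} = sum_l d_l(a|x) rho_l`` (with unit total trace) is solved
    by least squares over Hermitian rho_l -- a signalling assemblage already
    fails here, since any hidden-state model is non-signalling -- then the
    smallest uniform eigenvalue shift t with ``rho_l + t I >= 0`` is
    minimised over the affine solution set.  The model exists iff the
    linear residual and the optimal t are both below ``tol``.

    Returns ``(feasible, certificate)``; the certificate is the list of
    rho_l (eigenvalue-clipped) when feasible, else None.
    """
    members = _clean_members(assemblage)
    m, o = members.shape[:2]
    strategies = enumerate_strategies(m, o, cap=strategy_cap)
    L = len(strategies)
    kappa = np.array([1.0, 1.0, 2.0, 2.0])  # <B_k, B_k>

    nvar = 4 * L
    rows = []
    rhs = []
    for x in range(m):
        for a in range(o):
            for k in range(4):
                row = np.zeros(nvar)
                for l, lam in enumerate(strategies):
                    if lam.outcomes[x] == a:
                        row[4 * l + k] = kappa[k]
                rows.append(row)
                rhs.append(float(np.real(np.trace(_HERM_BASIS[k].conj().T @ members[x, a]))))
    # unit total trace of sum_l rho_l
    row = np.zeros(nvar)
    for l in range(L):
        row[4 * l] = 1.0
        row[4 * l + 1] = 1.0
    rows.append(row)
    rhs.append(1.0)

    A = np.array(rows)
    y = np.array(rhs)
    z0, *_ = np.linalg.lstsq(A, y, rcond=None)
    lin_residual = float(np.abs(A @ z0 - y).max())
    if lin_residual > tol:
        return False, None

    # Null space of the equality system.
    _, s, Vt = np.linalg.svd(A, full_matrices=True)
    rank = int(np.sum(s > max(A.shape) * np.finfo(float).eps * s[0]))
    N = Vt[rank:].T  # (nvar, nnull)
    nnull = N.shape[1]

    rho0 = _rho_from_z(z0, L)
    min_eig0 = min(float(np.linalg.eigvalsh(r).min()) for r in rho0)
    if min_eig0 >= -tol:
        return True, [_psd_clip(r) for r in rho0]
    if nnull == 0:
        return False, None

    # Phase-I LMI: minimise t subject to rho_l(z0 + N u) + t I >= 0.
    c = np.zeros(nnull + 1)
    c[-1] = 1.0
    f0 = rho0
    fs = []
    for j in range(nnull):
        fs.append(_rho_from_z(N[:, j], L))
    fs.append([_I2] * L)
    xopt, topt, sol = solve_lmi(c, f0, fs)
    if sol.status == "failed":
        raise RuntimeError("feasibility phase-I SDP did not converge")
    if topt > tol:
        return False, None
    z = z0 + N @ xopt[:-1]
    return True, [_psd_clip(r) for r in _rho_from_z(z, L)]
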