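"""Shared fixtures and independent oracles.

The full tensor-space propagator below re-implements the master equation on
the complete 2**n qubit space with operators embedded via Kronecker
products.  It shares no code with the package's restricted-sector
propagator and serves as the independent reference for the sector
equivalence checks.
"""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

import ststeer as st

# Qubit basis (g, e), matching the package convention.
SX = np.array([[0, 1], [1, 0]], dtype=complex)
SY = np.array([[0, -1j], [1j, 0]], dtype=complex)
SZ = np.diag([-1.0, 1.0]).astype(complex)
SPLUS = np.array([[0, 0], [1, 0]], dtype=complex)  # |e><g|
I2 = np.eye(2, dtype=complex)


def kron_chain(ops):
    out = np.array([[1.0]], dtype=complex)
    for op in ops:
        out = np.kron(out, op)
    return out


def full_site_op(op2, site, n):
    """Embed a single-qubit operator on 1-based ``site`` of an n-qubit register."""
    return kron_chain([op2 if k == site else I2 for k in range(1, n + 1)])


def full_basis_index(excited_site, n):
    """Tensor index of the state with one excitation at ``excited_site`` (0 = vacuum)."""
    bits = [0] * n
    if excited_site:
        bits[excited_site - 1] = 1
    idx = 0
    for b in bits:
        idx = 2 * idx + b
    return idx


def sector_to_full(rho_sector, space):
    """Lift a restricted-sector density matrix into the 2**n tensor space."""
    n = space.n_sites
    assert not space.include_reaction_center
    dim = 2**n
    out = np.zeros((dim, dim), dtype=complex)
    idx = [full_basis_index(0, n)] + [full_basis_index(s, n) for s in range(1, n + 1)]
    for i, fi in enumerate(idx):
        for j, fj in enumerate(idx):
            out[fi, fj] = rho_sector[i, j]
    return out


def full_to_sector(rho_full, space):
    n = space.n_sites
    idx = [full_basis_index(0, n)] + [full_basis_index(s, n) for s in range(1, n + 1)]
    return rho_full[np.ix_(idx, idx)]


def evolve_full_tensor(rho_full, H_full, dissipators_full, t_grid, rtol=1e-11, atol=1e-13):
    """Reference Lindblad propagation on the full tensor space.

    ``dissipators_full`` is a list of (rate, jump matrix) pairs in the same
    prefactor-free convention as the package.
    """
    dim = rho_full.shape[0]

    def rhs(_t, v):
        rho = v.reshape(dim, dim)
        out = -1j * (H_full @ rho - rho @ H_full)
        for rate, A in dissipators_full:
            AdA = A.conj().T @ A
            out = out + rate * (2 * A @ rho @ A.conj().T - AdA @ rho - rho @ AdA)
        return out.ravel()

    sol = solve_ivp(rhs, (t_grid[0], t_grid[-1]), rho_full.ravel(), t_eval=t_grid, rtol=rtol, atol=atol)
    assert sol.success
    return [sol.y[:, k].reshape(dim, dim) for k in range(len(t_grid))]


@pytest.fixture(scope="session")
def pauli_set():
    return st.pauli_measurement_set()


@pytest.fixture(scope="session")
def werner_steerable():
    return st.werner_assemblage(0.8)


@pytest.fixture(scope="session")
def werner_unsteerable():
    return st.werner_assemblage(0.5)


def werner_weight_closed_form(p):
    """STS weight of the Werner family under the three Pauli measurements.

    Derived by symmetrising the weight program over the signed-permutation
    symmetry of the scenario: the optimal hidden-state members take the form
    rho_s = (c/8)(I + v_s . sigma) with v_s along the diagonal strategy
    direction, which reduces the SDP to a two-variable linear program with
    optimum (sqrt(3) p - 1)/(sqrt(3) - 1) above the p = 1/sqrt(3) threshold.
    """
    r3 = np.sqrt(3.0)
    return max(0.0, (r3 * p - 1.0) / (r3 - 1.0))


def werner_robustness_closed_form(p):
    """STS robustness of the Werner family (same symmetrisation argument)."""
    r3 = np.sqrt(3.0)
    return max(0.0, (r3 * p - 1.0) / (r3 + 1.0))
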