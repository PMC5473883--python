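"""Synthetic scenarios and fixtures, plus the time-scan driver.

Everything here is generated programmatically: unsteerable assemblages
built directly from the hidden-state model (hence unsteerable by
construction), the Werner-state family whose steerability under the three
Pauli measurements switches on exactly at p = 1/sqrt(3), and a
discard-channel null scenario that can never steer.  A single seeded
pseudo-random generator drives all randomness.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .assemblage import (
    Assemblage,
    DiscardChannel,
    IdentityChannel,
    Scenario,
    assemblage_at,
    assemblage_trajectory,
    pauli_measurement_set,
)
from .dynamics import QuantumState, QubitPairSpace
from .steering import sts_robustness, sts_weight

__all__ = [
    "TimeScan",
    "unsteerable_fixture",
    "random_qubit_state",
    "werner_scenario",
    "werner_assemblage",
    "discard_channel_scenario",
    "scan_steering",
]

CSV_VERSION_HEADER = "# ststeer scan v1"


def random_qubit_state(rng: np.random.Generator, pure: bool = False) -> np.ndarray:
    """A random density matrix from the Ginibre ensemble (or a random pure state)."""
    if pure:
        v = rng.normal(size=2) + 1j * rng.normal(size=2)
        v /= np.linalg.norm(v)
        return np.outer(v, v.conj())
    G = rng.normal(size=(2, 2)) + 1j * rng.normal(size=(2, 2))
    rho = G @ G.conj().T
    return rho / np.trace(rho).real


def unsteerable_fixture(seed: int, m: int = 3, o: int = 2, n_lambda: int = 4) -> Assemblage:
    """An assemblage admitting a hidden-state model by construction.

    Draws hidden-state weights p(lambda), a deterministic response table per
    lambda, and random qubit states sigma_lambda, and assembles
    sigma_{a|x} = sum_lambda p(lambda) d_lambda(a|x) sigma_lambda.  The seed
    fully determines the output.
    """
    if n_lambda < 1:
        raise ValueError("n_lambda must be >= 1")
    rng = np.random.default_rng(seed)
    weights = rng.dirichlet(np.ones(n_lambda))
    tables = rng.integers(0, o, size=(n_lambda, m))
    states = [random_qubit_state(rng) for _ in range(n_lambda)]
    members = np.zeros((m, o, 2, 2), dtype=complex)
    for lam in range(n_lambda):
        for x in range(m):
            members[x, tables[lam, x]] += weights[lam] * states[lam]
    return Assemblage(
        members,
        time=0.0,
        metadata={"kind": "unsteerable_fixture", "seed": int(seed), "n_lambda": int(n_lambda)},
    )


def werner_scenario(p: float) -> Scenario:
    """Werner state p|Phi+><Phi+| + (1-p) I/4 with identity channel and Pauli set.

    The EPR reduction of spatio-temporal steering: two qubits, no dynamics.
    Steerable with the three Pauli measurements iff p > 1/sqrt(3).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    space = QubitPairSpace()
    phi = np.zeros(4, dtype=complex)
    phi[0] = phi[3] = 1.0 / np.sqrt(2.0)  # (|gg> + |ee>)/sqrt(2)
    rho = p * np.outer(phi, phi.conj()) + (1.0 - p) * np.eye(4) / 4.0
    return Scenario(
        rho0=QuantumState(space, rho),
        measured_site="A",
        target_site="B",
        assembly=pauli_measurement_set(),
        channel=IdentityChannel(),
        description=f"Werner p={p}",
    )


def werner_assemblage(p: float) -> Assemblage:
    """The steering assemblage of the Werner scenario (time plays no role)."""
    return assemblage_at(werner_scenario(p), 0.0)


def discard_channel_scenario(rho_fixed: np.ndarray | None = None) -> Scenario:
    """Null scenario: the channel replaces everything by a fixed target state.

    Models a fully broken link; the assemblage is p(a|x) * rho_fixed at all
    times, which always admits a single-state hidden-state model.
    """
    if rho_fixed is None:
        rho_fixed = np.eye(2, dtype=complex) / 2.0
    space = QubitPairSpace()
    phi = np.zeros(4, dtype=complex)
    phi[0] = phi[3] = 1.0 / np.sqrt(2.0)
    return Scenario(
        rho0=QuantumState(space, np.outer(phi, phi.conj())),
        measured_site="A",
        target_site="B",
        assembly=pauli_measurement_set(),
        channel=DiscardChannel(np.asarray(rho_fixed, dtype=complex)),
        description="discard channel",
    )


@dataclass
class TimeScan:
    """A steering measure evaluated along a time grid."""

    times: np.ndarray
    values: np.ndarray
    measure_name: str
    scenario_id: str = ""
    solver_statuses: list[str] = field(default_factory=list)
    residuals: list[float] = field(default_factory=list)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.values.size and self.values.min() < -1e-9:
            raise ValueError("steering values must be >= -1e-9")

    def peak(self) -> tuple[float, float]:
        """(time, value) of the maximum over the grid."""
        k = int(np.argmax(self.values))
        return float(self.times[k]), float(self.values[k])

    def death_time(self, threshold: float = 1e-4) -> float:
        """Last grid time at which the measure exceeds ``threshold`` (nan if never)."""
        above = np.nonzero(self.values > threshold)[0]
        if above.size == 0:
            return float("nan")
        return float(self.times[above[-1]])

    def to_csv(self, path_or_buffer) -> None:
        if hasattr(path_or_buffer, "write"):
            self._write(path_or_buffer)
        else:
            with open(path_or_buffer, "w", newline="") as fh:
                self._write(fh)

    def _write(self, fh) -> None:
        fh.write(CSV_VERSION_HEADER + "\n")
        w = csv.writer(fh)
        w.writerow(["time", "value", "measure", "scenario_id"])
        for t, v in zip(self.times, self.values):
            w.writerow([repr(float(t)), repr(float(v)), self.measure_name, self.scenario_id])

    @classmethod
    def from_csv(cls, path) -> "TimeScan":
        with open(path, newline="") as fh:
            first = fh.readline()
            if not first.startswith("#"):
                fh.seek(0)
            rows = list(csv.DictReader(fh))
        times = np.array([float(r["time"]) for r in rows])
        values = np.array([float(r["value"]) for r in rows])
        measure = rows[0]["measure"] if rows else ""
        sid = rows[0]["scenario_id"] if rows else ""
        return cls(times, values, measure, sid)


def scan_steering(
    scenario: Scenario,
    measure: str,
    time_grid,
    *,
    csv_path=None,
    log=None,
    **evolve_opts,
) -> TimeScan:
    """Evaluate a steering measure along a time grid (one SDP solve per point).

    Individual solver failures are recorded (value NaN) and the scan
    continues.  ``log`` may be a callable receiving one status line per
    point, covering solver status and constraint residual.
    """
    if measure not in ("weight", "robustness"):
        raise ValueError("measure must be 'weight' or 'robustness'")
    solver = sts_weight if measure == "weight" else sts_robustness
    grid = np.asarray(time_grid, dtype=float)
    assemblages = assemblage_trajectory(scenario, grid, **evolve_opts)
    values = np.empty(grid.size)
    statuses: list[str] = []
    residuals: list[float] = []
    for k, asm in enumerate(assemblages):
        try:
            res = solver(asm)
            values[k] = res.value
            statuses.append(res.solver_status)
            residuals.append(res.residuals.get("certificate", float("nan")))
        except RuntimeError as exc:  # per-point solver failure
            values[k] = float("nan")
            statuses.append(f"failed: {exc}")
            residuals.append(float("nan"))
        if log is not None:
            log(
                f"t={grid[k]:.6g} {measure}={values[k]:.6g} "
                f"status={statuses[-1]} residual={residuals[-1]:.2e}"
            )
    scan = TimeScan(
        grid,
        values,
        measure,
        scenario_id=scenario.description,
        solver_statuses=statuses,
        residuals=residuals,
    )
    if csv_path is not None:
        scan.to_csv(csv_path)
    return scan
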