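"""Dense primal-dual interior-point solver for small block-diagonal SDPs.

Solves the conic pair

    (P)  min  sum_b <C_b, X_b>     s.t.  sum_b <A_ib, X_b> = b_i,   X_b >= 0
    (D)  max  b . y                s.t.  C_b - sum_i y_i A_ib = S_b >= 0

over complex Hermitian blocks, with ``<P, Q> = Re tr(P^dag Q)``.  The
implementation uses the HKM search direction with a Mehrotra
predictor-corrector and an infeasible start, the classical recipe of
CSDP/SDPT3, specialised to the very small problems that arise in steering
diagnostics (a few dozen constraints, many 2x2 blocks).  All block
operations are batched with numpy over groups of equally-sized blocks.

The steering programs built on top of this never exceed ~40 constraints and
~20 blocks, so no sparsity or scaling machinery is needed; robustness on
rank-deficient (boundary) optima is what matters, hence the conservative
step control and the least-squares fallback for the Schur system.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg


@dataclass
class SDPSolution:
    """Result of an interior-point solve.

    ``x_blocks`` is the primal matrix variable (list of Hermitian PSD
    arrays), ``y`` the dual vector, ``s_blocks`` the dual slack.  ``status``
    is ``"optimal"``, ``"inaccurate"`` or ``"failed"``.
    """

    x_blocks: list[np.ndarray]
    y: np.ndarray
    s_blocks: list[np.ndarray]
    primal_objective: float
    dual_objective: float
    gap: float
    primal_residual: float
    dual_residual: float
    iterations: int
    status: str
    info: dict = field(default_factory=dict)


class _Group:
    """Blocks of one common dimension, stacked for batched linear algebra."""

    def __init__(self, dim: int, c_list: list[np.ndarray], a_list: list[list[np.ndarray]]):
        self.dim = dim
        self.nb = len(c_list)
        self.C = np.stack([np.asarray(c, dtype=complex) for c in c_list])
        m = len(a_list)
        # K[i] holds the row-major flattening of every A_ib in this group.
        K = np.empty((m, self.nb * dim * dim), dtype=complex)
        for i in range(m):
            K[i] = np.stack([np.asarray(a, dtype=complex) for a in a_list[i]]).ravel()
        self.K = K
        self.Kc = K.conj()

    def mats(self, flat: np.ndarray) -> np.ndarray:
        return flat.reshape(self.nb, self.dim, self.dim)


def _herm(M: np.ndarray) -> np.ndarray:
    return 0.5 * (M + np.conj(np.swapaxes(M, -1, -2)))


def _max_step(Z: np.ndarray, dZ: np.ndarray) -> float:
    """Largest alpha with Z + alpha*dZ >= 0, given Z > 0 (batched blocks)."""
    try:
        L = np.linalg.cholesky(Z)
    except np.linalg.LinAlgError:
        return 0.0
    Li = np.linalg.inv(L)
    V = Li @ dZ @ np.conj(np.swapaxes(Li, -1, -2))
    w = np.linalg.eigvalsh(_herm(V))
    wmin = w.min() if w.size else 0.0
    if wmin >= -1e-14:
        return np.inf
    return -1.0 / wmin


def solve_sdp(
    c_blocks: list[np.ndarray],
    a_blocks: list[list[np.ndarray]],
    b: np.ndarray,
    *,
    tol: float = 1e-9,
    feastol: float = 1e-8,
    max_iter: int = 200,
) -> SDPSolution:
    """Solve the block-diagonal SDP pair (P)/(D).

    Parameters
    ----------
    c_blocks : list of Hermitian arrays, one per block.
    a_blocks : ``a_blocks[i][b]`` is the Hermitian coefficient of constraint
        ``i`` on block ``b`` (dense; use zero matrices where absent).
    b : right-hand side / dual objective vector (real, length ``m``).
    tol : relative duality-gap accuracy.
    feastol : relative primal/dual residual accuracy.  Optima on the
        boundary of the cone (rank-deficient members) limit how far the
        primal residual can be driven, hence the slightly looser default.
    """
    b = np.asarray(b, dtype=float)
    m = len(b)
    nblocks = len(c_blocks)
    if any(len(row) != nblocks for row in a_blocks):
        raise ValueError("constraint rows must cover every block")

    # Group blocks by dimension; remember the original ordering.
    dims = [np.asarray(c).shape[0] for c in c_blocks]
    order: dict[int, list[int]] = {}
    for idx, d in enumerate(dims):
        order.setdefault(d, []).append(idx)
    groups = []
    for d, idxs in order.items():
        groups.append(
            (
                idxs,
                _Group(d, [c_blocks[j] for j in idxs], [[row[j] for j in idxs] for row in a_blocks]),
            )
        )

    n_cone = sum(dims)
    scale = max(1.0, float(np.abs(b).max(initial=0.0)), max(float(np.abs(g.C).max(initial=0.0)) for _, g in groups))

    # State per group: X, S (nb, d, d); shared y.
    X = {id(g): np.stack([np.eye(g.dim, dtype=complex)] * g.nb) * scale for _, g in groups}
    S = {id(g): np.stack([np.eye(g.dim, dtype=complex)] * g.nb) * scale for _, g in groups}
    y = np.zeros(m)

    norm_b = 1.0 + np.linalg.norm(b)
    norm_C = 1.0 + np.sqrt(sum(float(np.linalg.norm(g.C) ** 2) for _, g in groups))

    def A_of(mats_by_group: dict) -> np.ndarray:
        out = np.zeros(m)
        for _, g in groups:
            out += np.real(g.Kc @ mats_by_group[id(g)].ravel())
        return out

    def AT_of(yv: np.ndarray) -> dict:
        return {id(g): _herm(g.mats(yv @ g.K)) for _, g in groups}

    best: SDPSolution | None = None

    status = "failed"
    it = 0
    stall = 0
    for it in range(1, max_iter + 1):
        Rp = b - A_of(X)
        ATy = AT_of(y)
        Rd = {id(g): g.C - ATy[id(g)] - S[id(g)] for _, g in groups}

        xs = sum(float(np.real(np.vdot(X[id(g)], S[id(g)]))) for _, g in groups)
        mu = xs / n_cone
        pobj = sum(float(np.real(np.vdot(g.C, X[id(g)]))) for _, g in groups)
        dobj = float(b @ y)
        gap = abs(pobj - dobj) / (1.0 + abs(pobj) + abs(dobj))
        pres = np.linalg.norm(Rp) / norm_b
        dres = np.sqrt(sum(float(np.linalg.norm(Rd[id(g)]) ** 2) for _, g in groups)) / norm_C

        merit = gap + pres + dres
        if best is None or merit < 0.99 * best.info.get("merit", np.inf):
            best = _pack(groups, order, X, S, y, pobj, dobj, gap, pres, dres, it, "inaccurate")
            best.info["merit"] = merit
            stall = 0
        else:
            stall += 1

        if gap <= tol and pres <= feastol and dres <= feastol:
            status = "optimal"
            break
        if mu < 1e-15 or stall >= 8:
            break  # at the numerical floor; return the best iterate seen

        # Precompute per-group kernels for this iteration.
        T = {}
        W = {}
        try:
            for _, g in groups:
                gid = id(g)
                T[gid] = np.linalg.inv(S[gid])
                # W = kron(X_b, T_b^T) batched:  W[b, i*d+k, j*d+l] = X[i,j] T[l,k]
                d = g.dim
                W[gid] = np.einsum("bij,blk->bikjl", X[gid], T[gid]).reshape(g.nb, d * d, d * d)
        except np.linalg.LinAlgError:
            break  # S hit the numerical boundary; return the best iterate

        M = np.zeros((m, m))
        for _, g in groups:
            gid = id(g)
            d = g.dim
            Kr = g.K.reshape(m, g.nb, d * d)
            Krc = g.Kc.reshape(m, g.nb, d * d)
            M += np.real(np.einsum("ibp,bpq,jbq->ij", Krc, W[gid], Kr, optimize=True))
        M = 0.5 * (M + M.T)

        def schur_solve(rhs: np.ndarray) -> np.ndarray:
            try:
                cf = scipy.linalg.cho_factor(M + 1e-13 * np.eye(m), check_finite=False)
                return scipy.linalg.cho_solve(cf, rhs, check_finite=False)
            except scipy.linalg.LinAlgError:
                return np.linalg.lstsq(M, rhs, rcond=None)[0]

        def directions(nu: float, corr: dict | None):
            # rhs_i = Rp_i - nu A(S^-1) + A(X) + A(X Rd T) [+ A(corr T)]
            extra = {}
            for _, g in groups:
                gid = id(g)
                E = X[gid] @ Rd[gid] @ T[gid] - nu * T[gid] + X[gid]
                if corr is not None:
                    E = E + corr[gid] @ T[gid]
                extra[gid] = E
            rhs = Rp + A_of(extra)
            dy = schur_solve(rhs)
            dATy = AT_of(dy)
            dS = {id(g): Rd[id(g)] - dATy[id(g)] for _, g in groups}
            dX = {}
            for _, g in groups:
                gid = id(g)
                D = nu * T[gid] - X[gid] - X[gid] @ dS[gid] @ T[gid]
                if corr is not None:
                    D = D - corr[gid] @ T[gid]
                dX[gid] = _herm(D)
            return dy, dX, dS

        # Predictor (affine scaling).
        dy_a, dX_a, dS_a = directions(0.0, None)
        ap = min(1.0, 0.95 * min(_max_step(X[id(g)], dX_a[id(g)]) for _, g in groups))
        ad = min(1.0, 0.95 * min(_max_step(S[id(g)], dS_a[id(g)]) for _, g in groups))
        xs_aff = sum(
            float(
                np.real(
                    np.vdot(X[id(g)] + ap * dX_a[id(g)], S[id(g)] + ad * dS_a[id(g)])
                )
            )
            for _, g in groups
        )
        mu_aff = max(xs_aff / n_cone, 0.0)
        sigma = min(1.0, max((mu_aff / mu) ** 3 if mu > 0 else 0.0, 1e-12))

        corr = {id(g): dX_a[id(g)] @ dS_a[id(g)] for _, g in groups}
        dy, dX, dS = directions(sigma * mu, corr)

        tau = 0.9 + 0.09 * min(ap, ad)
        ap = min(1.0, tau * min(_max_step(X[id(g)], dX[id(g)]) for _, g in groups))
        ad = min(1.0, tau * min(_max_step(S[id(g)], dS[id(g)]) for _, g in groups))
        if not np.isfinite(ap) or not np.isfinite(ad) or min(ap, ad) <= 1e-13:
            break

        for _, g in groups:
            gid = id(g)
            X[gid] = _herm(X[gid] + ap * dX[gid])
            S[gid] = _herm(S[gid] + ad * dS[gid])
        y = y + ad * dy

    if status == "optimal":
        sol = _pack(groups, order, X, S, y, pobj, dobj, gap, pres, dres, it, "optimal")
        return sol
    assert best is not None
    if best.gap < 1e-6 and best.primal_residual < 1e-6 and best.dual_residual < 1e-6:
        best.status = "inaccurate"
    else:
        best.status = "failed"
    return best


def _pack(groups, order, X, S, y, pobj, dobj, gap, pres, dres, it, status) -> SDPSolution:
    nblocks = sum(len(idxs) for idxs, _ in groups)
    xb: list = [None] * nblocks
    sb: list = [None] * nblocks
    for idxs, g in groups:
        for k, j in enumerate(idxs):
            xb[j] = np.array(X[id(g)][k])
            sb[j] = np.array(S[id(g)][k])
    return SDPSolution(
        x_blocks=xb,
        y=np.array(y),
        s_blocks=sb,
        primal_objective=pobj,
        dual_objective=dobj,
        gap=gap,
        primal_residual=pres,
        dual_residual=dres,
        iterations=it,
        status=status,
    )


def solve_lmi(
    c: np.ndarray,
    f0_blocks: list[np.ndarray],
    f_blocks: list[list[np.ndarray]],
    *,
    tol: float = 1e-9,
    max_iter: int = 200,
) -> tuple[np.ndarray, float, SDPSolution]:
    """Minimise ``c . x`` subject to ``F0 + sum_i x_i F_i >= 0`` (block diagonal).

    Encoded as the dual side of :func:`solve_sdp` (``b = -c``, ``A_i = -F_i``,
    ``C = F0``), so the reported ``y`` of the conic solve is the LMI variable.
    Returns ``(x, value, solution)``.
    """
    c = np.asarray(c, dtype=float)
    a_blocks = [[-np.asarray(fb, dtype=complex) for fb in row] for row in f_blocks]
    sol = solve_sdp(f0_blocks, a_blocks, -c, tol=tol, max_iter=max_iter)
    x = sol.y
    return x, float(c @ x), sol
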