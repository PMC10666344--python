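"""Two-level preconditioned conjugate gradient solver.

Solves the symmetric positive (semi-)definite system C x = b with a
first-level Jacobi preconditioner M (the exact diagonal of C) and an
optional second level realised as deflation over effect-type subspaces
(projection form of deflated PCG).  Three convergence criteria are tracked
every iteration:

    CK = (1/mu_1)        * ||M^-1 (b - C x_i)|| / ||x_i||
    CM = kappa(M^-1 C)   * ||M^-1 (b - C x_i)|| / ||M^-1 b||
    CD = ||x_{i-1} - x_i|| / ||x_i||

with mu_1 the smallest active positive eigenvalue and kappa the effective
spectral condition number of the preconditioned matrix, both estimated
online from the Lanczos tridiagonal implied by the CG scalar recurrences
(Ritz values).  CD <= 1e-9 is the default stopping rule.  The solution is
snapshotted at iterations 1, 1 + s, 1 + 2s, ... (s = ``snapshot_every``)
plus the final iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
from scipy.linalg import eigh_tridiagonal


class PCGError(RuntimeError):
    pass


@dataclass
class PCGOptions:
    stop_cd: float = 1e-9
    max_iter: int = 10000
    snapshot_every: int = 20
    x0: Optional[np.ndarray] = None
    second_level: str = "none"      # {"none", "deflation"}

    def __post_init__(self):
        if self.stop_cd <= 0:
            raise ValueError("stop_cd must be > 0")
        if self.snapshot_every < 1:
            raise ValueError("snapshot_every must be >= 1")
        if self.second_level not in ("none", "deflation"):
            raise ValueError(f"unknown second level {self.second_level!r}")


@dataclass
class SpectralEstimates:
    mu1: float
    mu_max: float

    @property
    def kappa(self) -> float:
        return self.mu_max / self.mu1


@dataclass
class PCGTrajectory:
    ck: np.ndarray
    cm: np.ndarray
    cd: np.ndarray
    alphas: np.ndarray
    betas: np.ndarray
    snapshots: list            # [(iteration, x copy), ...] sorted, incl. final
    final_iteration: int
    x_final: np.ndarray
    converged: bool
    spectral: Optional[SpectralEstimates] = None


def criterion_cd(x_prev: np.ndarray, x_curr: np.ndarray) -> float:
    """Relative solution change ||x_{i-1} - x_i|| / ||x_i|| (Euclidean)."""
    denom = np.linalg.norm(x_curr)
    if denom == 0.0:
        return np.nan          # undefined-criterion signal
    return float(np.linalg.norm(x_prev - x_curr) / denom)


def criterion_ck(mu1: float, precond_residual_norm: float, x_norm: float) -> float:
    if mu1 <= 0:
        raise PCGError(f"mu1 must be positive, got {mu1}")
    if x_norm <= 0:
        raise PCGError("zero solution norm in CK")
    return float(precond_residual_norm / (mu1 * x_norm))


def criterion_cm(kappa: float, precond_residual_norm: float,
                 precond_rhs_norm: float) -> float:
    if precond_rhs_norm <= 0:
        raise PCGError("zero preconditioned RHS norm in CM")
    return float(kappa * precond_residual_norm / precond_rhs_norm)


def _lanczos_tridiagonal(alphas, betas):
    """Main/off diagonals of the Lanczos matrix implied by CG scalars."""
    alphas = np.asarray(alphas)
    betas = np.asarray(betas)
    k = len(alphas)
    d = 1.0 / alphas
    if k > 1:
        d = d + np.concatenate([[0.0], betas[:-1] / alphas[:-1]])
        e = np.sqrt(np.maximum(betas[:-1], 0.0)) / alphas[:-1]
    else:
        e = np.zeros(0)
    return d, e


def _ritz_extremes(alphas, betas, next_offdiag: float,
                   resid_tol: float = 1e-2, floor_rel: float = 1e-10):
    """(mu1, mu_max) from the Lanczos tridiagonal.

    mu1 is the smallest "active" Ritz value: Ritz residual (next_offdiag x
    last eigenvector component, relative to the value) below ``resid_tol``,
    excluding values below ``floor_rel * mu_max`` (numerically zero modes).
    Falls back to the smallest value above the floor when none is converged
    yet.
    """
    k = len(alphas)
    d, e = _lanczos_tridiagonal(alphas, betas)
    if k == 1:
        v = float(d[0])
        return v, v
    try:
        w_max = eigh_tridiagonal(d, e, select="i", select_range=(k - 1, k - 1),
                                 eigvals_only=True)
        mu_max = float(w_max[0])
        lo = min(5, k - 1)
        w, v = eigh_tridiagonal(d, e, select="i", select_range=(0, lo))
    except np.linalg.LinAlgError:      # pragma: no cover - degenerate input
        w = np.sort(np.linalg.eigvalsh(np.diag(d) + np.diag(e, 1) + np.diag(e, -1)))
        return float(w[0]), float(w[-1])
    floor = floor_rel * mu_max
    mu1 = None
    for j in range(len(w)):
        if w[j] <= floor:
            continue
        resid = next_offdiag * abs(v[-1, j])
        if resid <= resid_tol * w[j]:
            mu1 = float(w[j])
            break
    if mu1 is None:
        above = w[w > floor]
        mu1 = float(above[0]) if len(above) else float(w[0])
    return mu1, mu_max


def estimate_spectrum(trajectory: PCGTrajectory) -> SpectralEstimates:
    """Extremal Ritz values of M^-1 C from the full CG scalar history."""
    if trajectory.final_iteration < 2:
        raise PCGError("spectral estimation needs at least 2 iterations")
    alphas, betas = trajectory.alphas, trajectory.betas
    next_off = np.sqrt(max(betas[-1], 0.0)) / alphas[-1]
    mu1, mu_max = _ritz_extremes(alphas, betas, next_off)
    return SpectralEstimates(mu1=mu1, mu_max=mu_max)


def build_preconditioners(system, opts: PCGOptions):
    """First-level Jacobi M (exact diagonal, floored) and deflation basis.

    The deflation basis holds one indicator vector per nonempty effect
    block (beta, SNP, eps, animals, genetic groups); ``None`` when the
    second level is disabled.
    """
    diag = np.asarray(system.diag, dtype=float)
    if (diag <= 0).any():
        j = int(np.argmin(diag))
        raise PCGError(f"non-positive diagonal entry {diag[j]} at index {j}")
    M = np.maximum(diag, diag.max() * 1e-12)
    basis = None
    if opts.second_level == "deflation":
        lay = system.layout
        cols = []
        for sl in (lay.beta, lay.snp, lay.eps, lay.animal, lay.group):
            if sl.stop > sl.start:
                v = np.zeros(lay.total)
                v[sl] = 1.0
                cols.append(v)
        basis = np.column_stack(cols)
    return M, basis


def pcg_solve(system, M: np.ndarray, opts: PCGOptions,
              deflation_basis: Optional[np.ndarray] = None) -> PCGTrajectory:
    """Run (deflated) PCG on the system's operator.

    ``system`` needs ``matvec`` and ``rhs`` attributes; ``M`` is the Jacobi
    diagonal.  With a deflation basis W the iteration runs on the projected
    operator P C with P = I - C W E^-1 W' (E = W' C W) and the reported
    iterate is the physical solution x_i = W E^-1 W' b + (I - W E^-1 W' C) x.
    """
    A: Callable = system.matvec
    b = np.asarray(system.rhs, dtype=float)
    dim = len(b)
    Minv = 1.0 / M
    x = np.zeros(dim) if opts.x0 is None else np.array(opts.x0, dtype=float)

    bnorm = np.linalg.norm(b)
    if bnorm == 0.0:
        return PCGTrajectory(
            ck=np.array([]), cm=np.array([]), cd=np.array([]),
            alphas=np.array([]), betas=np.array([]),
            snapshots=[(0, x.copy())], final_iteration=0, x_final=x,
            converged=True)

    W = deflation_basis
    if W is not None:
        AW = np.column_stack([A(W[:, j]) for j in range(W.shape[1])])
        E = W.T @ AW
        Einv = np.linalg.inv(E)

        def project(Av):
            return Av - AW @ (Einv @ (W.T @ Av))

        def physical(xc, Ax_acc):
            corr = b - Ax_acc
            return W @ (Einv @ (W.T @ corr)) + xc

        def true_residual(xc, Ax_acc):
            # A xhat = AQ(b - Ax) + Ax
            v = b - Ax_acc
            return v - AW @ (Einv @ (W.T @ v))
    else:
        def project(Av):
            return Av

    Ax0 = A(x) if (W is not None or np.any(x)) else np.zeros(dim)
    r = b - Ax0
    if W is not None:
        Ax_acc = Ax0.copy()
        r = r - AW @ (Einv @ (W.T @ r))
    z = Minv * r
    p = z.copy()
    rz = float(r @ z)
    minv_b_norm = np.linalg.norm(Minv * b)

    xhat_prev = physical(x, Ax_acc) if W is not None else x.copy()

    alphas: list[float] = []
    betas: list[float] = []
    ck_l, cm_l, cd_l = [], [], []
    snapshots = []
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        Ap = A(p)
        PAp = project(Ap)
        pAp = float(p @ PAp)
        if not np.isfinite(pAp):
            raise PCGError(f"non-finite curvature at iteration {it}")
        if pAp <= 0.0:
            raise PCGError(
                f"loss of positive definiteness at iteration {it} (p'Cp = {pAp})")
        alpha = rz / pAp
        x += alpha * p
        if W is not None:
            Ax_acc += alpha * Ap
        r -= alpha * PAp
        z = Minv * r
        rz_new = float(r @ z)
        if not np.isfinite(rz_new):
            raise PCGError(f"non-finite recurrence at iteration {it}")
        beta = rz_new / rz if rz > 0 else 0.0
        alphas.append(alpha)
        betas.append(beta)

        xhat = physical(x, Ax_acc) if W is not None else x
        cd = criterion_cd(xhat_prev, xhat)
        if W is not None:
            tr = true_residual(x, Ax_acc)
        else:
            tr = r
        pr_norm = np.linalg.norm(Minv * tr)
        next_off = np.sqrt(max(beta, 0.0)) / alpha
        mu1, mu_max = _ritz_extremes(np.array(alphas), np.array(betas), next_off)
        xnorm = np.linalg.norm(xhat)
        ck = criterion_ck(mu1, pr_norm, xnorm) if xnorm > 0 else np.nan
        cm = criterion_cm(mu_max / mu1, pr_norm, minv_b_norm)
        ck_l.append(ck)
        cm_l.append(cm)
        cd_l.append(cd)

        if (it - 1) % opts.snapshot_every == 0:
            snapshots.append((it, xhat.copy()))
        xhat_prev = xhat.copy()
        exact = np.linalg.norm(r) <= 1e-15 * bnorm      # finite termination
        if (np.isfinite(cd) and cd <= opts.stop_cd) or exact:
            converged = True
            break
        rz = rz_new
        p = z + beta * p

    x_final = physical(x, Ax_acc) if W is not None else x
    if not snapshots or snapshots[-1][0] != it:
        snapshots.append((it, x_final.copy()))

    traj = PCGTrajectory(
        ck=np.array(ck_l), cm=np.array(cm_l), cd=np.array(cd_l),
        alphas=np.array(alphas), betas=np.array(betas),
        snapshots=snapshots, final_iteration=it, x_final=x_final,
        converged=converged)
    if it >= 2:
        traj.spectral = estimate_spectrum(traj)
    return traj
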