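"""Batched GMRES for stacks of independent linear systems.

The scattering and ``dbar_k`` solvers each produce thousands of small,
mutually independent linear systems (one per spectral node ``k``, or one per
image point ``z``).  Solving them one at a time through ``scipy`` wastes most
of the wall time in Python overhead; instead, a single Krylov iteration is
run for the whole stack at once, with all heavy operations (the FFT-based
operator application, orthogonalization inner products) vectorized over the
batch axis.  Each system keeps its own Hessenberg matrix and Givens
rotations, so the iterates are identical to running standard GMRES per
system; iteration stops when every system in the stack has converged.

The physical systems are *real-linear* (they involve complex conjugation of
the unknown).  ``solve_real_linear`` removes the antilinearity with the
classical squaring trick: for antilinear ``A``, ``(I - A)(I + A) = I - A^2``
and ``A^2`` is complex-linear, so ``(I - A^2) w = b`` is solved by GMRES and
``x = w + A w``.  The residual of the original system equals the residual of
the squared system exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["GmresResult", "gmres_batched", "solve_real_linear"]


@dataclass
class GmresResult:
    x: np.ndarray
    residuals: np.ndarray  # final relative residual per system
    iterations: int
    converged: bool


class SolverConvergenceError(RuntimeError):
    """Raised when the Krylov iteration fails to reach tolerance."""

    def __init__(self, message: str, result: "GmresResult"):
        super().__init__(message)
        self.result = result


def gmres_batched(
    matvec: Callable[[np.ndarray], np.ndarray],
    b: np.ndarray,
    tol: float = 1e-6,
    maxiter: int = 60,
) -> GmresResult:
    """Solve ``A x = b`` for a stack of systems.

    Parameters
    ----------
    matvec:
        Applies each system's operator to its own vector; maps arrays of
        shape ``(B, n)`` to arrays of the same shape.
    b:
        Right-hand sides, shape ``(B, n)``, complex.
    tol:
        Relative residual target (per system, w.r.t. ``||b||``).
    maxiter:
        Maximum Krylov dimension (no restarts; the systems solved here are
        compact perturbations of the identity and converge quickly).
    """
    b = np.ascontiguousarray(b)
    B, n = b.shape
    bnorm = np.linalg.norm(b, axis=1)
    nonzero = bnorm > 0
    if not np.any(nonzero):
        return GmresResult(np.zeros_like(b), np.zeros(B), 0, True)
    scale = np.where(nonzero, bnorm, 1.0)

    m = maxiter
    V = [b / scale[:, None]]  # Krylov basis, grown lazily
    H = np.zeros((B, m + 1, m), dtype=np.complex128)
    cs = np.zeros((B, m), dtype=np.complex128)
    sn = np.zeros((B, m), dtype=np.complex128)
    g = np.zeros((B, m + 1), dtype=np.complex128)

    g[:, 0] = np.where(nonzero, 1.0, 0.0)

    j_done = 0
    for j in range(m):
        w = matvec(V[j])
        # modified Gram-Schmidt, batched: project against all previous vectors
        for i in range(j + 1):
            hij = np.einsum("bn,bn->b", np.conj(V[i]), w)
            H[:, i, j] = hij
            w -= hij.astype(b.dtype)[:, None] * V[i]
        hlast = np.linalg.norm(w, axis=1)
        H[:, j + 1, j] = hlast
        safe = np.where(hlast > 0, hlast, 1.0)
        V.append(w / safe[:, None])

        # apply accumulated Givens rotations to the new column
        col = H[:, : j + 2, j].copy()
        for i in range(j):
            t0 = np.conj(cs[:, i]) * col[:, i] + np.conj(sn[:, i]) * col[:, i + 1]
            t1 = -sn[:, i] * col[:, i] + cs[:, i] * col[:, i + 1]
            col[:, i], col[:, i + 1] = t0, t1
        denom = np.sqrt(np.abs(col[:, j]) ** 2 + np.abs(col[:, j + 1]) ** 2)
        denom = np.where(denom > 0, denom, 1.0)
        cs[:, j] = col[:, j] / denom
        sn[:, j] = col[:, j + 1] / denom
        col[:, j] = np.conj(cs[:, j]) * col[:, j] + np.conj(sn[:, j]) * col[:, j + 1]
        col[:, j + 1] = 0.0
        H[:, : j + 2, j] = col

        g[:, j + 1] = -sn[:, j] * g[:, j]
        g[:, j] = np.conj(cs[:, j]) * g[:, j]

        j_done = j + 1
        res = np.abs(g[:, j + 1])
        if np.max(res) < tol:
            break

    # back substitution on the (rotated, triangular) Hessenberg, per system
    k = j_done
    y = np.zeros((B, k), dtype=np.complex128)
    for i in range(k - 1, -1, -1):
        acc = g[:, i].copy()
        if i + 1 < k:
            acc -= np.einsum("bj,bj->b", H[:, i, i + 1 : k], y[:, i + 1 : k])
        diag = H[:, i, i]
        diag = np.where(np.abs(diag) > 0, diag, 1.0)
        y[:, i] = acc / diag

    x = np.zeros_like(b)
    for i in range(k):
        x += y[:, i].astype(b.dtype)[:, None] * V[i]
    x *= scale[:, None]

    res = np.abs(g[:, k]) if k < m + 1 else np.abs(g[:, -1])
    res = np.where(nonzero, res, 0.0)
    return GmresResult(x, res, k, bool(np.max(res) < tol))


def solve_real_linear(
    apply_antilinear: Callable[[np.ndarray], np.ndarray],
    b: np.ndarray,
    tol: float = 1e-6,
    maxiter: int = 60,
    raise_on_fail: bool = True,
) -> GmresResult:
    """Solve ``(I - A) x = b`` with ``A`` antilinear (conjugating).

    ``apply_antilinear`` and ``b`` use arbitrary trailing field shape; the
    leading axis is the batch.
    """
    shape = b.shape
    flat = lambda u: u.reshape(shape[0], -1)
    unflat = lambda u: u.reshape(shape)

    def mv(wf: np.ndarray) -> np.ndarray:
        w = unflat(wf.copy())
        return wf - flat(apply_antilinear(apply_antilinear(w)))

    out = gmres_batched(mv, flat(b), tol=tol, maxiter=maxiter)
    w = unflat(out.x)
    x = w + apply_antilinear(w)
    result = GmresResult(x, out.residuals, out.iterations, out.converged)
    if raise_on_fail and not out.converged:
        raise SolverConvergenceError(
            f"GMRES did not reach tol={tol} in {out.iterations} iterations "
            f"(max residual {out.residuals.max():.3e})",
            result,
        )
    return result
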