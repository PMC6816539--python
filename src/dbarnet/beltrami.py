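"""Beltrami equation solver and the nonlinear Fourier (scattering) data tau.

For a conductivity ``sigma`` scaled to 1 near the boundary, the Beltrami
coefficient ``mu = (1 - sigma)/(1 + sigma)`` is compactly supported with
``|mu| < 1``.  For each spectral parameter ``k`` the exponentially-behaving
solutions ``f_pm`` of

    dbar_z f_pm = (+/- mu) conj(d_z f_pm)

with ``f_pm = exp(ikz) M_pm`` and ``M_pm -> 1`` at infinity exist and are
unique.  The scattering transform is read off from them:

    conj(tau(k)) = (1 / 2 pi) int dbar_z [M_plus - M_minus] dA(z).

Numerics
--------
Writing ``M = 1 + P u`` with ``u = dbar_z M`` (supported on ``supp mu``) and
``P`` the solid Cauchy transform turns the PDE into a real-linear integral
equation on the solver square,

    u = nu_k (z) [ conj(S u) - i conj(k) conj(P u) - i conj(k) ],
    nu_k(z) = (+/- mu)(z) exp(-i (k z + conj(k z))),

with ``S`` the Beurling transform.  ``P`` and ``S`` are evaluated by FFT on
a doubled grid and the real-linear system is solved by batched GMRES after
the antilinear-squaring trick (see ``_gmres``).  All spectral nodes (and
both coefficient signs) are solved simultaneously as one batched system.

Since the unknown ``u`` vanishes outside ``supp mu`` (inside the 0.95 disc),
the solver square only needs to contain the support: the default is
``[-1.05, 1.05)^2``.  The integral defining ``tau`` is the plain midpoint
quadrature of ``u_plus - u_minus``, which is supported inside the square, so
no far-field truncation error is incurred.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._fourier import PeriodicOps
from ._gmres import solve_real_linear
from .exceptions import ConfigurationError, ContractViolation, DomainError
from .grids import PlaneGrid

__all__ = [
    "BeltramiCoefficient",
    "BeltramiSolution",
    "TauGrid",
    "SolverOptions",
    "solve_beltrami",
    "tau_at_k",
    "scattering_sweep",
]

DEFAULT_SOLVER_GRID = PlaneGrid(64, 1.05)


@dataclass
class SolverOptions:
    """Krylov settings for the Beltrami solve."""

    tol: float = 1e-6
    maxiter: int = 60
    dtype: type = np.complex64
    # spectral nodes per GMRES call; None picks a size that bounds the
    # working set (~2^22 unknowns per batch) for the solver grid in use
    batch_size: int | None = None

    def effective_batch(self, grid_n: int) -> int:
        if self.batch_size is not None:
            return self.batch_size
        return max(1, 2**22 // (grid_n * grid_n))
    # Scattering data of a real coefficient obeys tau(-conj(k)) = conj(tau(k))
    # (asserted numerically in the test suite); when set, only half of the
    # k-plane is solved and the rest is filled by conjugation.
    use_symmetry: bool = True


@dataclass
class BeltramiCoefficient:
    """``+/- mu`` sampled on a :class:`PlaneGrid` solver square."""

    mu: np.ndarray
    grid: PlaneGrid
    sign: int = +1

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        if self.mu.shape != (self.grid.n, self.grid.n):
            raise ContractViolation("mu shape does not match the solver grid")
        if np.max(np.abs(self.mu)) >= 1.0:
            raise DomainError("|mu| must be < 1 everywhere")

    def flipped(self) -> "BeltramiCoefficient":
        return BeltramiCoefficient(-self.mu, self.grid, -self.sign)


@dataclass
class BeltramiSolution:
    """``M(z, k) = exp(-ikz) f(z, k)`` on the solver grid, for one ``k``.

    ``dbar_M`` stores ``u = dbar_z M`` (the solver unknown), from which the
    scattering integrand is formed without numerical differentiation.
    """

    M: np.ndarray
    k: complex
    grid: PlaneGrid
    dbar_M: np.ndarray | None = None
    residual: float = 0.0

    def outer_annulus_mean(self, fraction: float = 0.1) -> complex:
        """Mean of ``M`` over the outer ``fraction`` frame of the square
        (asymptotic contract: close to 1)."""
        n = self.grid.n
        w = max(1, int(round(fraction * n)))
        mask = np.zeros((n, n), dtype=bool)
        mask[:w, :] = mask[-w:, :] = True
        mask[:, :w] = mask[:, -w:] = True
        return complex(self.M[mask].mean())


@dataclass
class TauGrid:
    """Beltrami scattering data on a uniform k-grid over ``[-R, R)^2``.

    ``tau`` is zero at nodes with ``|k| > R`` (the corners of the square).
    """

    tau: np.ndarray
    kgrid: PlaneGrid

    @property
    def R(self) -> float:
        return self.kgrid.halfwidth

    def __post_init__(self):
        self.tau = np.asarray(self.tau, dtype=complex)
        if self.tau.shape != (self.kgrid.n, self.kgrid.n):
            raise ContractViolation("tau shape does not match the k-grid")
        if not np.all(np.isfinite(self.tau)):
            raise DomainError("tau must be finite")


# ---------------------------------------------------------------------------
# core batched solver
# ---------------------------------------------------------------------------

def _solve_u_batch(mu: np.ndarray, grid: PlaneGrid, ops: PeriodicOps,
                   ks: np.ndarray, signs: np.ndarray,
                   opts: SolverOptions) -> tuple[np.ndarray, np.ndarray]:
    """Solve the real-linear equation for ``u`` at a batch of (k, sign).

    Returns ``(u, residuals)`` with ``u`` of shape ``(B, n, n)``.
    """
    z = grid.z.astype(opts.dtype)
    ks = np.asarray(ks, dtype=complex)
    phase = np.exp(-2j * (ks[:, None, None] * z[None]).real).astype(opts.dtype)
    nu = signs[:, None, None] * mu[None].astype(opts.dtype) * phase
    kbar = np.conj(ks).astype(opts.dtype)[:, None, None]

    def A(w: np.ndarray) -> np.ndarray:
        Pw, Sw = ops.cauchy_and_beurling(w)
        return nu * (np.conj(Sw) - 1j * kbar * np.conj(Pw))

    b = -1j * kbar * nu
    res = solve_real_linear(A, b, tol=opts.tol, maxiter=opts.maxiter)
    return res.x, res.residuals


def solve_beltrami(coeff: BeltramiCoefficient, k: complex,
                   options: SolverOptions | None = None) -> BeltramiSolution:
    """Exponentially-behaving Beltrami solution ``M`` for one ``k``."""
    opts = options or SolverOptions()
    if not np.isfinite(k):
        raise DomainError("k must be finite")
    ops = PeriodicOps(coeff.grid, opts.dtype)
    # coeff.mu already stores the signed coefficient values
    u, res = _solve_u_batch(coeff.mu, coeff.grid, ops,
                            np.array([k]), np.ones(1), opts)
    M = 1.0 + ops.cauchy(u)
    return BeltramiSolution(M[0], k, coeff.grid, dbar_M=u[0],
                            residual=float(res[0]))


def tau_at_k(m_plus: BeltramiSolution, m_minus: BeltramiSolution) -> complex:
    """Scattering value ``tau(k)`` from the two Beltrami solutions.

    Uses the stored ``dbar_M`` fields when available (exact in the discrete
    formulation); falls back to spectral differentiation of ``M_plus -
    M_minus`` otherwise.
    """
    if m_plus.grid != m_minus.grid or m_plus.k != m_minus.k:
        raise ContractViolation("solutions must share grid and k")
    grid = m_plus.grid
    if m_plus.dbar_M is not None and m_minus.dbar_M is not None:
        integrand = m_plus.dbar_M - m_minus.dbar_M
    else:
        import scipy.fft as sfft

        diff = m_plus.M - m_minus.M
        freq = 2.0 * np.pi * sfft.fftfreq(grid.n, d=grid.h)
        xi = freq[None, :] + 1j * freq[:, None]
        integrand = sfft.ifft2(sfft.fft2(diff) * (1j * xi / 2.0))
    integral = integrand.sum() * grid.h**2
    return complex(np.conj(integral / (2.0 * np.pi)))


def scattering_sweep(coeff: BeltramiCoefficient, kgrid: PlaneGrid,
                     options: SolverOptions | None = None) -> TauGrid:
    """Evaluate ``tau`` on every node of ``kgrid`` with ``|k| <= R``.

    The per-``k`` problems are independent; they are solved in batches (both
    coefficient signs together) and the result does not depend on the batch
    partition or execution order.
    """
    opts = options or SolverOptions()
    if coeff.sign != +1:
        raise ConfigurationError("pass the +mu coefficient; the sweep forms -mu itself")
    ops = PeriodicOps(coeff.grid, opts.dtype)
    R = kgrid.halfwidth
    n = kgrid.n
    kz = kgrid.z
    active = kgrid.radius_mask(R)
    if opts.use_symmetry:
        # solve Re(k) >= 0 plus the unpaired leftmost column; mirror the rest
        jj = np.arange(n)
        solve_cols = (jj >= n // 2) | (jj == 0)
        solve_mask = active & solve_cols[None, :]
    else:
        solve_mask = active
    ks = kz[solve_mask]
    tau = np.zeros(kz.shape, dtype=complex)
    vals = np.empty(ks.shape[0], dtype=complex)
    half = max(1, opts.effective_batch(coeff.grid.n) // 2)
    for start in range(0, ks.shape[0], half):
        kb = ks[start:start + half]
        stacked_k = np.concatenate([kb, kb])
        signs = np.concatenate([np.ones(len(kb)), -np.ones(len(kb))])
        u, _ = _solve_u_batch(coeff.mu, coeff.grid, ops, stacked_k, signs, opts)
        diff = u[: len(kb)] - u[len(kb):]
        integrals = diff.sum(axis=(1, 2)) * coeff.grid.h**2
        vals[start:start + half] = np.conj(integrals / (2.0 * np.pi))
    tau[solve_mask] = vals
    if opts.use_symmetry:
        for j in range(1, n // 2):
            src = n - j  # mirror column: x[n - j] = -x[j]
            fill = active[:, j] & ~solve_cols[j]
            tau[fill, j] = np.conj(tau[fill, src])
    return TauGrid(tau, kgrid)
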