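"""Schrödinger scattering data and the dbar_k reconstruction.

The Beltrami scattering data ``tau`` is related to the Schrödinger
scattering data by ``t(k) = -4 pi i conj(k) tau(k)`` (with ``t(0) = 0``).
After truncation to ``|k| <= R_cut``, clipping of runaway values
(``|Re t|`` or ``|Im t|`` above a threshold, default 24), and optional
regridding, the conductivity is recovered by solving, for each image point
``z``, the integral form of the dbar_k equation

    m(z, kappa) = 1 + (1/4 pi^2) int t(k) e(z, -k) / ((kappa - k) conj(k))
                                   conj(m(z, k)) dk_1 dk_2,

with ``e(z, k) = exp(i (k z + conj(k z)))``, and reading off the low-pass
image ``sigma_DB(z) = sigma_b * (m(z, 0))^2``.  Truncating the scattering
data acts as low-pass regularization: smaller ``R_cut`` gives smoother,
more robust images.

The convolution with the Cauchy kernel ``1/kappa`` is evaluated by FFT on a
doubled grid and the real-linear system is solved by batched GMRES over
image points (see ``_gmres``); results are independent of how the ``z``
batch is partitioned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RectBivariateSpline

from ._fourier import PeriodicOps
from ._gmres import solve_real_linear
from .beltrami import TauGrid
from .exceptions import ConfigurationError, ContractViolation, DomainError
from .grids import ImageGrid, PlaneGrid

__all__ = [
    "ScatteringData",
    "DbarField",
    "DbarReconstruction",
    "DbarOptions",
    "tau_to_t",
    "apply_cutoffs",
    "regrid_scattering",
    "solve_dbar_at_z",
    "reconstruct_image",
]

DEFAULT_THRESH = 24.0


@dataclass
class DbarOptions:
    tol: float = 1e-5
    maxiter: int = 60
    dtype: type = np.complex64
    # image points per GMRES call; None bounds the working set by the k-grid
    batch_size: int | None = None

    def effective_batch(self, kgrid_n: int) -> int:
        if self.batch_size is not None:
            return self.batch_size
        return max(1, 2**22 // (kgrid_n * kgrid_n))


@dataclass
class ScatteringData:
    """Schrödinger-type scattering data on a uniform k-grid.

    ``R_cut`` is the active truncation radius (data is zero beyond it once
    cutoffs have been applied); ``thresh`` the magnitude cutoff applied, if
    any; ``provenance`` records whether the data came from the Beltrami
    route (``"beltrami"``) or from boundary measurements (``"exp"``).
    """

    t: np.ndarray
    kgrid: PlaneGrid
    R_cut: float
    thresh: float | None = None
    provenance: str = "beltrami"

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=complex)
        if self.t.shape != (self.kgrid.n, self.kgrid.n):
            raise ContractViolation("t shape does not match its k-grid")
        if not np.all(np.isfinite(self.t)):
            raise DomainError("scattering data must be finite")


@dataclass
class DbarField:
    """``m(z, .)`` on the k-grid for one image point ``z``."""

    m: np.ndarray
    z: complex
    kgrid: PlaneGrid
    residual: float = 0.0

    @property
    def m_at_zero(self) -> complex:
        i0 = self.kgrid.origin_index
        return complex(self.m[i0, i0])

    def outer_annulus_mean(self, fraction: float = 0.1) -> complex:
        n = self.kgrid.n
        w = max(1, int(round(fraction * n)))
        mask = np.zeros((n, n), dtype=bool)
        mask[:w, :] = mask[-w:, :] = True
        mask[:, :w] = mask[:, -w:] = True
        return complex(self.m[mask].mean())


@dataclass
class DbarReconstruction:
    sigma: np.ndarray  # sigma_DB, real, on `grid`
    grid: ImageGrid
    sigma_b: float
    R_cut: float
    imag_ratio_median: float = 0.0  # diagnostic: |Im m0^2| / |Re m0^2|

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not np.all(np.isfinite(self.sigma)):
            raise DomainError("reconstruction must be finite")


# ---------------------------------------------------------------------------
# scattering-data plumbing
# ---------------------------------------------------------------------------

def tau_to_t(tau: TauGrid) -> ScatteringData:
    """``t(k) = -4 pi i conj(k) tau(k)``; the ``k = 0`` node carries 0."""
    k = tau.kgrid.z
    t = -4.0 * np.pi * 1j * np.conj(k) * tau.tau
    i0 = tau.kgrid.origin_index
    t[i0, i0] = 0.0
    return ScatteringData(t, tau.kgrid, R_cut=tau.R, provenance="beltrami")


def apply_cutoffs(sd: ScatteringData, R_cut: float | None = None,
                  thresh: float = DEFAULT_THRESH) -> ScatteringData:
    """Zero the data outside ``|k| <= R_cut`` (inclusive) and wherever the
    real or imaginary part exceeds ``thresh`` in magnitude.  Idempotent."""
    if R_cut is None:
        R_cut = sd.R_cut
    if R_cut < 0 or thresh < 0:
        raise DomainError("cutoff radius and threshold must be nonnegative")
    t = sd.t.copy()
    t[~sd.kgrid.radius_mask(R_cut)] = 0.0
    t[(np.abs(t.real) > thresh) | (np.abs(t.imag) > thresh)] = 0.0
    return ScatteringData(t, sd.kgrid, R_cut=min(R_cut, sd.R_cut),
                          thresh=thresh, provenance=sd.provenance)


def regrid_scattering(sd: ScatteringData, R_new: float,
                      q_new: int = 6) -> ScatteringData:
    """Interpolate onto a fresh ``2^q_new`` grid over ``[-R_new, R_new)^2``.

    Piecewise-cubic spline interpolation on real and imaginary parts
    separately; target nodes outside the source grid's coverage get zero.
    Cutoffs are *not* applied here -- call :func:`apply_cutoffs` afterwards
    (interpolate first, then threshold).
    """
    if q_new < 4:
        raise ConfigurationError("regrid target coarser than 2^4 is meaningless")
    if R_new <= 0:
        raise DomainError("R_new must be positive")
    new_grid = PlaneGrid(2**q_new, R_new)
    xs = sd.kgrid.x
    sp_re = RectBivariateSpline(xs, xs, sd.t.real, kx=3, ky=3)
    sp_im = RectBivariateSpline(xs, xs, sd.t.imag, kx=3, ky=3)
    xn = new_grid.x
    inside = (xn >= xs[0]) & (xn <= xs[-1])
    t = np.zeros((new_grid.n, new_grid.n), dtype=complex)
    xi = xn[inside]
    block = sp_re(xi, xi) + 1j * sp_im(xi, xi)
    rows = np.where(inside)[0]
    t[np.ix_(rows, rows)] = block
    return ScatteringData(t, new_grid, R_cut=min(R_new, sd.R_cut),
                          thresh=sd.thresh, provenance=sd.provenance)


# ---------------------------------------------------------------------------
# dbar_k solves
# ---------------------------------------------------------------------------

def _solve_m_batch(sd: ScatteringData, zs: np.ndarray, ops: PeriodicOps,
                   opts: DbarOptions) -> tuple[np.ndarray, np.ndarray]:
    """Solve the dbar_k integral equation for a batch of image points."""
    kg = sd.kgrid
    k = kg.z
    with np.errstate(divide="ignore", invalid="ignore"):
        T = sd.t / (4.0 * np.pi**2 * np.conj(k))
    i0 = kg.origin_index
    T[i0, i0] = 0.0  # t(k)/conj(k) carries 0 at k = 0
    T = T.astype(opts.dtype)
    zs = np.asarray(zs, dtype=complex)
    E = np.exp(-2j * (k[None] * zs[:, None, None]).real).astype(opts.dtype)
    TE = T[None] * E

    def A(m: np.ndarray) -> np.ndarray:
        # kernel 1/kappa = pi * (1/(pi kappa))
        return np.pi * ops.cauchy(TE * np.conj(m))

    b = np.ones((zs.shape[0], kg.n, kg.n), dtype=opts.dtype)
    res = solve_real_linear(A, b, tol=opts.tol, maxiter=opts.maxiter)
    return res.x, res.residuals


def solve_dbar_at_z(sd: ScatteringData, z: complex,
                    options: DbarOptions | None = None) -> DbarField:
    """``m(z, .)`` for a single image point."""
    opts = options or DbarOptions()
    ops = PeriodicOps(sd.kgrid, opts.dtype)
    m, res = _solve_m_batch(sd, np.array([z]), ops, opts)
    return DbarField(m[0], z, sd.kgrid, residual=float(res[0]))


def reconstruct_image(sd: ScatteringData, sigma_b: float = 1.0,
                      grid: ImageGrid | None = None,
                      solver_grid: ImageGrid | None = None,
                      options: DbarOptions | None = None) -> DbarReconstruction:
    """Low-pass D-bar image ``sigma_DB = sigma_b * Re[(m(z, 0))^2]``.

    ``m(z, 0)`` is solved at every node of ``solver_grid`` (default: the
    output grid itself).  Because the image is low-pass by construction --
    spatial detail is limited by the truncation radius -- it can be solved on
    a coarser grid and spline-upsampled to ``grid`` without visible loss;
    this is the desk-scale production path.  The imaginary part of ``m^2``
    is recorded as a diagnostic (it is discretization noise; conductivities
    are real).
    """
    opts = options or DbarOptions()
    grid = grid or ImageGrid(64)
    sgrid = solver_grid or grid
    ops = PeriodicOps(sd.kgrid, opts.dtype)
    zs = sgrid.z.ravel()
    i0 = sd.kgrid.origin_index
    m0 = np.empty(zs.shape[0], dtype=complex)
    step = opts.effective_batch(sd.kgrid.n)
    for start in range(0, zs.shape[0], step):
        m, _ = _solve_m_batch(sd, zs[start:start + step], ops, opts)
        m0[start:start + step] = m[:, i0, i0]
    msq = (m0**2).reshape(sgrid.z.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.abs(msq.imag) / np.maximum(np.abs(msq.real), 1e-30)
    sigma = sigma_b * msq.real
    if sgrid.n != grid.n:
        sp = RectBivariateSpline(sgrid.x, sgrid.x, sigma, kx=3, ky=3)
        sigma = sp(grid.x, grid.x)
    return DbarReconstruction(sigma, grid, sigma_b=sigma_b, R_cut=sd.R_cut,
                              imag_ratio_median=float(np.median(ratios)))
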