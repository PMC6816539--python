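"""Measurement-side path: ND/DN matrices and the 'exp' scattering data.

Electrode current--voltage data determines a discrete Neumann-to-Dirichlet
(ND) matrix on the applied current-pattern basis,

    R_sigma(m, n) = sum_l phi_l^m v_l^n |e_l|,

with ``phi^m`` the normalized current patterns, ``v^n`` the matching
voltage vectors and ``|e_l|`` the electrode widths.  The DN matrix is its
inverse on that basis.  After scaling to a unit-radius domain with unit
boundary conductivity, the modified Schrödinger 'exp' scattering data

    t_exp(k) = oint e^{i conj(k z)} [ Lambda_sigma(e^{ikz})
                                      - i k nu e^{ikz} ] ds(z)

feeds the same dbar_k solver as the simulated training data; the recovered
conductivity is rescaled by the boundary conductivity ``sigma_0``
afterwards.

Because no archival tank data is shipped, an analytic forward model plays
the role of the measurement device: the DN map of the unit disc with a
concentric circular inclusion is diagonal on the trigonometric basis with
the classical reflection eigenvalues

    lambda_n = |n| (1 - mu_r rho^{2|n|}) / (1 + mu_r rho^{2|n|}),
    mu_r = (1 - sigma_1) / (1 + sigma_1),

(validated against a dense radial finite-difference solve in the tests);
voltages for arbitrary pattern families are synthesized from it.

Conventions (documented, round-trip tested): current patterns are
normalized to unit norm in the electrode-width-weighted inner product
``<f, g> = sum_l f_l g_l |e_l|``; the same constant rescales the matching
voltage vector.  On this basis the ND matrix of a homogeneous disc of
radius ``r`` and conductivity ``sigma_0`` has eigenvalues ``r/(sigma_0
|n|)``, so the unit scaling multiplies ND by ``sigma_0 / r_max`` (divides
DN).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .dbar import ScatteringData
from .exceptions import ConfigurationError, ContractViolation, DomainError
from .grids import PlaneGrid

__all__ = [
    "ElectrodeLayout",
    "PatternedData",
    "NDMatrix",
    "DNMatrix",
    "trig_patterns",
    "adjacent_patterns",
    "build_nd_matrix",
    "scale_measurement",
    "best_constant_fit",
    "analytic_dn_disc",
    "disc_dn_eigenvalues",
    "synthesize_voltage_data",
    "texp_scattering",
]


# ---------------------------------------------------------------------------
# layout and patterns
# ---------------------------------------------------------------------------

@dataclass
class ElectrodeLayout:
    """Electrode positions on a closed boundary curve.

    The boundary is parameterized uniformly by ``t in [0, 2 pi)``; electrode
    ``l`` is centered at parameter ``2 pi l / L``.  For non-circular
    boundaries pass ``boundary_samples`` (uniform-in-parameter closed curve
    samples, shape ``(P, 2)``); normals are then computed by periodic spline
    differentiation of the parameterization.
    """

    L: int
    widths: np.ndarray  # arc-length widths, same units as the curve
    radius: float | None = 1.0  # circular tank radius; None for general curve
    boundary_samples: np.ndarray | None = None

    def __post_init__(self):
        self.widths = np.broadcast_to(
            np.asarray(self.widths, dtype=float), (self.L,)
        ).copy()
        if self.L < 2:
            raise ConfigurationError("need at least two electrodes")
        if np.any(self.widths <= 0):
            raise ConfigurationError("electrode widths must be positive")
        if self.radius is None and self.boundary_samples is None:
            raise ConfigurationError("give either a radius or boundary samples")
        if self.boundary_samples is not None:
            pts = np.asarray(self.boundary_samples, dtype=float)
            if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 8:
                raise ConfigurationError("boundary samples must be (P>=8, 2)")
            self.boundary_samples = pts
            t = np.linspace(0, 2 * np.pi, pts.shape[0] + 1)
            closed = np.vstack([pts, pts[:1]])
            self._spline = CubicSpline(t, closed, bc_type="periodic")
        else:
            self._spline = None
        # electrodes must not overlap along the curve
        total = self.perimeter()
        if self.widths.sum() > total + 1e-12:
            raise ConfigurationError("electrode widths exceed the perimeter")

    @classmethod
    def disc(cls, L: int, radius: float = 1.0, width: float | None = None):
        """Circular tank; default width covers 85% of the electrode pitch."""
        if width is None:
            width = 0.85 * 2 * np.pi * radius / L
        return cls(L=L, widths=np.full(L, width), radius=radius)

    @property
    def electrode_params(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.L) / self.L

    def points(self, t: np.ndarray) -> np.ndarray:
        """Boundary points as complex numbers at parameters ``t``."""
        t = np.asarray(t, dtype=float)
        if self._spline is None:
            return self.radius * np.exp(1j * t)
        xy = self._spline(np.mod(t, 2 * np.pi))
        return xy[..., 0] + 1j * xy[..., 1]

    def normals(self, t: np.ndarray) -> np.ndarray:
        """Outward unit normals (complex) at parameters ``t``."""
        t = np.asarray(t, dtype=float)
        if self._spline is None:
            return np.exp(1j * t)
        d = self._spline(np.mod(t, 2 * np.pi), 1)
        tang = d[..., 0] + 1j * d[..., 1]
        nrm = -1j * tang  # rotate tangent clockwise: outward for ccw curves
        return nrm / np.abs(nrm)

    def speed(self, t: np.ndarray) -> np.ndarray:
        """``|dz/dt|`` at parameters ``t`` (arc measure)."""
        t = np.asarray(t, dtype=float)
        if self._spline is None:
            return np.full(np.shape(t), float(self.radius))
        d = self._spline(np.mod(t, 2 * np.pi), 1)
        return np.hypot(d[..., 0], d[..., 1])

    def perimeter(self, n: int = 2048) -> float:
        t = np.linspace(0, 2 * np.pi, n, endpoint=False)
        return float(np.sum(self.speed(t)) * 2 * np.pi / n)

    @property
    def r_max(self) -> float:
        """Radius of the smallest origin-centered circle containing the domain."""
        if self._spline is None:
            return float(self.radius)
        return float(np.max(np.abs(self.points(
            np.linspace(0, 2 * np.pi, 2048, endpoint=False)))))

    def scaled_to_unit(self) -> "ElectrodeLayout":
        """The layout shrunk by ``r_max`` so the domain fits the unit disc."""
        r = self.r_max
        if self._spline is None:
            return ElectrodeLayout(self.L, self.widths / r, radius=self.radius / r)
        return ElectrodeLayout(self.L, self.widths / r, radius=None,
                               boundary_samples=self.boundary_samples / r)


def trig_patterns(L: int, num_li: int | None = None) -> np.ndarray:
    """Trigonometric current patterns (rows), ``cos(j t_l)`` then
    ``sin(j t_l)``, maximum ``L - 1`` linearly independent zero-sum vectors."""
    num_li = (L - 1) if num_li is None else num_li
    if not 1 <= num_li <= L - 1:
        raise ConfigurationError("num_li must be in [1, L-1]")
    t = 2.0 * np.pi * np.arange(L) / L
    rows = [np.cos(j * t) for j in range(1, L // 2 + 1)]
    rows += [np.sin(j * t) for j in range(1, (L - 1) // 2 + 1)]
    return np.asarray(rows)[:num_li]


def adjacent_patterns(L: int) -> np.ndarray:
    """Adjacent (skip-0) current patterns: +1 / -1 on neighboring
    electrodes; ``L - 1`` independent patterns."""
    out = np.zeros((L - 1, L))
    for m in range(L - 1):
        out[m, m] = 1.0
        out[m, m + 1] = -1.0
    return out


@dataclass
class PatternedData:
    """Per-pattern electrode currents and voltages (rows = patterns)."""

    currents: np.ndarray  # (num_LI, L)
    voltages: np.ndarray  # (num_LI, L)
    family: str = "trigonometric"

    def __post_init__(self):
        self.currents = np.asarray(self.currents, dtype=float)
        self.voltages = np.asarray(self.voltages, dtype=float)
        if self.currents.shape != self.voltages.shape:
            raise ContractViolation("currents and voltages must align")
        if self.currents.ndim != 2:
            raise ContractViolation("patterned data must be 2-D (pattern, electrode)")
        sums = np.abs(self.currents.sum(axis=1))
        if np.any(sums > 1e-8 * np.abs(self.currents).max()):
            raise ContractViolation("current patterns must sum to zero")

    @property
    def num_li(self) -> int:
        return self.currents.shape[0]


@dataclass
class BoundaryMatrix:
    matrix: np.ndarray
    layout: ElectrodeLayout
    patterns: np.ndarray  # normalized pattern vectors (num_LI, L)
    scaled: bool = False  # True once unit-radius / unit-conductivity scaled
    sigma_0: float | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ContractViolation("boundary matrix must be square")
        if m.shape[0] != self.patterns.shape[0]:
            raise ContractViolation("matrix size must match the pattern count")


class NDMatrix(BoundaryMatrix):
    def invert(self) -> "DNMatrix":
        return DNMatrix(np.linalg.inv(self.matrix), self.layout, self.patterns,
                        scaled=self.scaled, sigma_0=self.sigma_0)


class DNMatrix(BoundaryMatrix):
    def invert(self) -> "NDMatrix":
        return NDMatrix(np.linalg.inv(self.matrix), self.layout, self.patterns,
                        scaled=self.scaled, sigma_0=self.sigma_0)


# ---------------------------------------------------------------------------
# building and scaling the ND matrix
# ---------------------------------------------------------------------------

def _weighted_norms(patterns: np.ndarray, widths: np.ndarray) -> np.ndarray:
    return np.sqrt(np.einsum("ml,l,ml->m", patterns, widths, patterns))


def build_nd_matrix(data: PatternedData, layout: ElectrodeLayout) -> NDMatrix:
    """Discrete ND matrix ``R(m, n) = sum_l phi_l^m v_l^n |e_l|``.

    Current patterns are normalized to unit width-weighted norm; each
    voltage vector is rescaled by the same constant as its current pattern
    (linearity of the ND map), so the result is the matrix of the ND
    operator on the normalized pattern basis.
    """
    if data.currents.shape[1] != layout.L:
        raise ContractViolation("pattern length does not match electrode count")
    w = layout.widths
    norms = _weighted_norms(data.currents, w)
    if np.any(norms == 0):
        raise ContractViolation("zero current pattern")
    phi = data.currents / norms[:, None]
    v = data.voltages / norms[:, None]
    R = np.einsum("ml,l,nl->mn", phi, w, v)
    return NDMatrix(R, layout, phi)


def scale_measurement(nd: NDMatrix, r_max: float | None = None,
                      sigma_0: float = 1.0) -> NDMatrix:
    """Scale a measured ND matrix to the unit disc with unit boundary
    conductivity: ND scales by ``sigma_0 / r_max`` (its eigenvalues on a
    homogeneous disc are ``r / (sigma_0 |n|)``).  The layout is shrunk
    accordingly; reconstructions must be rescaled by ``sigma_0`` at the end.
    """
    if r_max is None:
        r_max = nd.layout.r_max
    if r_max <= 0 or sigma_0 <= 0:
        raise DomainError("scales must be positive")
    # pattern vectors renormalized to the shrunk widths (|e_l| -> |e_l|/r)
    return NDMatrix(nd.matrix * (sigma_0 / r_max), nd.layout.scaled_to_unit(),
                    nd.patterns * np.sqrt(r_max), scaled=True, sigma_0=sigma_0)


def _fourier_coeff_matrix(patterns: np.ndarray) -> np.ndarray:
    """Complex Fourier coefficients (over electrode index) of each pattern."""
    return np.fft.fft(patterns, axis=1) / patterns.shape[1]


def _apply_disc_nd(patterns: np.ndarray, radius: float, sigma: float) -> np.ndarray:
    """Apply the homogeneous-disc ND operator (eigenvalues ``r/(sigma |n|)``)
    to current-density samples via the DFT over electrodes."""
    L = patterns.shape[1]
    coeff = np.fft.fft(patterns, axis=1)
    n = np.fft.fftfreq(L, d=1.0 / L)
    lam = np.zeros(L)
    nz = n != 0
    lam[nz] = radius / (sigma * np.abs(n[nz]))
    return np.real(np.fft.ifft(coeff * lam[None, :], axis=1))


def best_constant_fit(data: PatternedData, layout: ElectrodeLayout) -> float:
    """Best constant-conductivity fit ``sigma_0`` to the measured ND matrix.

    Minimizes ``|| R_meas - (1/sigma_0) R_ref ||_F`` where ``R_ref`` is the
    analytic ND matrix of the layout's disc geometry at unit conductivity
    (ND is inversely proportional to a constant conductivity).
    """
    if layout.radius is None:
        raise ConfigurationError("constant fit assumes a circular tank geometry")
    R_meas = build_nd_matrix(data, layout)
    phi = R_meas.patterns
    v_ref = _apply_disc_nd(phi, layout.radius, 1.0)
    R_ref = np.einsum("ml,l,nl->mn", phi, layout.widths, v_ref)
    denom = float(np.sum(R_meas.matrix * R_ref))
    if denom == 0 or not np.any(R_meas.matrix):
        raise DomainError("degenerate measurement data")
    return float(np.sum(R_ref * R_ref) / denom)


# ---------------------------------------------------------------------------
# analytic concentric-disc forward model
# ---------------------------------------------------------------------------

def disc_dn_eigenvalues(sigma_inner: float, rho: float, orders: np.ndarray,
                        sigma_outer: float = 1.0, radius: float = 1.0) -> np.ndarray:
    """DN eigenvalues of a disc of ``radius`` with background
    ``sigma_outer`` and a concentric inclusion (radius ``rho * radius``,
    conductivity ``sigma_inner``), on the basis ``e^{i n theta}``:

        lambda_n = sigma_outer |n| / radius
                   * (1 - mu_r rho^{2|n|}) / (1 + mu_r rho^{2|n|}),

    with ``mu_r = (sigma_outer - sigma_inner) / (sigma_outer + sigma_inner)``.
    """
    if not 0.0 < rho < 1.0:
        raise DomainError("inclusion radius fraction must be in (0, 1)")
    if sigma_inner <= 0 or sigma_outer <= 0:
        raise DomainError("conductivities must be positive")
    n = np.abs(np.asarray(orders, dtype=float))
    mu_r = (sigma_outer - sigma_inner) / (sigma_outer + sigma_inner)
    q = mu_r * rho ** (2 * n)
    lam = np.zeros_like(n)
    nz = n > 0
    lam[nz] = sigma_outer * n[nz] / radius * (1 - q[nz]) / (1 + q[nz])
    return lam


def analytic_dn_disc(sigma_inner: float, rho: float, basis_size: int = 16,
                     layout: ElectrodeLayout | None = None,
                     sigma_outer: float = 1.0) -> DNMatrix:
    """DN matrix of a disc with a concentric inclusion, on the (normalized)
    trigonometric pattern basis of ``layout``: diagonal with the classical
    reflection eigenvalues (``sigma_inner = sigma_outer`` or ``rho -> 0``
    reduce to the homogeneous eigenvalues ``sigma_outer |n| / r``).

    With the default unit-disc layout and unit background the matrix is
    already unit-scaled; at physical radius/conductivity it plays the role
    of a tank measurement and must go through :func:`scale_measurement`.
    """
    layout = layout or ElectrodeLayout.disc(32, radius=1.0)
    if layout.radius is None:
        raise ConfigurationError("the analytic forward model is a disc")
    num_li = min(2 * basis_size - 1, layout.L - 1)
    pats = trig_patterns(layout.L, num_li)
    norms = _weighted_norms(pats, layout.widths)
    phi = pats / norms[:, None]
    # mode numbers matching the trig_patterns row order (cos then sin)
    half = layout.L // 2
    orders = np.asarray(
        list(range(1, half + 1)) + list(range(1, (layout.L - 1) // 2 + 1))
    )[:num_li]
    lam = disc_dn_eigenvalues(sigma_inner, rho, orders,
                              sigma_outer=sigma_outer, radius=layout.radius)
    unit = (layout.radius == 1.0 and sigma_outer == 1.0)
    return DNMatrix(np.diag(lam), layout, phi, scaled=unit,
                    sigma_0=sigma_outer if unit else None)


def synthesize_voltage_data(dn: DNMatrix, patterns: np.ndarray,
                            noise_snr_db: float | None = None,
                            rng: np.random.Generator | None = None,
                            family: str = "trigonometric") -> PatternedData:
    """Voltages for the given current patterns under the ND map ``dn^-1``.

    The ND matrix acts on the width-orthonormalized pattern basis of ``dn``;
    arbitrary zero-sum current patterns are expanded on that basis.  Optional
    additive white Gaussian noise at ``noise_snr_db`` (relative to the rms
    voltage) emulates measurement noise; seeded via ``rng``.
    """
    patterns = np.asarray(patterns, dtype=float)
    if patterns.shape[1] != dn.layout.L:
        raise ContractViolation("pattern length does not match the layout")
    nd = np.linalg.inv(dn.matrix)
    w = dn.layout.widths
    # coefficients of the currents on the orthonormal basis
    c = np.einsum("bl,l,ml->bm", patterns, w, dn.patterns)
    resid = patterns - c @ dn.patterns
    if np.linalg.norm(resid) > 1e-8 * max(np.linalg.norm(patterns), 1e-30):
        raise ContractViolation("current patterns outside the measured basis")
    volt = (c @ nd.T) @ dn.patterns
    if noise_snr_db is not None:
        rng = rng or np.random.default_rng()
        std = np.sqrt(np.mean(volt**2)) * 10.0 ** (-noise_snr_db / 20.0)
        volt = volt + rng.normal(0.0, std, size=volt.shape)
    return PatternedData(patterns, volt, family=family)


# ---------------------------------------------------------------------------
# t^exp scattering data
# ---------------------------------------------------------------------------

def _basis_functions_at(patterns: np.ndarray, t_quad: np.ndarray) -> np.ndarray:
    """Evaluate the pattern basis as functions of the boundary parameter.

    Patterns are trigonometric polynomials in the (uniform) electrode
    parameter; their band-limited interpolants are evaluated at arbitrary
    parameters via the DFT coefficients.
    """
    L = patterns.shape[1]
    coeff = np.fft.fft(patterns, axis=1) / L
    n = np.fft.fftfreq(L, d=1.0 / L)  # integer mode numbers
    # interpolate: f(t) = sum_n c_n e^{i n t}; fold the Nyquist mode to cos
    basis = np.zeros((patterns.shape[0], t_quad.shape[0]))
    for idx, mode in enumerate(n):
        wave = np.exp(1j * mode * t_quad)
        if abs(mode) == L // 2:
            wave = np.cos(mode * t_quad)
        basis += np.real(coeff[:, [idx]] * wave[None, :])
    return basis


def texp_scattering(dn: DNMatrix, kgrid: PlaneGrid, R_meas: float = 4.0,
                    n_quad: int = 256) -> ScatteringData:
    """Modified Schrödinger 'exp' scattering data from a unit-scaled DN map.

    For each spectral node ``|k| <= R_meas``, ``e^{ikz}`` is expanded on the
    pattern basis, the DN matrix applied, the analytic homogeneous term ``i
    k nu e^{ikz}`` subtracted, and the boundary integral taken by the
    trapezoidal rule on ``n_quad`` uniform parameter samples.  The ``k = 0``
    node carries 0, as does everything beyond ``R_meas``.
    """
    if not dn.scaled:
        raise ContractViolation("texp needs a unit-scaled DN matrix")
    if R_meas <= 0 or R_meas > kgrid.halfwidth:
        raise DomainError("need 0 < R_meas <= k-grid half-width")
    layout = dn.layout
    t_q = np.linspace(0, 2 * np.pi, n_quad, endpoint=False)
    zq = layout.points(t_q)
    nu = layout.normals(t_q)
    ds = layout.speed(t_q) * (2 * np.pi / n_quad)

    basis_q = _basis_functions_at(dn.patterns, t_q)  # (num_LI, Q)
    # discrete-vs-continuum measure ratio (electrode coverage fraction)
    beta = float(np.sum(layout.widths) / np.sum(ds))

    kz = kgrid.z
    active = kgrid.radius_mask(R_meas)
    i0 = kgrid.origin_index
    active[i0, i0] = False
    t = np.zeros(kz.shape, dtype=complex)
    ks = kz[active]
    # expansions, batched over k
    g = np.exp(1j * ks[:, None] * zq[None, :])  # (K, Q)
    c = np.einsum("kq,mq,q->km", g, basis_q, ds)  # continuum pairing
    d = c @ dn.matrix.T  # apply DN on the basis
    lam_g = beta * (d @ basis_q)  # Lambda_sigma e^{ikz} at quadrature points
    lam_1 = 1j * ks[:, None] * nu[None, :] * g
    integrand = np.exp(1j * np.conj(ks[:, None] * zq[None, :])) * (lam_g - lam_1)
    t[active] = integrand @ ds
    return ScatteringData(t, kgrid, R_cut=R_meas, provenance="exp")
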