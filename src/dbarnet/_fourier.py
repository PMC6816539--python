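"""FFT evaluation of the solid Cauchy and Beurling transforms.

The scattering solvers repeatedly need, for fields ``u`` supported on a
uniform square grid,

* the solid Cauchy transform ``(P u)(z) = (1/pi) int u(w) / (z - w) dA(w)``
  (the inverse of ``dbar``), and
* the Beurling transform ``S u = d_z (P u)``.

Both are evaluated on a grid twice the linear size of the data grid so that
the circular convolution reproduces the non-periodic sum exactly for data
supported on the original grid: every offset between a source and a target
node of the original grid is represented exactly once on the doubled grid.
``P`` is applied as a convolution with the sampled kernel ``1/(pi z)``
(midpoint quadrature, singular node set to zero); ``S`` is applied as the
Fourier multiplier ``conj(xi)/xi`` on the doubled grid, which is spectrally
accurate up to the periodization of the ``1/z^2`` tail.

The same machinery serves the ``dbar_k`` integral equation, whose kernel is
``1/kappa = pi * (1/(pi kappa))``.
"""

from __future__ import annotations

import numpy as np
import scipy.fft as sfft

from .grids import PlaneGrid

__all__ = ["PeriodicOps"]


def _wrapped_offsets(n: int, h: float) -> np.ndarray:
    """Offsets ``d*h`` for ``d = -n..n-1`` arranged for circular convolution."""
    idx = np.arange(2 * n)
    return (((idx + n) % (2 * n)) - n) * h


class PeriodicOps:
    """Precomputed transforms for one :class:`PlaneGrid`.

    Parameters
    ----------
    grid:
        Data grid; inputs to the transforms have trailing shape
        ``(grid.n, grid.n)`` and arbitrary leading (batch) dimensions.
    dtype:
        Complex dtype used internally.  ``complex64`` is the production
        default (the Krylov tolerances used downstream sit comfortably above
        single-precision round-off); pass ``complex128`` for high-accuracy
        studies.
    """

    def __init__(self, grid: PlaneGrid, dtype=np.complex64):
        self.grid = grid
        self.dtype = np.dtype(dtype)
        n, h = grid.n, grid.h
        off = _wrapped_offsets(n, h)
        zoff = off[None, :] + 1j * off[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            cauchy_kernel = 1.0 / (np.pi * zoff)
        cauchy_kernel[0, 0] = 0.0
        # h^2 quadrature weight folded into the kernel transform
        self._cauchy_hat = sfft.fft2(cauchy_kernel.astype(self.dtype)) * (h * h)

        freq = 2.0 * np.pi * sfft.fftfreq(2 * n, d=h)
        xi = freq[None, :] + 1j * freq[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            beurling = np.conj(xi) / xi
        beurling[0, 0] = 0.0
        self._beurling_hat = beurling.astype(self.dtype)

    # -- internals ---------------------------------------------------------
    def _pad_fft(self, u: np.ndarray) -> np.ndarray:
        n = self.grid.n
        shape = u.shape[:-2] + (2 * n, 2 * n)
        buf = np.zeros(shape, dtype=self.dtype)
        buf[..., :n, :n] = u
        return sfft.fft2(buf, axes=(-2, -1))

    def _crop_ifft(self, uhat: np.ndarray) -> np.ndarray:
        n = self.grid.n
        return sfft.ifft2(uhat, axes=(-2, -1))[..., :n, :n]

    # -- public API --------------------------------------------------------
    def cauchy(self, u: np.ndarray) -> np.ndarray:
        """Solid Cauchy transform ``P u`` on the data grid."""
        return self._crop_ifft(self._pad_fft(u) * self._cauchy_hat)

    def beurling(self, u: np.ndarray) -> np.ndarray:
        """Beurling transform ``S u = d_z P u`` on the data grid."""
        return self._crop_ifft(self._pad_fft(u) * self._beurling_hat)

    def cauchy_and_beurling(self, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Both transforms from a single forward FFT of ``u``."""
        uhat = self._pad_fft(u)
        return (
            self._crop_ifft(uhat * self._cauchy_hat),
            self._crop_ifft(uhat * self._beurling_hat),
        )
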