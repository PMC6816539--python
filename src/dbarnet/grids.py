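"""Square grids used throughout the pipeline.

Two kinds of grid appear:

* :class:`PlaneGrid` -- a uniform periodic-style grid on ``[-s, s)`` per axis
  with ``n`` nodes and spacing ``h = 2 s / n``.  The origin is a node
  (index ``n // 2``), which is required by the scattering solvers: the
  spectral parameter ``k = 0`` and the evaluation of ``m(z, 0)`` must fall on
  grid nodes.  These grids are the natural domain for the FFT-based Cauchy /
  Beurling transforms.

* :class:`ImageGrid` -- a node-centered grid on ``[-1, 1]`` *including both
  endpoints* (``numpy.linspace(-1, 1, n)``), the convention used for
  conductivity images; with ``n = 64`` the spacing is ``2/63 ~ 0.0317``.

Array orientation follows the row-major image convention: the first index of
a field increases with the second coordinate ``x2`` (the imaginary part of
``z = x1 + i x2``), the second index with ``x1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PlaneGrid", "ImageGrid"]


@dataclass(frozen=True)
class PlaneGrid:
    """Uniform grid on ``[-s, s)^2`` with the origin as a node."""

    n: int
    halfwidth: float

    def __post_init__(self) -> None:
        if self.n < 2 or self.n % 2:
            raise ValueError("PlaneGrid needs an even node count >= 2")
        if self.halfwidth <= 0:
            raise ValueError("halfwidth must be positive")

    @property
    def h(self) -> float:
        return 2.0 * self.halfwidth / self.n

    @property
    def x(self) -> np.ndarray:
        return -self.halfwidth + self.h * np.arange(self.n)

    @property
    def z(self) -> np.ndarray:
        """Complex coordinates, shape ``(n, n)``; ``z[i, j] = x[j] + 1j x[i]``."""
        x = self.x
        return x[None, :] + 1j * x[:, None]

    @property
    def origin_index(self) -> int:
        return self.n // 2

    def radius_mask(self, r: float) -> np.ndarray:
        """Boolean mask of nodes with ``|z| <= r`` (inclusive)."""
        return np.abs(self.z) <= r


@dataclass(frozen=True)
class ImageGrid:
    """Node-centered grid on ``[-1, 1]^2`` including endpoints."""

    n: int = 64
    halfwidth: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("ImageGrid needs at least 2 nodes per axis")

    @property
    def h(self) -> float:
        return 2.0 * self.halfwidth / (self.n - 1)

    @property
    def x(self) -> np.ndarray:
        return np.linspace(-self.halfwidth, self.halfwidth, self.n)

    @property
    def z(self) -> np.ndarray:
        x = self.x
        return x[None, :] + 1j * x[:, None]

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        x = self.x
        return np.meshgrid(x, x, indexing="xy")
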