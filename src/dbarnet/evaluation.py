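"""Truth images and image-quality metrics (SSIM, relative l1/l2 errors).

Reconstructions are scored against piecewise-constant "truth" images built
from the known inclusion geometry and per-region conductivities.  Three
metrics are reported:

* SSIM -- mean local-statistics structural similarity, 7x7 uniform window,
  standard stabilization constants ``C1 = (0.01 L)^2``, ``C2 = (0.03 L)^2``
  with data range ``L`` (default: max of the truth image), sample-covariance
  normalization, edges cropped to full windows;
* relative l1 and l2 errors, ``100 * ||recon - truth||_p / ||truth||_p``,
  over the full square or restricted to the unit disc.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .exceptions import ConfigurationError, ContractViolation, DomainError
from .grids import ImageGrid
from .phantoms import ConductivityPhantom, rasterize

__all__ = ["MetricsReport", "build_truth_image", "ssim", "relative_error",
           "evaluate_pair", "evaluate_batch", "write_metrics_csv"]


@dataclass(frozen=True)
class MetricsReport:
    ssim: float
    l1_rel_pct: float
    l2_rel_pct: float
    mask: str = "square"  # {"square", "disc"}


def build_truth_image(phantom: ConductivityPhantom,
                      grid: ImageGrid | None = None) -> np.ndarray:
    """Piecewise-constant truth image on the reconstruction grid.

    Shares the rasterization kernel with the phantom generator: the whole
    designated region of a split/injury carries its single assigned value.
    """
    grid = grid or ImageGrid(64)
    return rasterize(phantom, grid).values


def ssim(a: np.ndarray, b: np.ndarray, data_range: float | None = None,
         win_size: int = 7, k1: float = 0.01, k2: float = 0.03) -> float:
    """Mean structural similarity of two equally-shaped images.

    Symmetric in its arguments; equals 1 exactly for identical images.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ContractViolation("ssim needs two equal-shape 2-D images")
    if min(a.shape) < win_size:
        raise ConfigurationError("window larger than the image")
    if data_range is None:
        data_range = float(b.max())
    if data_range <= 0:
        raise DomainError("data range must be positive")
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    filt = lambda img: uniform_filter(img, size=win_size)
    ua, ub = filt(a), filt(b)
    uaa, ubb, uab = filt(a * a), filt(b * b), filt(a * b)
    np_win = win_size**2
    cov_norm = np_win / (np_win - 1)  # sample covariance
    va = cov_norm * (uaa - ua * ua)
    vb = cov_norm * (ubb - ub * ub)
    vab = cov_norm * (uab - ua * ub)
    s = ((2 * ua * ub + c1) * (2 * vab + c2)) / (
        (ua**2 + ub**2 + c1) * (va + vb + c2))
    pad = (win_size - 1) // 2
    return float(s[pad:-pad, pad:-pad].mean())


def _mask_array(shape: tuple, mask: str) -> np.ndarray:
    if mask == "square":
        return np.ones(shape, dtype=bool)
    if mask == "disc":
        grid = ImageGrid(shape[0])
        return np.abs(grid.z) <= 1.0
    raise ConfigurationError("mask must be 'square' or 'disc'")


def relative_error(recon: np.ndarray, truth: np.ndarray, p: int = 2,
                   mask: str = "square") -> float:
    """``100 * ||recon - truth||_p / ||truth||_p`` over the mask."""
    recon = np.asarray(recon, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if recon.shape != truth.shape:
        raise ContractViolation("images must share a grid")
    if p not in (1, 2):
        raise ConfigurationError("p must be 1 or 2")
    m = _mask_array(truth.shape, mask)
    denom = np.linalg.norm(truth[m].ravel(), ord=p)
    if denom == 0:
        raise DomainError("truth image has zero norm on the mask")
    return float(100.0 * np.linalg.norm((recon - truth)[m].ravel(), ord=p)
                 / denom)


def evaluate_pair(recon: np.ndarray, truth: np.ndarray,
                  mask: str = "square",
                  data_range: float | None = None) -> MetricsReport:
    """All three metrics for one reconstruction/truth pair."""
    return MetricsReport(
        ssim=ssim(recon, truth, data_range=data_range),
        l1_rel_pct=relative_error(recon, truth, p=1, mask=mask),
        l2_rel_pct=relative_error(recon, truth, p=2, mask=mask),
        mask=mask,
    )


def evaluate_batch(recons: np.ndarray, truths: np.ndarray,
                   mask: str = "square") -> list[MetricsReport]:
    """Reports for matched stacks of images, order preserved."""
    if len(recons) != len(truths):
        raise ContractViolation("batch lengths differ")
    return [evaluate_pair(r, t, mask=mask) for r, t in zip(recons, truths)]


def write_metrics_csv(reports: list[MetricsReport], path: str,
                      ids: list | None = None):
    ids = ids if ids is not None else list(range(len(reports)))
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["id", "ssim", "l1_rel_pct", "l2_rel_pct", "mask"])
        for i, rep in zip(ids, reports):
            wr.writerow([i, f"{rep.ssim:.6f}", f"{rep.l1_rel_pct:.4f}",
                         f"{rep.l2_rel_pct:.4f}", rep.mask])
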