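"""End-to-end training-data production and measurement-side reconstruction.

One training pair per phantom: draw a random conductivity, scale it to unit
boundary value, sweep the Beltrami scattering transform, convert to
Schrödinger data, draw a random truncation radius ``R_n`` (uniform on
[3.5, 5] for the thoracic family, [4, 5.5] for the generic family --
varying the cutoff teaches the post-processor to handle reconstructions at
different noise-dictated regularization levels), regrid, threshold, solve
the dbar_k equation, and rescale by the boundary conductivity:

    { sigma_tilde_n , sigma_DB_n }   (both in S/m on the same image grid).

Grid sizes are configurable; :meth:`PipelineConfig.desk` defaults are sized
so that one pair takes about a second on a single CPU, while
:meth:`PipelineConfig.production` mirrors the full-scale settings (2^5
tau-grid, 2^6 dbar-grid, 2^6 image grid solved directly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import phantoms as ph
from .beltrami import BeltramiCoefficient, SolverOptions, scattering_sweep
from .boundary import (ElectrodeLayout, PatternedData, best_constant_fit,
                       build_nd_matrix, scale_measurement, texp_scattering)
from .dbar import (DbarOptions, DbarReconstruction, apply_cutoffs,
                   regrid_scattering, reconstruct_image, tau_to_t)
from .exceptions import ConfigurationError
from .grids import ImageGrid, PlaneGrid

__all__ = ["PipelineConfig", "make_training_pair", "make_training_set",
           "reconstruct_from_measurements"]

_FAMILY = {
    "ACT4": dict(R=5.0, rn_window=(3.5, 5.0)),
    "KIT4": dict(R=5.5, rn_window=(4.0, 5.5)),
}


@dataclass(frozen=True)
class PipelineConfig:
    """Resolution and solver settings for training-data production."""

    family: str = "KIT4"
    R: float = 5.5                      # scattering radius of the tau sweep
    rn_window: tuple = (4.0, 5.5)       # truncation radius R_n ~ U[window]
    thresh: float = 24.0                # scattering magnitude cutoff
    tau_kgrid_n: int = 16               # nodes per axis of the tau k-grid
    dbar_kgrid_exp: int = 5             # regrid target: 2^exp nodes per axis
    image_grid_n: int = 64              # output image grid on [-1, 1]^2
    dbar_solver_grid_n: int = 24        # m(z,0) solved here, spline-upsampled
    beltrami_grid_n: int = 64           # solver square [-1.05, 1.05)^2
    beltrami_halfwidth: float = 1.05
    beltrami_opts: SolverOptions = field(default_factory=SolverOptions)
    dbar_opts: DbarOptions = field(default_factory=DbarOptions)

    @classmethod
    def desk(cls, family: str = "KIT4") -> "PipelineConfig":
        """Settings sized for minutes-scale runs on one CPU.

        The generic-ellipse family (inclusion axes >= 0.2) is resolved on a
        40-node solver square; the thoracic family keeps 64 nodes for its
        small organs (aorta radius ~ 0.075).
        """
        if family not in _FAMILY:
            raise ConfigurationError("family must be 'ACT4' or 'KIT4'")
        zn = 40 if family == "KIT4" else 64
        return cls(family=family, beltrami_grid_n=zn,
                   beltrami_opts=SolverOptions(tol=1e-5),
                   **_FAMILY[family])

    @classmethod
    def production(cls, family: str = "KIT4") -> "PipelineConfig":
        """Full-scale settings (2^5 tau-grid, 2^6 dbar-grid, direct 2^6
        image solve); roughly two orders of magnitude slower."""
        if family not in _FAMILY:
            raise ConfigurationError("family must be 'ACT4' or 'KIT4'")
        return cls(family=family, tau_kgrid_n=32, dbar_kgrid_exp=6,
                   dbar_solver_grid_n=64, beltrami_grid_n=128,
                   **_FAMILY[family])

    @property
    def beltrami_grid(self) -> PlaneGrid:
        return PlaneGrid(self.beltrami_grid_n, self.beltrami_halfwidth)

    @property
    def tau_kgrid(self) -> PlaneGrid:
        return PlaneGrid(self.tau_kgrid_n, self.R)

    @property
    def image_grid(self) -> ImageGrid:
        return ImageGrid(self.image_grid_n)


def sample_phantom(config: PipelineConfig, rng: np.random.Generator):
    if config.family == "ACT4":
        return ph.sample_act4_phantom(ph.ACT4Rules(), rng)
    return ph.sample_kit4_phantom(ph.KIT4Rules(), rng)


def make_training_pair(phantom: ph.ConductivityPhantom, R_n: float,
                       config: PipelineConfig) -> tuple[np.ndarray, np.ndarray]:
    """One ``(sigma_tilde, sigma_DB)`` pair for a given phantom and cutoff."""
    raw = ph.rasterize(phantom, config.beltrami_grid)
    scaled = ph.scale_to_unit_boundary(raw)
    mu = ph.conductivity_to_mu(scaled, sign=+1)
    coeff = BeltramiCoefficient(mu, config.beltrami_grid)
    tau = scattering_sweep(coeff, config.tau_kgrid, config.beltrami_opts)
    sd = tau_to_t(tau)
    sd = regrid_scattering(sd, R_n, q_new=config.dbar_kgrid_exp)
    sd = apply_cutoffs(sd, R_cut=R_n, thresh=config.thresh)
    rec = reconstruct_image(
        sd, sigma_b=raw.boundary_sigma, grid=config.image_grid,
        solver_grid=ImageGrid(config.dbar_solver_grid_n),
        options=config.dbar_opts)
    truth = ph.rasterize(phantom, config.image_grid).values
    return truth, rec.sigma


def make_training_set(n: int, seed: int,
                      config: PipelineConfig | None = None) -> dict:
    """Generate ``n`` phantom / D-bar reconstruction pairs.

    Returns a dict of arrays: ``sigma`` (truth, S/m), ``sigma_db``
    (reconstruction, S/m), ``R_n`` (cutoff radii), plus the seed and family.
    """
    config = config or PipelineConfig.desk()
    rng = np.random.default_rng(seed)
    N = config.image_grid_n
    sigma = np.empty((n, N, N))
    sigma_db = np.empty((n, N, N))
    rns = np.empty(n)
    for i in range(n):
        phantom = sample_phantom(config, rng)
        rns[i] = rng.uniform(*config.rn_window)
        sigma[i], sigma_db[i] = make_training_pair(phantom, rns[i], config)
    return dict(sigma=sigma, sigma_db=sigma_db, R_n=rns, seed=seed,
                family=config.family)


def reconstruct_from_measurements(
        data: PatternedData, layout: ElectrodeLayout,
        R_meas: float = 4.0, sigma_0: float | None = None,
        kgrid_n: int = 32, thresh: float = 24.0,
        image_grid: ImageGrid | None = None,
        solver_grid: ImageGrid | None = None,
        options: DbarOptions | None = None) -> DbarReconstruction:
    """Measurement-side D-bar image from electrode current/voltage data.

    Assembles the ND matrix, scales it to the unit disc with unit boundary
    conductivity (estimating ``sigma_0`` by the best constant-conductivity
    fit when not given), computes the 'exp' scattering data, applies the
    cutoffs and reconstructs; the image is rescaled by ``sigma_0``.
    """
    nd = build_nd_matrix(data, layout)
    if sigma_0 is None:
        sigma_0 = best_constant_fit(data, layout)
    nd_unit = scale_measurement(nd, layout.r_max, sigma_0)
    dn_unit = nd_unit.invert()
    kgrid = PlaneGrid(kgrid_n, R_meas)
    sd = apply_cutoffs(texp_scattering(dn_unit, kgrid, R_meas=R_meas),
                       R_cut=R_meas, thresh=thresh)
    return reconstruct_image(sd, sigma_b=sigma_0,
                             grid=image_grid or ImageGrid(64),
                             solver_grid=solver_grid, options=options)
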