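"""Random conductivity phantoms and their rasterization.

Two stochastic phantom families are provided, mirroring the two kinds of
training prior used for learned post-processing of D-bar images:

* **Thoracic / high prior** (:func:`sample_act4_phantom`): five reference
  organs (two lungs, spine, heart, aorta) are each included independently
  with a fixed probability, given a conductivity drawn uniformly from a
  per-tissue window, and jittered by additive white Gaussian noise on the
  boundary vertex coordinates.  Each included lung may carry a simulated
  "injury": a horizontal dividing line splits the lung and one side is
  reassigned a conductivity drawn from a wide window.

* **Generic ellipses / low prior** (:func:`sample_kit4_phantom`): one to
  three random non-overlapping ellipses inside the disc of radius 0.95,
  each conductive or resistive versus the background with equal chance, and
  split in two by a random chord with probability 1/3 (no part smaller than
  a quarter of the inclusion).

Conductivities are in S/m.  Phantoms are rasterized onto square grids by
point-in-polygon sampling; scaling to a unit boundary value and the
conversion to the Beltrami coefficient ``mu = (1 - sigma) / (1 + sigma)``
prepare them for the scattering solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import shapely
from shapely.geometry import Point, Polygon

from ._synthetic_organs import ORGAN_LABELS, default_organ_polygons
from .exceptions import (
    ConfigurationError,
    ContractViolation,
    DomainError,
    GenerationError,
)

__all__ = [
    "SplitSpec",
    "Inclusion",
    "ConductivityPhantom",
    "ConductivityImage",
    "ACT4Rules",
    "KIT4Rules",
    "sample_act4_phantom",
    "sample_kit4_phantom",
    "rasterize",
    "scale_to_unit_boundary",
    "conductivity_to_mu",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """Division of an inclusion by the line through ``point`` with unit
    ``normal``; the half-plane ``(p - point) . normal >= 0`` takes
    ``sigma_pos``, the other side ``sigma_neg``."""

    point: tuple[float, float]
    normal: tuple[float, float]
    sigma_pos: float
    sigma_neg: float

    def __post_init__(self):
        if self.sigma_pos <= 0 or self.sigma_neg <= 0:
            raise DomainError("split conductivities must be positive")


@dataclass(frozen=True)
class Inclusion:
    """A closed planar region with constant (or split) conductivity."""

    vertices: np.ndarray  # (n, 2), closed polygon (not repeated endpoint)
    sigma: float
    label: str = "ellipse"
    split: SplitSpec | None = None

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        object.__setattr__(self, "vertices", v)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ConfigurationError("inclusion boundary needs >= 3 planar vertices")
        if self.sigma <= 0:
            raise DomainError("inclusion conductivity must be positive")
        if not self.polygon.is_valid:
            raise ConfigurationError("inclusion boundary must be a simple polygon")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        return self.polygon.area

    def sigma_at_side(self, positive: np.ndarray) -> tuple[float, float]:
        """Conductivities on the (positive, negative) side of the split line."""
        if self.split is None:
            return self.sigma, self.sigma
        return self.split.sigma_pos, self.split.sigma_neg


@dataclass
class ConductivityPhantom:
    inclusions: list[Inclusion]
    background_sigma: float
    family: str  # {"ACT4", "KIT4"}
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.background_sigma <= 0:
            raise DomainError("background conductivity must be positive")


@dataclass
class ConductivityImage:
    """Conductivity sampled on a square grid over ``[-1, 1]^2`` (or the
    solver square).  ``scaled`` marks boundary-normalized images (value 1 in
    the background / outside the domain)."""

    values: np.ndarray
    grid: object  # ImageGrid or PlaneGrid
    boundary_sigma: float
    scaled: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ConfigurationError("conductivity image must be a square array")
        if np.any(self.values <= 0):
            raise DomainError("conductivity image must be positive everywhere")


# ---------------------------------------------------------------------------
# rule sets
# ---------------------------------------------------------------------------

def _check_window(name, window):
    lo, hi = window
    if not (0 < lo <= hi):
        raise ConfigurationError(f"invalid conductivity window for {name}: {window}")


@dataclass(frozen=True)
class ACT4Rules:
    """Stochastic rules for the thoracic (high-prior) family."""

    organ_polygons: Mapping[str, np.ndarray] = field(
        default_factory=default_organ_polygons
    )
    inclusion_probability: Mapping[str, float] = field(
        default_factory=lambda: {
            "left_lung": 0.90,
            "right_lung": 0.90,
            "spine": 1.00,
            "heart": 0.95,
            "aorta": 0.95,
        }
    )
    conductivity_window: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "heart": (0.5, 0.8),
            "aorta": (0.5, 0.8),
            "left_lung": (0.01, 0.2),
            "right_lung": (0.01, 0.2),
            "spine": (0.01, 0.2),
        }
    )
    background_window: tuple[float, float] = (0.29, 0.31)
    injury_probability: float = 0.5
    injury_window: tuple[float, float] = (0.01, 1.5)
    jitter_snr_db: float = 20.0  # awgn-style SNR of vertex coordinates
    containment_radius: float = 0.95
    max_attempts: int = 50

    def validate(self):
        for organ, p in self.inclusion_probability.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"inclusion probability of {organ}: {p}")
        if not 0.0 <= self.injury_probability <= 1.0:
            raise ConfigurationError("injury probability outside [0, 1]")
        for organ, w in self.conductivity_window.items():
            _check_window(organ, w)
        _check_window("background", self.background_window)
        _check_window("injury", self.injury_window)


@dataclass(frozen=True)
class KIT4Rules:
    """Stochastic rules for the generic-ellipse (low-prior) family."""

    n_inclusions: tuple[int, int] = (1, 3)
    axis_window: tuple[float, float] = (0.2, 0.35)
    center_radius_max: float = 0.6
    background_window: tuple[float, float] = (0.13, 0.145)
    conductive_window: tuple[float, float] = (0.29, 0.34)
    resistive_window: tuple[float, float] = (0.05, 0.075)
    split_probability: float = 1.0 / 3.0
    min_region_fraction: float = 0.25
    containment_radius: float = 0.95
    ellipse_vertices: int = 128
    max_attempts: int = 1000

    def validate(self):
        if not 0.0 <= self.split_probability <= 1.0:
            raise ConfigurationError("split probability outside [0, 1]")
        _check_window("background", self.background_window)
        _check_window("conductive", self.conductive_window)
        _check_window("resistive", self.resistive_window)
        lo, hi = self.axis_window
        if not 0 < lo <= hi:
            raise ConfigurationError("invalid axis window")


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------

def _uniform(rng, window):
    lo, hi = window
    return float(rng.uniform(lo, hi))


def _clip_to_disc(poly: Polygon, radius: float) -> Polygon:
    disc = Point(0.0, 0.0).buffer(radius, quad_segs=64)
    clipped = poly.intersection(disc)
    if clipped.is_empty:
        raise GenerationError("inclusion fell entirely outside the domain disc")
    if clipped.geom_type == "MultiPolygon":
        clipped = max(clipped.geoms, key=lambda g: g.area)
    return clipped


def _jitter_polygon(coords: np.ndarray, snr_db: float, radius: float,
                    rng: np.random.Generator, max_attempts: int) -> np.ndarray:
    """Additive white Gaussian noise on the vertex coordinate vector, at the
    given SNR (dB) relative to the mean coordinate power, redrawn until the
    perturbed boundary is a simple polygon."""
    power = float(np.mean(coords**2))
    std = np.sqrt(power * 10.0 ** (-snr_db / 10.0))
    for _ in range(max_attempts):
        pts = coords + rng.normal(0.0, std, size=coords.shape)
        poly = Polygon(pts)
        if poly.is_valid:
            clipped = _clip_to_disc(poly, radius)
            return np.asarray(clipped.exterior.coords)[:-1]
    raise GenerationError("could not draw a simple jittered organ boundary")


def sample_act4_phantom(rules: ACT4Rules, rng: np.random.Generator) -> ConductivityPhantom:
    """Draw one thoracic phantom (conductivities unscaled, S/m)."""
    rules.validate()
    background = _uniform(rng, rules.background_window)
    inclusions: list[Inclusion] = []
    for organ in ORGAN_LABELS:
        if rng.random() >= rules.inclusion_probability[organ]:
            continue
        sigma = _uniform(rng, rules.conductivity_window[organ])
        coords = np.asarray(rules.organ_polygons[organ], dtype=float)
        pts = _jitter_polygon(coords, rules.jitter_snr_db,
                              rules.containment_radius, rng, rules.max_attempts)
        split = None
        if organ.endswith("lung") and rng.random() < rules.injury_probability:
            ymin, ymax = pts[:, 1].min(), pts[:, 1].max()
            ycut = float(rng.uniform(ymin, ymax))
            injured_top = rng.random() < 0.5
            injury_sigma = _uniform(rng, rules.injury_window)
            split = SplitSpec(
                point=(0.0, ycut),
                normal=(0.0, 1.0),
                sigma_pos=injury_sigma if injured_top else sigma,
                sigma_neg=sigma if injured_top else injury_sigma,
            )
        inclusions.append(Inclusion(pts, sigma, label=organ, split=split))
    return ConductivityPhantom(inclusions, background, family="ACT4")


def _ellipse_vertices(center, a, b, angle, n):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x = a * np.cos(t)
    y = b * np.sin(t)
    c, s = np.cos(angle), np.sin(angle)
    return np.column_stack([c * x - s * y + center[0], s * x + c * y + center[1]])


def _split_line(poly: Polygon, rng, min_fraction, max_attempts):
    """A random chord whose two sides both hold at least ``min_fraction`` of
    the inclusion area."""
    total = poly.area
    minx, miny, maxx, maxy = poly.bounds
    big = 10.0
    for _ in range(max_attempts):
        px = rng.uniform(minx, maxx)
        py = rng.uniform(miny, maxy)
        if not poly.contains(Point(px, py)):
            continue
        psi = rng.uniform(0.0, 2.0 * np.pi)
        normal = np.array([np.cos(psi), np.sin(psi)])
        tang = np.array([-normal[1], normal[0]])
        p0 = np.array([px, py])
        halfplane = Polygon(
            [p0 - big * tang, p0 + big * tang,
             p0 + big * tang + big * normal, p0 - big * tang + big * normal]
        )
        pos_area = poly.intersection(halfplane).area
        neg_area = total - pos_area
        if min(pos_area, neg_area) >= min_fraction * total:
            return (float(px), float(py)), (float(normal[0]), float(normal[1]))
    raise GenerationError("could not find an admissible split line")


def sample_kit4_phantom(rules: KIT4Rules, rng: np.random.Generator) -> ConductivityPhantom:
    """Draw one generic-ellipse phantom (conductivities unscaled, S/m)."""
    rules.validate()
    background = _uniform(rng, rules.background_window)
    n_incl = int(rng.integers(rules.n_inclusions[0], rules.n_inclusions[1] + 1))
    accepted: list[Polygon] = []
    inclusions: list[Inclusion] = []
    for _ in range(n_incl):
        for attempt in range(rules.max_attempts):
            a = _uniform(rng, rules.axis_window)
            b = _uniform(rng, rules.axis_window)
            rho = rng.uniform(0.0, rules.center_radius_max)
            theta = rng.uniform(0.0, 2.0 * np.pi)
            phi = rng.uniform(0.0, 2.0 * np.pi)
            center = (rho * np.cos(theta), rho * np.sin(theta))
            verts = _ellipse_vertices(center, a, b, phi, rules.ellipse_vertices)
            if np.max(np.hypot(verts[:, 0], verts[:, 1])) > rules.containment_radius:
                continue
            poly = Polygon(verts)
            if any(poly.intersects(other) for other in accepted):
                continue
            break
        else:
            raise GenerationError(
                f"ellipse rejection sampling exceeded {rules.max_attempts} attempts"
            )
        conductive = rng.random() < 0.5
        sigma = _uniform(
            rng, rules.conductive_window if conductive else rules.resistive_window
        )
        split = None
        if rng.random() < rules.split_probability:
            point, normal = _split_line(poly, rng, rules.min_region_fraction,
                                        rules.max_attempts)
            if rng.random() < 0.5:
                # one part matches the background
                if rng.random() < 0.5:
                    s_pos, s_neg = background, sigma
                else:
                    s_pos, s_neg = sigma, background
            else:
                # one part above, one below the background
                s_cond = _uniform(rng, rules.conductive_window)
                s_res = _uniform(rng, rules.resistive_window)
                if rng.random() < 0.5:
                    s_pos, s_neg = s_cond, s_res
                else:
                    s_pos, s_neg = s_res, s_cond
            split = SplitSpec(point, normal, s_pos, s_neg)
        accepted.append(poly)
        inclusions.append(Inclusion(verts, sigma, label="ellipse", split=split))
    return ConductivityPhantom(inclusions, background, family="KIT4")


# ---------------------------------------------------------------------------
# rasterization and scaling
# ---------------------------------------------------------------------------

def rasterize(phantom: ConductivityPhantom, grid) -> ConductivityImage:
    """Sample the phantom onto a square grid.

    Each node takes the conductivity of the innermost (smallest-area)
    inclusion containing it -- boundary nodes count as inside -- or the
    background value.  Split regions are respected.  Deterministic.
    """
    z = grid.z
    x = np.real(z).ravel()
    y = np.imag(z).ravel()
    values = np.full(z.shape, phantom.background_sigma, dtype=float).ravel()
    # paint larger inclusions first so the smallest containing one wins
    for incl in sorted(phantom.inclusions, key=lambda i: i.area, reverse=True):
        inside = shapely.intersects_xy(incl.polygon, x, y)
        if incl.split is None:
            values[inside] = incl.sigma
        else:
            p0 = np.asarray(incl.split.point)
            nrm = np.asarray(incl.split.normal)
            side = (x - p0[0]) * nrm[0] + (y - p0[1]) * nrm[1] >= 0.0
            values[inside & side] = incl.split.sigma_pos
            values[inside & ~side] = incl.split.sigma_neg
    return ConductivityImage(values.reshape(z.shape), grid,
                             boundary_sigma=phantom.background_sigma, scaled=False)


def scale_to_unit_boundary(image: ConductivityImage) -> ConductivityImage:
    """Divide pointwise by the boundary conductivity so the background is 1.

    The boundary value ``sigma_b`` is retained for rescaling reconstructions
    back to physical units.
    """
    if image.scaled:
        raise ContractViolation("image is already scaled to unit boundary")
    if image.boundary_sigma <= 0:
        raise DomainError("boundary conductivity must be positive")
    return ConductivityImage(image.values / image.boundary_sigma, image.grid,
                             boundary_sigma=image.boundary_sigma, scaled=True)


def conductivity_to_mu(image: ConductivityImage, sign: int = +1) -> np.ndarray:
    """Beltrami coefficient ``+/- mu = sign * (1 - sigma) / (1 + sigma)``.

    Requires a boundary-scaled image (background 1), so that ``mu`` vanishes
    wherever ``sigma = 1``; ``|mu| < 1`` follows from ``sigma > 0``.  The
    minus case equals ``(1 - 1/sigma) / (1 + 1/sigma) = -mu`` exactly.
    """
    if not image.scaled:
        raise DomainError("conductivity must be scaled to unit boundary first")
    if sign not in (+1, -1):
        raise ConfigurationError("sign must be +1 or -1")
    sigma = image.values
    if np.any(sigma <= 0):
        raise DomainError("conductivity must be positive")
    return sign * (1.0 - sigma) / (1.0 + sigma)
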