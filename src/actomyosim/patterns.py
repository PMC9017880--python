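"""Synthetic frames and point patterns with known statistical structure.

These generators provide ground-truth inputs for validating every measure
without running any simulation: complete spatial randomness (CSR) and
Thomas-cluster / jittered-lattice processes for the Ripley statistics,
aligned and isotropic filament fields for the order parameter, asters for
the contractility and radial-distribution measures, and paired motor clouds
for the segregation measures.  Every generator is deterministic given its
seed, and generated frames satisfy the structural invariants of the geometry
types (offspring falling outside the box are clipped to its edges, which
costs a little edge density but keeps production-domain constants usable
everywhere).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import Domain, Filament, Frame, MotorMinifilament

__all__ = [
    "PatternSpec",
    "generate",
    "gen_csr_points",
    "gen_thomas_cluster",
    "gen_regular_grid",
    "gen_aligned_frame",
    "gen_aster_frame",
    "gen_two_population_frame",
]


@dataclass
class PatternSpec:
    """Declarative description of a fixture, for config/CLI use."""

    kind: str                       # csr | thomas_cluster | regular |
    #                                 aligned_bundle | aster | two_population
    n: int = 100
    seed: int = 0
    sigma: float = 50.0             # cluster spread (nm)
    n_parents: int = 10
    mean_children: float = 20.0
    n_side: int = 10
    jitter: float = 0.0
    direction: tuple = (1.0, 0.0, 0.0)
    spread: float = 0.0
    center: Optional[tuple] = None
    separation: float = 0.0
    domain: Domain = field(default_factory=Domain)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sigma < 0 or self.jitter < 0:
            raise ValueError("sigma and jitter must be >= 0")


def generate(spec: PatternSpec):
    """Dispatch a PatternSpec to its generator."""
    d, s = spec.domain, spec.seed
    if spec.kind == "csr":
        return gen_csr_points(spec.n, d, s)
    if spec.kind == "thomas_cluster":
        return gen_thomas_cluster(spec.n_parents, spec.mean_children, spec.sigma, d, s)
    if spec.kind == "regular":
        return gen_regular_grid(spec.n_side, spec.jitter, d, s)
    if spec.kind == "aligned_bundle":
        return gen_aligned_frame(spec.n, np.asarray(spec.direction), spec.spread, d, s)
    if spec.kind == "aster":
        centre = spec.center if spec.center is not None else tuple(d.center)
        return gen_aster_frame(spec.n, np.asarray(centre), d, s)
    if spec.kind == "two_population":
        return gen_two_population_frame(spec.separation, spec.n, d, s)
    raise ValueError(f"unknown pattern kind {spec.kind!r}")


def gen_csr_points(n: int, domain: Optional[Domain] = None, seed: int = 0) -> np.ndarray:
    """Homogeneous Poisson (binomial) pattern: n i.i.d. uniform x-y points."""
    if n < 1:
        raise ValueError("n must be >= 1")
    domain = domain or Domain()
    rng = np.random.default_rng(seed)
    return rng.uniform([0, 0], [domain.lx, domain.ly], size=(n, 2))


def gen_thomas_cluster(
    n_parents: int = 10,
    mean_children: float = 20.0,
    sigma: float = 50.0,
    domain: Optional[Domain] = None,
    seed: int = 0,
) -> np.ndarray:
    """Thomas process: Poisson offspring around uniform parents (clustered)."""
    if n_parents < 1:
        raise ValueError("n_parents must be >= 1")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    domain = domain or Domain()
    rng = np.random.default_rng(seed)
    parents = rng.uniform([0, 0], [domain.lx, domain.ly], size=(n_parents, 2))
    counts = rng.poisson(mean_children, size=n_parents)
    pts = []
    for p, k in zip(parents, counts):
        if k:
            pts.append(p + rng.normal(0.0, sigma, size=(k, 2)))
    if not pts:
        return np.empty((0, 2))
    out = np.concatenate(pts, axis=0)
    return np.clip(out, [0, 0], [domain.lx, domain.ly])


def gen_regular_grid(
    n_side: int = 10,
    jitter: float = 0.0,
    domain: Optional[Domain] = None,
    seed: int = 0,
) -> np.ndarray:
    """n_side^2 lattice points (cell centres) plus uniform jitter (regular)."""
    if n_side < 2:
        raise ValueError("n_side must be >= 2")
    domain = domain or Domain()
    rng = np.random.default_rng(seed)
    hx, hy = domain.lx / n_side, domain.ly / n_side
    xs = (np.arange(n_side) + 0.5) * hx
    ys = (np.arange(n_side) + 0.5) * hy
    grid = np.array([(x, y) for x in xs for y in ys])
    if jitter > 0:
        grid = grid + rng.uniform(-jitter, jitter, size=grid.shape)
    return np.clip(grid, [0, 0], [domain.lx, domain.ly])


def _place_filament(
    centre: np.ndarray, direction: np.ndarray, length: float, n_beads: int
) -> np.ndarray:
    ts = np.linspace(-0.5, 0.5, n_beads)
    return centre[None, :] + np.outer(ts * length, direction)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def gen_aligned_frame(
    n_fil: int,
    direction=(1.0, 0.0, 0.0),
    spread: float = 0.0,
    domain: Optional[Domain] = None,
    seed: int = 0,
    length: float = 500.0,
    n_beads: int = 4,
) -> Frame:
    """Straight filaments along ``direction`` with optional angular noise.

    ``spread = 0`` gives perfect alignment (order parameter exactly 1); large
    spread approaches an isotropic direction field.  Placement is rejection
    sampled so every bead lies in the box.
    """
    domain = domain or Domain()
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm < 1e-12:
        raise ValueError("direction must be a nonzero vector")
    direction = direction / norm
    rng = np.random.default_rng(seed)
    fils = []
    for i in range(n_fil):
        for _ in range(1000):
            if spread > 0:
                d = direction + spread * rng.normal(size=3)
                d = d / np.linalg.norm(d)
            else:
                d = direction
            centre = rng.uniform(np.zeros(3), domain.lengths)
            beads = _place_filament(centre, d, length, n_beads)
            if domain.contains(beads):
                fils.append(Filament(id=f"f{i}", beads=beads))
                break
        else:
            raise RuntimeError("could not place filament inside the domain")
    return Frame(time=0.0, filaments=fils, motors=[], linkers=[], domain=domain)


def gen_aster_frame(
    n_fil: int,
    center=None,
    domain: Optional[Domain] = None,
    seed: int = 0,
    inner_radius: float = 100.0,
    length: float = 400.0,
    n_beads: int = 4,
) -> Frame:
    """Radial aster: filaments point inward, plus ends (last beads) innermost."""
    domain = domain or Domain()
    centre = np.asarray(center if center is not None else domain.center, dtype=float)
    if not domain.contains(centre):
        raise ValueError("aster center must lie inside the domain")
    rng = np.random.default_rng(seed)
    fils = []
    for i in range(n_fil):
        for _ in range(1000):
            phi = rng.uniform(0, 2 * math.pi)
            radial = np.array([math.cos(phi), math.sin(phi), 0.0])
            inner = centre + inner_radius * radial
            outer = centre + (inner_radius + length) * radial
            # beads ordered outer -> inner so the plus end points at the core
            beads = np.linspace(outer, inner, n_beads)
            if domain.contains(beads):
                fils.append(Filament(id=f"f{i}", beads=beads))
                break
        else:
            raise RuntimeError("could not place aster filament inside the domain")
    return Frame(time=0.0, filaments=fils, motors=[], linkers=[], domain=domain)


def gen_two_population_frame(
    separation: float = 0.0,
    n_per_pop: int = 30,
    domain: Optional[Domain] = None,
    seed: int = 0,
    cloud_sigma: float = 150.0,
) -> Frame:
    """Two motor species as Gaussian clouds with centroids ``separation`` apart."""
    if separation < 0:
        raise ValueError("separation must be >= 0")
    domain = domain or Domain()
    rng = np.random.default_rng(seed)
    centre = domain.center
    offsets = np.array([[-separation / 2, 0, 0], [separation / 2, 0, 0]])
    # the two clouds share one noise draw, so separation = 0 means identical
    # point sets and the centroid distance grows cleanly with the separation
    base = np.concatenate(
        [rng.normal(0, cloud_sigma, size=(n_per_pop, 2)), np.zeros((n_per_pop, 1))],
        axis=1,
    )
    motors = []
    for si, sp in enumerate(("A", "B")):
        pts = centre + offsets[si] + base
        pts = np.clip(pts, np.zeros(3), domain.lengths)
        for j, p in enumerate(pts):
            motors.append(
                MotorMinifilament(
                    id=f"m{sp}{j}",
                    species=sp,
                    state="diffusing",
                    endpoints=np.vstack([p, p]),
                    n_heads=20,
                )
            )
    return Frame(time=0.0, filaments=[], motors=motors, linkers=[], domain=domain)
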