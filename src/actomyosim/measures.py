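"""Quantification of actin-myosin organization.

The suite covers the standard descriptors used for cortical actomyosin
networks:

* network **radius of gyration** R_g (contractility proxy; decreasing R_g
  means the network is contracting),
* the nematic **orientational order parameter** S, the largest eigenvalue of
  the ordering tensor Q = (3/2)(<r_hat r_hat^T> - I/3),
* a **radial distribution function** over all pairwise bead distances,
* **motor localization** counts in cylindrical annuli about the domain axis,
* **motor spread** A_mot: area of a concave boundary polygon around motor
  centres, as a fraction of the planar domain area,
* two **segregation** measures for motor pairs: normalized intersection area
  A_int = |P1 n P2| / |P1 u P2| and centroid distance D_cent / L,
* **Ripley's K** with the variance-stabilized H(r) = sqrt(K/pi) - r and its
  signed area under the curve (0 for complete spatial randomness, > 0 for
  clustering, < 0 for regularity).

All distances are in nm.  Polygon measures operate on motor centres
projected to the x-y plane, matching the thin-slab geometry of the cortical
patch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .geometry import Domain, Frame, Trajectory, filament_direction, pairwise_distances
from .hulls import concave_boundary

__all__ = [
    "MeasureSeries",
    "RipleyResult",
    "BoundaryResult",
    "radius_of_gyration",
    "normalize_series",
    "orientational_order",
    "radial_distribution",
    "motor_localization",
    "motor_boundary_area",
    "segregation_intersection",
    "segregation_centroid_distance",
    "sample_actin_points",
    "ripley_K",
    "ripley_H_signed_area",
    "threshold_crossing_time",
    "measure_all",
    "measures_to_table",
    "default_r_grid",
]

DEFAULT_ANNULI = (0.0, 250.0, 500.0, 750.0, 1000.0)


@dataclass
class MeasureSeries:
    """Per-frame values of one measure along a trajectory."""

    name: str
    times: np.ndarray
    values: list                      # scalars or 1-D arrays, one per frame
    component: str = "all"
    seed: int = 0
    valid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.valid is None:
            self.valid = np.ones(len(self.times), dtype=bool)
        if len(self.values) != len(self.times) or len(self.valid) != len(self.times):
            raise ValueError("times, values and valid must have equal length")

    def scalars(self) -> np.ndarray:
        return np.array([np.nan if v is None else float(v) for v in self.values])


@dataclass
class RipleyResult:
    """K and H functions on a radius grid, plus the signed area under H."""

    r: np.ndarray
    K: np.ndarray
    H: np.ndarray
    signed_area: float


@dataclass
class BoundaryResult:
    """Concave-boundary outcome; ``valid`` is False for degenerate inputs."""

    area_fraction: float
    polygon: object = None
    valid: bool = True


def radius_of_gyration(frame: Frame) -> float:
    """RMS distance of all filament beads from their geometric centre (nm)."""
    beads = frame.actin_beads()
    if len(beads) == 0:
        raise ValueError("radius_of_gyration: frame has no filaments")
    centre = beads.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((beads - centre) ** 2, axis=1))))


def normalize_series(series: MeasureSeries) -> MeasureSeries:
    """Divide a scalar series by its first value (so it starts at exactly 1)."""
    vals = series.scalars()
    if vals[0] == 0 or not np.isfinite(vals[0]):
        raise ValueError("cannot normalize: first value is zero or non-finite")
    return MeasureSeries(
        name=series.name + "_norm",
        times=series.times,
        values=list(vals / vals[0]),
        component=series.component,
        seed=series.seed,
        valid=series.valid.copy(),
    )


def orientational_order(frame: Frame) -> float:
    """Largest eigenvalue of the nematic ordering tensor of filament axes."""
    if not frame.filaments:
        raise ValueError("orientational_order: frame has no filaments")
    dirs = np.array([filament_direction(f) for f in frame.filaments])
    outer = np.einsum("ni,nj->ij", dirs, dirs) / len(dirs)
    q = 1.5 * (outer - np.eye(3) / 3.0)
    return float(np.linalg.eigvalsh(q)[-1])


def radial_distribution(frame: Frame, n_bins: int = 50) -> np.ndarray:
    """Normalized histogram of all pairwise bead distances.

    Bins are half-open on [0, d_max] with d_max the 3-D box diagonal, so the
    masses sum to exactly 1: g_j = (#ordered pairs with Z_ij in bin j) /
    (N_s (N_s - 1)).
    """
    beads = frame.actin_beads()
    if len(beads) < 2:
        raise ValueError("radial_distribution needs at least 2 beads")
    d_max = frame.domain.diagonal
    edges = np.linspace(0.0, d_max, n_bins + 1)
    z = pairwise_distances(beads)
    iu = np.triu_indices(len(beads), k=1)
    dists = z[iu]
    idx = np.minimum(np.searchsorted(edges, dists, side="right") - 1, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    n = len(beads)
    return 2.0 * counts / (n * (n - 1))


def motor_localization(
    frame: Frame, radii: Sequence[float] = DEFAULT_ANNULI
) -> np.ndarray:
    """Counts of bound motors per cylindrical annulus about the domain axis.

    Annuli are bounded by ``radii`` (planar distance from (Lx/2, Ly/2)); the
    final annulus extends from the last radius outward, so the counts always
    sum to the number of bound motors.
    """
    radii = np.asarray(radii, dtype=float)
    if radii[0] != 0 or np.any(np.diff(radii) <= 0):
        raise ValueError("radii must increase strictly from 0")
    centre = frame.domain.center[:2]
    counts = np.zeros(len(radii), dtype=int)
    for m in frame.bound_motors():
        d = float(np.linalg.norm(m.center[:2] - centre))
        counts[np.searchsorted(radii, d, side="right") - 1] += 1
    return counts


def motor_boundary_area(
    motor_centers, shrink: float = 0.5, domain: Optional[Domain] = None
) -> BoundaryResult:
    """Concave-boundary area around motor centres / planar domain area."""
    domain = domain or Domain()
    pts = np.asarray(motor_centers, dtype=float).reshape(-1, 2)
    poly = concave_boundary(pts, shrink=shrink) if len(pts) >= 3 else None
    if poly is None:
        return BoundaryResult(area_fraction=0.0, polygon=None, valid=False)
    return BoundaryResult(
        area_fraction=poly.area / domain.planar_area, polygon=poly, valid=True
    )


def segregation_intersection(pop1, pop2, shrink: float = 0.5) -> BoundaryResult:
    """Normalized intersection area of the two population boundary polygons."""
    p1 = concave_boundary(np.asarray(pop1, dtype=float)[:, :2], shrink=shrink)
    p2 = concave_boundary(np.asarray(pop2, dtype=float)[:, :2], shrink=shrink)
    if p1 is None or p2 is None:
        return BoundaryResult(area_fraction=0.0, polygon=None, valid=False)
    union = p1.union(p2).area
    inter = p1.intersection(p2).area
    return BoundaryResult(area_fraction=inter / union, polygon=(p1, p2), valid=True)


def segregation_centroid_distance(
    pop1, pop2, domain: Optional[Domain] = None, shrink: float = 0.5
) -> BoundaryResult:
    """Planar distance between polygon centroids, normalized by the box side."""
    domain = domain or Domain()
    p1 = concave_boundary(np.asarray(pop1, dtype=float)[:, :2], shrink=shrink)
    p2 = concave_boundary(np.asarray(pop2, dtype=float)[:, :2], shrink=shrink)
    if p1 is None or p2 is None:
        return BoundaryResult(area_fraction=0.0, polygon=None, valid=False)
    c1, c2 = p1.centroid, p2.centroid
    d = math.hypot(c1.x - c2.x, c1.y - c2.y)
    return BoundaryResult(area_fraction=d / domain.lx, polygon=(p1, p2), valid=True)


def sample_actin_points(
    frame: Frame, fraction: float = 0.3, rng: Optional[np.random.Generator] = None
) -> np.ndarray:
    """Random per-filament subsample of beads, projected to the x-y plane.

    ``ceil(fraction * n_beads)`` beads (at least one) are drawn without
    replacement from each filament independently.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if not frame.filaments:
        raise ValueError("sample_actin_points: frame has no filaments")
    rng = rng or np.random.default_rng()
    out = []
    for f in frame.filaments:
        k = max(1, math.ceil(fraction * f.n_beads))
        idx = rng.choice(f.n_beads, size=k, replace=False)
        out.append(f.beads[np.sort(idx), :2])
    return np.concatenate(out, axis=0)


def default_r_grid(domain: Optional[Domain] = None, n: int = 100) -> np.ndarray:
    """Radius grid for K/H: ``n`` points from 0 to half the box side."""
    domain = domain or Domain()
    return np.linspace(0.0, domain.lx / 2.0, n)


def ripley_K(
    points,
    r_grid,
    region=None,
    correction: str = "translation",
) -> RipleyResult:
    """Ripley's K on a rectangular region.

    ``region`` is a Domain or an (Lx, Ly) pair.  ``correction`` is
    ``"translation"`` (default; pair (i, j) weighted by
    A / ((Lx - |dx|)(Ly - |dy|)), unbiased on a bounded box) or ``"none"``
    (the bare estimator K(r) = (1/lambda) sum_i sum_{j!=i} 1[d_ij < r] / N).
    The returned H is ``sqrt(K/pi) - r``; ``signed_area`` is its trapezoidal
    integral over the grid.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 2:
        raise ValueError("ripley_K needs at least 2 points")
    r_grid = np.asarray(r_grid, dtype=float)
    if np.any(np.diff(r_grid) <= 0):
        raise ValueError("r_grid must be strictly increasing")
    if region is None:
        region = Domain()
    if isinstance(region, Domain):
        lx, ly = region.lx, region.ly
    else:
        lx, ly = region
    area = lx * ly
    n = len(pts)

    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    iu = np.triu_indices(n, k=1)
    dists = d[iu]
    if correction == "translation":
        # clamp the overlap area away from zero: a pair spanning the full
        # window has an undefined weight but can never fall inside the grid
        overlap = np.maximum(
            (lx - np.abs(diff[..., 0])) * (ly - np.abs(diff[..., 1])), 1e-9
        )
        w = area / overlap
        weights = w[iu]
    elif correction == "none":
        weights = np.ones_like(dists)
    else:
        raise ValueError(f"unknown edge correction {correction!r}")

    order = np.argsort(dists)
    dists_s = dists[order]
    cum_w = np.concatenate([[0.0], np.cumsum(weights[order])])
    # pairs with d < r (half-open, matching the indicator 1_[0, r))
    counts = cum_w[np.searchsorted(dists_s, r_grid, side="left")]
    lam = n / area
    k_vals = 2.0 * counts / (lam * n)  # each unordered pair counted twice
    h_vals = np.sqrt(k_vals / np.pi) - r_grid
    signed_area = float(np.trapezoid(h_vals, r_grid))
    return RipleyResult(r=r_grid, K=k_vals, H=h_vals, signed_area=signed_area)


def ripley_H_signed_area(
    points, r_grid=None, region=None, correction: str = "translation"
) -> float:
    """Signed area under H(r); positive for clustered, negative for regular."""
    if r_grid is None:
        r_grid = default_r_grid(region if isinstance(region, Domain) else None)
    return ripley_K(points, r_grid, region=region, correction=correction).signed_area


def threshold_crossing_time(
    series: MeasureSeries, threshold: float, direction: str = "either"
) -> Optional[float]:
    """Earliest time a normalized series moves past ``1 +- threshold``.

    ``direction`` is "up" (>= 1 + threshold), "down" (<= 1 - threshold) or
    "either".  Returns ``None`` if the series never crosses.  The series must
    be normalized (first value exactly 1).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if direction not in ("up", "down", "either"):
        raise ValueError(f"bad direction {direction!r}")
    vals = series.scalars()
    if abs(vals[0] - 1.0) > 1e-9:
        raise ValueError("series is not normalized (first value != 1)")
    up = vals >= 1.0 + threshold
    down = vals <= 1.0 - threshold
    if direction == "up":
        hit = up
    elif direction == "down":
        hit = down
    else:
        hit = up | down
    idx = np.flatnonzero(hit)
    return float(series.times[idx[0]]) if len(idx) else None


def _ripley_times(times: np.ndarray, cadence: float) -> np.ndarray:
    """Frames at the reporting cadence when the span permits, else all."""
    span = times[-1] - times[0]
    if span < cadence:
        return np.ones(len(times), dtype=bool)
    mask = np.isclose(np.mod(times, cadence), 0.0, atol=1e-6) | np.isclose(
        np.mod(times, cadence), cadence, atol=1e-6
    )
    return mask if mask.sum() >= 2 else np.ones(len(times), dtype=bool)


def measure_all(
    traj: Trajectory,
    shrink: float = 0.5,
    rdf_bins: int = 50,
    actin_sample_fraction: float = 0.3,
    ripley_cadence: float = 250.0,
    annuli: Sequence[float] = DEFAULT_ANNULI,
    correction: str = "translation",
    sample_seed: Optional[int] = None,
) -> list:
    """Apply every measure to every frame of a trajectory.

    Per-measure failures (too few beads or motors in a frame) are flagged as
    invalid values rather than aborting the batch.  Returns a list of
    :class:`MeasureSeries`; Ripley signed areas are evaluated every
    ``ripley_cadence`` seconds when the span permits.
    """
    if len(traj) == 0:
        raise ValueError("measure_all: empty trajectory")
    times = traj.times
    domain = traj.domain
    species = traj.frames[0].motor_species()
    rng = np.random.default_rng(traj.seed if sample_seed is None else sample_seed)
    r_grid = default_r_grid(domain)
    ripley_mask = _ripley_times(times, ripley_cadence)

    def series(name, values, component="all", valid=None):
        return MeasureSeries(
            name=name,
            times=times,
            values=values,
            component=component,
            seed=traj.seed,
            valid=None if valid is None else np.asarray(valid, dtype=bool),
        )

    out = []

    def per_frame(fn):
        vals, ok = [], []
        for f in traj.frames:
            try:
                vals.append(fn(f))
                ok.append(True)
            except ValueError:
                vals.append(None)
                ok.append(False)
        return vals, ok

    rg_vals, rg_ok = per_frame(radius_of_gyration)
    rg = series("rg", rg_vals, valid=rg_ok)
    out.append(rg)
    if rg_ok[0] and rg_vals[0]:
        out.append(normalize_series(rg))

    vals, ok = per_frame(orientational_order)
    out.append(series("order_param", vals, valid=ok))

    vals, ok = per_frame(lambda f: radial_distribution(f, n_bins=rdf_bins))
    out.append(series("rdf", vals, valid=ok))

    vals, ok = per_frame(lambda f: motor_localization(f, radii=annuli))
    out.append(series("motor_localization", vals, valid=ok))

    def amot(frame, sp=None):
        motors = frame.bound_motors(sp)
        res = motor_boundary_area(
            np.array([m.center[:2] for m in motors]).reshape(-1, 2),
            shrink=shrink,
            domain=domain,
        )
        if not res.valid:
            raise ValueError("degenerate motor boundary")
        return res.area_fraction

    vals, ok = per_frame(amot)
    out.append(series("amot", vals, valid=ok))
    if len(species) > 1:
        for sp in species:
            vals, ok = per_frame(lambda f, sp=sp: amot(f, sp))
            out.append(series("amot", vals, component=sp, valid=ok))

        sp1, sp2 = species[0], species[1]

        def pops(frame):
            a = np.array([m.center[:2] for m in frame.bound_motors(sp1)])
            b = np.array([m.center[:2] for m in frame.bound_motors(sp2)])
            return a.reshape(-1, 2), b.reshape(-1, 2)

        def aint(frame):
            a, b = pops(frame)
            res = segregation_intersection(a, b, shrink=shrink)
            if not res.valid:
                raise ValueError("degenerate segregation polygons")
            return res.area_fraction

        def dcent(frame):
            a, b = pops(frame)
            res = segregation_centroid_distance(a, b, domain=domain, shrink=shrink)
            if not res.valid:
                raise ValueError("degenerate segregation polygons")
            return res.area_fraction

        vals, ok = per_frame(aint)
        out.append(series("aint", vals, component=f"{sp1}|{sp2}", valid=ok))
        vals, ok = per_frame(dcent)
        out.append(series("dcent", vals, component=f"{sp1}|{sp2}", valid=ok))

    # Ripley signed areas at the reporting cadence
    def ripley_series(name, point_fn, component="all"):
        vals, ok = [], []
        for f, m in zip(traj.frames, ripley_mask):
            if not m:
                vals.append(None)
                ok.append(False)
                continue
            try:
                pts = point_fn(f)
                vals.append(
                    ripley_K(pts, r_grid, region=domain, correction=correction).signed_area
                )
                ok.append(True)
            except ValueError:
                vals.append(None)
                ok.append(False)
        return series(name, vals, component=component, valid=ok)

    out.append(
        ripley_series(
            "ripley_h_area",
            lambda f: sample_actin_points(f, fraction=actin_sample_fraction, rng=rng),
            component="actin",
        )
    )
    out.append(
        ripley_series(
            "ripley_h_area",
            lambda f: np.array([m.center[:2] for m in f.bound_motors()]),
            component="motors",
        )
    )
    if len(species) > 1:
        for sp in species:
            out.append(
                ripley_series(
                    "ripley_h_area",
                    lambda f, sp=sp: np.array(
                        [m.center[:2] for m in f.bound_motors(sp)]
                    ),
                    component=f"motors:{sp}",
                )
            )
    return out


def measures_to_table(series_list, extra: Optional[dict] = None):
    """Flatten MeasureSeries into a tidy table (one row per scalar value).

    Vector-valued measures are exploded with an indexed ``component`` label
    (e.g. ``bin03`` for RDF bins, ``annulus2`` for localization shells).
    """
    import pandas as pd

    rows = []
    for s in series_list:
        for t, v, ok in zip(s.times, s.values, s.valid):
            base = {
                "seed": s.seed,
                "time_s": float(t),
                "measure": s.name,
                "component": s.component,
            }
            if extra:
                base.update(extra)
            if v is None or np.isscalar(v) or np.ndim(v) == 0:
                rows.append(
                    {**base, "value": np.nan if v is None else float(v), "valid": bool(ok)}
                )
            else:
                arr = np.asarray(v).ravel()
                label = "annulus" if s.name == "motor_localization" else "bin"
                width = 2 if len(arr) > 10 else 1
                for i, vi in enumerate(arr):
                    rows.append(
                        {
                            **base,
                            "component": f"{s.component}:{label}{i:0{width}d}",
                            "value": float(vi),
                            "valid": bool(ok),
                        }
                    )
    cols = ["seed", "time_s", "measure", "component", "value", "valid"]
    if extra:
        cols = list(extra.keys()) + cols
    return pd.DataFrame(rows, columns=cols)
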