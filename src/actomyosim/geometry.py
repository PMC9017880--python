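"""Domain types and geometric primitives shared by the simulator and the measures.

Coordinates are in nanometres, with the origin at a corner of the simulation
box; the domain is ``[0, Lx] x [0, Ly] x [0, Lz]`` with hard-wall confinement
(no periodicity).  The box models a thin patch of the cell cortex, so the
default geometry is 2000 x 2000 x 200 nm.  Each actin filament is a
piecewise-linear chain of bead positions whose **last** bead is the barbed
(plus) end; all polarity-dependent logic (myosin walking direction) reads
this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "Domain",
    "Filament",
    "Attachment",
    "MotorMinifilament",
    "Crosslinker",
    "Frame",
    "Trajectory",
    "pairwise_distances",
    "filament_direction",
]

#: tolerance (nm) for "endpoint lies on its attached filament"; far below all
#: physical length scales of the model
POSITION_TOL = 1.0


@dataclass
class Domain:
    """Rectangular simulation box with cubic reaction-diffusion compartments."""

    lx: float = 2000.0
    ly: float = 2000.0
    lz: float = 200.0
    compartment_size: float = 200.0

    def __post_init__(self) -> None:
        for name in ("lx", "ly", "lz", "compartment_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"Domain.{name} must be positive")
        for name in ("lx", "ly", "lz"):
            ratio = getattr(self, name) / self.compartment_size
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError(
                    f"compartment_size must divide {name} "
                    f"({getattr(self, name)} / {self.compartment_size})"
                )

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.lx, self.ly, self.lz])

    @property
    def planar_area(self) -> float:
        """Area of the x-y footprint (nm^2), the L^2 of the spread measures."""
        return self.lx * self.ly

    @property
    def center(self) -> np.ndarray:
        return self.lengths / 2.0

    @property
    def diagonal(self) -> float:
        """Full 3-D diagonal, the largest possible pair distance."""
        return float(np.sqrt(self.lx**2 + self.ly**2 + self.lz**2))

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> bool:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        lo = pts >= -tol
        hi = pts <= self.lengths[: pts.shape[1]] + tol
        return bool(np.all(lo) and np.all(hi))


@dataclass
class Filament:
    """Ordered bead chain; the plus (barbed) end is the last bead."""

    id: str
    beads: np.ndarray  # (n, 3) float, nm

    def __post_init__(self) -> None:
        self.beads = np.asarray(self.beads, dtype=float)
        if self.beads.ndim != 2 or self.beads.shape[1] != 3:
            raise ValueError("beads must be an (n, 3) array")
        if len(self.beads) < 2:
            raise ValueError("a filament needs at least 2 beads")

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def plus_end(self) -> np.ndarray:
        return self.beads[-1]

    @property
    def minus_end(self) -> np.ndarray:
        return self.beads[0]

    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.beads, axis=0), axis=1)

    def total_length(self) -> float:
        return float(self.segment_lengths().sum())

    def point_at_arc(self, arc: float) -> np.ndarray:
        """Position at arc length ``arc`` measured from the minus end."""
        seg = self.segment_lengths()
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        arc = float(np.clip(arc, 0.0, cum[-1]))
        i = int(np.searchsorted(cum[1:], arc, side="left"))
        i = min(i, len(seg) - 1)
        s = (arc - cum[i]) / seg[i]
        return (1 - s) * self.beads[i] + s * self.beads[i + 1]


@dataclass
class Attachment:
    """Where a motor/linker endpoint sits on a filament: segment + arc offset."""

    filament_id: str
    segment: int          # bead interval [segment, segment+1]
    offset: float         # nm along that segment from bead `segment`


@dataclass
class MotorMinifilament:
    """Bipolar myosin aggregate: two head ensembles that bind two filaments."""

    id: str
    species: str
    state: str                         # "bound" | "diffusing"
    endpoints: np.ndarray              # (2, 3) nm; for a diffusing motor both
    #                                    rows hold the diffusing centre
    n_heads: int                       # sampled N_t
    params: "object" = None            # MotorParams; kept loose to avoid cycles
    attachments: Sequence[Optional[Attachment]] = (None, None)
    rest_length: float = 0.0           # spring rest length set at binding (nm)

    def __post_init__(self) -> None:
        self.endpoints = np.asarray(self.endpoints, dtype=float).reshape(2, 3)
        if self.state not in ("bound", "diffusing"):
            raise ValueError(f"bad motor state {self.state!r}")

    @property
    def center(self) -> np.ndarray:
        return self.endpoints.mean(axis=0)

    @property
    def is_bound(self) -> bool:
        return self.state == "bound"

    @property
    def separation(self) -> float:
        return float(np.linalg.norm(self.endpoints[1] - self.endpoints[0]))


@dataclass
class Crosslinker:
    """Passive two-headed linker (alpha-actinin-like): binds, never walks."""

    id: str
    state: str
    endpoints: np.ndarray
    attachments: Sequence[Optional[Attachment]] = (None, None)
    rest_length: float = 0.0

    def __post_init__(self) -> None:
        self.endpoints = np.asarray(self.endpoints, dtype=float).reshape(2, 3)
        if self.state not in ("bound", "diffusing"):
            raise ValueError(f"bad linker state {self.state!r}")

    @property
    def center(self) -> np.ndarray:
        return self.endpoints.mean(axis=0)

    @property
    def is_bound(self) -> bool:
        return self.state == "bound"


@dataclass
class Frame:
    """One timestamped snapshot: filaments, motors, linkers, and the box."""

    time: float
    filaments: list
    motors: list
    linkers: list
    domain: Domain = field(default_factory=Domain)

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("Frame.time must be >= 0")
        ids = [f.id for f in self.filaments] + [m.id for m in self.motors] + [
            l.id for l in self.linkers
        ]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate ids in frame")

    def actin_beads(self) -> np.ndarray:
        """All filament bead positions stacked into an (n, 3) array."""
        if not self.filaments:
            return np.empty((0, 3))
        return np.concatenate([f.beads for f in self.filaments], axis=0)

    def bound_motors(self, species: Optional[str] = None) -> list:
        out = [m for m in self.motors if m.is_bound]
        if species is not None:
            out = [m for m in out if m.species == species]
        return out

    def motor_species(self) -> list:
        seen: list = []
        for m in self.motors:
            if m.species not in seen:
                seen.append(m.species)
        return seen

    def validate(self) -> None:
        """Check the structural invariants; raises ValueError on violation."""
        for f in self.filaments:
            if not self.domain.contains(f.beads):
                raise ValueError(f"filament {f.id} has beads outside the domain")
        for m in self.motors:
            if m.is_bound:
                for ep, att in zip(m.endpoints, m.attachments):
                    if att is None:
                        raise ValueError(f"bound motor {m.id} lacks an attachment")
                    fil = next(f for f in self.filaments if f.id == att.filament_id)
                    seg_start = fil.beads[att.segment]
                    seg_vec = fil.beads[att.segment + 1] - seg_start
                    seg_len = np.linalg.norm(seg_vec)
                    pos = seg_start + seg_vec * (att.offset / seg_len)
                    if np.linalg.norm(pos - ep) > POSITION_TOL:
                        raise ValueError(
                            f"motor {m.id} endpoint off its filament by "
                            f"{np.linalg.norm(pos - ep):.3f} nm"
                        )


@dataclass
class Trajectory:
    """Ordered frames with strictly increasing time plus run metadata."""

    frames: list
    seed: int = 0
    config_hash: str = ""

    def __post_init__(self) -> None:
        times = [f.time for f in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def domain(self) -> Domain:
        return self.frames[0].domain


def pairwise_distances(points) -> np.ndarray:
    """Symmetric matrix of Euclidean distances Z with Z[i, j] = |r_i - r_j|.

    Raises ``ValueError`` on empty input.  Works for 2-D or 3-D points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("pairwise_distances needs at least one point")
    pts = np.atleast_2d(pts)
    if len(pts) == 1:
        return np.zeros((1, 1))
    return squareform(pdist(pts))


def filament_direction(f: Filament) -> np.ndarray:
    """Unit vector from the first bead to the plus-end bead.

    Only the two end beads enter, so the value reflects the overall
    orientation even when the filament bends.  Raises on coincident ends.
    """
    vec = f.beads[-1] - f.beads[0]
    norm = np.linalg.norm(vec)
    if norm < 1e-12:
        raise ValueError(f"filament {f.id} has coincident end beads")
    return vec / norm
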