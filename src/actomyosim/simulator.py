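"""Simplified stochastic mechanochemical simulator of a cortical actomyosin patch.

Actin filaments (bead chains with 108 nm segments), bipolar myosin
minifilaments and passive crosslinkers evolve in a thin box by alternating

* **chemistry**: exact stochastic sampling (Gillespie) of discrete events —
  filament tip (de)polymerization, motor binding within the reaction range,
  catch-bond unbinding, load-dependent plus-end-directed stepping, linker
  binding/unbinding — over a fixed interval ``dt_chem`` with the mechanical
  forces frozen at their last relaxed values, and
* **mechanics**: overdamped relaxation of the total elastic energy
  (filament stretching and bending, motor/linker Hookean springs, soft
  excluded volume, hard-wall confinement) to a force tolerance.

Diffusing motors and linkers are advanced by one Brownian displacement per
chemistry window (reflecting walls); with the default diffusivity a motor
mixes over a compartment much faster than it binds, which is the well-mixed
limit the compartment picture targets.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from ._mech_kernels import energy_grad_kernel, relax_kernel
from .geometry import (
    Attachment,
    Crosslinker,
    Domain,
    Filament,
    Frame,
    MotorMinifilament,
    Trajectory,
)
from .kinetics import (
    MotorParams,
    base_walking_rate,
    unbinding_rate,
    walking_rate,
)

__all__ = [
    "LinkerParams",
    "MechParams",
    "RateSwitch",
    "SimConfig",
    "EventLog",
    "init_state",
    "step_chemistry",
    "relax_mechanics",
    "run_simulation",
]


@dataclass(frozen=True)
class LinkerParams:
    """Passive crosslinker (alpha-actinin-like) kinetics and mechanics."""

    k_on: float = 0.3         # 1/s when a site pair is in reach
    k_off: float = 0.3        # 1/s
    stiffness: float = 8.0    # pN/nm
    rxn_min: float = 30.0     # nm
    rxn_max: float = 40.0     # nm


@dataclass(frozen=True)
class MechParams:
    """Mechanical constants and relaxation controls."""

    k_stretch: float = 10.0       # pN/nm per filament segment
    k_bend: float = 400.0         # pN nm (persistence-length-scale bending)
    k_excluded: float = 20.0      # pN/nm soft segment repulsion
    ev_clearance: float = 10.0    # nm
    ev_cutoff: float = 40.0       # nm pair-list build radius
    k_wall: float = 2.0           # pN/nm one-sided confinement
    force_tol: float = 0.1        # pN max residual force
    max_iter: int = 5000
    #: per-window iteration budget while alternating with chemistry; the
    #: quasi-static limit is approached over successive windows (finite-drag
    #: overdamped dynamics), full convergence being enforced only by the
    #: standalone relaxation entry point
    window_max_iter: int = 60
    excluded_volume: bool = True


@dataclass(frozen=True)
class RateSwitch:
    """Scheduled mid-run change of one motor-species parameter."""

    time: float
    species: str
    parameter: str
    value: float


@dataclass
class SimConfig:
    """Full simulation configuration (defaults = Table-baseline desk run)."""

    domain: Domain = field(default_factory=Domain)
    n_filaments: int = 20
    filament_length: float = 540.0     # nm initial
    segment_length: float = 108.0      # nm equilibrium
    species: Sequence[MotorParams] = field(default_factory=lambda: (MotorParams(),))
    n_motors: int = 32                 # total, split equally across species
    n_linkers: int = 30
    linker: LinkerParams = field(default_factory=LinkerParams)
    # symmetric tip exchange: segment-scale turnover with no net treadmill
    # translation (a strong treadmill bias walks filaments into the walls)
    k_poly_plus: float = 0.04          # 1/s per filament tip
    k_depoly_plus: float = 0.04
    k_poly_minus: float = 0.04
    k_depoly_minus: float = 0.04
    dt_chem: float = 1.0               # s chemistry/mechanics alternation
    total_time: float = 400.0          # s
    snapshot_every: float = 25.0       # s
    seed: int = 0
    switches: Sequence[RateSwitch] = ()
    motor_diffusion: float = 1.0e5     # nm^2/s
    binding_search_radius: float = 400.0  # nm around a diffusing motor
    stretch_cap_factor: float = 2.0    # force-unbind beyond cap * rxn_max
    mech: MechParams = field(default_factory=MechParams)

    def __post_init__(self) -> None:
        self.species = tuple(self.species)
        self.switches = tuple(self.switches)
        if self.total_time < 0:
            raise ValueError("total_time must be >= 0")
        if self.snapshot_every < self.dt_chem:
            raise ValueError("snapshot cadence must be >= dt_chem")
        if self.n_motors % max(1, len(self.species)) != 0:
            raise ValueError("n_motors must split equally across species")
        names = [p.name for p in self.species]
        if len(names) != len(set(names)):
            raise ValueError("species names must be unique")
        for sw in self.switches:
            if not 0 <= sw.time <= self.total_time:
                raise ValueError("switch times must lie within [0, total_time]")
            if sw.species not in names:
                raise ValueError(f"switch references unknown species {sw.species!r}")

    def config_hash(self) -> str:
        return hashlib.sha1(repr(self).encode()).hexdigest()[:12]


@dataclass
class EventLog:
    """Chronological record of executed stochastic events."""

    records: list = field(default_factory=list)

    def append(self, time: float, kind: str, actor: str, detail: str = "") -> None:
        self.records.append((time, kind, actor, detail))

    def count(self, kind: str) -> int:
        return sum(1 for r in self.records if r[1] == kind)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.records, columns=["time", "kind", "actor", "detail"])


# ---------------------------------------------------------------------------
# internal mutable state


class _Fil:
    """Mutable filament with cached arc-length tables (mutate via set_beads)."""

    __slots__ = ("id", "_beads", "_seg", "_cum")

    def __init__(self, fid: str, beads: np.ndarray):
        self.id = fid
        self.set_beads(np.asarray(beads, dtype=float))

    @property
    def beads(self) -> np.ndarray:
        return self._beads

    def set_beads(self, beads: np.ndarray) -> None:
        self._beads = beads
        self._seg = np.linalg.norm(beads[1:] - beads[:-1], axis=1)
        self._cum = np.concatenate([[0.0], np.cumsum(self._seg)])

    def seg_lengths(self) -> np.ndarray:
        return self._seg

    def total_length(self) -> float:
        return float(self._cum[-1])

    def _locate(self, arc: float) -> Tuple[int, float]:
        arc = min(max(arc, 0.0), self._cum[-1])
        i = min(int(np.searchsorted(self._cum[1:], arc, side="left")),
                len(self._seg) - 1)
        return i, arc - self._cum[i]

    def point_at(self, arc: float) -> np.ndarray:
        i, off = self._locate(arc)
        s = off / self._seg[i]
        return (1 - s) * self._beads[i] + s * self._beads[i + 1]

    def points_at(self, arcs: np.ndarray) -> np.ndarray:
        arcs = np.clip(arcs, 0.0, self._cum[-1])
        idx = np.minimum(np.searchsorted(self._cum[1:], arcs, side="left"),
                         len(self._seg) - 1)
        s = ((arcs - self._cum[idx]) / self._seg[idx])[:, None]
        return (1 - s) * self._beads[idx] + s * self._beads[idx + 1]

    def arc_to_segment(self, arc: float) -> Tuple[int, float]:
        return self._locate(arc)


class _Bond:
    """A bound or diffusing two-headed agent (motor or linker)."""

    __slots__ = ("id", "species_idx", "state", "nt", "fil", "arc", "rest",
                 "pos", "tension")

    def __init__(self, bid, species_idx, pos, nt=0):
        self.id = bid
        self.species_idx = species_idx
        self.state = "diffusing"
        self.nt = nt
        self.fil: list = [None, None]     # filament ids
        self.arc = [0.0, 0.0]             # nm from the minus end
        self.rest = 0.0
        self.pos = np.asarray(pos, dtype=float)
        self.tension = 0.0

    @property
    def bound(self) -> bool:
        return self.state == "bound"


class _State:
    def __init__(self, config: SimConfig, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.species = list(config.species)
        self.fils: dict = {}
        self.motors: List[_Bond] = []
        self.linkers: List[_Bond] = []
        self.time = 0.0

    def fil_list(self) -> list:
        return list(self.fils.values())


# ---------------------------------------------------------------------------
# initialization


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
        if n > 1e-9:
            return v / n


def _init_state(config: SimConfig, rng: np.random.Generator) -> _State:
    st = _State(config, rng)
    d = config.domain
    n_seg = max(1, round(config.filament_length / config.segment_length))
    n_beads = n_seg + 1
    for i in range(config.n_filaments):
        for attempt in range(5000):
            centre = rng.uniform(np.zeros(3), d.lengths)
            u = _random_unit(rng)
            ts = (np.arange(n_beads) - (n_beads - 1) / 2.0) * config.segment_length
            beads = centre[None, :] + np.outer(ts, u)
            if d.contains(beads):
                st.fils[f"f{i}"] = _Fil(f"f{i}", beads)
                break
        else:
            raise RuntimeError("could not place filaments inside the domain")
    per_species = config.n_motors // max(1, len(config.species))
    for i in range(config.n_motors):
        sp = min(i // per_species, len(config.species) - 1)
        p = config.species[sp]
        nt = int(rng.integers(p.heads_min, p.heads_max + 1))
        st.motors.append(_Bond(f"m{i}", sp, rng.uniform(np.zeros(3), d.lengths), nt))
    for i in range(config.n_linkers):
        st.linkers.append(_Bond(f"l{i}", -1, rng.uniform(np.zeros(3), d.lengths)))
    return st


def _snapshot(st: _State) -> Frame:
    fils = [Filament(id=f.id, beads=f.beads.copy()) for f in st.fil_list()]
    motors = []
    for m in st.motors:
        p = st.species[m.species_idx]
        if m.bound:
            eps, atts = [], []
            for e in range(2):
                fil = st.fils[m.fil[e]]
                eps.append(fil.point_at(m.arc[e]))
                seg, off = fil.arc_to_segment(m.arc[e])
                atts.append(Attachment(fil.id, seg, off))
            motors.append(
                MotorMinifilament(
                    id=m.id, species=p.name, state="bound",
                    endpoints=np.array(eps), n_heads=m.nt, params=p,
                    attachments=tuple(atts), rest_length=m.rest,
                )
            )
        else:
            motors.append(
                MotorMinifilament(
                    id=m.id, species=p.name, state="diffusing",
                    endpoints=np.vstack([m.pos, m.pos]), n_heads=m.nt, params=p,
                )
            )
    linkers = []
    for l in st.linkers:
        if l.bound:
            eps, atts = [], []
            for e in range(2):
                fil = st.fils[l.fil[e]]
                eps.append(fil.point_at(l.arc[e]))
                seg, off = fil.arc_to_segment(l.arc[e])
                atts.append(Attachment(fil.id, seg, off))
            linkers.append(
                Crosslinker(id=l.id, state="bound", endpoints=np.array(eps),
                            attachments=tuple(atts), rest_length=l.rest)
            )
        else:
            linkers.append(
                Crosslinker(id=l.id, state="diffusing",
                            endpoints=np.vstack([l.pos, l.pos]))
            )
    return Frame(time=st.time, filaments=fils, motors=motors, linkers=linkers,
                 domain=st.config.domain)


def _state_from_frame(frame: Frame, config: SimConfig,
                      rng: np.random.Generator) -> _State:
    st = _State(config, rng)
    st.time = frame.time
    names = [p.name for p in config.species]
    for f in frame.filaments:
        st.fils[f.id] = _Fil(f.id, f.beads.copy())
    for m in frame.motors:
        sp = names.index(m.species) if m.species in names else 0
        b = _Bond(m.id, sp, m.center.copy(), m.n_heads)
        if m.is_bound:
            b.state = "bound"
            b.rest = m.rest_length if m.rest_length > 0 else m.separation
            for e, att in enumerate(m.attachments):
                fil = st.fils[att.filament_id]
                seg = fil.seg_lengths()
                b.fil[e] = att.filament_id
                b.arc[e] = float(np.sum(seg[: att.segment]) + att.offset)
            p = config.species[sp]
            b.tension = max(0.0, p.k_motor * (m.separation - b.rest))
        st.motors.append(b)
    for l in frame.linkers:
        b = _Bond(l.id, -1, l.center.copy())
        if l.is_bound:
            b.state = "bound"
            sep = float(np.linalg.norm(l.endpoints[1] - l.endpoints[0]))
            b.rest = l.rest_length if l.rest_length > 0 else sep
            for e, att in enumerate(l.attachments):
                fil = st.fils[att.filament_id]
                seg = fil.seg_lengths()
                b.fil[e] = att.filament_id
                b.arc[e] = float(np.sum(seg[: att.segment]) + att.offset)
        st.linkers.append(b)
    return st


def init_state(config: SimConfig, rng: Optional[np.random.Generator] = None) -> Frame:
    """Initial frame: short straight filaments at random positions and
    orientations inside the box; every motor and linker diffusing."""
    rng = rng or np.random.default_rng(config.seed)
    return _snapshot(_init_state(config, rng))


# ---------------------------------------------------------------------------
# mechanics


class _MechSystem:
    """Flat-array view of the elastic network for vectorized energy/grad."""

    def __init__(self, st: _State):
        cfg = st.config
        self.mech = cfg.mech
        self.domain = cfg.domain
        fils = st.fil_list()
        self.fil_ids = [f.id for f in fils]
        self.offsets = {}
        off = 0
        coords = []
        seg_i, seg_j = [], []
        bend = []
        for f in fils:
            n = len(f.beads)
            self.offsets[f.id] = off
            coords.append(f.beads)
            seg_i.extend(range(off, off + n - 1))
            seg_j.extend(range(off + 1, off + n))
            bend.extend((k - 1, k, k + 1) for k in range(off + 1, off + n - 1))
            off += n
        self.x0 = np.concatenate(coords, axis=0)
        self.n_beads = off
        self.seg_i = np.array(seg_i, dtype=np.int64)
        self.seg_j = np.array(seg_j, dtype=np.int64)
        self.l0 = cfg.segment_length
        self.bend = np.array(bend, dtype=np.int64).reshape(-1, 3)

        # springs from bound motors and linkers
        sp_idx = np.zeros((0, 4), dtype=np.int64)
        sp_s = np.zeros((0, 2))
        sp_k: list = []
        sp_rest: list = []
        rows_idx, rows_s = [], []
        self.spring_owner: list = []
        for agent, stiffness in (
            [(m, st.species[m.species_idx].k_motor) for m in st.motors if m.bound]
            + [(l, cfg.linker.stiffness) for l in st.linkers if l.bound]
        ):
            idx4, s2 = [], []
            for e in range(2):
                fil = st.fils[agent.fil[e]]
                seg, offn = fil.arc_to_segment(agent.arc[e])
                base = self.offsets[fil.id]
                seglen = float(np.linalg.norm(fil.beads[seg + 1] - fil.beads[seg]))
                idx4.extend([base + seg, base + seg + 1])
                s2.append(offn / seglen)
            rows_idx.append(idx4)
            rows_s.append(s2)
            sp_k.append(stiffness)
            sp_rest.append(agent.rest)
            self.spring_owner.append(agent)
        if rows_idx:
            sp_idx = np.array(rows_idx, dtype=np.int64)
            sp_s = np.array(rows_s)
        self.sp_idx = sp_idx
        self.sp_s = sp_s
        self.sp_k = np.array(sp_k, dtype=float)
        self.sp_rest = np.array(sp_rest, dtype=float)

        # excluded-volume bead pairs (cross-filament), built once per relax
        self.ev_pairs = np.zeros((0, 2), dtype=np.int64)
        if self.mech.excluded_volume and self.n_beads > 1:
            fil_of = np.concatenate(
                [np.full(len(f.beads), k) for k, f in enumerate(fils)]
            )
            tree = cKDTree(self.x0)
            pairs = tree.query_pairs(self.mech.ev_cutoff, output_type="ndarray")
            if len(pairs):
                mask = fil_of[pairs[:, 0]] != fil_of[pairs[:, 1]]
                self.ev_pairs = pairs[mask].astype(np.int64)

    def _kernel_args(self):
        m = self.mech
        d = self.domain
        return (
            self.seg_i, self.seg_j, self.l0, m.k_stretch,
            self.bend[:, 0].copy(), self.bend[:, 1].copy(),
            self.bend[:, 2].copy(), m.k_bend,
            self.sp_idx[:, 0].copy(), self.sp_idx[:, 1].copy(),
            self.sp_idx[:, 2].copy(), self.sp_idx[:, 3].copy(),
            self.sp_s[:, 0].copy(), self.sp_s[:, 1].copy(),
            self.sp_k, self.sp_rest,
            self.ev_pairs[:, 0].copy(), self.ev_pairs[:, 1].copy(),
            m.ev_clearance, m.k_excluded,
            d.lx, d.ly, d.lz, m.k_wall,
        )

    def energy_grad(self, x: np.ndarray) -> Tuple[float, np.ndarray]:
        X = np.ascontiguousarray(x, dtype=float).reshape(-1, 3)
        G = np.zeros_like(X)
        e = energy_grad_kernel(X, G, *self._kernel_args())
        return float(e), G.ravel()

    def relax(self, force_tol: float, max_iter: int, max_disp: float = 20.0):
        X, e, iters = relax_kernel(
            np.ascontiguousarray(self.x0, dtype=float), *self._kernel_args(),
            force_tol, max_iter, max_disp,
        )
        return X, float(e), int(iters)


def _relax(st: _State, max_iter: Optional[int] = None) -> None:
    """Relax the elastic network in place and refresh cached spring tensions."""
    sysm = _MechSystem(st)
    if sysm.n_beads == 0:
        return
    e0, _ = sysm.energy_grad(sysm.x0.ravel())
    cap = st.config.mech.max_iter if max_iter is None else max_iter
    X, e1, _iters = sysm.relax(st.config.mech.force_tol, cap)
    if e1 > e0 + 1e-9:  # descent contract: never accept an energy increase
        X = sysm.x0
    if not np.all(np.isfinite(X)):
        raise FloatingPointError("non-finite coordinates after relaxation")
    for fid in sysm.fil_ids:
        f = st.fils[fid]
        off = sysm.offsets[fid]
        f.set_beads(X[off : off + len(f.beads)].copy())
    # refresh tensions (positive part of Hookean stretch)
    for agent in st.motors + st.linkers:
        if not agent.bound:
            agent.tension = 0.0
            continue
        p1 = st.fils[agent.fil[0]].point_at(agent.arc[0])
        p2 = st.fils[agent.fil[1]].point_at(agent.arc[1])
        d = float(np.linalg.norm(p2 - p1))
        k = (
            st.species[agent.species_idx].k_motor
            if agent.species_idx >= 0
            else st.config.linker.stiffness
        )
        agent.tension = max(0.0, k * (d - agent.rest))


def relax_mechanics(frame: Frame, config: Optional[SimConfig] = None) -> Frame:
    """Overdamped relaxation of a frame's elastic energy (descent contract:
    the energy never increases)."""
    config = config or SimConfig()
    st = _state_from_frame(frame, config, np.random.default_rng(0))
    _relax(st)
    return _snapshot(st)


# ---------------------------------------------------------------------------
# chemistry


def _binding_candidates(st: _State):
    """Site list and per-agent candidate site pairs for this window."""
    cfg = st.config
    site_pos, site_fil, site_arc = [], [], []
    for f in st.fil_list():
        arcs = np.arange(0.0, f.total_length() + 1e-9, cfg.species[0].d_total)
        site_pos.append(f.points_at(arcs))
        site_fil.extend([f.id] * len(arcs))
        site_arc.append(arcs)
    site_pos = np.concatenate(site_pos, axis=0)
    site_fil = np.array(site_fil)
    site_arc = np.concatenate(site_arc)

    def pairs_in(lo, hi):
        tree = cKDTree(site_pos)
        pr = tree.query_pairs(hi, output_type="ndarray")
        if len(pr) == 0:
            return pr
        d = np.linalg.norm(site_pos[pr[:, 0]] - site_pos[pr[:, 1]], axis=1)
        mask = (d >= lo) & (site_fil[pr[:, 0]] != site_fil[pr[:, 1]])
        return pr[mask]

    out = {}
    rmin = min(p.rxn_min for p in cfg.species)
    rmax = max(p.rxn_max for p in cfg.species)
    motor_pairs = pairs_in(rmin, rmax)
    linker_pairs = pairs_in(cfg.linker.rxn_min, cfg.linker.rxn_max)
    for name, pr, agents in (
        ("motor", motor_pairs, st.motors),
        ("linker", linker_pairs, st.linkers),
    ):
        per_agent = [[] for _ in agents]
        if len(pr):
            mid = 0.5 * (site_pos[pr[:, 0]] + site_pos[pr[:, 1]])
            tree = cKDTree(mid)
            for k, a in enumerate(agents):
                if not a.bound:
                    per_agent[k] = tree.query_ball_point(
                        a.pos, cfg.binding_search_radius
                    )
        out[name] = (pr, per_agent)
    return site_pos, site_fil, site_arc, out


def _unbind(agent: _Bond, st: _State) -> None:
    p1 = st.fils[agent.fil[0]].point_at(agent.arc[0])
    p2 = st.fils[agent.fil[1]].point_at(agent.arc[1])
    agent.pos = 0.5 * (p1 + p2)
    agent.state = "diffusing"
    agent.fil = [None, None]
    agent.arc = [0.0, 0.0]
    agent.rest = 0.0
    agent.tension = 0.0


def _detach_from_segment(st: _State, log: EventLog, fid: str, lo: float,
                         hi: float, table: Optional["_RateTable"] = None) -> None:
    """Force-unbind agents whose attachment arc on ``fid`` lies in [lo, hi]."""
    for mi, m in enumerate(st.motors):
        if m.bound and any(
            m.fil[e] == fid and lo <= m.arc[e] <= hi for e in range(2)
        ):
            _unbind(m, st)
            log.append(st.time, "unbind", m.id, "turnover")
            if table is not None:
                _refresh_motor(st, table, mi)
    for li, l in enumerate(st.linkers):
        if l.bound and any(
            l.fil[e] == fid and lo <= l.arc[e] <= hi for e in range(2)
        ):
            _unbind(l, st)
            log.append(st.time, "linker-unbind", l.id, "turnover")
            if table is not None:
                table.set(("lu", li), 0.0)


class _RateTable:
    """Indexed event/rate list; rates are frozen within a chemistry window
    except for targeted updates after state-changing events."""

    __slots__ = ("rates", "events", "index")

    def __init__(self):
        self.rates: list = []
        self.events: list = []
        self.index: dict = {}

    def add(self, key, rate: float, event) -> None:
        self.index[key] = len(self.rates)
        self.rates.append(rate)
        self.events.append(event)

    def set(self, key, rate: float) -> None:
        self.rates[self.index[key]] = rate

    def total(self) -> float:
        return sum(self.rates)

    def pick(self, x: float) -> int:
        acc = 0.0
        for k, r in enumerate(self.rates):
            acc += r
            if x < acc:
                return k
        return len(self.rates) - 1


def _motor_entry_rates(st: _State, mi: int):
    """(unbind, walk0, walk1) rates for motor mi at its frozen tension."""
    m = st.motors[mi]
    if not m.bound:
        return 0.0, 0.0, 0.0
    p = st.species[m.species_idx]
    ku = unbinding_rate(m.tension, m.nt, p)
    kw = walking_rate(base_walking_rate(p), m.tension, p)
    out = [ku]
    for e in range(2):
        total = st.fils[m.fil[e]].total_length()
        out.append(kw if (kw > 0 and m.arc[e] < total - 1e-6) else 0.0)
    return tuple(out)


def _refresh_motor(st: _State, table: _RateTable, mi: int) -> None:
    ku, w0, w1 = _motor_entry_rates(st, mi)
    table.set(("mu", mi), ku)
    table.set(("mw", mi, 0), w0)
    table.set(("mw", mi, 1), w1)


def _refresh_fil_tips(st: _State, table: _RateTable, fid: str) -> None:
    cfg = st.config
    eligible = len(st.fils[fid].beads) > 2
    table.set(("tdp", fid), cfg.k_depoly_plus if eligible else 0.0)
    table.set(("tdm", fid), cfg.k_depoly_minus if eligible else 0.0)


def _build_table(st: _State, cand) -> _RateTable:
    cfg = st.config
    table = _RateTable()
    for f in st.fil_list():
        eligible = len(f.beads) > 2
        table.add(("tp", f.id), cfg.k_poly_plus, ("poly", f.id, "plus"))
        table.add(("tm", f.id), cfg.k_poly_minus, ("poly", f.id, "minus"))
        table.add(("tdp", f.id), cfg.k_depoly_plus if eligible else 0.0,
                  ("depoly", f.id, "plus"))
        table.add(("tdm", f.id), cfg.k_depoly_minus if eligible else 0.0,
                  ("depoly", f.id, "minus"))
    _, motor_cand = cand["motor"]
    for mi, m in enumerate(st.motors):
        p = st.species[m.species_idx]
        ku, w0, w1 = _motor_entry_rates(st, mi)
        table.add(("mu", mi), ku, ("m_unbind", mi))
        table.add(("mw", mi, 0), w0, ("m_walk", mi, 0))
        table.add(("mw", mi, 1), w1, ("m_walk", mi, 1))
        bind = p.binding_propensity if (not m.bound and motor_cand[mi]) else 0.0
        table.add(("mb", mi), bind, ("m_bind", mi, motor_cand[mi]))
    _, linker_cand = cand["linker"]
    for li, l in enumerate(st.linkers):
        table.add(("lu", li), cfg.linker.k_off if l.bound else 0.0,
                  ("l_unbind", li))
        bind = cfg.linker.k_on if (not l.bound and linker_cand[li]) else 0.0
        table.add(("lb", li), bind, ("l_bind", li, linker_cand[li]))
    return table


def _execute(st: _State, log: EventLog, ev, site_pos, site_fil, site_arc,
             cand, table: Optional[_RateTable] = None) -> None:
    cfg = st.config
    rng = st.rng
    kind = ev[0]

    def refresh_fil(fid):
        if table is None:
            return
        _refresh_fil_tips(st, table, fid)
        for mi, m in enumerate(st.motors):
            if m.bound and fid in m.fil:
                _refresh_motor(st, table, mi)

    if kind == "poly":
        f = st.fils[ev[1]]
        if ev[2] == "plus":
            u = f.beads[-1] - f.beads[-2]
            new = f.beads[-1] + u / np.linalg.norm(u) * cfg.segment_length
            if cfg.domain.contains(new):
                f.set_beads(np.vstack([f.beads, new]))
                log.append(st.time, "polymerize", f.id, "plus")
                refresh_fil(f.id)
        else:
            u = f.beads[0] - f.beads[1]
            new = f.beads[0] + u / np.linalg.norm(u) * cfg.segment_length
            if cfg.domain.contains(new):
                seg0 = float(np.linalg.norm(f.beads[0] - new))
                f.set_beads(np.vstack([new, f.beads]))
                for agent in st.motors + st.linkers:
                    if agent.bound:
                        for e in range(2):
                            if agent.fil[e] == f.id:
                                agent.arc[e] += seg0
                log.append(st.time, "polymerize", f.id, "minus")
                refresh_fil(f.id)
    elif kind == "depoly":
        f = st.fils[ev[1]]
        if len(f.beads) <= 2:
            return
        if ev[2] == "plus":
            seg = float(np.linalg.norm(f.beads[-1] - f.beads[-2]))
            _detach_from_segment(st, log, f.id, f.total_length() - seg + 1e-9,
                                 np.inf, table)
            f.set_beads(f.beads[:-1])
            total = f.total_length()
            for agent in st.motors + st.linkers:
                if agent.bound:
                    for e in range(2):
                        if agent.fil[e] == f.id:
                            agent.arc[e] = min(agent.arc[e], total)
        else:
            seg = float(np.linalg.norm(f.beads[1] - f.beads[0]))
            _detach_from_segment(st, log, f.id, -np.inf, seg - 1e-9, table)
            f.set_beads(f.beads[1:])
            for agent in st.motors + st.linkers:
                if agent.bound:
                    for e in range(2):
                        if agent.fil[e] == f.id:
                            agent.arc[e] = max(agent.arc[e] - seg, 0.0)
        log.append(st.time, "depolymerize", f.id, ev[2])
        refresh_fil(f.id)
    elif kind == "m_unbind":
        mi = ev[1]
        m = st.motors[mi]
        _unbind(m, st)
        log.append(st.time, "unbind", m.id)
        if table is not None:
            _refresh_motor(st, table, mi)
    elif kind == "m_walk":
        mi, e = ev[1], ev[2]
        m = st.motors[mi]
        p = st.species[m.species_idx]
        total = st.fils[m.fil[e]].total_length()
        m.arc[e] = min(m.arc[e] + p.d_step, total)
        log.append(st.time, "walk", m.id, f"end{e}")
        # the step stretches the motor spring: update its tension estimate on
        # the frozen bead geometry so stalling and the catch bond engage
        # within the window, not only after the next relaxation
        p1 = st.fils[m.fil[0]].point_at(m.arc[0])
        p2 = st.fils[m.fil[1]].point_at(m.arc[1])
        m.tension = max(0.0, p.k_motor * (float(np.linalg.norm(p2 - p1)) - m.rest))
        if table is not None:
            _refresh_motor(st, table, mi)
    elif kind == "m_bind":
        mi = ev[1]
        m = st.motors[mi]
        p = st.species[m.species_idx]
        pairs, _ = cand["motor"]
        # restrict to pairs within this species' own reaction range
        choices = []
        for pi in ev[2]:
            i, j = pairs[pi]
            d = float(np.linalg.norm(site_pos[i] - site_pos[j]))
            if p.rxn_min <= d <= p.rxn_max:
                choices.append(pi)
        if not choices:
            return
        pi = choices[int(rng.integers(len(choices)))]
        i, j = pairs[pi]
        m.state = "bound"
        m.fil = [str(site_fil[i]), str(site_fil[j])]
        m.arc = [float(site_arc[i]), float(site_arc[j])]
        m.rest = float(np.linalg.norm(site_pos[i] - site_pos[j]))
        m.nt = int(rng.integers(p.heads_min, p.heads_max + 1))
        m.tension = 0.0
        log.append(st.time, "bind", m.id)
        if table is not None:
            table.set(("mb", mi), 0.0)
            _refresh_motor(st, table, mi)
    elif kind == "l_unbind":
        li = ev[1]
        l = st.linkers[li]
        _unbind(l, st)
        log.append(st.time, "linker-unbind", l.id)
        if table is not None:
            table.set(("lu", li), 0.0)
    elif kind == "l_bind":
        li = ev[1]
        l = st.linkers[li]
        pairs, _ = cand["linker"]
        pi = ev[2][int(rng.integers(len(ev[2])))]
        i, j = pairs[pi]
        l.state = "bound"
        l.fil = [str(site_fil[i]), str(site_fil[j])]
        l.arc = [float(site_arc[i]), float(site_arc[j])]
        l.rest = float(np.linalg.norm(site_pos[i] - site_pos[j]))
        l.tension = 0.0
        log.append(st.time, "linker-bind", l.id)
        if table is not None:
            table.set(("lb", li), 0.0)
            table.set(("lu", li), cfg.linker.k_off)


def _reflect(pos: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    m = np.mod(pos, 2 * lengths)
    return np.where(m > lengths, 2 * lengths - m, m)


def _diffuse(st: _State, dt: float) -> None:
    sigma = math.sqrt(2.0 * st.config.motor_diffusion * dt)
    for agent in st.motors + st.linkers:
        if not agent.bound:
            step = st.rng.normal(0.0, sigma, size=3)
            agent.pos = _reflect(agent.pos + step, st.config.domain.lengths)


def _chem_window(st: _State, t_end: float, log: EventLog) -> None:
    """Exact stochastic sampling of the event system on [st.time, t_end]."""
    _diffuse(st, t_end - st.time)
    site_pos, site_fil, site_arc, cand = _binding_candidates(st)
    table = _build_table(st, cand)
    while True:
        total = table.total()
        if total <= 1e-15:
            st.time = t_end
            return
        tau = st.rng.exponential(1.0 / total)
        if st.time + tau > t_end:
            st.time = t_end
            return
        st.time += tau
        k = table.pick(st.rng.uniform(0.0, total))
        _execute(st, log, table.events[k], site_pos, site_fil, site_arc, cand,
                 table)


def _stretch_cap(st: _State, log: EventLog) -> None:
    for m in st.motors:
        if not m.bound:
            continue
        p = st.species[m.species_idx]
        p1 = st.fils[m.fil[0]].point_at(m.arc[0])
        p2 = st.fils[m.fil[1]].point_at(m.arc[1])
        if np.linalg.norm(p2 - p1) > st.config.stretch_cap_factor * p.rxn_max:
            _unbind(m, st)
            log.append(st.time, "unbind", m.id, "stretch-cap")


def step_chemistry(
    frame: Frame,
    dt_chem: float,
    rng: np.random.Generator,
    config: Optional[SimConfig] = None,
) -> Tuple[Frame, EventLog]:
    """One chemistry window on a frame (no mechanical relaxation)."""
    if dt_chem <= 0:
        raise ValueError("dt_chem must be positive")
    config = config or SimConfig()
    st = _state_from_frame(frame, config, rng)
    log = EventLog()
    _chem_window(st, frame.time + dt_chem, log)
    return _snapshot(st), log


def run_simulation(config: SimConfig) -> Tuple[Trajectory, EventLog]:
    """Alternate chemistry and mechanics until ``total_time``; snapshots at
    the configured cadence, scheduled parameter switches applied exactly once."""
    rng = np.random.default_rng(config.seed)
    st = _init_state(config, rng)
    log = EventLog()
    _relax(st)
    frames = [_snapshot(st)]
    switches = sorted(config.switches, key=lambda s: s.time)
    applied = [False] * len(switches)
    next_snap = config.snapshot_every
    while st.time < config.total_time - 1e-9:
        for i, sw in enumerate(switches):
            if not applied[i] and st.time >= sw.time - 1e-9:
                names = [p.name for p in st.species]
                k = names.index(sw.species)
                st.species[k] = st.species[k].with_(**{sw.parameter: sw.value})
                applied[i] = True
                log.append(st.time, "switch", sw.species,
                           f"{sw.parameter}={sw.value}")
        t_end = min(st.time + config.dt_chem, config.total_time)
        for sw, done in zip(switches, applied):
            if not done and st.time < sw.time < t_end:
                t_end = sw.time
        _chem_window(st, t_end, log)
        _relax(st, max_iter=config.mech.window_max_iter)
        _stretch_cap(st, log)
        if st.time >= next_snap - 1e-9 or st.time >= config.total_time - 1e-9:
            frames.append(_snapshot(st))
            next_snap += config.snapshot_every
    traj = Trajectory(frames=frames, seed=config.seed,
                      config_hash=config.config_hash())
    return traj, log
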