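"""Plain-text trajectory snapshots, configuration files, and result writers.

Snapshot grammar (one frame)::

    TIME 100.000
    DOMAIN 2000.000 2000.000 200.000 200.000
    FILAMENT f0 6
    x y z            # one line per bead, plus end last
    ...
    MOTOR m0 myosin bound x1 y1 z1 x2 y2 z2 22
    LINKER l0 diffusing x1 y1 z1 x2 y2 z2

Coordinates are nm with three decimals; a trajectory file is a concatenation
of frames.  The format mirrors the information content of MEDYAN-style
snapshot output (bead chains with marked plus ends, motor and linker
endpoint pairs) so converters are straightforward; bound-agent attachments
are re-derivable from the endpoint coordinates.

Configs are YAML with the motor parameter table's own key names (``d_step``,
``k_head_bind``, ``F_s``, ``range_heads``, ``K_motor``, ``F_0``,
``range_rxn``); an empty file yields the full baseline defaults.  Unknown
keys are rejected.
"""

from __future__ import annotations

import json

from pathlib import Path
from typing import Optional, TextIO, Union

import numpy as np
import yaml

from .geometry import Crosslinker, Domain, Filament, Frame, MotorMinifilament, Trajectory
from .kinetics import MotorParams
from .simulator import LinkerParams, MechParams, RateSwitch, SimConfig

__all__ = [
    "write_frame",
    "read_frame",
    "write_trajectory",
    "read_trajectory",
    "load_config",
    "dump_config",
    "write_results",
]

FORMAT_VERSION = 1


class SnapshotError(ValueError):
    """Malformed snapshot stream; carries the offending line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


def _fmt(x: float) -> str:
    return f"{x:.3f}"


def write_frame(frame: Frame, stream: TextIO) -> None:
    """Serialize one frame in the plain-text snapshot grammar."""
    d = frame.domain
    stream.write(f"TIME {_fmt(frame.time)}\n")
    stream.write(
        f"DOMAIN {_fmt(d.lx)} {_fmt(d.ly)} {_fmt(d.lz)} {_fmt(d.compartment_size)}\n"
    )
    for f in frame.filaments:
        stream.write(f"FILAMENT {f.id} {f.n_beads}\n")
        for b in f.beads:
            stream.write(f"{_fmt(b[0])} {_fmt(b[1])} {_fmt(b[2])}\n")
    for m in frame.motors:
        e = m.endpoints
        stream.write(
            f"MOTOR {m.id} {m.species} {m.state} "
            f"{_fmt(e[0, 0])} {_fmt(e[0, 1])} {_fmt(e[0, 2])} "
            f"{_fmt(e[1, 0])} {_fmt(e[1, 1])} {_fmt(e[1, 2])} {m.n_heads}\n"
        )
    for l in frame.linkers:
        e = l.endpoints
        stream.write(
            f"LINKER {l.id} {l.state} "
            f"{_fmt(e[0, 0])} {_fmt(e[0, 1])} {_fmt(e[0, 2])} "
            f"{_fmt(e[1, 0])} {_fmt(e[1, 1])} {_fmt(e[1, 2])}\n"
        )


class _LineReader:
    def __init__(self, stream: TextIO):
        self.lines = stream if hasattr(stream, "readline") else iter(stream)
        self.lineno = 0
        self._pushed: Optional[str] = None

    def next(self) -> Optional[str]:
        if self._pushed is not None:
            line, self._pushed = self._pushed, None
            return line
        for raw in self.lines:
            self.lineno += 1
            line = raw.strip()
            if line:
                return line
        return None

    def push(self, line: str) -> None:
        self._pushed = line


def _read_one_frame(rd: _LineReader) -> Optional[Frame]:
    line = rd.next()
    if line is None:
        return None
    tok = line.split()
    if tok[0] != "TIME" or len(tok) != 2:
        raise SnapshotError(rd.lineno, f"expected TIME record, got {line!r}")
    try:
        time = float(tok[1])
    except ValueError:
        raise SnapshotError(rd.lineno, f"bad time value {tok[1]!r}")
    domain = Domain()
    filaments, motors, linkers = [], [], []
    while True:
        line = rd.next()
        if line is None:
            break
        tok = line.split()
        kind = tok[0]
        if kind == "TIME":
            rd.push(line)
            rd.lineno -= 0
            break
        if kind == "DOMAIN":
            if len(tok) != 5:
                raise SnapshotError(rd.lineno, "DOMAIN needs 4 numbers")
            lx, ly, lz, comp = map(float, tok[1:])
            domain = Domain(lx, ly, lz, comp)
        elif kind == "FILAMENT":
            if len(tok) != 3:
                raise SnapshotError(rd.lineno, "FILAMENT needs id and bead count")
            fid, n = tok[1], int(tok[2])
            beads = []
            for _ in range(n):
                bl = rd.next()
                if bl is None:
                    raise SnapshotError(rd.lineno, f"truncated bead list for {fid}")
                parts = bl.split()
                if len(parts) != 3:
                    raise SnapshotError(rd.lineno, f"bad bead line {bl!r}")
                try:
                    beads.append([float(p) for p in parts])
                except ValueError:
                    raise SnapshotError(rd.lineno, f"bad bead coordinates {bl!r}")
            filaments.append(Filament(id=fid, beads=np.array(beads)))
        elif kind == "MOTOR":
            if len(tok) != 11:
                raise SnapshotError(rd.lineno, "MOTOR needs 10 fields after the tag")
            try:
                coords = [float(p) for p in tok[4:10]]
                n_heads = int(tok[10])
            except ValueError:
                raise SnapshotError(rd.lineno, f"bad MOTOR numbers in {line!r}")
            motors.append(
                MotorMinifilament(
                    id=tok[1], species=tok[2], state=tok[3],
                    endpoints=np.array(coords).reshape(2, 3), n_heads=n_heads,
                )
            )
        elif kind == "LINKER":
            if len(tok) != 9:
                raise SnapshotError(rd.lineno, "LINKER needs 8 fields after the tag")
            try:
                coords = [float(p) for p in tok[3:9]]
            except ValueError:
                raise SnapshotError(rd.lineno, f"bad LINKER numbers in {line!r}")
            linkers.append(
                Crosslinker(
                    id=tok[1], state=tok[2],
                    endpoints=np.array(coords).reshape(2, 3),
                )
            )
        else:
            raise SnapshotError(rd.lineno, f"unknown record type {kind!r}")
    return Frame(time=time, filaments=filaments, motors=motors, linkers=linkers,
                 domain=domain)


def read_frame(stream: TextIO) -> Frame:
    """Parse a single frame; raises :class:`SnapshotError` with the line
    number on malformed input."""
    frame = _read_one_frame(_LineReader(stream))
    if frame is None:
        raise SnapshotError(0, "empty stream")
    return frame


def write_trajectory(traj: Trajectory, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write(f"# actomyosim trajectory v{FORMAT_VERSION} "
                 f"seed={traj.seed} config={traj.config_hash}\n")
        for frame in traj.frames:
            write_frame(frame, fh)


def read_trajectory(path: Union[str, Path]) -> Trajectory:
    seed, config_hash = 0, ""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for part in first.split():
                if part.startswith("seed="):
                    seed = int(part[5:])
                elif part.startswith("config="):
                    config_hash = part[7:]
        else:
            fh.seek(0)
        rd = _LineReader(fh)
        frames = []
        while True:
            frame = _read_one_frame(rd)
            if frame is None:
                break
            frames.append(frame)
    if not frames:
        raise SnapshotError(0, "trajectory file contains no frames")
    return Trajectory(frames=frames, seed=seed, config_hash=config_hash)


# ---------------------------------------------------------------------------
# configuration

_MOTOR_KEYS = {
    "name": "name",
    "d_step": "d_step",
    "k_head_bind": "k_head_bind",
    "F_s": "f_stall",
    "range_heads": None,      # pair -> heads_min/heads_max
    "K_motor": "k_motor",
    "F_0": "f0_head",
    "range_rxn": None,        # pair -> rxn_min/rxn_max
    "k_head_unbind": "k_head_unbind",
    "d_total": "d_total",
    "alpha": "alpha",
}

_SIM_KEYS = {
    "n_filaments", "filament_length", "segment_length", "n_motors", "n_linkers",
    "k_poly_plus", "k_depoly_plus", "k_poly_minus", "k_depoly_minus",
    "dt_chem", "total_time", "snapshot_every", "seed", "motor_diffusion",
    "binding_search_radius", "stretch_cap_factor",
}


def _motor_from_mapping(data: dict, context: str) -> MotorParams:
    kwargs = {}
    for key, val in data.items():
        if key not in _MOTOR_KEYS:
            raise ValueError(f"unknown motor key {key!r} in {context}")
        if key == "range_heads":
            lo, hi = val
            kwargs["heads_min"], kwargs["heads_max"] = int(lo), int(hi)
        elif key == "range_rxn":
            lo, hi = val
            kwargs["rxn_min"], kwargs["rxn_max"] = float(lo), float(hi)
        elif key == "name":
            kwargs["name"] = str(val)
        else:
            kwargs[_MOTOR_KEYS[key]] = float(val)
    try:
        return MotorParams(**kwargs)
    except ValueError as exc:
        raise ValueError(f"{context}: {exc}") from exc


def load_config(path: Union[str, Path]) -> SimConfig:
    """Load a YAML config; absent keys fall back to the baseline defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    kwargs: dict = {}
    motor_overrides: dict = {}
    species = None
    for key, val in data.items():
        if key in _MOTOR_KEYS:
            motor_overrides[key] = val
        elif key == "species":
            species = tuple(
                _motor_from_mapping(sp, f"species[{i}]") for i, sp in enumerate(val)
            )
        elif key == "domain":
            kwargs["domain"] = Domain(
                lx=float(val.get("lx", 2000.0)),
                ly=float(val.get("ly", 2000.0)),
                lz=float(val.get("lz", 200.0)),
                compartment_size=float(val.get("compartment_size", 200.0)),
            )
        elif key == "linker":
            kwargs["linker"] = LinkerParams(**{k: float(v) for k, v in val.items()})
        elif key == "mechanics":
            kwargs["mech"] = MechParams(**val)
        elif key == "switches":
            kwargs["switches"] = tuple(
                RateSwitch(
                    time=float(s["time"]), species=str(s["species"]),
                    parameter=str(s["parameter"]), value=float(s["value"]),
                )
                for s in val
            )
        elif key in _SIM_KEYS:
            kwargs[key] = type(getattr(SimConfig(), key))(val)
        else:
            raise ValueError(f"unknown config key {key!r}")
    if species is None:
        species = (_motor_from_mapping(motor_overrides, "motor parameters"),)
    elif motor_overrides:
        raise ValueError("give either top-level motor keys or a species list, not both")
    return SimConfig(species=species, **kwargs)


def dump_config(config: SimConfig, path: Union[str, Path]) -> None:
    """Write a config back to YAML (round-trips through load_config)."""
    data: dict = {
        "domain": {
            "lx": config.domain.lx, "ly": config.domain.ly,
            "lz": config.domain.lz,
            "compartment_size": config.domain.compartment_size,
        },
        "species": [
            {
                "name": p.name, "d_step": p.d_step, "k_head_bind": p.k_head_bind,
                "F_s": p.f_stall, "range_heads": [p.heads_min, p.heads_max],
                "K_motor": p.k_motor, "F_0": p.f0_head,
                "range_rxn": [p.rxn_min, p.rxn_max],
                "k_head_unbind": p.k_head_unbind, "d_total": p.d_total,
                "alpha": p.alpha,
            }
            for p in config.species
        ],
    }
    for key in sorted(_SIM_KEYS):
        data[key] = getattr(config, key)
    if config.switches:
        data["switches"] = [
            {"time": s.time, "species": s.species, "parameter": s.parameter,
             "value": s.value}
            for s in config.switches
        ]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def write_results(tables: dict, manifest: dict, outdir: Union[str, Path]) -> list:
    """Write tidy CSVs plus a JSON manifest; returns the written paths.

    Column order is preserved and rows are written as-is, so rewriting the
    same inputs yields byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    mp = outdir / "manifest.json"
    with open(mp, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    written.append(mp)
    return written
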