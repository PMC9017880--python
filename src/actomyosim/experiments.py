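"""Drivers for the computational experiments: single-parameter sweeps,
two-motor-population runs, and the mid-run rate-switch protocol.

Each driver runs seeded replicate simulations (seed = base seed + run
index), measures every trajectory with :func:`measure_all`, and returns a
tidy table.  Aggregation reports mean and sample SD over seeds per time
point.  Individual run failures are recorded and the batch continues.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .kinetics import MotorParams
from .measures import MeasureSeries, measure_all, measures_to_table, threshold_crossing_time
from .simulator import RateSwitch, SimConfig, run_simulation

__all__ = [
    "SweepSpec",
    "TwoMotorSpec",
    "SwitchSpec",
    "run_measured",
    "run_sweep",
    "run_two_motor",
    "run_switch",
    "dominance_summary",
    "aggregate_mean_sd",
    "crossing_times_from_table",
]

#: motor-parameter keys accepted by sweeps, alongside "n_motors"
MOTOR_PARAM_KEYS = (
    "d_step", "k_head_bind", "f_stall", "heads_min", "heads_max",
    "k_motor", "f0_head", "rxn_min", "rxn_max",
)


@dataclass
class SweepSpec:
    """One-parameter-at-a-time sweep over seeded replicates."""

    parameter: str                      # MotorParams field, "heads_range",
    #                                     or "n_motors"
    values: Sequence
    n_seeds: int = 5
    base: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        if len(self.values) < 1:
            raise ValueError("need at least one value")
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")


@dataclass
class TwoMotorSpec:
    """Equal-split mixture of two motor parameter sets."""

    species_a: MotorParams
    species_b: MotorParams
    n_seeds: int = 5
    base: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        if self.species_a.name == self.species_b.name:
            self.species_a = self.species_a.with_(name=self.species_a.name + "_a")
            self.species_b = self.species_b.with_(name=self.species_b.name + "_b")


@dataclass
class SwitchSpec:
    """Mid-run change of one motor parameter (binding-rate switch protocol)."""

    parameter: str = "k_head_bind"
    value_before: float = 0.8
    value_after: float = 0.4
    t_switch: float = 4000.0
    total_time: float = 9000.0
    n_seeds: int = 5
    base: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        if not 0 < self.t_switch < self.total_time:
            raise ValueError("need 0 < t_switch < total_time")


def _with_param(config: SimConfig, parameter: str, value) -> SimConfig:
    if parameter == "n_motors":
        return replace(config, n_motors=int(value))
    if parameter == "heads_range":
        lo, hi = value
        sp = tuple(p.with_(heads_min=int(lo), heads_max=int(hi)) for p in config.species)
        return replace(config, species=sp)
    if parameter in MOTOR_PARAM_KEYS:
        sp = tuple(p.with_(**{parameter: value}) for p in config.species)
        return replace(config, species=sp)
    raise ValueError(f"unknown sweep parameter {parameter!r}")


def run_measured(config: SimConfig, extra: Optional[dict] = None) -> pd.DataFrame:
    """Run one simulation and return its tidy measure table."""
    traj, _ = run_simulation(config)
    return measures_to_table(measure_all(traj), extra=extra)


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Tidy table over value x seed; failed runs are logged as error rows."""
    tables = []
    run_idx = 0
    for value in spec.values:
        for s in range(spec.n_seeds):
            seed = spec.base.seed + run_idx
            run_idx += 1
            cfg = replace(_with_param(spec.base, spec.parameter, value), seed=seed)
            extra = {"parameter": spec.parameter, "param_value": repr(value)}
            try:
                tables.append(run_measured(cfg, extra=extra))
            except Exception as exc:  # record and continue
                tables.append(
                    pd.DataFrame(
                        [{**extra, "seed": seed, "time_s": np.nan,
                          "measure": "error", "component": type(exc).__name__,
                          "value": np.nan, "valid": False}]
                    )
                )
    return pd.concat(tables, ignore_index=True)


def run_two_motor(spec: TwoMotorSpec) -> pd.DataFrame:
    """Equal-split two-species runs; per-species and pooled measures."""
    base = spec.base
    cfg0 = replace(base, species=(spec.species_a, spec.species_b))
    tables = []
    for s in range(spec.n_seeds):
        cfg = replace(cfg0, seed=base.seed + s)
        extra = {
            "parameter": "two_motor",
            "param_value": f"{spec.species_a.name}+{spec.species_b.name}",
        }
        try:
            tables.append(run_measured(cfg, extra=extra))
        except Exception as exc:
            tables.append(
                pd.DataFrame(
                    [{**extra, "seed": cfg.seed, "time_s": np.nan,
                      "measure": "error", "component": type(exc).__name__,
                      "value": np.nan, "valid": False}]
                )
            )
    return pd.concat(tables, ignore_index=True)


def run_switch(spec: SwitchSpec) -> pd.DataFrame:
    """Rate-switch runs; rows annotated with the pre/post phase."""
    base = spec.base
    sp = tuple(
        p.with_(**{spec.parameter: spec.value_before}) for p in base.species
    )
    switches = tuple(
        RateSwitch(spec.t_switch, p.name, spec.parameter, spec.value_after)
        for p in sp
    )
    cfg0 = replace(base, species=sp, switches=switches, total_time=spec.total_time)
    tables = []
    for s in range(spec.n_seeds):
        cfg = replace(cfg0, seed=base.seed + s)
        extra = {
            "parameter": spec.parameter,
            "param_value": f"{spec.value_before}->{spec.value_after}@{spec.t_switch}",
        }
        df = run_measured(cfg, extra=extra)
        df["phase"] = np.where(df["time_s"] < spec.t_switch, "pre", "post")
        tables.append(df)
    return pd.concat(tables, ignore_index=True)


def aggregate_mean_sd(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD over seeds per (parameter, value, measure,
    component, time)."""
    keys = [k for k in ("parameter", "param_value") if k in table.columns]
    keys += ["measure", "component", "time_s"]
    valid = table[table["valid"] & table["value"].notna()] if "valid" in table else table
    g = valid.groupby(keys)["value"]
    out = g.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count").reset_index()
    return out


def crossing_times_from_table(
    table: pd.DataFrame, threshold: float, direction: str = "either"
) -> pd.DataFrame:
    """Per-seed threshold-crossing times of the normalized R_g series."""
    rows = []
    sub = table[(table["measure"] == "rg_norm") & (table["component"] == "all")]
    group_keys = [k for k in ("parameter", "param_value") if k in sub.columns]
    for key, g in sub.groupby(group_keys + ["seed"]):
        g = g.sort_values("time_s")
        series = MeasureSeries(
            name="rg_norm",
            times=g["time_s"].to_numpy(),
            values=list(g["value"].to_numpy()),
            seed=int(g["seed"].iloc[0]),
        )
        t = threshold_crossing_time(series, threshold, direction)
        row = dict(zip(group_keys + ["seed"], key if isinstance(key, tuple) else (key,)))
        row.update({"threshold": threshold, "time": np.nan if t is None else t,
                    "censored": t is None})
        rows.append(row)
    return pd.DataFrame(rows)


def dominance_summary(
    a_alone: pd.DataFrame,
    b_alone: pd.DataFrame,
    mixture: pd.DataFrame,
    thresholds: Sequence[float] = (0.05, 0.10),
    direction: str = "either",
):
    """Per-seed crossing times and group medians for the dominance readout.

    Censored runs (series never crossing the threshold) are excluded from the
    medians but reported in the ``n_censored`` column.
    """
    per_run = []
    summaries = []
    for name, table in (("a_alone", a_alone), ("b_alone", b_alone),
                        ("mixture", mixture)):
        for thr in thresholds:
            ct = crossing_times_from_table(table, thr, direction)
            ct["group"] = name
            per_run.append(ct)
            observed = ct.loc[~ct["censored"], "time"]
            summaries.append(
                {
                    "group": name,
                    "threshold": thr,
                    "median_time": float(observed.median()) if len(observed) else np.nan,
                    "n_observed": int(len(observed)),
                    "n_censored": int(ct["censored"].sum()),
                }
            )
    return pd.concat(per_run, ignore_index=True), pd.DataFrame(summaries)
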