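"""Myosin minifilament kinetic parameters and rate laws.

A minifilament is a bipolar ensemble of N_t myosin heads per end whose
collective binding, walking, stalling and unbinding follow the parallel
cluster model for non-processive motors.  Units: nm, s, pN.

Rate laws
---------
* duty ratio            rho = k_bind / (k_bind + k_unbind)          (per head)
* base walking rate     k0  = (d_step / d_total) (1 - rho)/rho k_bind
* loaded walking rate   k(F) = max{0, k0 (F_s - F) / (F_s + F/alpha)}
* unbinding (catch bond) k_u(F) = k_u0(N_t) exp(-F / (N_bound F_0))

The zero-force minifilament unbinding rate is inversely proportional to the
head count (residence time grows with N_t) with a duty-ratio-dependent
prefactor,

    k_u0 = k_head_unbind (1 - rho)^(rho N_ref) / N_t,

an ensemble closure in the spirit of the parallel cluster model: a higher
duty ratio means more heads simultaneously bound and a combinatorially rarer
complete release, so residence time grows steeply with the per-head binding
rate.  ``N_ref`` is a fixed reference ensemble size (default 20), not the
sampled N_t, which keeps k_u0 exactly proportional to 1/N_t.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Tuple

__all__ = [
    "MotorParams",
    "duty_ratio",
    "base_walking_rate",
    "walking_rate",
    "zero_force_unbinding_rate",
    "unbinding_rate",
]


@dataclass(frozen=True)
class MotorParams:
    """Kinetic parameter set of one motor species (non-muscle myosin II-like
    baselines).

    ``k_motor`` is the stretching force constant in pN/nm; ``f0_head`` is the
    per-head characteristic unbinding force of the catch bond.  ``d_total``
    is the spacing of binding sites along a model filament segment (segment
    length 108 nm with 4 sites, so 27 nm).  ``alpha`` tunes how steeply the
    walking rate falls with load.
    """

    name: str = "myosin"
    d_step: float = 6.0           # nm
    k_head_bind: float = 0.2      # 1/s
    f_stall: float = 100.0        # pN
    heads_min: int = 15
    heads_max: int = 30
    k_motor: float = 2.5          # pN/nm
    f0_head: float = 12.62        # pN
    rxn_min: float = 175.0        # nm
    rxn_max: float = 225.0        # nm
    k_head_unbind: float = 1.8    # 1/s (sets a ~0.1 baseline duty ratio)
    d_total: float = 27.0         # nm
    alpha: float = 0.2
    n_ref: int = 20

    def __post_init__(self) -> None:
        for attr in ("d_step", "k_head_bind", "f_stall", "k_motor", "f0_head",
                     "rxn_min", "rxn_max", "k_head_unbind", "d_total", "alpha"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"MotorParams.{attr} must be positive")
        if not 1 <= self.heads_min <= self.heads_max:
            raise ValueError("need 1 <= heads_min <= heads_max")
        if not self.rxn_min < self.rxn_max:
            raise ValueError("need rxn_min < rxn_max")

    @property
    def heads_range(self) -> Tuple[int, int]:
        return (self.heads_min, self.heads_max)

    @property
    def heads_mean(self) -> float:
        return 0.5 * (self.heads_min + self.heads_max)

    @property
    def duty_ratio(self) -> float:
        return duty_ratio(self)

    @property
    def base_walk_rate(self) -> float:
        return base_walking_rate(self)

    @property
    def binding_propensity(self) -> float:
        """Minifilament attachment propensity when sites are in reach (1/s)."""
        return self.k_head_bind * self.heads_mean

    def with_(self, **kwargs) -> "MotorParams":
        return replace(self, **kwargs)


def duty_ratio(p: MotorParams) -> float:
    """Fraction of the cycle a head spends bound: k_b / (k_b + k_u)."""
    if p.k_head_bind <= 0 or p.k_head_unbind <= 0:
        raise ValueError("rates must be positive")
    return p.k_head_bind / (p.k_head_bind + p.k_head_unbind)


def base_walking_rate(p: MotorParams) -> float:
    """Unloaded minifilament stepping rate (1/s)."""
    rho = duty_ratio(p)
    if rho <= 0:
        raise ValueError("duty ratio must be positive")
    return (p.d_step / p.d_total) * ((1.0 - rho) / rho) * p.k_head_bind


def walking_rate(k0: float, f_ext: float, p: MotorParams) -> float:
    """Load-dependent stepping rate; zero at and beyond the stall force."""
    if f_ext < 0:
        raise ValueError("external force must be >= 0")
    return max(0.0, k0 * (p.f_stall - f_ext) / (p.f_stall + f_ext / p.alpha))


def zero_force_unbinding_rate(p: MotorParams, n_heads: int) -> float:
    """Minifilament unbinding rate at zero load; proportional to 1/N_t."""
    if n_heads < 1:
        raise ValueError("n_heads must be >= 1")
    rho = duty_ratio(p)
    return p.k_head_unbind * (1.0 - rho) ** (rho * p.n_ref) / n_heads


def unbinding_rate(
    f: float, n_heads: int, p: MotorParams, n_bound: Optional[int] = None
) -> float:
    """Catch-bond minifilament unbinding rate under stretching force ``f``.

    The load is shared over ``n_bound`` engaged heads (default: the expected
    number, rho * N_t, at least one), and the rate decays exponentially with
    the per-head share — so the bond tightens under load.
    """
    if f < 0:
        raise ValueError("force must be >= 0")
    if n_heads < 1:
        raise ValueError("n_heads must be >= 1")
    if n_bound is None:
        n_bound = max(1, round(duty_ratio(p) * n_heads))
    elif n_bound < 1:
        raise ValueError("n_bound must be >= 1")
    import math

    return zero_force_unbinding_rate(p, n_heads) * math.exp(-f / (n_bound * p.f0_head))
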