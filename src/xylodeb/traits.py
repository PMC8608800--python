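"""Functional-trait inference from the abj-DEB model.

Scenario conventions
--------------------
Trait scenarios (growth curves, maximum size, total reproductive output)
run the whole life cycle at constant temperature and food level, with the
egg provisioned by a mother at the scenario ``f`` (so the scaled reserve
density at birth equals ``f``).  Scenario horizons — the lifespans used as
integration limits — are counted from *birth*, while the age at puberty is
reported as the actual age since fertilization; these are the conventions
under which the model reproduces the published trait tables.

Larval chronology scenarios run at the constant dispersal temperature; the
hatching age is reported at the spawning-ground temperature (4 degC, eggs
spawned at the deep-sea wood fall), obtained by exact Arrhenius rescaling
of the non-feeding pre-hatch phase.  The pelagic larval duration (PLD) is
the time from hatching to settlement, with settlement preceding the
completion of metamorphosis by the one-week convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forcing import ForcingSchedule, Segment, KappaOverride
from .lifecycle import (
    LifeCycle,
    Trajectory,
    initial_reserve,
    SETTLEMENT_LEAD_D,
)
from .params import ParameterSet, arrhenius_correction, derive_compound

__all__ = [
    "TraitRow",
    "LarvalChronology",
    "von_bertalanffy_rate",
    "simulate_scenario",
    "shell_height_at_age",
    "traits_for_scenario",
    "traits_table",
    "larval_chronology",
    "pld_table",
    "dwarf_scenario",
    "max_reproduction_rate",
]

T_SPAWN_DEFAULT = 4.0  # degC at the deep-sea wood fall where eggs are spawned


def von_bertalanffy_rate(params: ParameterSet, f: float, T_celsius: float) -> float:
    """Closed-form von Bertalanffy growth rate r_B (d^-1).

    ``r_B = (k_M / 3) / (1 + f/g) * c(T)`` with ``k_M = [p_M]/[E_G]`` and
    ``g = [E_G]/(kappa [E_m])``; this is the asymptotic rate of the
    post-metamorphosis growth curve at constant food.  ``f = 0`` is the
    starvation regime — the formula then returns the rate of approach to
    zero size, which the engine never realizes (structure does not shrink).
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"f must lie in [0, 1], got {f}")
    cp = derive_compound(params)
    return (cp.k_M / 3.0) / (1.0 + f / cp.g) * arrhenius_correction(T_celsius, params)


def simulate_scenario(params: ParameterSet, f: float, T_celsius: float,
                      horizon: float, horizon_from: str = "birth",
                      kappa_post_j: float | None = None,
                      f_post_j: float | None = None,
                      fast: bool = False) -> Trajectory:
    """Constant-environment life-cycle run, optionally switching kappa
    and/or f at the completion of metamorphosis (dwarf-male scenario)."""
    segments = [Segment(0.0, T_celsius, f)]
    if f_post_j is not None:
        segments.append(Segment("metamorphosis", T_celsius, f_post_j))
    overrides = []
    if kappa_post_j is not None:
        overrides.append(KappaOverride("metamorphosis", kappa_post_j))
    forcing = ForcingSchedule(segments=segments, kappa_overrides=overrides)
    model = LifeCycle(params, forcing, fast=fast)
    return model.simulate(horizon, f_mother=f, horizon_from=horizon_from)


def shell_height_at_age(params: ParameterSet, f: float, T_celsius: float,
                        age: float, age_from: str = "birth",
                        trajectory: Trajectory | None = None) -> float:
    """Shell height (cm) at ``age`` days under a constant scenario."""
    if trajectory is None:
        trajectory = simulate_scenario(params, f, T_celsius, age, age_from)
    offset = 0.0
    if age_from == "birth":
        offset = trajectory.chronology.age_birth
    return trajectory.shell_height_at(age + offset)


@dataclass
class TraitRow:
    """One scenario row of the functional-trait table."""

    scenario: str
    f: float
    T_celsius: float
    horizon_d: float
    r_B: float               # d^-1
    Lmax_cm: float           # shell height at the end of the horizon
    age_at_puberty_d: float | None  # since fertilization; None if not reached
    TRO: int | None          # oocytes over the horizon; None before puberty


def traits_for_scenario(params: ParameterSet, f: float, T_celsius: float,
                        horizon: float, label: str | None = None,
                        trajectory: Trajectory | None = None) -> TraitRow:
    """Functional traits for one (f, T) scenario over a lifespan horizon.

    The total reproductive output converts the reproduction buffer at the
    end of the horizon into an oocyte count, ``TRO = floor(E_R / E_0)``
    with the egg cost at the scenario f (reproduction efficiency kappa_R is
    applied during buffer accumulation, not at conversion).
    """
    traj = trajectory or simulate_scenario(params, f, T_celsius, horizon)
    end_age = traj.chronology.age_birth + horizon
    st = traj.state_at(end_age)
    a_p = traj.chronology.age_puberty
    if a_p is None:
        tro = None
    else:
        tro = int(math.floor(st.E_R / traj.E_0))
    return TraitRow(
        scenario=label or f"f={f:g}, {T_celsius:g}C",
        f=f, T_celsius=T_celsius, horizon_d=horizon,
        r_B=von_bertalanffy_rate(params, f, T_celsius),
        Lmax_cm=traj.shell_height_at(end_age),
        age_at_puberty_d=a_p,
        TRO=tro,
    )


def traits_table(params: ParameterSet,
                 grid: list[tuple[float, float, float]] | None = None) -> pd.DataFrame:
    """Trait table over a scenario grid of (f, T degC, horizon d).

    The default grid is the published four-scenario design: f in {1, 0.5}
    crossed with 4 degC (deep sea, 821-d lifespan) and 11 degC (100 m
    depth, 404-d lifespan).
    """
    if grid is None:
        grid = [(1.0, 4.0, 821.0), (1.0, 11.0, 404.0),
                (0.5, 4.0, 821.0), (0.5, 11.0, 404.0)]
    rows = [traits_for_scenario(params, f, T, hor) for f, T, hor in grid]
    return pd.DataFrame([{
        "f": r.f, "T_C": r.T_celsius, "horizon_d": r.horizon_d,
        "r_B_per_d": r.r_B, "Lmax_cm": r.Lmax_cm,
        "age_at_puberty_d": r.age_at_puberty_d, "TRO": r.TRO,
    } for r in rows])


@dataclass
class LarvalChronology:
    """Stage ages (d since fertilization) for one dispersal scenario."""

    f: float
    T_dispersal: float
    T_spawn: float
    age_hatch: float          # at the spawning temperature
    age_birth: float          # at the dispersal temperature
    age_metamorphosis: float  # at the dispersal temperature
    pld: float                # age_metamorphosis - age_hatch - 7

    def __post_init__(self):
        if not 0.0 < self.age_hatch < self.age_birth < self.age_metamorphosis:
            raise ValueError(
                "larval ages must be positive and increasing: "
                f"{self.age_hatch}, {self.age_birth}, {self.age_metamorphosis}"
            )


def larval_chronology(params: ParameterSet, f: float, T_dispersal: float,
                      T_spawn: float = T_SPAWN_DEFAULT,
                      max_days: float = 500.0) -> LarvalChronology:
    """Larval stage ages and pelagic larval duration for one scenario.

    The run is at the constant dispersal temperature with the egg
    provisioned at the scenario ``f``.  Hatching — which happens at the
    spawning ground before dispersal — is reported at ``T_spawn`` by exact
    Arrhenius rescaling (the pre-hatch phase does not feed, so its duration
    scales as 1/c(T)).
    """
    traj = simulate_scenario(params, f, T_dispersal, max_days,
                             horizon_from="fertilization")
    ch = traj.chronology
    if ch.age_metamorphosis is None:
        raise RuntimeError(
            f"metamorphosis not reached within {max_days} d at "
            f"f={f}, T={T_dispersal} degC"
        )
    scale = (arrhenius_correction(T_dispersal, params)
             / arrhenius_correction(T_spawn, params))
    age_hatch_spawn = ch.age_hatch * scale
    pld = ch.age_metamorphosis - age_hatch_spawn - SETTLEMENT_LEAD_D
    return LarvalChronology(
        f=f, T_dispersal=T_dispersal, T_spawn=T_spawn,
        age_hatch=age_hatch_spawn, age_birth=ch.age_birth,
        age_metamorphosis=ch.age_metamorphosis, pld=pld,
    )


def pld_table(params: ParameterSet,
              fs: tuple[float, ...] = (0.5, 0.8, 1.0),
              Ts: tuple[float, ...] = (4.0, 11.0, 16.0)) -> pd.DataFrame:
    """Larval chronology over the dispersal grid (published 3x3 design:
    demersal 4 degC, 100-m 11 degC, surface 16 degC)."""
    rows = []
    for f in fs:
        for T in Ts:
            lc = larval_chronology(params, f, T)
            rows.append({
                "f": f, "T_C": T,
                "age_hatch_d": lc.age_hatch,
                "age_birth_d": lc.age_birth,
                "age_metamorphosis_d": lc.age_metamorphosis,
                "pld_d": lc.pld,
            })
    return pd.DataFrame(rows)


def dwarf_scenario(params: ParameterSet, kappa_post_j: float = 0.06,
                   f_post_j: float = 0.8, T_celsius: float = 4.0,
                   f_pre: float = 1.0, horizon: float = 821.0) -> Trajectory:
    """Dwarf-male scenario: normal development through metamorphosis, then
    the allocation fraction drops to ``kappa_post_j`` and food to
    ``f_post_j``.  The acceleration factor stays frozen at its achieved
    value.  Returns the trajectory (horizon counted from birth); query
    shell height and reproduction buffer at deployment ages through it.
    """
    if not 0.0 < kappa_post_j < 1.0:
        raise ValueError(f"kappa_post_j must lie in (0, 1), got {kappa_post_j}")
    traj = simulate_scenario(params, f_pre, T_celsius, horizon,
                             kappa_post_j=kappa_post_j, f_post_j=f_post_j)
    if not traj.alive:
        raise RuntimeError(
            f"dwarf scenario starved to death at age {traj.age_death:.1f} d "
            f"(kappa_post_j={kappa_post_j} cannot cover maintenance)"
        )
    return traj


def max_reproduction_rate(params: ParameterSet, T_celsius: float | None = None,
                          f: float = 1.0, fast: bool = False) -> float:
    """Maximum reproduction rate (oocytes d^-1) at the ultimate size.

    Evaluated at structural length ``L_i = s_M L_m f`` with reserve at
    equilibrium (e = f): ``R_i = kappa_R ((1-kappa) p_C - k_J E_H^p) / E_0``.
    The reference temperature is used unless ``T_celsius`` is given (the
    evaluation temperature of the published figure is not stated).
    """
    cp = derive_compound(params)
    if cp.s_M_max == 1.0:
        # no printed after-metamorphosis rates: take the achieved factor
        traj = simulate_scenario(params, f, params.T_ref - 273.15, 10.0,
                                 horizon_from="birth", fast=True)
        s_M = traj.s_M
    else:
        s_M = cp.s_M_max
    T = params.T_ref - 273.15 if T_celsius is None else T_celsius
    c = arrhenius_correction(T, params)
    L_i = f * s_M * cp.L_m
    V = L_i ** 3
    E = f * cp.E_m * V
    p_C = E * (params.E_G * params.v_b * s_M * c / L_i + params.p_M * c) / (
        params.E_G + params.kappa * f * cp.E_m)
    p_R = (1.0 - params.kappa) * p_C - params.k_J * c * params.EH_p
    E_0 = initial_reserve(params, f, fast=fast)
    return params.kappa_R * max(p_R, 0.0) / E_0
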