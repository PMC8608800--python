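"""DEB parameter set, compound parameters, thermal correction and size conversions.

The parameter container holds the primary parameters of an abj dynamic
energy budget (DEB) model — the standard DEB model extended with a phase of
metabolic acceleration between first feeding (birth, ``b``) and the
completion of metamorphosis (``j``) during which surface-specific
assimilation and energy conductance scale with structural length.

All rate parameters are referenced to ``T_ref`` and corrected to the
environmental temperature with a one-parameter Arrhenius factor.  User-facing
temperatures are in degrees Celsius; kelvin is used internally.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace as _dc_replace
from enum import IntEnum
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "Stage",
    "ParameterSet",
    "CompoundParams",
    "arrhenius_correction",
    "derive_compound",
    "shell_height",
    "structural_length",
    "wet_weight",
    "load_parameters",
    "save_parameters",
    "default_parameters",
]

ZERO_CELSIUS = 273.15


class Stage(IntEnum):
    """Life stages in the fixed order they are traversed."""

    EMBRYO = 0            # fertilization -> hatching (trochophore)
    LARVA_PRE_BIRTH = 1   # hatching -> birth; swims but does not feed
    LARVA_ACCELERATING = 2  # birth -> metamorphosis; feeding, V1-morphic
    JUVENILE = 3          # metamorphosis -> puberty; isomorphic wood borer
    ADULT = 4             # puberty onward; allocates to reproduction buffer


#: stages whose physical length is measured with the larval shape coefficient
_LARVAL_STAGES = frozenset(
    {Stage.EMBRYO, Stage.LARVA_PRE_BIRTH, Stage.LARVA_ACCELERATING}
)


@dataclass
class ParameterSet:
    """Primary abj-DEB parameters plus auxiliary constants for one organism.

    Rates (``pAm_b``, ``v_b``, ``p_M``, ``k_J``) are at the reference
    temperature ``T_ref``.  ``pAm_j`` and ``v_j`` are the after-metamorphosis
    values ``{p_Am}_b * s_M`` and ``v_b * s_M``; when supplied they pin the
    acceleration factor, otherwise it emerges from a simulation as
    ``L_j / L_b``.

    Parameters
    ----------
    kappa : float
        Allocation fraction of mobilized reserve to soma, in (0, 1).
    pAm_b : float
        Maximum surface-specific assimilation rate at birth, J cm^-2 d^-1.
    v_b : float
        Energy conductance at birth, cm d^-1.
    E_G : float
        Volume-specific cost for structure, J cm^-3.
    p_M : float
        Volume-specific somatic maintenance, J cm^-3 d^-1.
    k_J : float
        Maturity maintenance rate coefficient, d^-1.
    kappa_R : float
        Reproduction efficiency (fraction of the reproduction flux fixed
        into the buffer), dimensionless.
    EH_h, EH_b, EH_j, EH_p : float
        Maturity thresholds at hatch, birth, metamorphosis and puberty, J.
    T_A : float
        Arrhenius temperature, K.
    T_ref : float
        Reference temperature, K.
    delta_ME, delta_M : float
        Shape coefficients (structural length / shell height) for the
        larval and juvenile/adult stages.
    d_V, w_E, mu_E : float
        Structural dry-mass density (g cm^-3), reserve molar weight
        (g mol^-1) and reserve chemical potential (J mol^-1); together they
        set the wet-weight coefficient ``omega``.
    """

    kappa: float = 0.73
    pAm_b: float = 14.36
    v_b: float = 0.0053
    E_G: float = 2349.0
    p_M: float = 29.22
    k_J: float = 0.002
    kappa_R: float = 0.95
    EH_h: float = 2.3586e-05
    EH_b: float = 1.04e-3
    EH_j: float = 2.03e-2
    EH_p: float = 1.65
    T_A: float = 8000.0
    T_ref: float = 293.15
    delta_ME: float = 0.629
    delta_M: float = 0.599
    d_V: float = 0.09
    w_E: float = 23.9
    mu_E: float = 550000.0
    pAm_j: float | None = None
    v_j: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 < self.kappa < 1.0:
            raise ValueError(f"kappa must lie in (0, 1), got {self.kappa}")
        positive = {
            "pAm_b": self.pAm_b, "v_b": self.v_b, "E_G": self.E_G,
            "p_M": self.p_M, "k_J": self.k_J, "kappa_R": self.kappa_R,
            "EH_h": self.EH_h, "EH_b": self.EH_b, "EH_j": self.EH_j,
            "EH_p": self.EH_p, "T_A": self.T_A, "T_ref": self.T_ref,
            "delta_ME": self.delta_ME, "delta_M": self.delta_M,
            "d_V": self.d_V, "w_E": self.w_E, "mu_E": self.mu_E,
        }
        for name, value in positive.items():
            if not value > 0.0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if not self.EH_h < self.EH_b < self.EH_j < self.EH_p:
            raise ValueError(
                "maturity thresholds must be ordered EH_h < EH_b < EH_j < EH_p, "
                f"got {self.EH_h}, {self.EH_b}, {self.EH_j}, {self.EH_p}"
            )
        if self.pAm_j is not None and self.v_j is not None:
            r1 = self.pAm_j / self.pAm_b
            r2 = self.v_j / self.v_b
            if abs(r1 - r2) / r2 > 0.005:
                raise ValueError(
                    "inconsistent acceleration factor: pAm_j/pAm_b = "
                    f"{r1:.4f} but v_j/v_b = {r2:.4f} (differ by more than 0.5%)"
                )

    def replace(self, **changes) -> "ParameterSet":
        """Return a copy with the given fields replaced (re-validated)."""
        return _dc_replace(self, **changes)

    @property
    def omega(self) -> float:
        """Wet-weight contribution of reserve: omega = [E_m] w_E / (d_V mu_E)."""
        return (self.pAm_b / self.v_b) * self.w_E / (self.d_V * self.mu_E)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass(frozen=True)
class CompoundParams:
    """Compound parameters derived from a :class:`ParameterSet`.

    ``E_m = {p_Am}_b / v_b`` (maximum reserve capacity, J cm^-3),
    ``k_M = [p_M] / [E_G]`` (somatic maintenance rate coefficient, d^-1),
    ``L_m = kappa {p_Am}_b / [p_M]`` (maximum structural length before
    acceleration, cm), ``g = [E_G] / (kappa [E_m])`` (energy investment
    ratio) and ``s_M_max`` (acceleration factor after metamorphosis).
    """

    E_m: float
    k_M: float
    L_m: float
    g: float
    s_M_max: float


def derive_compound(params: ParameterSet, s_M: float | None = None) -> CompoundParams:
    """Derive compound parameters.

    ``s_M_max`` is taken from the printed after-metamorphosis assimilation
    rate (``pAm_j/pAm_b``) when available, else from the supplied simulated
    ``s_M = L_j/L_b``, else it defaults to 1 (no acceleration information).
    """
    E_m = params.pAm_b / params.v_b
    k_M = params.p_M / params.E_G
    L_m = params.kappa * params.pAm_b / params.p_M
    g = params.E_G / (params.kappa * E_m)
    if params.pAm_j is not None:
        s_M_max = params.pAm_j / params.pAm_b
    elif s_M is not None:
        s_M_max = float(s_M)
    else:
        s_M_max = 1.0
    return CompoundParams(E_m=E_m, k_M=k_M, L_m=L_m, g=g, s_M_max=s_M_max)


def arrhenius_correction(T_celsius, params: ParameterSet):
    """Dimensionless thermal correction c(T) = exp(T_A/T_ref - T_A/T).

    Multiplies every rate parameter; c(T_ref) = 1 and c is strictly
    increasing in temperature.  Accepts scalars or arrays of temperature in
    degrees Celsius.
    """
    T = np.asarray(T_celsius, dtype=float) + ZERO_CELSIUS
    if np.any(T <= 0.0):
        raise ValueError(
            f"non-physical temperature {T_celsius} degC (at or below absolute zero)"
        )
    c = np.exp(params.T_A / params.T_ref - params.T_A / T)
    return float(c) if np.isscalar(T_celsius) else c


def shell_height(V, stage: Stage, params: ParameterSet):
    """Physical shell height (cm) from structural volume (cm^3).

    ``Lw = V^{1/3} / delta`` with the larval shape coefficient ``delta_ME``
    through the completion of metamorphosis and the juvenile/adult
    coefficient ``delta_M`` after.
    """
    V = np.asarray(V, dtype=float)
    if np.any(V < 0.0):
        raise ValueError("structural volume must be non-negative")
    if not isinstance(stage, Stage):
        raise ValueError(f"unknown life stage: {stage!r}")
    delta = params.delta_ME if stage in _LARVAL_STAGES else params.delta_M
    out = np.cbrt(V) / delta
    return float(out) if out.ndim == 0 else out


def structural_length(Lw, stage: Stage, params: ParameterSet):
    """Inverse of :func:`shell_height`: structural length V^{1/3} (cm)."""
    Lw = np.asarray(Lw, dtype=float)
    if np.any(Lw < 0.0):
        raise ValueError("shell height must be non-negative")
    if not isinstance(stage, Stage):
        raise ValueError(f"unknown life stage: {stage!r}")
    delta = params.delta_ME if stage in _LARVAL_STAGES else params.delta_M
    out = Lw * delta
    return float(out) if out.ndim == 0 else out


def wet_weight(V, e, params: ParameterSet):
    """Wet weight (g): Ww = V (1 + e * omega), reproduction buffer excluded.

    ``e`` is the scaled reserve density [E]/[E_m] in [0, 1]; the structural
    contribution assumes a wet specific density of 1 g cm^-3.
    """
    V = np.asarray(V, dtype=float)
    e = np.asarray(e, dtype=float)
    if np.any(V < 0.0):
        raise ValueError("structural volume must be non-negative")
    if np.any((e < 0.0) | (e > 1.0 + 1e-9)):
        raise ValueError("scaled reserve density must lie in [0, 1]")
    out = V * (1.0 + e * params.omega)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# parameter file I/O

def save_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write a flat JSON parameter file (round-trips with load_parameters)."""
    d = params.to_dict()
    meta = d.pop("meta")
    doc = {"meta": meta, **d}
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=False) + "\n")


def load_parameters(path: str | Path) -> ParameterSet:
    """Read a flat JSON parameter file written by :func:`save_parameters`."""
    doc = json.loads(Path(path).read_text())
    meta = doc.pop("meta", {})
    return ParameterSet(meta=meta, **doc)


def default_parameters() -> ParameterSet:
    """The shipped parameter set for *Xylonora atlantica*."""
    with resources.files("xylodeb.data").joinpath("xylonora_atlantica.json").open() as fh:
        doc = json.load(fh)
    meta = doc.pop("meta", {})
    return ParameterSet(meta=meta, **doc)
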