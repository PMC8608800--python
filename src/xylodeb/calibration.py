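"""Calibration: predict an observation set, score the fit, estimate parameters.

The observation set mirrors the structure used to parameterize DEB models:
*zerovariate* entries (single-valued life-history traits, each with its
temperature and food context) and *univariate* series (shell height against
age from colonization experiments, whose food level may be left free and
estimated jointly with the parameters).

Goodness of fit follows the two standard scores: the mean relative error
(MRE, >= 0, 0 = perfect) and the symmetric mean squared error
(SMSE in [0, 1], entry-wise ``(p - o)^2 / (o^2 + p^2)``).  Estimation
minimizes the weighted symmetric bounded loss (the SMSE form) with a
bounded Nelder-Mead simplex over log-scaled parameters, with a restart
schedule for robustness.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace as _dc_replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import minimize

from .params import ParameterSet
from .lifecycle import initial_reserve
from .traits import simulate_scenario, max_reproduction_rate
from .params import arrhenius_correction, derive_compound

__all__ = [
    "ZerovariateEntry",
    "UnivariateSeries",
    "ObservationSet",
    "predict_observations",
    "relative_error",
    "mre",
    "smse",
    "DEBCalibration",
    "CalibrationResults",
    "TRAIT_NAMES",
]

#: zerovariate traits with predictors (lifespan is carried as metadata only:
#: there is no aging submodule, so it must have weight 0)
TRAIT_NAMES = (
    "age_at_hatching",
    "age_at_birth",
    "time_since_birth_to_metamorphosis",
    "time_since_birth_to_puberty",
    "lifespan",
    "shell_height_at_hatching",
    "shell_height_at_birth",
    "shell_height_at_metamorphosis",
    "shell_height_at_puberty",
    "max_shell_height",
    "wet_weight_at_puberty",
    "max_reproduction_rate",
)


@dataclass
class ZerovariateEntry:
    """One single-valued life-history observation with its (T, f) context."""

    name: str
    value: float
    unit: str
    T_celsius: float
    f: float
    weight: float = 1.0
    trait: str | None = None  # predictor key; defaults to `name`

    def __post_init__(self):
        if self.weight < 0.0:
            raise ValueError(f"{self.name}: weight must be non-negative")
        if self.trait is None:
            self.trait = self.name
        if self.trait not in TRAIT_NAMES:
            raise ValueError(
                f"{self.name}: no predictor for trait {self.trait!r}; "
                f"known traits: {TRAIT_NAMES}"
            )


@dataclass
class UnivariateSeries:
    """Shell height against age (d since fertilization) at one (T, f).

    ``f=None`` marks the food level as free: it is estimated during
    calibration.  The series' total weight is split uniformly over its
    points so a long series counts like one zerovariate entry.
    """

    name: str
    ages: np.ndarray
    values: np.ndarray
    T_celsius: float
    f: float | None
    weight: float = 1.0

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.ages.shape != self.values.shape:
            raise ValueError(f"{self.name}: ages and values must align")
        if self.weight < 0.0:
            raise ValueError(f"{self.name}: weight must be non-negative")
        if self.f is not None and not 0.0 < self.f <= 1.0:
            raise ValueError(f"{self.name}: f must lie in (0, 1] or be None (free)")


@dataclass
class ObservationSet:
    """Weighted zerovariate entries plus univariate growth series."""

    zerovariate: list[ZerovariateEntry] = field(default_factory=list)
    univariate: list[UnivariateSeries] = field(default_factory=list)
    notes: str = ""

    @property
    def free_f_names(self) -> list[str]:
        return [s.name for s in self.univariate if s.f is None]

    def series(self, name: str) -> UnivariateSeries:
        for s in self.univariate:
            if s.name == name:
                return s
        raise KeyError(name)

    # -- directory I/O ------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([{
            "name": z.name, "value": z.value, "unit": z.unit,
            "T_celsius": z.T_celsius, "f": z.f, "weight": z.weight,
            "trait": z.trait,
        } for z in self.zerovariate]).to_csv(d / "zerovariate.csv", index=False)
        rows = []
        for s in self.univariate:
            for a, v in zip(s.ages, s.values):
                rows.append({"series": s.name, "age_d": a, "shell_height_cm": v})
        pd.DataFrame(rows).to_csv(d / "univariate.csv", index=False)
        ctx = {
            "notes": self.notes,
            "series": {
                s.name: {"T_celsius": s.T_celsius, "f": s.f, "weight": s.weight}
                for s in self.univariate
            },
        }
        (d / "context.yaml").write_text(yaml.safe_dump(ctx, sort_keys=False))

    @classmethod
    def load(cls, directory: str | Path) -> "ObservationSet":
        d = Path(directory)
        zdf = pd.read_csv(d / "zerovariate.csv")
        zero = [ZerovariateEntry(
            name=r["name"], value=float(r["value"]), unit=str(r["unit"]),
            T_celsius=float(r["T_celsius"]), f=float(r["f"]),
            weight=float(r["weight"]), trait=str(r["trait"]),
        ) for r in zdf.to_dict("records")]
        ctx = yaml.safe_load((d / "context.yaml").read_text())
        udf = pd.read_csv(d / "univariate.csv")
        uni = []
        for name, c in (ctx.get("series") or {}).items():
            sub = udf[udf["series"] == name]
            uni.append(UnivariateSeries(
                name=name, ages=sub["age_d"].to_numpy(),
                values=sub["shell_height_cm"].to_numpy(),
                T_celsius=float(c["T_celsius"]),
                f=None if c["f"] is None else float(c["f"]),
                weight=float(c.get("weight", 1.0)),
            ))
        return cls(zerovariate=zero, univariate=uni,
                   notes=str(ctx.get("notes", "")))


# ---------------------------------------------------------------------------
# prediction

class _ScenarioCache:
    """One life-cycle run per (T, f) context, reused across entries."""

    def __init__(self, params: ParameterSet, fast: bool = True):
        self.params = params
        self.fast = fast
        self._runs: dict[tuple, object] = {}

    def run(self, T: float, f: float, min_age: float = 0.0):
        key = (round(T, 9), round(f, 12))
        c4 = arrhenius_correction(4.0, self.params)
        cT = arrhenius_correction(T, self.params)
        horizon = max(min_age + 1.0, 450.0 / max(f, 0.05) * c4 / cT)
        traj = self._runs.get(key)
        if traj is None or traj.t_end < min_age:
            traj = simulate_scenario(self.params, f, T, horizon,
                                     horizon_from="fertilization",
                                     fast=self.fast)
            self._runs[key] = traj
        return traj


def _predict_zerovariate(entry: ZerovariateEntry, cache: _ScenarioCache) -> float:
    p = cache.params
    trait = entry.trait
    if trait == "lifespan":
        if entry.weight != 0.0:
            raise ValueError(
                "lifespan has no predictor (no aging submodule); give it weight 0"
            )
        return entry.value
    if trait == "max_reproduction_rate":
        return max_reproduction_rate(p, T_celsius=entry.T_celsius, f=entry.f,
                                     fast=cache.fast)
    traj = cache.run(entry.T_celsius, entry.f)
    ch = traj.chronology
    if trait == "max_shell_height":
        s_M = traj.s_M
        if s_M is None:
            return math.nan
        return entry.f * s_M * derive_compound(p).L_m / p.delta_M
    needs = {
        "age_at_hatching": ch.age_hatch,
        "age_at_birth": ch.age_birth,
        "shell_height_at_hatching": ch.sh_hatch,
        "shell_height_at_birth": ch.sh_birth,
        "shell_height_at_metamorphosis": ch.sh_metamorphosis,
        "shell_height_at_puberty": ch.sh_puberty,
    }
    if trait in needs:
        v = needs[trait]
        return math.nan if v is None else v
    if trait == "time_since_birth_to_metamorphosis":
        if ch.age_metamorphosis is None:
            return math.nan
        return ch.age_metamorphosis - ch.age_birth
    if trait == "time_since_birth_to_puberty":
        if ch.age_puberty is None:
            return math.nan
        return ch.age_puberty - ch.age_birth
    if trait == "wet_weight_at_puberty":
        if ch.age_puberty is None:
            return math.nan
        return traj.wet_weight_at(ch.age_puberty)
    raise ValueError(f"no predictor for trait {trait!r}")


def predict_observations(params: ParameterSet, obs: ObservationSet,
                         free_f: dict | None = None, fast: bool = True):
    """Model predictions aligned to an observation set.

    Returns ``(zero_pred, uni_pred)``: an array of predictions for the
    zerovariate entries (in order) and a dict mapping series name to the
    predicted shell heights at the series' ages.  Series with free f must
    have a value supplied through ``free_f``.
    """
    free_f = dict(free_f or {})
    cache = _ScenarioCache(params, fast=fast)
    # warm the cache with the series contexts first so a shared context is
    # simulated once, long enough for both uses
    uni_pred = {}
    for s in obs.univariate:
        f = s.f if s.f is not None else free_f.get(s.name)
        if f is None:
            raise ValueError(
                f"series {s.name!r} has free f; supply it via free_f"
            )
        traj = cache.run(s.T_celsius, f, min_age=float(np.max(s.ages)))
        uni_pred[s.name] = traj.shell_height_at(s.ages)
    zero_pred = np.array(
        [_predict_zerovariate(z, cache) for z in obs.zerovariate])
    return zero_pred, uni_pred


# ---------------------------------------------------------------------------
# fit scores

def relative_error(pred, obs) -> np.ndarray:
    """Entry-wise RE = |p - o| / |o|."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    return np.abs(pred - obs) / np.abs(obs)


def mre(obs, pred, weights=None) -> float:
    """Weighted mean relative error (0 = perfect, unbounded above).

    Entries with a zero observed value are excluded with a warning.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    w = np.ones_like(obs) if weights is None else np.asarray(weights, dtype=float)
    keep = obs != 0.0
    if not np.all(keep):
        warnings.warn("entries with zero observed value excluded from MRE")
    obs, pred, w = obs[keep], pred[keep], w[keep]
    if w.sum() == 0.0:
        return 0.0
    return float(np.sum(w * relative_error(pred, obs)) / np.sum(w))


def smse(obs, pred, weights=None) -> float:
    """Weighted symmetric mean squared error, in [0, 1].

    Entry-wise ``(p - o)^2 / (o^2 + p^2)`` (0 where both vanish); symmetric
    in (p, o) and invariant to a common rescaling of each entry's units.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    w = np.ones_like(obs) if weights is None else np.asarray(weights, dtype=float)
    denom = obs ** 2 + pred ** 2
    term = np.zeros_like(denom)
    nz = denom > 0.0
    term[nz] = (pred[nz] - obs[nz]) ** 2 / denom[nz]
    if w.sum() == 0.0:
        return 0.0
    return float(np.sum(w * term) / np.sum(w))


def _stack(obs: ObservationSet, zero_pred, uni_pred):
    """Flatten an observation set and its predictions into aligned arrays
    (observed, predicted, weight); series weight split over points."""
    o, p, w = [], [], []
    for z, zp in zip(obs.zerovariate, zero_pred):
        o.append(z.value)
        p.append(zp)
        w.append(z.weight)
    for s in obs.univariate:
        sp = uni_pred[s.name]
        per_point = s.weight / len(s.ages)
        o.extend(s.values)
        p.extend(sp)
        w.extend([per_point] * len(s.ages))
    return np.array(o), np.array(p), np.array(w)


# ---------------------------------------------------------------------------
# the estimation model

_DEFAULT_BOUNDS = {
    "kappa": (0.02, 0.98),
    "kappa_R": (0.5, 1.0),
}


@dataclass
class CalibrationResults:
    """Results of a calibration fit.

    Carries the estimated parameter set, estimated free food levels, the
    goodness-of-fit scores, per-entry relative errors and convergence
    diagnostics.  ``summary()`` renders a readable report.
    """

    model: "DEBCalibration"
    params: ParameterSet
    free_f: dict
    loss: float
    mre: float
    smse: float
    loss_init: float
    n_restarts: int
    nfev: int
    converged: bool
    restart_losses: list = field(default_factory=list)

    @property
    def re_table(self) -> pd.DataFrame:
        zero_pred, uni_pred = predict_observations(
            self.params, self.model.observations, free_f=self.free_f,
            fast=self.model.fast)
        rows = []
        for z, zp in zip(self.model.observations.zerovariate, zero_pred):
            rows.append({
                "entry": z.name, "kind": "zerovariate", "observed": z.value,
                "predicted": zp, "weight": z.weight,
                "RE": abs(zp - z.value) / abs(z.value) if z.value else np.nan,
            })
        for s in self.model.observations.univariate:
            sp = uni_pred[s.name]
            re = float(np.mean(np.abs(sp - s.values) / np.abs(s.values)))
            rows.append({
                "entry": s.name, "kind": "univariate",
                "observed": np.nan, "predicted": np.nan,
                "weight": s.weight, "RE": re,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = []
        lines.append("abj-DEB calibration results")
        lines.append("=" * 60)
        lines.append(f"free parameters : {', '.join(self.model.free)}")
        lines.append(f"restarts        : {self.n_restarts}"
                     f"   function evals: {self.nfev}")
        lines.append(f"converged       : {self.converged}")
        lines.append(f"loss (sym.)     : {self.loss:.6g}"
                     f"   (initial {self.loss_init:.6g})")
        lines.append(f"MRE             : {self.mre:.4f}")
        lines.append(f"SMSE            : {self.smse:.4f}")
        lines.append("-" * 60)
        lines.append(f"{'parameter':<28}{'initial':>14}{'estimate':>14}")
        for name in self.model.free:
            init = self.model._get(self.model.params_init, {}, name)
            est = self.model._get(self.params, self.free_f, name)
            lines.append(f"{name:<28}{init:>14.6g}{est:>14.6g}")
        lines.append("-" * 60)
        tbl = self.re_table
        lines.append(f"{'entry':<36}{'obs':>10}{'pred':>10}{'RE':>8}")
        for r in tbl.to_dict("records"):
            ov = "-" if pd.isna(r["observed"]) else f"{r['observed']:.4g}"
            pv = "-" if pd.isna(r["predicted"]) else f"{r['predicted']:.4g}"
            lines.append(f"{r['entry']:<36}{ov:>10}{pv:>10}{r['RE']:>8.3f}")
        return "\n".join(lines)


class DEBCalibration:
    """Estimation model: fit free DEB parameters to an observation set.

    Parameters
    ----------
    observations : ObservationSet
    params_init : ParameterSet
        Starting parameter set; non-free fields stay fixed.
    free : sequence of str
        Free-parameter names: ParameterSet field names, plus ``"f:<series>"``
        for each univariate series whose food level is free.  Series marked
        free in the observation set are added automatically.
    bounds : dict, optional
        name -> (lo, hi); defaults are a decade around the initial value
        (natural bounds for kappa and f).
    """

    def __init__(self, observations: ObservationSet, params_init: ParameterSet,
                 free: tuple = ("kappa", "v_b", "p_M", "EH_p"),
                 bounds: dict | None = None, fast: bool = True):
        self.observations = observations
        self.params_init = params_init
        free = list(free)
        for name in observations.free_f_names:
            key = f"f:{name}"
            if key not in free:
                free.append(key)
        if not free:
            raise ValueError("free parameter subset must be non-empty")
        self.free = free
        self.fast = fast
        self.bounds = {}
        user_bounds = dict(bounds or {})
        for name in self.free:
            if name in user_bounds:
                lo, hi = user_bounds[name]
            elif name.startswith("f:"):
                lo, hi = 0.05, 1.0
            elif name in _DEFAULT_BOUNDS:
                lo, hi = _DEFAULT_BOUNDS[name]
            else:
                v = self._get(params_init, {}, name)
                lo, hi = v / 10.0, v * 10.0
            if not 0.0 < lo < hi:
                raise ValueError(f"bounds for {name} must be positive and ordered")
            self.bounds[name] = (lo, hi)

    # -- parameter vector plumbing -----------------------------------------

    @staticmethod
    def _get(params: ParameterSet, free_f: dict, name: str) -> float:
        if name.startswith("f:"):
            return free_f.get(name[2:], 0.8)
        return getattr(params, name)

    def _unpack(self, theta: np.ndarray) -> tuple[ParameterSet, dict]:
        values = np.exp(theta)
        changes, free_f = {}, {}
        for name, v in zip(self.free, values):
            if name.startswith("f:"):
                free_f[name[2:]] = min(float(v), 1.0)
            else:
                changes[name] = float(v)
        # the printed after-metamorphosis rates are tied to the at-birth ones
        # through the acceleration factor; keep the ratio when freeing the base
        init = self.params_init
        if "v_b" in changes and init.v_j is not None and "v_j" not in changes:
            changes["v_j"] = init.v_j * changes["v_b"] / init.v_b
        if ("pAm_b" in changes and init.pAm_j is not None
                and "pAm_j" not in changes):
            changes["pAm_j"] = init.pAm_j * changes["pAm_b"] / init.pAm_b
        return init.replace(**changes), free_f

    def _theta0(self) -> np.ndarray:
        vals = []
        for name in self.free:
            v = self._get(self.params_init, {}, name)
            lo, hi = self.bounds[name]
            vals.append(min(max(v, lo), hi))
        return np.log(vals)

    # -- objective ----------------------------------------------------------

    def loss(self, theta: np.ndarray) -> float:
        """Weighted symmetric bounded loss at a log-parameter vector."""
        try:
            params, free_f = self._unpack(theta)
            zero_pred, uni_pred = predict_observations(
                params, self.observations, free_f=free_f, fast=self.fast)
        except (ValueError, RuntimeError):
            return 1.0  # infeasible region: worst possible symmetric loss
        o, p, w = _stack(self.observations, zero_pred, uni_pred)
        if np.any(~np.isfinite(p) & (w > 0.0)):
            return 1.0
        return smse(o, np.nan_to_num(p), w)

    def fit(self, n_restarts: int = 1, seed: int = 0, maxiter: int = 400,
            xatol: float = 1e-5, step_cv: float = 0.2) -> CalibrationResults:
        """Minimize the loss with restarted bounded Nelder-Mead.

        Restart k > 1 starts from the initial point perturbed by a
        seeded lognormal factor with coefficient of variation ``step_cv``;
        the best restart wins.  Deterministic for fixed seed and order.
        """
        rng = np.random.default_rng(seed)
        theta0 = self._theta0()
        log_bounds = [tuple(np.log(self.bounds[n])) for n in self.free]
        sigma = math.sqrt(math.log(1.0 + step_cv ** 2))
        loss_init = self.loss(theta0)
        best = None
        restart_losses = []
        nfev_total = 0
        for k in range(n_restarts):
            if k == 0:
                start = theta0.copy()
            else:
                start = theta0 + rng.normal(0.0, sigma, size=theta0.size)
            start = np.clip(start, [b[0] for b in log_bounds],
                            [b[1] for b in log_bounds])
            res = minimize(self.loss, start, method="Nelder-Mead",
                           bounds=log_bounds,
                           options={"maxiter": maxiter, "xatol": xatol,
                                    "fatol": 1e-9, "adaptive": True})
            nfev_total += res.nfev
            restart_losses.append(float(res.fun))
            if best is None or res.fun < best.fun:
                best = res
        theta_hat = best.x if best.fun <= loss_init else theta0
        converged = bool(best.success) or best.fun <= loss_init
        params_hat, free_f_hat = self._unpack(theta_hat)
        final_loss = min(float(best.fun), loss_init)
        zero_pred, uni_pred = predict_observations(
            params_hat, self.observations, free_f=free_f_hat, fast=self.fast)
        o, p, w = _stack(self.observations, zero_pred, uni_pred)
        return CalibrationResults(
            model=self, params=params_hat, free_f=free_f_hat,
            loss=final_loss, mre=mre(o, p, w), smse=smse(o, p, w),
            loss_init=loss_init, n_restarts=n_restarts, nfev=nfev_total,
            converged=converged, restart_losses=restart_losses,
        )
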