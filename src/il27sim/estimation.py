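"""Closed-form two-time-point parameter estimators.

Each estimator is the exact algebraic inverse of a *simplified*, well-mixed
(diffusion-free) version of one model equation, driven by measurements at two
sampling days (default days 1 and 5) plus a longitudinal tumor-volume series:

* net tumor growth from log-ratios of consecutive volume measurements;
* degradation/death rates from literature half-lives (``ln 2 / t_half``);
* per-cell production rates from the constant-source linear ODE
  ``du/dt = a*S - d*u`` sampled at two times;
* the CTL activation rate and the survival-modulation constants from the
  CD8+ T-cell counts of the control vs IL-27 genotype arms;
* the IL-10 and IFN-gamma killing rates from the genotype contrast between
  arms whose CTLs can and cannot produce IL-10.

Wherever a "constant" source is needed, the arithmetic mean of the two
sampled values is used (configurable to the geometric mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import DomainError

__all__ = [
    "ObservationSet", "EstimatedParameters", "FIXED_CONSTANTS_DEFAULT",
    "net_growth_from_series", "rate_from_halflife", "production_from_two_points",
    "enhanced_production", "activation_rate", "killing_rate", "estimate_all",
    "InsufficientDataError", "UnidentifiableError", "ARMS",
]

#: the four experimental genotype arms: (CTL type x tumor type)
ARMS = ("P1CTL", "IL10KO-P1CTL", "P1CTL-IL27", "IL10KO-P1CTL-IL27")

#: which arms pair with an IL-27-secreting tumor / IL-10-competent CTLs
ARM_HAS_IL27 = {"P1CTL": False, "IL10KO-P1CTL": False,
                "P1CTL-IL27": True, "IL10KO-P1CTL-IL27": True}
ARM_HAS_IL10 = {"P1CTL": True, "IL10KO-P1CTL": False,
                "P1CTL-IL27": True, "IL10KO-P1CTL-IL27": False}


class InsufficientDataError(ValueError):
    """Not enough observations to run an estimator."""


class UnidentifiableError(ValueError):
    """The requested parameter is not identifiable from the given data."""


@dataclass
class ObservationSet:
    """Tidy container for the measurements the estimators consume.

    ``table`` has columns ``arm, quantity, day, value, units``.  Quantities:
    ``volume`` (tumor volume, mm^3; arm ``tumor-only``), ``T`` (tumor density,
    cells/cm^3), ``E`` (CD8+ T-cell density, cells/cm^3), ``I27``/``I10``/``G``
    (cytokine concentrations, pg/cm^3).  ``occupied_volume`` (cm^3) converts
    cell counts to densities.
    """

    table: pd.DataFrame
    occupied_volume: float = 0.1

    def __post_init__(self) -> None:
        required = {"arm", "quantity", "day", "value"}
        missing = required - set(self.table.columns)
        if missing:
            raise DomainError(f"observation table missing columns {sorted(missing)}")
        if (self.table["value"] < 0).any():
            raise DomainError("observations must be nonnegative")

    def series(self, quantity: str, arm: str = "tumor-only") -> tuple[np.ndarray, np.ndarray]:
        sub = self.table[(self.table["arm"] == arm) & (self.table["quantity"] == quantity)]
        sub = sub.sort_values("day")
        return sub["day"].to_numpy(dtype=float), sub["value"].to_numpy(dtype=float)

    def at(self, arm: str, quantity: str, day: float) -> float:
        days, vals = self.series(quantity, arm)
        hit = np.isclose(days, day)
        if not hit.any():
            raise InsufficientDataError(f"no {quantity} observation for {arm} at day {day}")
        return float(vals[hit][0])

    def has_arm(self, arm: str) -> bool:
        return bool((self.table["arm"] == arm).any())

    def to_csv(self, path: Union[str, Path]) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path], occupied_volume: float = 0.1) -> "ObservationSet":
        return cls(pd.read_csv(path), occupied_volume=occupied_volume)


#: literature-sourced constants the estimation cascade conditions on (never
#: estimated): degradation/death rates, half-saturations, diffusivities, the
#: tumor-cell half-life and the survival half-saturation ratio K_E2/K_E1.
FIXED_CONSTANTS_DEFAULT: Dict[str, float] = {
    "d_I27": 1.38889,
    "d_I10": 4.16,
    "d_E": 1.0,
    "d_G": 2.16,
    "K_I27_10": 5.0,
    "K_T": 1.0e7,
    "K_kill10": 60.0,
    "K_killG": 20.0,
    "K_E2_over_K_E1": 0.015,
    "tumor_halflife": 2.0,
    "D_I27": 1.24e-2, "D_I10": 1.24e-2, "D_E": 8.64e-6,
    "D_G": 1.24e-2, "D_T": 8.64e-7,
    "K_I27_G": 1000.0,
}


def _mean(a: float, b: float, kind: str = "arithmetic") -> float:
    if kind == "geometric":
        return float(np.sqrt(a * b))
    return 0.5 * (a + b)


# ---------------------------------------------------------------------------
# elementary estimators
# ---------------------------------------------------------------------------

def net_growth_from_series(times: Sequence[float], values: Sequence[float]) -> float:
    """Mean over consecutive pairs of ``ln(V(t2)/V(t1)) / (t2 - t1)`` (/day)."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 2:
        raise InsufficientDataError("need at least two volume measurements")
    if np.any(v <= 0):
        raise DomainError("volumes must be strictly positive")
    if np.any(np.diff(t) <= 0):
        raise DomainError("measurement days must be strictly increasing")
    return float(np.mean(np.log(v[1:] / v[:-1]) / np.diff(t)))


def rate_from_halflife(halflife: float) -> float:
    """First-order rate ``ln 2 / t_half`` (/day)."""
    if halflife <= 0:
        raise DomainError("half-life must be positive")
    return float(np.log(2.0) / halflife)


def production_from_two_points(u1: float, u2: float, t1: float, t2: float,
                               source_density: float, d: float) -> float:
    """Invert ``du/dt = a*S - d*u`` (constant source density S) for ``a``.

    ``a = d * (u2 - u1*exp(-d*dt)) / (S * (1 - exp(-d*dt)))`` (pg/cell/day).
    """
    if t2 <= t1:
        raise DomainError("t2 must exceed t1")
    if d <= 0:
        raise DomainError("degradation rate must be positive")
    if source_density <= 0:
        raise InsufficientDataError("source density is zero: production unidentifiable")
    decay = np.exp(-d * (t2 - t1))
    return float(d * (u2 - u1 * decay) / (source_density * (1.0 - decay)))


def enhanced_production(u1: float, u2: float, t1: float, t2: float,
                        E_bar: float, I27_bar: float, K: float,
                        lam1: float, d: float) -> float:
    """Invert ``du/dt = lam1*E + lam2*E*I27/(K+I27) - d*u`` for ``lam2``.

    The baseline and enhanced productions share the CTL source ``E_bar``;
    the total source rate is recovered by the two-point formula and the
    known baseline part subtracted.
    """
    if K <= 0:
        raise DomainError("half-saturation K must be positive")
    if I27_bar < 0:
        raise DomainError("I27_bar must be nonnegative")
    if I27_bar == 0:
        raise UnidentifiableError("lam2 is unidentifiable without IL-27")
    total_per_cell = production_from_two_points(u1, u2, t1, t2, E_bar, d)
    saturation = I27_bar / (K + I27_bar)
    return float((total_per_cell - lam1) / saturation)


def _invert_linear_source(E1: float, E2: float, dt: float, d: float) -> float:
    """Source term ``a`` of ``dE/dt = a - d*E`` from two samples."""
    decay = np.exp(-d * dt)
    return float(d * (E2 - E1 * decay) / (1.0 - decay))


def activation_rate(E1: float, E5: float, T_bar: float, K_T: float,
                    d_E_effective: float, t1: float = 1.0, t5: float = 5.0) -> float:
    """Invert ``dE/dt = lamE*T/(K_T+T) - d*E`` for ``lamE`` (cells/cm^3/day)."""
    if t5 <= t1:
        raise DomainError("second sampling day must exceed the first")
    if E1 < 0 or E5 < 0:
        raise DomainError("cell densities must be nonnegative")
    if T_bar <= 0:
        raise UnidentifiableError("activation rate unidentifiable without tumor cells")
    a = _invert_linear_source(E1, E5, t5 - t1, d_E_effective)
    return float(a * (K_T + T_bar) / T_bar)


def effective_death_rate(E1: float, E5: float, a: float, dt: float,
                         bracket: tuple[float, float] = (1e-6, 50.0)) -> float:
    """Solve ``E5 = E1*exp(-d*dt) + (a/d)*(1 - exp(-d*dt))`` for the effective
    CTL death rate ``d`` (monotone scalar root find)."""
    def resid(d: float) -> float:
        decay = np.exp(-d * dt)
        return E1 * decay + (a / d) * (1.0 - decay) - E5
    lo, hi = bracket
    flo, fhi = resid(lo), resid(hi)
    # resid is decreasing in d; clamp to the bracket edge when noisy counts
    # fall outside the range any death rate can explain
    if flo <= 0:
        return lo
    if fhi >= 0:
        return hi
    return float(brentq(resid, lo, hi, xtol=1e-14, rtol=1e-14))


def killing_rate(T1: float, T2: float, t1: float, t2: float, net_growth: float,
                 killer_bar: float, K_kill: float, other_kill: float = 0.0) -> float:
    """Invert ``dT/dt = g*T - eta*T*u/(K+u) - other_kill*T`` for ``eta`` (/day).

    ``other_kill`` subtracts an already-attributed killing rate (used when the
    IFN-gamma contribution has been identified from the IL-10-knockout arm).
    """
    if T1 <= 0 or T2 <= 0:
        raise DomainError("tumor densities must be strictly positive")
    if t2 <= t1:
        raise DomainError("t2 must exceed t1")
    if killer_bar < 0:
        raise DomainError("killer concentration must be nonnegative")
    if killer_bar == 0:
        raise UnidentifiableError("killing rate unidentifiable without the killer present")
    g_obs = np.log(T2 / T1) / (t2 - t1)
    return float((net_growth - g_obs - other_kill) * (K_kill + killer_bar) / killer_bar)


# ---------------------------------------------------------------------------
# the full cascade
# ---------------------------------------------------------------------------

@dataclass
class EstimatedParameters:
    """Output of :func:`estimate_all`: estimated values, the fixed constants
    they conditioned on, every averaged intermediate, and which parameters
    were unestimable (and why)."""

    values: Dict[str, float]
    fixed: Dict[str, float]
    intermediates: Dict[str, float] = field(default_factory=dict)
    unestimable: Dict[str, str] = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def relative_errors(self, truth) -> Dict[str, float]:
        """Relative error of each estimate against a generating ModelParameters."""
        return {k: abs(v - getattr(truth, k)) / abs(getattr(truth, k))
                for k, v in self.values.items() if hasattr(truth, k) and getattr(truth, k) != 0}


def estimate_all(obs: ObservationSet, fixed: Optional[Dict[str, float]] = None,
                 mean_kind: str = "arithmetic") -> EstimatedParameters:
    """Run the full closed-form estimation cascade in dependency order.

    Order: net growth -> d_T/lamT -> mu1 -> lam1 -> lam2 -> lamE and the
    survival-modulation constants -> lamG -> eta2 -> eta1.  Genotype contrasts
    are used exactly as designed: the IL-10-knockout arms isolate the
    IFN-gamma killing rate; the control-tumor vs IL-27-tumor arms isolate the
    IL-27-dependent terms.  Missing arms mark only their dependent parameters
    unestimable.
    """
    fixed = {**FIXED_CONSTANTS_DEFAULT, **(fixed or {})}
    est: Dict[str, float] = {}
    inter: Dict[str, float] = {}
    un: Dict[str, str] = {}

    # -- tumor net growth and proliferation/death split
    days, vols = obs.series("volume")
    g = net_growth_from_series(days, vols)
    d_T = rate_from_halflife(fixed["tumor_halflife"])
    est["d_T"] = d_T
    est["lamT"] = g + d_T
    inter["net_growth"] = g

    def arm_pair(arm: str, qty: str) -> tuple[float, float, float, float]:
        """First/last sampled day and value of a per-arm quantity."""
        d, v = obs.series(qty, arm)
        if d.size < 2:
            raise InsufficientDataError(f"{arm}/{qty}: need two sampling days")
        return float(d[0]), float(v[0]), float(d[-1]), float(v[-1])

    def arm_mean(arm: str, qty: str) -> float:
        _, v1, _, v5 = arm_pair(arm, qty)
        m = _mean(v1, v5, mean_kind)
        inter[f"{qty}_bar[{arm}]"] = m
        return m

    ctrl, ctrl_ko = "P1CTL", "IL10KO-P1CTL"
    il27, il27_ko = "P1CTL-IL27", "IL10KO-P1CTL-IL27"

    # -- mu1 from the IL-27-secreting arm's IL-27 measurements
    if obs.has_arm(il27):
        t1, I27_1, t5, I27_5 = arm_pair(il27, "I27")
        T_bar_27 = arm_mean(il27, "T")
        est["mu1"] = production_from_two_points(I27_1, I27_5, t1, t5,
                                                T_bar_27, fixed["d_I27"])
    else:
        un["mu1"] = "missing IL-27-tumor arm"

    # -- lam1 from the control arm (no IL-27 enhancement)
    if obs.has_arm(ctrl):
        t1, I10_1, t5, I10_5 = arm_pair(ctrl, "I10")
        E_bar_ctrl = arm_mean(ctrl, "E")
        est["lam1"] = production_from_two_points(I10_1, I10_5, t1, t5,
                                                 E_bar_ctrl, fixed["d_I10"])
    else:
        un["lam1"] = "missing control P1CTL arm"

    # -- lam2 from the IL-27 arm, conditioned on lam1 and K_I27_10
    if obs.has_arm(il27) and "lam1" in est:
        t1, I10_1, t5, I10_5 = arm_pair(il27, "I10")
        E_bar_27 = arm_mean(il27, "E")
        I27_bar = arm_mean(il27, "I27")
        est["lam2"] = enhanced_production(I10_1, I10_5, t1, t5, E_bar_27,
                                          I27_bar, fixed["K_I27_10"],
                                          est["lam1"], fixed["d_I10"])
    else:
        un["lam2"] = "requires both the control and IL-27-tumor P1CTL arms"

    # -- lamE from the control arm (death rate = d_E, unmodulated)
    if obs.has_arm(ctrl):
        t1, E1, t5, E5 = arm_pair(ctrl, "E")
        T_bar = arm_mean(ctrl, "T")
        est["lamE"] = activation_rate(E1, E5, T_bar, fixed["K_T"], fixed["d_E"],
                                      t1=t1, t5=t5)
    else:
        un["lamE"] = "missing control P1CTL arm"

    # -- survival-modulation constants from the IL-27 arm: recover the
    #    effective death rate, then split 1 + I27/K_E1 + I10/K_E2 under the
    #    fixed ratio K_E2/K_E1
    if obs.has_arm(il27) and "lamE" in est:
        t1, E1, t5, E5 = arm_pair(il27, "E")
        T_bar_27 = arm_mean(il27, "T")
        a = est["lamE"] * T_bar_27 / (fixed["K_T"] + T_bar_27)
        d_eff = effective_death_rate(E1, E5, a, t5 - t1)
        inter["d_E_effective[P1CTL-IL27]"] = d_eff
        s = fixed["d_E"] / d_eff
        I27_bar = arm_mean(il27, "I27")
        I10_bar = arm_mean(il27, "I10")
        ratio = fixed["K_E2_over_K_E1"]
        if s <= 1:
            un["K_E1"] = "no detectable survival enhancement in the IL-27 arm"
        else:
            est["K_E1"] = (I27_bar + I10_bar / ratio) / (s - 1.0)
            est["K_E2"] = ratio * est["K_E1"]
    elif "K_E1" not in un:
        un["K_E1"] = "requires control and IL-27-tumor P1CTL arms"

    # -- lamG from the control arm (no IL-27 inhibition)
    if obs.has_arm(ctrl):
        t1, G1, t5, G5 = arm_pair(ctrl, "G")
        E_bar_ctrl = arm_mean(ctrl, "E")
        est["lamG"] = production_from_two_points(G1, G5, t1, t5,
                                                 E_bar_ctrl, fixed["d_G"])
    else:
        un["lamG"] = "missing control P1CTL arm"

    # -- eta2 from the IL-10-knockout control arm (IL-10 killing absent)
    if obs.has_arm(ctrl_ko):
        t1, T1, t5, T5 = arm_pair(ctrl_ko, "T")
        G_bar_ko = arm_mean(ctrl_ko, "G")
        est["eta2"] = killing_rate(T1, T5, t1, t5, g, G_bar_ko, fixed["K_killG"])
    else:
        un["eta2"] = "missing IL-10-knockout arm"

    # -- eta1 from the IL-10-competent control arm, subtracting the
    #    already-identified IFN-gamma contribution
    if obs.has_arm(ctrl) and "eta2" in est:
        t1, T1, t5, T5 = arm_pair(ctrl, "T")
        I10_bar = arm_mean(ctrl, "I10")
        G_bar = arm_mean(ctrl, "G")
        kill_G = est["eta2"] * G_bar / (fixed["K_killG"] + G_bar)
        est["eta1"] = killing_rate(T1, T5, t1, t5, g, I10_bar,
                                   fixed["K_kill10"], other_kill=kill_G)
    else:
        un["eta1"] = "requires the control P1CTL arm and eta2 (IL-10-knockout arm)"

    return EstimatedParameters(values=est, fixed=fixed, intermediates=inter,
                               unestimable=un)
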