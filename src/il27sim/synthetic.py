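"""Synthetic observation generator and well-mixed simulator.

No measurements from the underlying mouse experiments are deposited anywhere,
so this module generates observation sets with the statistical structure the
estimation cascade assumes: a tumor-volume series over the third week of
growth, CD8+ T-cell densities at days 1 and 5 for the four genotype arms
(P1CTL, IL-10-knockout P1CTL, each against a control or an IL-27-secreting
tumor), and IL-27/IL-10/IFN-gamma concentrations at the same days, under
seeded multiplicative lognormal noise.

Two generating modes exist:

* ``"simplified"`` (default): each arm's observations are produced by the
  same simplified constant-source linear ODEs that the closed-form estimators
  invert, solved to self-consistency of the day-1/day-5 averages.  Zero-noise
  data from this mode round-trips through :func:`il27sim.estimation.estimate_all`
  to machine precision.
* ``"wellmixed"``: observations are sampled from the full nonlinear
  diffusion-free reaction system; recovery is then only approximate, since
  the estimators neglect within-window source variation.

The well-mixed integrator :func:`simulate_wellmixed` doubles as the
independent ODE oracle for the PDE solver tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .estimation import ARM_HAS_IL10, ARM_HAS_IL27, ARMS, ObservationSet
from .model import ConfigurationError, IDX, ModelParameters, reaction_rates

__all__ = ["ObservationDesign", "simulate_wellmixed", "arm_parameters",
           "generate_observations", "lognormal_factors"]


def arm_parameters(p: ModelParameters, arm: str) -> ModelParameters:
    """Apply the genotype masks of an experimental arm: IL-10-knockout CTLs
    cannot produce IL-10 (lam1 = lam2 = 0); control tumors do not secrete
    IL-27 (mu1 = 0)."""
    if arm not in ARMS:
        raise ConfigurationError(f"unknown arm {arm!r}; expected one of {ARMS}")
    kwargs = {}
    if not ARM_HAS_IL10[arm]:
        kwargs.update(lam1=0.0, lam2=0.0)
    if not ARM_HAS_IL27[arm]:
        kwargs.update(mu1=0.0)
    return p.with_(**kwargs) if kwargs else p


def simulate_wellmixed(p: ModelParameters, days: Sequence[float],
                       y0: Optional[Sequence[float]] = None,
                       f_inj: float | Callable[[float], float] = 0.0,
                       rtol: float = 1.0e-9, atol: float = 1.0e-12,
                       ) -> pd.DataFrame:
    """Integrate the diffusion-free reaction system and sample it at ``days``.

    ``y0`` defaults to a fresh tumor of density 5e7 cells/cm^3 with IL-27 at
    its production/degradation balance and no activated CTLs.  ``f_inj`` may
    be a constant or a function of time (IL-27 source, pg/cm^3/day).

    Returns a tidy frame with columns ``day, species, value``.
    """
    days = np.asarray(sorted(days), dtype=float)
    if y0 is None:
        T0 = 5.0e7
        y0 = [p.mu1 * T0 / p.d_I27, 0.0, 0.0, 0.0, T0]
    y0 = np.asarray(y0, dtype=float)
    source = f_inj if callable(f_inj) else (lambda t, c=float(f_inj): c)

    def rhs(t, y):
        return reaction_rates(y, p, f_inj=source(t), check=False)

    t_span = (min(0.0, days[0]), days[-1])
    sol = solve_ivp(rhs, t_span, y0, method="LSODA", t_eval=days,
                    rtol=rtol, atol=np.asarray(atol) * np.array([1, 1, 1, 1, 1e6]))
    if not sol.success:
        raise RuntimeError(f"well-mixed integration failed: {sol.message}")
    rows = [(d, sp, sol.y[i, k]) for k, d in enumerate(sol.t)
            for sp, i in IDX.items()]
    return pd.DataFrame(rows, columns=["day", "species", "value"])


@dataclass
class ObservationDesign:
    """Measurement schedule, per-arm initial densities and noise model.

    The defaults emulate the source experiments: tumor volume measured every
    three days through the third week; cells and cytokines measured at days
    1 and 5 in adoptive-transfer arms with ``E1`` transferred CTLs per cm^3.
    """

    volume_days: tuple = (11.0, 14.0, 17.0, 20.0)
    volume_at_first_day: float = 50.0        # mm^3
    cell_days: tuple = (1.0, 5.0)
    arms: tuple = ARMS
    T1: float = 2.0e7                        # tumor density at day 1 (cells/cm^3)
    E1: float = 3.0e6                        # transferred CTL density at day 1
    occupied_volume: float = 0.1             # cm^3
    cv: float = 0.1                          # lognormal coefficient of variation per animal
    n_replicates: int = 5                    # animals per group; observations are group means
    seed: int = 0
    mode: str = "simplified"                 # simplified | wellmixed

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ConfigurationError("noise CV must be nonnegative")
        if self.n_replicates < 1:
            raise ConfigurationError("need at least one replicate animal per group")
        if self.mode not in ("simplified", "wellmixed"):
            raise ConfigurationError(f"unknown generator mode {self.mode!r}")
        if len(self.cell_days) != 2 or self.cell_days[1] <= self.cell_days[0]:
            raise ConfigurationError("cell_days must be two increasing days")
        if np.any(np.diff(self.volume_days) <= 0) or self.volume_days[0] <= 0:
            raise ConfigurationError("volume days must be positive and increasing")


def lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Median-preserving multiplicative noise factors with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(sigma * rng.standard_normal(size))


def _simplified_arm(p: ModelParameters, arm: str, design: ObservationDesign) -> dict:
    """Self-consistent solution of the per-arm simplified models.

    Cytokines sit at the quasi-steady state of their constant-source linear
    equations; CTLs relax from the transferred density toward the
    activation/death balance (with survival modulation active in the IL-27
    arms); the tumor follows net exponential growth minus the killing rates
    evaluated at the arm's average cytokine levels.  A fixed-point iteration
    makes the day-1/day-5 averages used as "constant" sources agree with the
    emitted observations, so the closed-form cascade inverts them exactly.
    """
    has_il27, has_il10 = ARM_HAS_IL27[arm], ARM_HAS_IL10[arm]
    t1, t5 = design.cell_days
    dt = t5 - t1
    g = p.lamT - p.d_T
    T1, E1 = design.T1, design.E1

    T5, E5 = T1, E1
    I27_1 = p.mu1 * T1 / p.d_I27 if has_il27 else 0.0
    I27_5 = I27_1
    I10 = 0.0
    G = 0.0
    for _ in range(300):
        T_bar = 0.5 * (T1 + T5)
        E_bar = 0.5 * (E1 + E5)
        I27_bar = 0.5 * (I27_1 + I27_5)
        if has_il27:
            I27_5_new = (I27_1 * np.exp(-p.d_I27 * dt)
                         + (p.mu1 * T_bar / p.d_I27) * (1.0 - np.exp(-p.d_I27 * dt)))
        else:
            I27_5_new = 0.0
        if has_il10:
            src10 = (p.lam1 + (p.lam2 * I27_bar / (p.K_I27_10 + I27_bar)
                               if has_il27 else 0.0)) * E_bar
            I10_new = src10 / p.d_I10
        else:
            I10_new = 0.0
        srcG = p.lamG * E_bar * (p.K_I27_G / (p.K_I27_G + I27_bar) if has_il27 else 1.0)
        G_new = srcG / p.d_G
        a = p.lamE * T_bar / (p.K_T + T_bar)
        d_eff = (p.d_E / (1.0 + I27_bar / p.K_E1 + I10_new / p.K_E2)
                 if has_il27 else p.d_E)
        E5_new = E1 * np.exp(-d_eff * dt) + (a / d_eff) * (1.0 - np.exp(-d_eff * dt))
        kill = p.eta2 * G_new / (p.K_killG + G_new)
        if has_il10:
            kill += p.eta1 * I10_new / (p.K_kill10 + I10_new)
        T5_new = T1 * np.exp((g - kill) * dt)
        shift = max(abs(T5_new - T5) / T1, abs(E5_new - E5) / E1,
                    abs(I10_new - I10) / max(I10, 1e-300) if has_il10 else 0.0)
        T5, E5, I27_5, I10, G = T5_new, E5_new, I27_5_new, I10_new, G_new
        if shift < 1e-14:
            break
    return {"T": (T1, T5), "E": (E1, E5), "I27": (I27_1, I27_5),
            "I10": (I10, I10), "G": (G, G)}


def _wellmixed_arm(p: ModelParameters, arm: str, design: ObservationDesign) -> dict:
    pa = arm_parameters(p, arm)
    t1, t5 = design.cell_days
    y0 = [pa.mu1 * design.T1 / pa.d_I27, 0.0, design.E1, 0.0, design.T1]
    frame = simulate_wellmixed(pa, [t1, t5], y0=y0)
    out = {}
    for sp in ("T", "E", "I27", "I10", "G"):
        vals = frame[frame["species"] == sp].sort_values("day")["value"].to_numpy()
        out[sp] = (float(vals[0]), float(vals[1]))
    return out


def generate_observations(p: ModelParameters, design: ObservationDesign) -> ObservationSet:
    """Generate a seeded :class:`~il27sim.estimation.ObservationSet`.

    All randomness flows through one ``numpy`` generator seeded by
    ``design.seed``; with ``cv = 0`` the output is deterministic and (in
    ``"simplified"`` mode) exactly invertible by the estimation cascade.
    """
    rng = np.random.default_rng(design.seed)
    rows = []

    # longitudinal tumor volumes: net exponential growth of the simplified
    # tumor equation (no adoptive transfer in the volume-series animals)
    g = p.lamT - p.d_T
    t0 = design.volume_days[0]
    for day in design.volume_days:
        v = design.volume_at_first_day * np.exp(g * (day - t0))
        rows.append(("tumor-only", "volume", day, v, "mm^3"))

    units = {"T": "cell/cm^3", "E": "cell/cm^3",
             "I27": "pg/cm^3", "I10": "pg/cm^3", "G": "pg/cm^3"}
    make_arm = _simplified_arm if design.mode == "simplified" else _wellmixed_arm
    for arm in design.arms:
        sampled = make_arm(p, arm, design)
        for qty, (v1, v5) in sampled.items():
            rows.append((arm, qty, design.cell_days[0], v1, units[qty]))
            rows.append((arm, qty, design.cell_days[1], v5, units[qty]))

    table = pd.DataFrame(rows, columns=["arm", "quantity", "day", "value", "units"])
    # each reported value is the mean over a group of animals, each measured
    # with multiplicative lognormal noise
    factors = lognormal_factors(rng, design.cv, len(table) * design.n_replicates)
    table["value"] *= factors.reshape(len(table), design.n_replicates).mean(axis=1)
    return ObservationSet(table=table, occupied_volume=design.occupied_volume)
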