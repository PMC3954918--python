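"""Latin hypercube sampling and PRCC sensitivity analysis.

The uncertainty analysis follows the standard LHS/PRCC methodology for
biological dynamical systems (Marino et al., J. Theor. Biol. 2008): sample
the uncertain parameters with a Latin hypercube, evaluate a scalar model
output per sample, rank-transform inputs and output, and report for each
parameter the partial correlation between its ranks and the output ranks
after regressing out all other ranked parameters, with a Student-t p-value.

The output functional is the *treated/control tumor ratio*: the tumor density
of an IL-27-secreting tumor divided by that of a matched non-secreting tumor
(identical parameters except ``mu1 = 0``) at a fixed evaluation time (and
radius, in PDE mode).  A negative PRCC therefore means that increasing the
parameter strengthens IL-27-mediated tumor rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from .model import ConfigurationError, IDX, ModelParameters, baseline_parameters
from .solver import SolverSettings, build_grid, initial_state, simulate

__all__ = ["ParameterRanges", "SensitivityResult", "default_ranges",
           "lhs_sample", "tumor_ratio", "prcc", "run_sensitivity"]

#: the 13 analyzed parameters: three per-cell production rates, the CTL
#: activation rate, five concentration half-saturations, three first-order
#: rates (CTL death and both killing rates) and the carrying capacity.
SENSITIVITY_PARAMETERS = (
    "lam1", "lam2", "lamG",          # pg/cell/day
    "lamE",                          # cell/cm^3/day
    "K_I27_10", "K_E1", "K_E2", "K_kill10", "K_killG",   # pg/cm^3
    "d_E", "eta1", "eta2",           # /day
    "T_max",                         # cell/cm^3
)


@dataclass
class ParameterRanges:
    """Per-parameter (lower, upper, baseline, unit) for the LHS study."""

    table: pd.DataFrame  # index: parameter; columns: lower, upper, baseline, unit

    def __post_init__(self) -> None:
        t = self.table
        if not (t["lower"] < t["upper"]).all():
            raise ConfigurationError("each lower bound must be below its upper bound")
        inside = (t["baseline"] >= t["lower"]) & (t["baseline"] <= t["upper"])
        if not inside.all():
            raise ConfigurationError("baselines must lie inside their ranges")

    @property
    def names(self) -> list:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)


def default_ranges(p: Optional[ModelParameters] = None,
                   spread: float = 1.25) -> ParameterRanges:
    """Ranges ``[baseline/spread, baseline*spread]`` around the model baseline
    for the 13 analyzed parameters."""
    from .model import PARAMETER_UNITS
    p = p or baseline_parameters()
    rows = {}
    for name in SENSITIVITY_PARAMETERS:
        b = getattr(p, name)
        rows[name] = {"lower": b / spread, "upper": b * spread,
                      "baseline": b, "unit": PARAMETER_UNITS[name][0]}
    return ParameterRanges(pd.DataFrame(rows).T)


def lhs_sample(ranges: ParameterRanges, n: int, seed: int = 0) -> pd.DataFrame:
    """Latin hypercube sample: one draw per equal-probability stratum of each
    parameter's ``[lower, upper]``, independently permuted across parameters."""
    if n < 2:
        raise ConfigurationError("need at least 2 samples")
    sampler = qmc.LatinHypercube(d=len(ranges), seed=int(seed))
    unit = sampler.random(n)
    lo = ranges.table["lower"].to_numpy(dtype=float)
    hi = ranges.table["upper"].to_numpy(dtype=float)
    return pd.DataFrame(qmc.scale(unit, lo, hi), columns=ranges.names)


# ---------------------------------------------------------------------------
# output functional
# ---------------------------------------------------------------------------

def _wellmixed_density(p: ModelParameters, eval_time: float, T0: float) -> float:
    """Tumor density of the diffusion-free system at eval_time."""
    from .synthetic import simulate_wellmixed
    frame = simulate_wellmixed(p, [eval_time], y0=[p.mu1 * T0 / p.d_I27, 0, 0, 0, T0],
                               rtol=1e-7, atol=1e-9)
    return float(frame[frame["species"] == "T"]["value"].iloc[0])


def tumor_ratio(p: ModelParameters, eval_time: float = 15.0, eval_radius: float = 0.0,
                mode: str = "wellmixed", T0: float = 5.0e7,
                grid_N: int = 100, R: float = 0.5,
                settings: Optional[SolverSettings] = None) -> float:
    """Treated/control tumor-density ratio at the evaluation point.

    Runs two matched simulations differing only in ``mu1`` (treated keeps
    ``p.mu1``; the control sets it to 0) and returns
    ``T_treated / T_control``.  ``mode="wellmixed"`` uses the diffusion-free
    surrogate (the default for large sample counts); ``mode="pde"`` evaluates
    the full radial model at ``(eval_time, eval_radius)``.
    """
    ctrl = p.with_(mu1=0.0)
    if mode == "wellmixed":
        t_treat = _wellmixed_density(p, eval_time, T0)
        t_ctrl = _wellmixed_density(ctrl, eval_time, T0)
    elif mode == "pde":
        grid = build_grid(R, grid_N)
        settings = settings or SolverSettings(output_times=[eval_time])
        i = int(np.argmin(np.abs(grid.r - eval_radius)))
        tr = simulate(p, grid, initial_state(grid, p, "transfected", T0=T0),
                      eval_time, settings)
        tc = simulate(ctrl, grid, initial_state(grid, ctrl, "wildtype", T0=T0),
                      eval_time, settings)
        t_treat = float(tr.data[-1, IDX["T"], i])
        t_ctrl = float(tc.data[-1, IDX["T"], i])
    else:
        raise ConfigurationError(f"unknown mode {mode!r}")
    if t_ctrl <= 0:
        raise ZeroDivisionError("control tumor density vanished at the evaluation point")
    return t_treat / t_ctrl


# ---------------------------------------------------------------------------
# PRCC
# ---------------------------------------------------------------------------

@dataclass
class SensitivityResult:
    """Per-parameter PRCC and p-value plus the run's provenance."""

    table: pd.DataFrame       # index: parameter; columns: prcc, p_value
    n_samples: int
    eval_time: float
    eval_radius: float
    seed: Optional[int] = None
    mode: str = "wellmixed"

    def prcc(self, name: str) -> float:
        return float(self.table.loc[name, "prcc"])

    def p_value(self, name: str) -> float:
        return float(self.table.loc[name, "p_value"])


def prcc(X, y, names=None, eval_time: float = np.nan,
         eval_radius: float = np.nan) -> SensitivityResult:
    """Partial rank correlation of each column of ``X`` with ``y``.

    All columns and ``y`` are rank-transformed (average ranks on ties); for
    each parameter the Pearson correlation of the residuals of its ranks and
    the output ranks after linear regression on all other ranked parameters
    is reported, with a p-value from ``t = r*sqrt((n-2-k)/(1-r^2))`` against
    Student's t with ``n-2-k`` degrees of freedom (k = number of adjusted
    covariates).
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k_all = X.shape
    if len(y) != n:
        raise ConfigurationError("X rows and y length differ")
    if n < k_all + 2:
        raise ConfigurationError("need at least p + 2 samples for PRCC")
    names = names or [f"x{j}" for j in range(k_all)]

    Xr = np.column_stack([stats.rankdata(X[:, j]) for j in range(k_all)])
    yr = stats.rankdata(y)
    rows = {}
    dof = n - 2 - (k_all - 1)
    for j, name in enumerate(names):
        if np.ptp(X[:, j]) == 0:
            raise ConfigurationError(f"parameter {name} is constant: PRCC undefined")
        others = np.delete(Xr, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        rx = Xr[:, j] - A @ np.linalg.lstsq(A, Xr[:, j], rcond=None)[0]
        ry = yr - A @ np.linalg.lstsq(A, yr, rcond=None)[0]
        r = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
        r = float(np.clip(r, -1.0, 1.0))
        if abs(r) >= 1.0:
            pv = 0.0
        else:
            t = r * np.sqrt(dof / (1.0 - r**2))
            pv = float(2.0 * stats.t.sf(abs(t), dof))
        rows[name] = {"prcc": r, "p_value": pv}
    return SensitivityResult(table=pd.DataFrame(rows).T, n_samples=n,
                             eval_time=eval_time, eval_radius=eval_radius)


def run_sensitivity(ranges: Optional[ParameterRanges] = None, n: int = 5000,
                    seed: int = 0, eval_time: float = 15.0,
                    eval_radius: float = 0.0, mode: str = "wellmixed",
                    base: Optional[ModelParameters] = None,
                    T0: float = 5.0e7) -> SensitivityResult:
    """LHS -> treated/control tumor ratio per sample -> PRCC.

    ``n = 5000`` is the full-fidelity default sample count; the well-mixed
    surrogate is the default output mode (use ``mode="pde"`` with small ``n``
    for the spatial functional).  Negative PRCC means the parameter promotes
    rejection of the IL-27-treated tumor.
    """
    base = base or baseline_parameters(mu1_case="large")
    ranges = ranges or default_ranges(base)
    X = lhs_sample(ranges, n, seed=seed)
    y = np.empty(n)
    for i in range(n):
        p_i = base.with_(**{name: float(X.iloc[i][name]) for name in ranges.names})
        y[i] = tumor_ratio(p_i, eval_time=eval_time, eval_radius=eval_radius,
                           mode=mode, T0=T0)
    res = prcc(X, y, eval_time=eval_time, eval_radius=eval_radius)
    res.seed = seed
    res.mode = mode
    return res
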