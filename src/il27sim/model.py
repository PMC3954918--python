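"""Core state/parameter model and pointwise reaction kinetics.

The model tracks five radially symmetric variables in a spherical tumor
microenvironment:

* ``I27`` -- IL-27 concentration (pg/cm^3), secreted by transfected tumor
  cells and/or delivered by injection;
* ``I10`` -- IL-10 concentration (pg/cm^3), produced by activated CD8+ T
  cells, production enhanced by IL-27;
* ``E``   -- activated CD8+ T-cell (CTL) density (cells/cm^3), activated by
  tumor antigen; IL-27 and IL-10 promote CTL survival;
* ``G``   -- IFN-gamma concentration (pg/cm^3), produced by CTLs, production
  inhibited by IL-27;
* ``T``   -- tumor-cell density (cells/cm^3), logistic proliferation, killed
  (indirectly) by IL-10 and IFN-gamma.

Every modulated interaction uses a Michaelis-Menten saturation with a single
half-saturation constant; unmodulated productions are mass-action.  The
non-diffusive right-hand side lives in :func:`reaction_rates`; the diffusion
operator and time integration live in :mod:`il27sim.solver`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Union

import numpy as np
import yaml

__all__ = [
    "SPECIES",
    "IDX",
    "ModelParameters",
    "ScaleSet",
    "DimensionlessParameters",
    "baseline_parameters",
    "MU1_LADDER",
    "reaction_rates",
    "nondimensionalize",
    "dimensionalize",
    "load_parameters",
    "save_parameters",
]

#: species order used throughout the package for stacked arrays
SPECIES = ("I27", "I10", "E", "G", "T")
IDX = {name: i for i, name in enumerate(SPECIES)}


class ConfigurationError(ValueError):
    """Invalid parameter, scale or grid configuration."""


class DomainError(ValueError):
    """Input outside the mathematical domain of an operation."""


@dataclass
class ModelParameters:
    """Dimensional rate/diffusion/saturation constants of the five-species model.

    Units: day, cm, pg/cm^3 for cytokines, cells/cm^3 for cells.  Defaults are
    the package baseline calibration (see docs/methods.md): a control tumor
    escapes immune pressure while IL-27-secreting tumors are progressively
    suppressed as ``mu1`` grows.
    """

    # -- diffusion / dispersion (cm^2/day)
    D_I27: float = 1.24e-2
    D_I10: float = 1.24e-2
    D_E: float = 8.64e-6
    D_G: float = 1.24e-2
    D_T: float = 8.64e-7
    # -- IL-27 equation
    mu1: float = 1.0e-6      # IL-27 production per tumor cell (pg/cell/day); 0 for J558-Ctrl
    d_I27: float = 1.38889   # IL-27 degradation (/day)
    # -- IL-10 equation
    lam1: float = 2.0e-5     # baseline IL-10 production per CTL (pg/cell/day)
    lam2: float = 4.0e-5     # max IL-27-enhanced IL-10 production per CTL (pg/cell/day)
    K_I27_10: float = 5.0    # IL-27 half-saturation in IL-10 enhancement (pg/cm^3)
    d_I10: float = 4.16      # IL-10 degradation (/day)
    # -- CD8+ T-cell equation
    lamE: float = 3.0e5      # max CTL activation rate by tumor antigen (cells/cm^3/day)
    K_T: float = 1.0e7       # tumor half-saturation for activation (cells/cm^3)
    K_E1: float = 400.0      # IL-27 half-saturation in CTL death-rate reduction (pg/cm^3)
    K_E2: float = 6.0        # IL-10 half-saturation in CTL death-rate reduction (pg/cm^3)
    d_E: float = 1.0         # CTL death rate (/day)
    # -- IFN-gamma equation
    lamG: float = 2.0e-5     # max IFN-gamma production per CTL (pg/cell/day)
    K_I27_G: float = 1000.0  # IL-27 half-saturation in IFN-gamma inhibition (pg/cm^3)
    d_G: float = 2.16        # IFN-gamma degradation (/day)
    # -- tumor equation
    lamT: float = 0.5466     # max tumor proliferation rate (/day)
    T_max: float = 1.0e9     # tumor carrying capacity (cells/cm^3)
    d_T: float = 0.34657359027997264  # tumor death rate (/day, half-life 2 days)
    eta1: float = 1.2        # max IL-10-mediated tumor kill rate (/day)
    K_kill10: float = 60.0   # IL-10 half-saturation in killing (pg/cm^3)
    eta2: float = 0.5        # max IFN-gamma-mediated kill rate (/day)
    K_killG: float = 20.0    # IFN-gamma half-saturation in killing (pg/cm^3)

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ConfigurationError(f"parameter {f.name} is not finite: {v!r}")
            if v < 0:
                raise ConfigurationError(f"parameter {f.name} must be nonnegative: {v!r}")
        for name in _STRICTLY_POSITIVE:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"parameter {name} must be strictly positive")

    def with_(self, **kwargs: float) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def as_dict(self) -> dict:
        return asdict(self)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])


_STRICTLY_POSITIVE = (
    "D_I27", "D_I10", "D_E", "D_G", "D_T",
    "d_I27", "d_I10", "d_E", "d_G", "d_T",
    "K_I27_10", "K_T", "K_E1", "K_E2", "K_I27_G", "K_kill10", "K_killG",
    "T_max",
)

#: unit bookkeeping: field -> (unit string, numerator species or None, denominator species or None)
#: The species tags drive nondimensionalization: a per-cell production rate
#: ``pg/cell/day`` producing cytokine X from cell Y scales by t_s * C_Y / C_X.
PARAMETER_UNITS = {
    "D_I27": ("cm^2/day", None, None), "D_I10": ("cm^2/day", None, None),
    "D_E": ("cm^2/day", None, None), "D_G": ("cm^2/day", None, None),
    "D_T": ("cm^2/day", None, None),
    "mu1": ("pg/cell/day", "T", "I27"),
    "d_I27": ("/day", None, None),
    "lam1": ("pg/cell/day", "E", "I10"),
    "lam2": ("pg/cell/day", "E", "I10"),
    "K_I27_10": ("pg/cm^3", None, "I27"),
    "d_I10": ("/day", None, None),
    "lamE": ("cell/cm^3/day", None, "E"),
    "K_T": ("cell/cm^3", None, "T"),
    "K_E1": ("pg/cm^3", None, "I27"),
    "K_E2": ("pg/cm^3", None, "I10"),
    "d_E": ("/day", None, None),
    "lamG": ("pg/cell/day", "E", "G"),
    "K_I27_G": ("pg/cm^3", None, "I27"),
    "d_G": ("/day", None, None),
    "lamT": ("/day", None, None),
    "T_max": ("cell/cm^3", None, "T"),
    "d_T": ("/day", None, None),
    "eta1": ("/day", None, None),
    "K_kill10": ("pg/cm^3", None, "I10"),
    "eta2": ("/day", None, None),
    "K_killG": ("pg/cm^3", None, "G"),
}

#: free-text annotation mapping canonical names to the glyphs used in the
#: field's literature for this network (subscripts spelled out).
PAPER_SYMBOLS = {
    "D_I27": "delta_I27", "mu1": "mu_1", "d_I27": "d_I27",
    "D_I10": "delta_I10", "lam1": "lambda_1", "lam2": "lambda_2",
    "K_I27_10": "K_1", "d_I10": "d_I10",
    "D_E": "delta_E", "lamE": "lambda_E", "K_T": "K_T",
    "K_E1": "K_E1", "K_E2": "K_E2", "d_E": "d_E",
    "D_G": "delta_G", "lamG": "lambda_G", "K_I27_G": "K_2", "d_G": "d_G",
    "D_T": "delta_T", "lamT": "lambda_T", "T_max": "T_max", "d_T": "d_T",
    "eta1": "eta_1", "K_kill10": "K_3", "eta2": "eta_2", "K_killG": "K_4",
}

#: the four IL-27 production cases: control plus small/moderate/large
#: transfected-tumor secretion (pg/cell/day)
MU1_LADDER = {
    "control": 0.0,
    "small": 2.5e-7,
    "moderate": 1.0e-6,
    "large": 4.0e-6,
}


def baseline_parameters(scenario: str = "transfected", mu1_case: str = "moderate") -> ModelParameters:
    """Baseline parameter set.

    ``scenario="transfected"`` gives a J558-IL-27-like tumor secreting IL-27
    at the ``mu1_case`` rate of :data:`MU1_LADDER`; ``scenario="wildtype"``
    sets ``mu1 = 0`` (tumor cells do not secrete IL-27; any IL-27 must come
    from injection).
    """
    p = ModelParameters()
    if scenario == "wildtype":
        return p.with_(mu1=0.0)
    if scenario == "transfected":
        return p.with_(mu1=MU1_LADDER[mu1_case])
    raise ConfigurationError(f"unknown scenario {scenario!r}")


# ---------------------------------------------------------------------------
# reaction kinetics
# ---------------------------------------------------------------------------

def reaction_rates(u: np.ndarray, p: ModelParameters, f_inj: Union[float, np.ndarray] = 0.0,
                   check: bool = True) -> np.ndarray:
    """Pointwise non-diffusive right-hand side of the five-species system.

    Parameters
    ----------
    u
        State, shape ``(5,)`` or ``(5, n)`` in :data:`SPECIES` order.
    p
        Model parameters.
    f_inj
        IL-27 injection source rate (pg/cm^3/day), scalar or per-point.
    check
        Validate nonnegativity of the inputs (disable inside inner solver
        loops where the integrator may probe slightly negative states).

    Returns
    -------
    numpy.ndarray
        Time derivatives, same shape as ``u``.
    """
    u = np.asarray(u, dtype=float)
    if u.shape[0] != 5:
        raise DomainError(f"state must have 5 species as leading axis, got shape {u.shape}")
    if check:
        if np.any(u < 0):
            raise DomainError("state components must be nonnegative")
        if np.any(np.asarray(f_inj) < 0):
            raise DomainError("injection rate must be nonnegative")

    I27, I10, E, G, T = u
    out = np.empty_like(u)
    out[IDX["I27"]] = p.mu1 * T - p.d_I27 * I27 + f_inj
    out[IDX["I10"]] = (p.lam1 * E
                       + p.lam2 * E * I27 / (p.K_I27_10 + I27)
                       - p.d_I10 * I10)
    out[IDX["E"]] = (p.lamE * T / (p.K_T + T)
                     - p.d_E * E / (1.0 + I27 / p.K_E1 + I10 / p.K_E2))
    out[IDX["G"]] = p.lamG * E * p.K_I27_G / (p.K_I27_G + I27) - p.d_G * G
    out[IDX["T"]] = (p.lamT * T * (1.0 - T / p.T_max)
                     - p.d_T * T
                     - p.eta1 * T * I10 / (p.K_kill10 + I10)
                     - p.eta2 * T * G / (p.K_killG + G))
    return out


# ---------------------------------------------------------------------------
# nondimensionalization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScaleSet:
    """Characteristic scales: time (day), length (cm), one reference
    concentration per species (pg/cm^3 or cells/cm^3)."""

    time: float = 1.0
    length: float = 0.5
    I27: float = 400.0
    I10: float = 60.0
    E: float = 1.0e9
    G: float = 20.0
    T: float = 1.0e9

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0 or not np.isfinite(getattr(self, f.name)):
                raise ConfigurationError(f"scale {f.name} must be strictly positive and finite")

    def concentration(self, species: str) -> float:
        return getattr(self, species)


def default_scales(p: ModelParameters, R: float = 0.5) -> ScaleSet:
    """Scales under which /day rates keep their numerical values: 1 day, the
    domain radius, carrying capacity for cell densities and each cytokine's
    survival/killing half-saturation for concentrations."""
    return ScaleSet(time=1.0, length=R, I27=p.K_E1, I10=p.K_kill10,
                    E=p.T_max, G=p.K_killG, T=p.T_max)


@dataclass
class DimensionlessParameters:
    """Dimensionless image of a :class:`ModelParameters`; round-trips exactly
    with the generating :class:`ScaleSet`."""

    values: dict

    def __getattr__(self, name: str) -> float:
        try:
            return self.values[name]
        except KeyError as e:  # pragma: no cover
            raise AttributeError(name) from e


def _scale_factor(name: str, s: ScaleSet) -> float:
    """Multiplicative factor taking the dimensional parameter to its
    dimensionless value, from the unit registry."""
    unit, num_species, den_species = PARAMETER_UNITS[name]
    if unit == "/day":
        return s.time
    if unit == "cm^2/day":
        return s.time / s.length**2
    if unit in ("pg/cm^3", "cell/cm^3"):
        return 1.0 / s.concentration(den_species)
    if unit == "pg/cell/day":
        # per-cell production of cytokine `den` by cell `num`
        return s.time * s.concentration(num_species) / s.concentration(den_species)
    if unit == "cell/cm^3/day":
        return s.time / s.concentration(den_species)
    raise ConfigurationError(f"no scaling rule for unit {unit!r}")  # pragma: no cover


def nondimensionalize(p: ModelParameters, s: ScaleSet) -> DimensionlessParameters:
    """Rescale every parameter by its units under the scale set ``s``."""
    return DimensionlessParameters(
        {f.name: getattr(p, f.name) * _scale_factor(f.name, s) for f in fields(p)}
    )


def dimensionalize(dp: DimensionlessParameters, s: ScaleSet) -> ModelParameters:
    """Exact inverse of :func:`nondimensionalize`."""
    return ModelParameters(
        **{name: v / _scale_factor(name, s) for name, v in dp.values.items()}
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_parameters(p: ModelParameters, path: Union[str, Path]) -> None:
    """Write parameters to JSON or YAML (by extension), annotated with units
    and the canonical-name <-> symbol map."""
    path = Path(path)
    payload = {
        name: {"value": float(getattr(p, name)),
               "unit": PARAMETER_UNITS[name][0],
               "paper_symbol": PAPER_SYMBOLS[name]}
        for name in (f.name for f in fields(p))
    }
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2))


def load_parameters(path: Union[str, Path]) -> ModelParameters:
    """Read parameters written by :func:`save_parameters` (values may also be
    bare numbers)."""
    path = Path(path)
    raw = (yaml.safe_load(path.read_text()) if path.suffix in (".yaml", ".yml")
           else json.loads(path.read_text()))
    values = {k: (v["value"] if isinstance(v, dict) else float(v)) for k, v in raw.items()}
    return ModelParameters(**values)
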