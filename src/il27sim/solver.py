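"""Radially symmetric finite-volume discretization and method-of-lines solver.

The tumor grows in a ball of radius ``R``; all variables are radially
symmetric, so each species lives on a 1-D radial grid.  Diffusion is
discretized with conservative finite-volume shells: the flux through each
spherical face telescopes, so with the no-flux boundary (zero normal
derivative at ``r=R``, symmetry at ``r=0``) the scheme conserves the total
amount of each species exactly, up to time-integration error.  The reaction
terms are evaluated pointwise by :func:`il27sim.model.reaction_rates` and the
coupled ODE system is integrated with a stiff adaptive scheme (BDF) using an
analytic sparsity pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.sparse import lil_matrix

from .model import (IDX, SPECIES, ConfigurationError, DomainError,
                    ModelParameters, reaction_rates)

__all__ = [
    "RadialGrid", "Fields", "SolverSettings", "Trajectory",
    "build_grid", "radial_laplacian", "initial_state", "simulate",
    "total_amount", "SolverError", "PositivityError",
]


class SolverError(RuntimeError):
    """Time integrator failed."""


class PositivityError(RuntimeError):
    """A field undershot below the positivity tolerance."""


@dataclass(frozen=True)
class RadialGrid:
    """Uniform radial grid on ``[0, R]`` with finite-volume shell weights.

    Nodes ``r_i = i*h`` for ``i = 0..N`` (``N+1`` nodes, ``h = R/N``).  The
    control volume of node ``i`` spans the spherical shell between faces at
    ``(i-1/2)h`` and ``(i+1/2)h`` (clipped to ``[0, R]``); shell volumes sum
    to the ball volume exactly.
    """

    R: float
    N: int
    r: np.ndarray = field(repr=False)
    faces: np.ndarray = field(repr=False)
    shell_volumes: np.ndarray = field(repr=False)
    face_areas: np.ndarray = field(repr=False)

    @property
    def h(self) -> float:
        return self.R / self.N

    @property
    def n_nodes(self) -> int:
        return self.N + 1


def build_grid(R: float, N: int) -> RadialGrid:
    """Build a uniform finite-volume radial grid of ``N`` intervals on ``[0, R]``."""
    if R <= 0:
        raise ConfigurationError("domain radius R must be positive")
    if N < 8:
        raise ConfigurationError(f"need at least 8 intervals, got N={N}")
    h = R / N
    r = np.linspace(0.0, R, N + 1)
    # interior faces between consecutive nodes, plus the two boundary "faces"
    faces = np.concatenate(([0.0], (r[:-1] + r[1:]) / 2.0, [R]))
    shell_volumes = (4.0 * np.pi / 3.0) * np.diff(faces**3)
    # areas of the N interior faces (where diffusive flux is exchanged)
    face_areas = 4.0 * np.pi * faces[1:-1] ** 2
    return RadialGrid(R=float(R), N=int(N), r=r, faces=faces,
                      shell_volumes=shell_volumes, face_areas=face_areas)


def radial_laplacian(f: np.ndarray, grid: RadialGrid) -> np.ndarray:
    """Conservative spherical Laplacian of a field with no-flux boundaries.

    Works on shape ``(n_nodes,)`` or ``(k, n_nodes)`` (per-species batch).
    """
    f = np.asarray(f, dtype=float)
    if f.shape[-1] != grid.n_nodes:
        raise DomainError(f"field length {f.shape[-1]} != grid nodes {grid.n_nodes}")
    flux = grid.face_areas * np.diff(f, axis=-1) / grid.h  # A * df/dr at interior faces
    out = np.zeros_like(f)
    out[..., 0] = flux[..., 0]
    out[..., 1:-1] = np.diff(flux, axis=-1)
    out[..., -1] = -flux[..., -1]
    return out / grid.shell_volumes


def total_amount(f: np.ndarray, grid: RadialGrid) -> float:
    """Shell-volume quadrature ``4*pi*int f r^2 dr`` of a field (pg or cells)."""
    f = np.asarray(f, dtype=float)
    if f.shape[-1] != grid.n_nodes:
        raise DomainError(f"field length {f.shape[-1]} != grid nodes {grid.n_nodes}")
    return f @ grid.shell_volumes


@dataclass
class Fields:
    """The five concentration profiles on a radial grid at one time."""

    data: np.ndarray  # shape (5, n_nodes), SPECIES order
    time: float = 0.0

    def __getitem__(self, species: str) -> np.ndarray:
        return self.data[IDX[species]]

    def copy(self) -> "Fields":
        return Fields(self.data.copy(), self.time)


def smooth_bump(r: np.ndarray, eps: float) -> np.ndarray:
    """C-infinity compactly supported bump: 1 at r=0, 0 for r >= eps."""
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    inside = r < eps
    x = r[inside] / eps
    out[inside] = np.exp(-x**2 / (1.0 - x**2))
    return out


def initial_state(grid: RadialGrid, p: ModelParameters, scenario: str = "transfected",
                  eps: float = 0.25, T0: float = 2.0e8) -> Fields:
    """Initial profiles: tumor cells concentrated in a smooth bump of width
    ``eps`` and amplitude ``T0`` at the origin; no activated CTLs, hence no
    IL-10 or IFN-gamma; IL-27 mirrors the tumor profile at its local
    production/degradation balance for a transfected tumor, and is zero for a
    wildtype (non-secreting) tumor."""
    if not 0 < eps <= grid.R:
        raise ConfigurationError(f"bump width eps={eps} must lie in (0, R]")
    if scenario not in ("transfected", "wildtype"):
        raise ConfigurationError(f"unknown scenario {scenario!r}")
    data = np.zeros((5, grid.n_nodes))
    T = T0 * smooth_bump(grid.r, eps)
    data[IDX["T"]] = T
    if scenario == "transfected":
        data[IDX["I27"]] = (p.mu1 / p.d_I27) * T
    return Fields(data=data, time=0.0)


@dataclass
class SolverSettings:
    """Integration tolerances and output schedule."""

    rtol: float = 1.0e-6
    atol: float = 1.0e-9           # relative to per-species characteristic scales
    max_step: float = np.inf
    positivity_tol: float = 1.0e-6  # allowed undershoot, relative to species scale
    output_times: Optional[Sequence[float]] = None
    method: str = "BDF"

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0 or self.positivity_tol <= 0:
            raise ConfigurationError("tolerances must be positive")


def species_scales(p: ModelParameters) -> np.ndarray:
    """Characteristic magnitude per species, used for absolute tolerances and
    positivity thresholds."""
    return np.array([
        max(p.K_E1, p.K_I27_10),      # I27
        max(p.K_kill10, p.K_E2),      # I10
        max(p.lamE / p.d_E, 1.0),     # E
        p.K_killG,                    # G
        p.T_max,                      # T
    ])


@dataclass
class Trajectory:
    """Ordered snapshots of the five fields plus per-time species totals."""

    times: np.ndarray            # (n_times,)
    data: np.ndarray             # (n_times, 5, n_nodes)
    grid: RadialGrid
    totals: np.ndarray           # (n_times, 5) shell-quadrature totals

    def field_at(self, t: float) -> Fields:
        i = int(np.argmin(np.abs(self.times - t)))
        return Fields(self.data[i], float(self.times[i]))

    def total(self, species: str) -> np.ndarray:
        return self.totals[:, IDX[species]]


def _sparsity(n_nodes: int) -> lil_matrix:
    """Jacobian sparsity: diffusion couples radial neighbors within a species,
    reactions couple all species at a node."""
    n = 5 * n_nodes
    S = lil_matrix((n, n), dtype=np.int8)
    for s in range(5):
        base = s * n_nodes
        for i in range(n_nodes):
            S[base + i, base + i] = 1
            if i > 0:
                S[base + i, base + i - 1] = 1
            if i < n_nodes - 1:
                S[base + i, base + i + 1] = 1
    for i in range(n_nodes):
        for s1 in range(5):
            for s2 in range(5):
                S[s1 * n_nodes + i, s2 * n_nodes + i] = 1
    return S


def simulate(p: ModelParameters, grid: RadialGrid, init: Fields, t_end: float,
             settings: Optional[SolverSettings] = None, protocol=None) -> Trajectory:
    """Integrate the full reaction-diffusion system by the method of lines.

    Parameters
    ----------
    protocol
        Optional injection protocol (see :mod:`il27sim.protocols`) providing
        ``rate(r, t)`` (IL-27 source, pg/cm^3/day) and ``switch_times(t_end)``
        (on/off discontinuities; integration restarts there so the stiff
        integrator never steps across a jump).
    """
    if t_end <= 0:
        raise ConfigurationError("t_end must be positive")
    if init.data.shape != (5, grid.n_nodes):
        raise DomainError("initial fields do not match grid")
    settings = settings or SolverSettings()

    scales = species_scales(p)
    atol = np.repeat(settings.atol * scales, grid.n_nodes)
    D = np.array([p.D_I27, p.D_I10, p.D_E, p.D_G, p.D_T])[:, None]

    if settings.output_times is not None:
        t_out = np.asarray(sorted(settings.output_times), dtype=float)
    else:
        t_out = np.linspace(0.0, t_end, 151)
    if t_out[0] > 0.0:
        t_out = np.concatenate(([0.0], t_out))

    if protocol is not None:
        inj_profile = protocol.spatial_profile(grid.r, grid.R)
        switch = [t for t in protocol.switch_times(t_end) if 0.0 < t < t_end]
    else:
        inj_profile = None
        switch = []

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        u = y.reshape(5, grid.n_nodes)
        f_inj = 0.0
        if inj_profile is not None:
            f_inj = protocol.amplitude(t) * inj_profile
        du = reaction_rates(u, p, f_inj=f_inj, check=False)
        du += D * radial_laplacian(u, grid)
        return du.ravel()

    sparsity = _sparsity(grid.n_nodes)
    seg_bounds = np.concatenate(([0.0], np.asarray(switch, dtype=float), [t_end]))

    times = [0.0]
    snaps = [init.data.copy()]
    y0 = init.data.ravel().copy()
    for a, b in zip(seg_bounds[:-1], seg_bounds[1:]):
        te = t_out[(t_out > a + 1e-12) & (t_out <= b + 1e-12)]
        te_full = np.unique(np.concatenate((te, [b])))
        sol = solve_ivp(rhs, (a, b), y0, method=settings.method, t_eval=te_full,
                        rtol=settings.rtol, atol=atol, max_step=settings.max_step,
                        jac_sparsity=sparsity)
        if not sol.success:
            raise SolverError(f"integrator failed on [{a}, {b}]: {sol.message}")
        for tk, yk in zip(sol.t, sol.y.T):
            if np.any(np.isclose(tk, t_out, rtol=0, atol=1e-9)):
                times.append(float(tk))
                snaps.append(yk.reshape(5, grid.n_nodes).copy())
        y0 = sol.y[:, -1]

    data = np.array(snaps)
    undershoot = data.min(axis=(0, 2))
    bad = undershoot < -settings.positivity_tol * scales
    if np.any(bad):
        names = [SPECIES[i] for i in np.where(bad)[0]]
        raise PositivityError(
            f"species {names} undershot beyond positivity tolerance: min={undershoot[bad]}")
    data = np.clip(data, 0.0, None)

    if data[:, IDX["T"], -1].max() > 1e-6 * p.T_max:
        warnings.warn(
            "tumor density at the outer boundary exceeds 1e-6 * T_max; "
            "increase the domain radius R for a containment-safe run",
            stacklevel=2)

    totals = data @ grid.shell_volumes
    return Trajectory(times=np.array(times), data=data, grid=grid, totals=totals)
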