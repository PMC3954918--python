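"""Tidy CSV/JSON export and run manifests.

Every artifact a run writes can be regenerated bit-identically from its
manifest (config + seed + package version); the manifest also records the
full parameter set actually used, including the canonical-name <-> symbol
map, so a reader can trace every constant.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .model import PAPER_SYMBOLS, PARAMETER_UNITS, ModelParameters, SPECIES
from .sensitivity import SensitivityResult
from .solver import Trajectory

__all__ = ["trajectory_frame", "totals_frame", "write_trajectory",
           "write_sensitivity", "run_manifest", "parameter_hash"]


def trajectory_frame(traj: Trajectory) -> pd.DataFrame:
    """Long-format snapshot table: time_day, r_cm, species, value."""
    n_t, _, n_r = traj.data.shape
    rows = {
        "time_day": np.repeat(traj.times, 5 * n_r),
        "r_cm": np.tile(np.tile(traj.grid.r, 5), n_t),
        "species": np.tile(np.repeat(list(SPECIES), n_r), n_t),
        "value": traj.data.reshape(-1),
    }
    return pd.DataFrame(rows)


def totals_frame(traj: Trajectory) -> pd.DataFrame:
    """Per-time species totals (pg or cells in the whole ball)."""
    frames = [pd.DataFrame({"time_day": traj.times, "species": sp,
                            "total": traj.totals[:, i]})
              for i, sp in enumerate(SPECIES)]
    return pd.concat(frames, ignore_index=True)


def parameter_hash(p: ModelParameters) -> str:
    payload = json.dumps(p.as_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_manifest(p: ModelParameters, seed: Optional[int] = None,
                 config: Optional[dict] = None) -> dict:
    """JSON-serializable provenance record for a run."""
    return {
        "package_version": __version__,
        "parameter_hash": parameter_hash(p),
        "seed": seed,
        "config": config or {},
        "parameters": {
            name: {"value": v, "unit": PARAMETER_UNITS[name][0],
                   "paper_symbol": PAPER_SYMBOLS[name]}
            for name, v in p.as_dict().items()
        },
    }


def write_trajectory(traj: Trajectory, outdir: Union[str, Path], stem: str,
                     p: ModelParameters, seed: Optional[int] = None,
                     config: Optional[dict] = None,
                     snapshot_times: Optional[list] = None) -> dict:
    """Write <stem>_totals.csv, <stem>_fields.csv (optionally restricted to
    snapshot times) and <stem>_manifest.json; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    totals_frame(traj).to_csv(outdir / f"{stem}_totals.csv", index=False)
    frame = trajectory_frame(traj)
    if snapshot_times is not None:
        keep = np.zeros(len(frame), dtype=bool)
        for t in snapshot_times:
            keep |= np.isclose(frame["time_day"], t)
        frame = frame[keep]
    frame.to_csv(outdir / f"{stem}_fields.csv", index=False)
    manifest = run_manifest(p, seed=seed, config=config)
    (outdir / f"{stem}_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def write_sensitivity(res: SensitivityResult, outdir: Union[str, Path],
                      stem: str = "sensitivity") -> None:
    """Write the PRCC table as CSV plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = res.table.rename_axis("parameter").reset_index()
    table.to_csv(outdir / f"{stem}.csv", index=False)
    meta = {"n_samples": res.n_samples, "eval_time": res.eval_time,
            "eval_radius": res.eval_radius, "seed": res.seed, "mode": res.mode,
            "package_version": __version__}
    (outdir / f"{stem}_manifest.json").write_text(json.dumps(meta, indent=2))
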