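"""Tabular reports and reproducible run manifests (TSV + JSON)."""

from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .model import DimerSpec, diagonalize_dimer, eigen_transition_dipoles, vibrational_character

__all__ = ["eigen_report", "write_tsv", "write_manifest", "signal_frame"]


def eigen_report(dimer: DimerSpec) -> pd.DataFrame:
    """Single-realization eigenstate report.

    One row per eigenstate: energy (absolute and relative to the lowest
    state), |c|^2 composition over the one-particle basis, squared dipole
    length, and chi with respect to every other state.
    """
    eig = diagonalize_dimer(dimer)
    dip = eigen_transition_dipoles(eig, dimer)
    rows = []
    for a in range(eig.n_states):
        row: dict[str, float] = {
            "state": a + 1,
            "energy_cm": float(eig.energies[a]),
            "energy_rel_cm": float(eig.energies[a] - eig.energies[0]),
            "dipole_sq": dip.length(a, 0) ** 2,
        }
        for i, b in enumerate(eig.basis):
            row[f"w({b.label})"] = float(eig.coefficients[i, a] ** 2)
        for b2 in range(eig.n_states):
            if b2 != a:
                row[f"chi_{a + 1}{b2 + 1}"] = vibrational_character(eig, a, b2)
        rows.append(row)
    return pd.DataFrame(rows)


def signal_frame(omega1: np.ndarray, t2: np.ndarray, amplitude: np.ndarray) -> pd.DataFrame:
    """|S(omega1, t2)| as a tidy frame (omega1 rows, t2 columns in fs)."""
    return pd.DataFrame(
        np.abs(amplitude), index=pd.Index(omega1, name="omega1_cm"),
        columns=[f"{t:.0f}" for t in t2],
    )


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")
    return path


def _grid_hash(cfg: RunConfig) -> str:
    g = cfg.grids
    payload = np.concatenate([g.omega1, g.t1, g.t2]).tobytes()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_manifest(cfg: RunConfig, outdir: str | Path, outputs: list[str]) -> Path:
    """JSON manifest: config snapshot, seeds, grid hash, version, timestamp."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": cfg.as_dict(),
        "applied_defaults": list(cfg.applied_defaults),
        "seed": cfg.disorder.seed,
        "grid_hash": _grid_hash(cfg),
        "version": __version__,
        "python": platform.python_version(),
        "written_utc": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "outputs": outputs,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
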