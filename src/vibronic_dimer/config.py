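"""YAML run configuration with validated, documented defaults."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import reference
from .bath import BathSpec
from .disorder import DisorderSpec
from .model import DimerSpec

__all__ = ["GridSpec", "RunConfig", "load_config", "save_config"]

_MODEL_KEYS = {
    "site_energy", "gap", "coupling", "mode_frequency", "huang_rhys",
    "dipole_angle", "n_quanta",
}
_BATH_KEYS = {"debye_frequency", "reorganization_energy", "temperature", "n_matsubara"}
_DISORDER_KEYS = {"center", "fwhm", "n_samples", "seed"}
_GRID_KEYS = {
    "omega1_min", "omega1_max", "omega1_step", "t1_max", "t1_step",
    "t2_max", "t2_step",
}

_RANGES = {
    "site_energy": (1000.0, 50000.0),
    "gap": (-1000.0, 1000.0),
    "coupling": (-1000.0, 1000.0),
    "mode_frequency": (1.0, 5000.0),
    "huang_rhys": (0.0, 10.0),
    "dipole_angle": (0.0, 180.0),
    "debye_frequency": (1.0, 5000.0),
    "reorganization_energy": (0.1, 5000.0),
    "temperature": (0.1, 1000.0),
    "fwhm": (0.1, 2000.0),
}


@dataclass(frozen=True)
class GridSpec:
    """Evaluation grids: excitation frequency (cm^-1) and delay times (fs)."""

    omega1_min: float = 11900.0
    omega1_max: float = 12650.0
    omega1_step: float = 3.0
    t1_max: float = 2000.0
    t1_step: float = 4.0
    t2_max: float = 2000.0
    t2_step: float = 10.0

    @property
    def omega1(self) -> np.ndarray:
        return np.arange(self.omega1_min, self.omega1_max, self.omega1_step)

    @property
    def t1(self) -> np.ndarray:
        return np.arange(0.0, self.t1_max + 1e-9, self.t1_step)

    @property
    def t2(self) -> np.ndarray:
        return np.arange(0.0, self.t2_max + 1e-9, self.t2_step)


@dataclass(frozen=True)
class RunConfig:
    dimer: DimerSpec
    bath: BathSpec
    disorder: DisorderSpec
    grids: GridSpec
    outdir: Path = Path("out")
    applied_defaults: tuple[str, ...] = field(default=(), compare=False)

    def as_dict(self) -> dict:
        d = self.dimer
        return {
            "model": {
                "site_energy": d.monomer1.site_energy,
                "gap": d.gap,
                "coupling": d.coupling,
                "mode_frequency": d.monomer1.mode.frequency,
                "huang_rhys": d.monomer1.mode.huang_rhys,
                "dipole_angle": d.dipole_angle,
                "n_quanta": d.monomer1.mode.n_quanta,
            },
            "bath": dataclasses.asdict(self.bath),
            "disorder": dataclasses.asdict(self.disorder),
            "grids": dataclasses.asdict(self.grids),
            "outdir": str(self.outdir),
        }


def _check_block(name: str, block: dict, allowed: set[str]) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config block {name!r}; "
            f"allowed: {sorted(allowed)}"
        )
    for k, v in block.items():
        if k in _RANGES:
            lo, hi = _RANGES[k]
            if not lo <= float(v) <= hi:
                raise ValueError(f"{name}.{k} = {v} outside the valid range [{lo}, {hi}]")


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML config; missing keys fall back to the reference defaults.

    An empty (or absent) file yields the full reference parameterization:
    J = -53.5, gap = 110, omega0 = 117, S = 0.05, Lambda = 130, lambda = 35,
    T = 77 K, disorder FWHM = 80 (all energies cm^-1).  Every silently
    applied default is recorded in ``applied_defaults``.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError("config root must be a mapping")
    unknown = set(raw) - {"model", "bath", "disorder", "grids", "outdir"}
    if unknown:
        raise ValueError(f"unknown config block(s): {sorted(unknown)}")

    model = dict(raw.get("model") or {})
    bathb = dict(raw.get("bath") or {})
    disb = dict(raw.get("disorder") or {})
    gridb = dict(raw.get("grids") or {})
    _check_block("model", model, _MODEL_KEYS)
    _check_block("bath", bathb, _BATH_KEYS)
    _check_block("disorder", disb, _DISORDER_KEYS)
    _check_block("grids", gridb, _GRID_KEYS)

    defaults_model = {
        "site_energy": reference.SITE_ENERGY,
        "gap": reference.GAP_DE0,
        "coupling": reference.COUPLING_J0,
        "mode_frequency": reference.MODE_FREQUENCY,
        "huang_rhys": reference.HUANG_RHYS,
        "dipole_angle": reference.DIPOLE_VECTOR_ANGLE,
        "n_quanta": 1,
    }
    applied = []
    for block_name, block, defaults in (
        ("model", model, defaults_model),
        ("bath", bathb, dataclasses.asdict(BathSpec())),
        ("disorder", disb, dataclasses.asdict(DisorderSpec())),
        ("grids", gridb, dataclasses.asdict(GridSpec())),
    ):
        for k, v in defaults.items():
            if k not in block:
                block[k] = v
                applied.append(f"{block_name}.{k}={v}")

    dimer = DimerSpec.from_parameters(**model)
    return RunConfig(
        dimer=dimer,
        bath=BathSpec(**bathb),
        disorder=DisorderSpec(**disb),
        grids=GridSpec(**gridb),
        outdir=Path(raw.get("outdir", "out")),
        applied_defaults=tuple(applied),
    )


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.as_dict(), sort_keys=False))
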