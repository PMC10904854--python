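"""Orientation-averaged projection-approximation collision cross section.

The PA estimate of an ion-mobility CCS is the mean shadow area of the molecule
over uniformly random orientations: each atom projects to a disk of radius
(r_atom + probe) on the viewing plane and the union area of the disks is the
shadow.  Union areas are estimated by uniform Monte-Carlo sampling over the
disks' bounding box.  Absolute agreement with drift-gas experiments requires a
linear calibration (``calibrate_ccs``); uncalibrated values are meaningful for
ordering ensembles by compaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensembles import ConformerEnsemble, Selection, select
from .geometry import random_rotation


@dataclass(frozen=True)
class CCSSettings:
    probe_radius: float = 1.0  # Å
    n_orientations: int = 300
    n_area_samples: int = 4096
    tolerance: float = 1.0  # Å² standard error for early stop
    min_orientations: int = 32


@dataclass(frozen=True)
class CCSResult:
    ccs: float  # Å²
    standard_error: float
    n_orientations: int
    probe_radius: float
    calibration: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self):
        if self.ccs <= 0 or self.standard_error < 0:
            raise ValueError("invalid CCS result")


def pa_ccs(
    coords: np.ndarray,
    radii: np.ndarray,
    settings: CCSSettings = CCSSettings(),
    seed: int = 0,
) -> CCSResult:
    """Projection-approximation CCS of one conformation.

    Orientations are quaternion-uniform random rotations from a seeded
    generator; iteration stops early once the running standard error over
    orientations drops below ``settings.tolerance`` (after a minimum number of
    orientations).
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or len(coords) < 1:
        raise ValueError("need at least one atom")
    if (radii <= 0).any():
        raise ValueError("radii must be positive")
    disk_r = radii + settings.probe_radius
    rng = np.random.default_rng(seed)
    areas = []
    for k in range(settings.n_orientations):
        rot = random_rotation(rng)
        xy = (coords @ rot.T)[:, :2]
        lo = (xy - disk_r[:, None]).min(axis=0)
        hi = (xy + disk_r[:, None]).max(axis=0)
        span = hi - lo
        pts = lo + rng.random((settings.n_area_samples, 2)) * span
        d2 = ((pts[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
        inside = (d2 <= disk_r**2).any(axis=1)
        areas.append(span[0] * span[1] * inside.mean())
        if k + 1 >= settings.min_orientations:
            se = np.std(areas, ddof=1) / np.sqrt(k + 1)
            if se < settings.tolerance:
                break
    areas = np.asarray(areas)
    n = len(areas)
    se = float(np.std(areas, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return CCSResult(float(areas.mean()), se, n, settings.probe_radius)


def ensemble_ccs(
    ens: ConformerEnsemble,
    sel: Selection | None = None,
    settings: CCSSettings = CCSSettings(),
    radii: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[list[CCSResult], dict]:
    """Per-frame PA CCS plus an ensemble summary (mean, SD over frames)."""
    if sel is not None:
        ens = select(ens, sel)
    if radii is None:
        radii = ens.gb_radius
    results = [
        pa_ccs(ens.frames[f], radii, settings, seed=seed + f) for f in range(ens.n_frames)
    ]
    vals = np.array([r.ccs for r in results])
    return results, {"mean": float(vals.mean()), "sd": float(vals.std()), "n_frames": len(vals)}


def calibrate_ccs(ccs: float, scale: float = 1.0, offset: float = 0.0) -> float:
    """Linear PA-to-experiment calibration (identity by default)."""
    return scale * ccs + offset


def ccs_to_tsv(results: list[CCSResult], path) -> None:
    pd.DataFrame(
        {
            "frame": range(len(results)),
            "ccs": [r.ccs for r in results],
            "se": [r.standard_error for r in results],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.3f")
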