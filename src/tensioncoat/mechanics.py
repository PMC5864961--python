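"""Compression mechanics of coated and uncoated reticulated scaffolds.

Converts Instron-style force-displacement records into stress-strain curves
(sigma = F/SA in MPa given N and mm^2; epsilon = dL/L0), fits the effective
compressive modulus K as the slope of the ordinary least-squares line over
the first 0.5 mm of displacement, and detects buckling as the first local
stress maximum followed by a significant drop.  Displacement and force are
positive in compression.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CompressionRecord",
    "StressStrainCurve",
    "ModulusEstimate",
    "BucklingEstimate",
    "to_stress_strain",
    "effective_modulus",
    "detect_buckling",
    "load_record",
    "save_record",
]


@dataclass
class CompressionRecord:
    """One uniaxial compression test.

    ``displacement`` in mm (starting at 0, strictly increasing), ``force``
    in N, ``cross_section_area`` (SA) in mm^2 and ``initial_length`` (L0)
    in mm of the test geometry.  ``meta`` may carry generator ground truth.
    """

    displacement: np.ndarray
    force: np.ndarray
    cross_section_area: float
    initial_length: float
    axis: str = "longitudinal"
    device: str = "rectangular"
    coated: bool = False
    meta: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.displacement.ndim != 1 or self.displacement.shape != self.force.shape:
            raise ValueError("displacement and force must be 1-d arrays of equal length")
        if self.displacement.size < 2:
            raise ValueError("a compression record needs at least 2 samples")
        if abs(self.displacement[0]) > 1e-12:
            raise ValueError("displacement must start at 0")
        if np.any(np.diff(self.displacement) <= 0):
            raise ValueError("displacement must be strictly increasing")
        if not np.isfinite(self.force).all():
            raise ValueError("force contains non-finite values")
        if self.cross_section_area <= 0:
            raise ValueError("cross_section_area must be positive")
        if self.initial_length <= 0:
            raise ValueError("initial_length must be positive")
        if self.axis not in ("longitudinal", "radial"):
            raise ValueError(f"unknown axis {self.axis!r}")
        if self.device not in ("rectangular", "anisotropic"):
            raise ValueError(f"unknown device {self.device!r}")


@dataclass(frozen=True)
class StressStrainCurve:
    """Engineering stress (MPa) versus strain (dimensionless)."""

    strain: np.ndarray
    stress: np.ndarray


@dataclass(frozen=True)
class ModulusEstimate:
    """Effective compressive modulus from the initial linear fit."""

    K: float  # MPa
    fit_displacement_window: float  # mm
    n_points_used: int
    r_squared: float


@dataclass(frozen=True)
class BucklingEstimate:
    buckling_strain: float
    buckling_stress: float
    detected: bool


def to_stress_strain(record: CompressionRecord) -> StressStrainCurve:
    """Element-wise sigma = F/SA (MPa) and epsilon = dL/L0."""
    return StressStrainCurve(
        strain=record.displacement / record.initial_length,
        stress=record.force / record.cross_section_area,
    )


def effective_modulus(
    record: CompressionRecord, window_mm: float = 0.5
) -> ModulusEstimate:
    """OLS slope of stress on strain over displacement <= ``window_mm``.

    The intercept is fitted (tolerating small force offsets at platen
    contact) and discarded; K is the slope in MPa.
    """
    mask = record.displacement <= window_mm + 1e-12
    n = int(mask.sum())
    if n < 3:
        raise ValueError(
            f"only {n} samples fall within the first {window_mm} mm of "
            "displacement; sample the curve more densely"
        )
    curve = to_stress_strain(record)
    res = stats.linregress(curve.strain[mask], curve.stress[mask])
    return ModulusEstimate(
        K=float(res.slope),
        fit_displacement_window=float(window_mm),
        n_points_used=n,
        r_squared=float(res.rvalue**2),
    )


def detect_buckling(
    curve: StressStrainCurve, drop_fraction: float = 0.05
) -> BucklingEstimate:
    """Buckling = first local stress maximum followed by a drop > ``drop_fraction``.

    The 5% default drop threshold is a robustness choice against measurement
    noise (configurable).  Monotonically increasing curves return
    ``detected=False``.
    """
    s = np.asarray(curve.stress, dtype=float)
    e = np.asarray(curve.strain, dtype=float)
    if s.size < 10:
        raise ValueError("buckling detection needs at least 10 samples")
    interior = np.arange(1, s.size - 1)
    is_max = (s[interior] > s[interior - 1]) & (s[interior] >= s[interior + 1])
    for i in interior[is_max]:
        peak = s[i]
        if peak <= 0:
            continue
        if s[i + 1 :].min() < peak * (1.0 - drop_fraction):
            return BucklingEstimate(
                buckling_strain=float(e[i]), buckling_stress=float(peak), detected=True
            )
    return BucklingEstimate(
        buckling_strain=float("nan"), buckling_stress=float("nan"), detected=False
    )


def load_record(csv_path: str | Path, meta_path: str | Path) -> CompressionRecord:
    """Read a curve CSV (columns displacement_mm, force_N) plus its JSON sidecar."""
    df = pd.read_csv(csv_path)
    missing = {"displacement_mm", "force_N"} - set(df.columns)
    if missing:
        raise ValueError(f"curve CSV lacks required columns: {sorted(missing)}")
    meta = json.loads(Path(meta_path).read_text())
    return CompressionRecord(
        displacement=df["displacement_mm"].to_numpy(),
        force=df["force_N"].to_numpy(),
        cross_section_area=float(meta["sa_mm2"]),
        initial_length=float(meta["l0_mm"]),
        axis=meta.get("axis", "longitudinal"),
        device=meta.get("device", "rectangular"),
        coated=bool(meta.get("coated", False)),
        meta=meta.get("truth"),
    )


def save_record(
    record: CompressionRecord, csv_path: str | Path, meta_path: str | Path
) -> None:
    """Write a record as the curve CSV + JSON sidecar pair read by :func:`load_record`."""
    pd.DataFrame(
        {"displacement_mm": record.displacement, "force_N": record.force}
    ).to_csv(csv_path, index=False)
    meta = {
        "sa_mm2": record.cross_section_area,
        "l0_mm": record.initial_length,
        "axis": record.axis,
        "device": record.device,
        "coated": record.coated,
    }
    if record.meta is not None:
        meta["truth"] = record.meta
    Path(meta_path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
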