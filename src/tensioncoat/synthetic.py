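"""Synthetic inputs with known ground truth for every pipeline stage.

Generates wetting systems spanning coatable and non-coatable regimes, the
printed window/pipe dimension grid of the physical study, and noisy
Instron-style compression records whose effective modulus and buckling
strain are prescribed — so parameter-recovery tests can compare estimates
against embedded truth without any downloaded data.

The device cross-section (SA = 78.5 mm^2, an annular-wall proxy) and gauge
length (L0 = 20 mm) are synthetic stand-ins: the study does not print its
specimen cross-sections, and no quantitative claim depends on them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mechanics import CompressionRecord
from .wetting import FrameShape, FrameSpec, WettingSystem, make_system

__all__ = [
    "DeviceProfile",
    "GeneratorConfig",
    "PRESET_NAMES",
    "paper_device_presets",
    "device_preset",
    "gen_compression",
    "gen_frame_specs",
    "gen_wetting_systems",
]

#: Total platen travel of the compression protocol, mm, per test axis.
PROTOCOL_TRAVEL_MM = {"longitudinal": 10.0, "radial": 6.0}

#: Fractional stress drop applied at buckling (cosmetic plateau; the
#: post-buckling branch only exercises the detector, it models no material).
POST_BUCKLING_DROP = 0.20


@dataclass(frozen=True)
class DeviceProfile:
    """Ground-truth mechanical behaviour of one scaffold design/axis pair."""

    name: str
    device: str  # rectangular | anisotropic
    axis: str  # longitudinal | radial
    K_true: float  # MPa
    max_strain: float
    buckling_strain: float | None = None

    def __post_init__(self) -> None:
        if self.K_true <= 0:
            raise ValueError("K_true must be positive")
        if self.buckling_strain is not None and not (
            0.0 < self.buckling_strain < self.max_strain
        ):
            raise ValueError("buckling_strain must lie in (0, max_strain)")


@dataclass(frozen=True)
class GeneratorConfig:
    """Sampling and noise settings for compression-record generation."""

    seed: int = 0
    n_samples: int = 200
    noise_rel: float = 0.01
    sa_mm2: float = 78.5
    l0_mm: float = 20.0

    def __post_init__(self) -> None:
        if self.noise_rel < 0:
            raise ValueError("noise_rel must be non-negative")
        if self.n_samples < 10:
            raise ValueError("n_samples must be at least 10")


def paper_device_presets() -> list[DeviceProfile]:
    """The four scaffold design/axis conditions of the compression study.

    Rectangular-window cylinders are stiff longitudinally (77 MPa) and
    buckle near 2.6% strain; the anisotropic (parallelogram-window) design
    is two orders of magnitude softer longitudinally (0.69 MPa) and
    compresses reversibly to ~30% strain; radially the two designs are
    similar (3.6 and 4.1 MPa).
    """
    return [
        DeviceProfile(
            name="rect-long",
            device="rectangular",
            axis="longitudinal",
            K_true=77.0,
            max_strain=0.50,
            buckling_strain=0.026,
        ),
        DeviceProfile(
            name="aniso-long",
            device="anisotropic",
            axis="longitudinal",
            K_true=0.69,
            max_strain=0.30,
        ),
        DeviceProfile(
            name="rect-radial",
            device="rectangular",
            axis="radial",
            K_true=3.6,
            max_strain=0.30,
        ),
        DeviceProfile(
            name="aniso-radial",
            device="anisotropic",
            axis="radial",
            K_true=4.1,
            max_strain=0.30,
        ),
    ]


PRESET_NAMES = tuple(p.name for p in paper_device_presets())


def device_preset(name: str) -> DeviceProfile:
    for p in paper_device_presets():
        if p.name == name:
            return p
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


def gen_compression(
    profile: DeviceProfile, config: GeneratorConfig = GeneratorConfig()
) -> CompressionRecord:
    """Noisy force-displacement record with the profile's modulus as truth.

    The displacement grid runs to min(max_strain * L0, protocol travel for
    the axis); stress is K_true * strain in the linear regime, with an
    abrupt 20% drop to a plateau past the programmed buckling strain;
    multiplicative Gaussian noise of s.d. ``noise_rel`` is applied to force.
    """
    rng = np.random.default_rng(config.seed)
    total = min(profile.max_strain * config.l0_mm, PROTOCOL_TRAVEL_MM[profile.axis])
    disp = np.linspace(0.0, total, config.n_samples)
    strain = disp / config.l0_mm
    stress = profile.K_true * strain
    if profile.buckling_strain is not None:
        plateau = (1.0 - POST_BUCKLING_DROP) * profile.K_true * profile.buckling_strain
        stress = np.where(strain > profile.buckling_strain, plateau, stress)
    force = stress * config.sa_mm2
    if config.noise_rel > 0:
        force = force * (1.0 + config.noise_rel * rng.standard_normal(force.size))
    return CompressionRecord(
        displacement=disp,
        force=force,
        cross_section_area=config.sa_mm2,
        initial_length=config.l0_mm,
        axis=profile.axis,
        device=profile.device,
        coated=False,
        meta={
            "K_true_mpa": profile.K_true,
            "buckling_strain_true": profile.buckling_strain,
            "max_strain": profile.max_strain,
            "noise_rel": config.noise_rel,
            "seed": config.seed,
            "preset": profile.name,
        },
    )


def gen_frame_specs() -> list[FrameSpec]:
    """The printed 3 x 3 grid of window lengths and pipe diameters (mm)."""
    return [
        FrameSpec(l=l, h=h, shape=FrameShape.square)
        for l in (2.25, 5.5, 8.75)
        for h in (0.25, 0.5, 1.0)
    ]


#: Contact angles (degrees) of the reference energy-curve family.
REFERENCE_THETAS_DEG = (0.0, 15.0, 30.0, 45.0, 60.0, 75.0, 90.0, 105.0, 114.0)


def gen_wetting_systems(seed: int, n: int = 9) -> list[WettingSystem]:
    """Wetting systems spanning the coatable and non-coatable regimes.

    The first nine contact angles are the reference family (0 to 114 deg),
    deterministically; any further systems draw theta uniformly on
    [0, 135) deg.  gamma_SL/gamma_L is drawn uniformly on [0, 2] for every
    system; all systems close Young's equation by construction.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    thetas = list(np.radians(REFERENCE_THETAS_DEG[:n]))
    if n > len(REFERENCE_THETAS_DEG):
        extra = n - len(REFERENCE_THETAS_DEG)
        thetas.extend(rng.uniform(0.0, np.radians(135.0), extra))
    g_sl = rng.uniform(0.0, 2.0, n)
    return [make_system(t, g) for t, g in zip(thetas, g_sl)]
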