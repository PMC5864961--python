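"""Capillary wetting thermodynamics of a two-dimensional square-cell mesh.

When a reticulated (fenestrated) scaffold is dipped into a liquid, surface
tension decides how the liquid distributes over the open cells.  At low
saturation the liquid collects in circular-arc *fillets* in the four corners
of each square cell (phase I).  A hypothetical alternative is a cell that is
almost completely filled except for a shrinking circular hole (phase II).
Comparing the interfacial free energy of these configurations — reduced by
the liquid surface energy and the cell edge length, F/(gamma_L * l) — shows
that beyond a critical saturation the mixture phase-separates: some cells
fill completely while the rest stay in the fillet state.  Complete filling
(the precondition for suspending a liquid film over every window) is
energetically favorable for wetting liquids, i.e. contact angle < 90 deg.

All angles are stored in radians; energies are dimensionless (reduced by
gamma_L * l).  Gravity is ignored throughout: the analysis applies to
millimetre-scale cells where capillarity dominates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "Coatability",
    "FrameShape",
    "WettingSystem",
    "FrameSpec",
    "FilletState",
    "EnergyCurve",
    "PhaseSeparationResult",
    "make_system",
    "fillet_geometry",
    "fillet_area_polygon",
    "fillet_shape_ratio",
    "critical_saturation",
    "reduced_energy_phase1",
    "reduced_energy_phase2",
    "energy_curve",
    "detect_phase_separation",
    "coatability",
    "absolute_energy",
]

_QUARTER_PI = math.pi / 4.0
#: Largest admissible contact angle.  Above 135 deg the convex fillet arc
#: exceeds a semicircle and the corner construction degenerates.
THETA_MAX = 3.0 * math.pi / 4.0
#: Contact angles above this are admitted but flagged with a warning: the
#: fillet construction is an extrapolation there (the critical saturation
#: saturates at 1 just above 114 deg).
THETA_FLAG = math.radians(105.0)


class Coatability(str, Enum):
    """Verdict on whether the fully coated state is energetically preferred."""

    favorable = "favorable"
    neutral = "neutral"
    unfavorable = "unfavorable"


class FrameShape(str, Enum):
    square = "square"
    circle = "circle"


@dataclass(frozen=True)
class WettingSystem:
    """A solid/liquid/vapor system characterised by its interfacial energies.

    Parameters
    ----------
    theta : float
        Contact angle in radians, in [0, pi).
    gamma_sl_ratio : float
        Solid-liquid surface energy divided by the liquid-vapor surface
        energy, gamma_SL / gamma_L.
    gamma_s_ratio : float
        Solid-vapor surface energy divided by gamma_L.  Tied to the other
        two through Young's equation gamma_S = gamma_SL + gamma_L cos(theta).
    """

    theta: float
    gamma_sl_ratio: float
    gamma_s_ratio: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta < math.pi):
            raise ValueError(
                f"contact angle must lie in [0, pi); got {self.theta!r}"
            )
        residual = self.gamma_s_ratio - self.gamma_sl_ratio - math.cos(self.theta)
        if abs(residual) > 1e-12:
            raise ValueError(
                "Young's equation violated: gamma_s_ratio - gamma_sl_ratio "
                f"- cos(theta) = {residual:.3e} (tolerance 1e-12)"
            )


def make_system(theta: float, gamma_sl_ratio: float = 0.0) -> WettingSystem:
    """Construct a :class:`WettingSystem`, closing Young's equation.

    ``gamma_s_ratio`` is derived as ``gamma_sl_ratio + cos(theta)``.
    """
    if not (0.0 <= theta < math.pi):
        raise ValueError(f"contact angle must lie in [0, pi); got {theta!r}")
    return WettingSystem(
        theta=float(theta),
        gamma_sl_ratio=float(gamma_sl_ratio),
        gamma_s_ratio=float(gamma_sl_ratio) + math.cos(theta),
    )


@dataclass(frozen=True)
class FrameSpec:
    """Geometry of one fenestrated cell: window edge length and pipe diameter.

    Lengths in millimetres.  ``h`` (the printed pipe/strut diameter) must be
    smaller than the window length ``l``.
    """

    l: float
    h: float
    shape: FrameShape = FrameShape.square

    def __post_init__(self) -> None:
        if self.l <= 0:
            raise ValueError(f"window length l must be positive; got {self.l}")
        if self.h <= 0:
            raise ValueError(f"pipe diameter h must be positive; got {self.h}")
        if self.h >= self.l:
            raise ValueError(
                f"pipe diameter h={self.h} must be smaller than window length l={self.l}"
            )


@dataclass(frozen=True)
class FilletState:
    """Geometry of one corner fillet.

    ``r`` is the radius of the circular liquid-vapor arc, ``x0`` the wetted
    length measured from the corner along each wall, ``area`` the liquid
    cross-section per fillet and ``arc_angle`` the signed angle subtended by
    the arc (positive: concave meniscus, theta < 45 deg; negative: convex,
    theta > 45 deg; zero: straight interface at exactly 45 deg, where a
    finite arc radius parameterises a degenerate zero-size fillet).
    """

    r: float
    x0: float
    area: float
    arc_angle: float


def _check_fillet_theta(theta: float) -> None:
    if not (0.0 <= theta < THETA_MAX):
        raise ValueError(
            "fillet geometry requires contact angle in [0, 3*pi/4); "
            f"got {theta!r} (the wetted length per wall vanishes at 135 deg)"
        )
    if theta > THETA_FLAG:
        warnings.warn(
            f"contact angle {math.degrees(theta):.1f} deg exceeds 105 deg: the "
            "corner-fillet construction is extrapolated in this regime",
            stacklevel=3,
        )


def _area_coeff(theta: float) -> float:
    # area / r^2 for a fillet of arc radius r; stable at theta = pi/4
    t = theta - _QUARTER_PI
    return math.sin(t) ** 2 + (t - 0.5 * math.sin(2.0 * t))


def fillet_shape_ratio(theta: float) -> float:
    """Dimensionless fillet shape factor ``area / x0**2``.

    Equals the critical saturation: when opposing fillets touch
    (2*x0 = l) the filled fraction of the cell is 4*area/l**2 = area/x0**2.
    Evaluated in a cancellation-free form; the removable singularity at
    theta = pi/4 (straight interface, triangular fillet) has the value 1/2.
    """
    t = theta - _QUARTER_PI
    if abs(t) < 1e-3:
        # series of (t - sin(2t)/2) / (2 sin^2 t) about the straight-interface point
        return 0.5 + (t / 3.0) * (1.0 + 2.0 * t * t / 15.0)
    return 0.5 + (t - 0.5 * math.sin(2.0 * t)) / (2.0 * math.sin(t) ** 2)


def fillet_geometry(r: float, theta: float) -> FilletState:
    """Geometry of a corner fillet of arc radius ``r`` at contact angle ``theta``.

    The fillet is the region of a 90-degree corner bounded by the two walls
    and a circular arc that meets both walls at the contact angle.  For
    theta < 45 deg the meniscus is concave (wall contact at
    ``x0 = r (cos(theta) - sin(theta))`` from the corner, arc centre outside
    the liquid); for theta > 45 deg it is convex (``x0 = r (sin - cos)``).
    Both branches share the closed forms

        x0   = r |cos(theta) - sin(theta)|
        area = r^2 [cos(theta) (cos(theta) - sin(theta)) - (pi/4 - theta)]

    which reduce at theta = 0 to the square-minus-quarter-disk result
    r^2 (1 - pi/4) behind the (8 - 2 pi) and (4 - pi) coefficients of the
    phase I energy.
    """
    if r <= 0:
        raise ValueError(f"arc radius must be positive; got {r}")
    _check_fillet_theta(theta)
    x0 = r * abs(math.cos(theta) - math.sin(theta))
    area = r * r * _area_coeff(theta)
    return FilletState(r=float(r), x0=x0, area=area, arc_angle=math.pi / 2.0 - 2.0 * theta)


def fillet_area_polygon(r: float, theta: float, n_segments: int = 200_000) -> float:
    """Independent numerical-geometry oracle for the fillet area.

    Discretises the region bounded by the two walls and the circular arc into
    a polygon and returns its shapely area.  Used only to cross-check the
    closed form in tests and in the acceptance script; the closed form is the
    implementation.
    """
    if r <= 0:
        raise ValueError(f"arc radius must be positive; got {r}")
    _check_fillet_theta(theta)
    sign = 1.0 if theta < _QUARTER_PI else -1.0
    c = sign * r * math.cos(theta)
    x0 = r * abs(math.cos(theta) - math.sin(theta))
    a1 = math.atan2(0.0 - c, x0 - c)
    a2 = math.atan2(x0 - c, 0.0 - c)
    # shorter way around: the fillet arc subtends |pi/2 - 2 theta| < pi
    delta = (a2 - a1 + math.pi) % (2.0 * math.pi) - math.pi
    phi = a1 + delta * np.linspace(0.0, 1.0, n_segments + 1)
    arc = np.column_stack((c + r * np.cos(phi), c + r * np.sin(phi)))
    ring = np.vstack(([[0.0, 0.0]], arc))
    return float(Polygon(ring).area)


def critical_saturation(theta: float) -> float:
    """Saturation at which adjacent corner fillets touch, ending phase I.

    Closed form ``alpha_Lc = area / x0**2`` evaluated at the radius where
    ``2 x0 = l``; capped at 1 (just above theta = 114.1 deg the fillets can
    no longer touch before the cell is completely full, which is where the
    phase II branch disappears).
    """
    _check_fillet_theta(theta)
    return min(fillet_shape_ratio(theta), 1.0)


def _arc_length_factor(theta: float) -> float:
    # (liquid-vapor arc length per fillet) / (sqrt(2) * x0); -> 1 at theta=pi/4
    t = theta - _QUARTER_PI
    if abs(t) < 1e-8:
        return 1.0 + t * t / 6.0
    return t / math.sin(t)


def reduced_energy_phase1(alpha_l, system: WettingSystem):
    """Reduced Gibbs energy F_I/(gamma_L l) of corner-fillet (phase I) filling.

    Assembled from the fillet geometry: the empty-cell wall energy 4 gamma_S,
    minus the walls converted from solid-vapor to solid-liquid over the
    wetted length 8 x0, plus the four liquid-vapor arcs.  At theta = 0 this
    reduces exactly to

        F_I/(gamma_L l) = 4 (1 + gamma_SL/gamma_L)
                          - (8 - 2 pi) sqrt(alpha_L / (4 - pi)).

    Accepts a scalar or array ``alpha_l``; valid for
    0 <= alpha_l <= critical_saturation(theta).
    """
    theta = system.theta
    _check_fillet_theta(theta)
    alpha = np.asarray(alpha_l, dtype=float)
    a_lc = critical_saturation(theta)
    if np.any(alpha < -1e-15) or np.any(alpha > a_lc + 1e-12):
        raise ValueError(
            f"phase I saturation must lie in [0, critical_saturation(theta)] = "
            f"[0, {a_lc:.6f}]; got values outside that range"
        )
    q = fillet_shape_ratio(theta)
    x0_over_l = 0.5 * np.sqrt(np.clip(alpha, 0.0, None) / q)
    arc_over_l = math.sqrt(2.0) * _arc_length_factor(theta) * x0_over_l
    out = (
        4.0 * system.gamma_s_ratio
        - 8.0 * x0_over_l * math.cos(theta)
        + 4.0 * arc_over_l
    )
    return out if out.ndim else float(out)


def reduced_energy_phase2(alpha_l, system: WettingSystem):
    """Reduced Gibbs energy F_II/(gamma_L l) of hole-shrinking (phase II) filling.

        F_II/(gamma_L l) = 4 gamma_SL/gamma_L + 2 sqrt(pi) sqrt(1 - alpha_L)

    The walls are entirely wetted and the only free interface is the circular
    hole, so the value is independent of the contact angle at fixed
    gamma_SL/gamma_L.  Valid for 0 <= alpha_l <= 1.
    """
    alpha = np.asarray(alpha_l, dtype=float)
    if np.any(alpha < -1e-15) or np.any(alpha > 1.0 + 1e-15):
        raise ValueError("phase II saturation must lie in [0, 1]")
    out = 4.0 * system.gamma_sl_ratio + 2.0 * math.sqrt(math.pi) * np.sqrt(
        np.clip(1.0 - alpha, 0.0, None)
    )
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class EnergyCurve:
    """Composite reduced-energy curve: phase I up to alpha_lc, phase II above."""

    saturations: np.ndarray
    reduced_energy: np.ndarray
    phase_label: np.ndarray  # "I" or "II" per grid point
    alpha_lc: float
    system: WettingSystem = field(repr=False)


def energy_curve(system: WettingSystem, n_points: int = 201) -> EnergyCurve:
    """Sample the composite reduced Gibbs energy on [0, 1].

    The grid is uniform with the endpoints 0 and 1 and the critical
    saturation inserted exactly; the curve follows the phase I branch up to
    alpha_lc and the phase II branch above it (no smoothing — the physically
    realised path beyond alpha_lc is the phase-separation chord, recovered by
    :func:`detect_phase_separation`).
    """
    if n_points < 10:
        raise ValueError(f"n_points must be at least 10; got {n_points}")
    a_lc = critical_saturation(system.theta)
    grid = np.linspace(0.0, 1.0, int(n_points))
    if np.min(np.abs(grid - a_lc)) > 1e-12:
        grid = np.sort(np.append(grid, a_lc))
    in_phase1 = grid <= a_lc + 1e-15
    energy = np.empty_like(grid)
    energy[in_phase1] = reduced_energy_phase1(np.minimum(grid[in_phase1], a_lc), system)
    energy[~in_phase1] = reduced_energy_phase2(grid[~in_phase1], system)
    labels = np.where(in_phase1, "I", "II")
    return EnergyCurve(
        saturations=grid,
        reduced_energy=energy,
        phase_label=labels,
        alpha_lc=a_lc,
        system=system,
    )


@dataclass(frozen=True)
class PhaseSeparationResult:
    """Outcome of the convexity analysis of a composite energy curve.

    ``inflection_at`` is where the discrete second derivative changes sign
    (convex phase I branch -> concave phase II branch); the coexistence
    window [coexist_lo, coexist_hi] is the lever-rule chord anchored at the
    inflection: beyond it, added liquid fills whole cells rather than
    growing the fillets.
    """

    inflection_at: float | None
    coexist_lo: float | None
    coexist_hi: float | None
    is_separating: bool


def detect_phase_separation(curve: EnergyCurve) -> PhaseSeparationResult:
    """Locate the phase separation on a sampled composite energy curve.

    A sign change of the second derivative of F(alpha_L) marks the end of
    homogeneous phase I filling.  The coexistence endpoints follow from the
    common-tangent (lower convex hull) construction anchored at that
    inflection: the chord of minimum slope from the inflection to the rest
    of the curve touches it again at the upper coexistence endpoint (the
    completely filled state, alpha_L = 1, for wetting systems).
    """
    a = curve.saturations
    f = curve.reduced_energy
    if a.size < 50:
        raise ValueError(
            "energy curve too coarse for convexity analysis; resample with "
            "n_points >= 50"
        )
    d2 = np.gradient(np.gradient(f, a), a)
    scale = np.max(np.abs(d2))
    if scale == 0.0:
        return PhaseSeparationResult(None, None, None, False)
    pos = d2 > 1e-9 * scale
    neg = d2 < -1e-9 * scale
    is_separating = bool(neg.any())
    signed = np.nonzero(pos | neg)[0]
    inflection_idx: int | None = None
    for k in range(signed.size - 1):
        i, j = signed[k], signed[k + 1]
        if pos[i] and neg[j]:
            inflection_idx = int(np.argmin(np.abs(a - 0.5 * (a[i] + a[j]))))
            break
    if not is_separating:
        return PhaseSeparationResult(
            None if inflection_idx is None else float(a[inflection_idx]),
            None,
            None,
            False,
        )
    anchor = inflection_idx if inflection_idx is not None else 0
    da = a[anchor + 1 :] - a[anchor]
    slopes = (f[anchor + 1 :] - f[anchor]) / da
    hi = anchor + 1 + int(np.argmin(slopes))
    return PhaseSeparationResult(
        inflection_at=None if inflection_idx is None else float(a[inflection_idx]),
        coexist_lo=float(a[anchor]),
        coexist_hi=float(a[hi]),
        is_separating=True,
    )


def coatability(system: WettingSystem) -> Coatability:
    """Compare the empty-cell and completely filled-cell energies.

    The difference 4 gamma_S - 4 gamma_SL = 4 cos(theta) (per gamma_L l)
    makes complete coating favorable for wetting liquids (theta < 90 deg),
    neutral at 90 deg and unfavorable above.
    """
    c = math.cos(system.theta)
    if abs(c) < 1e-12:
        return Coatability.neutral
    return Coatability.favorable if c > 0 else Coatability.unfavorable


def absolute_energy(reduced: float, gamma_l: float, l: float) -> float:
    """Convert a reduced energy F/(gamma_L l) to an absolute energy.

    Provided as a convenience multiplication only; the package stores and
    reports energies exclusively in reduced form.
    """
    return reduced * gamma_l * l
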