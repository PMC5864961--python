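"""Minimal-surface relaxation of liquid films suspended on fenestrated frames.

A suspended liquid film is modelled as a triangulated surface pinned to the
frame boundary (the window midline).  Its energy is the surface area times
the liquid surface energy; in reduced form the energy *is* the area
(single-face convention, one liquid-vapor interface).  The film is relaxed
by gradient descent on the free vertex positions with a backtracking
(Armijo) line search and Barzilai-Borwein step initialisation, optionally
under an enclosed-volume constraint enforced by Newton projection along the
volume gradient each step.  A film is deemed stable when the relaxation
converges to an energetic equilibrium with every vertex inside a bounding
box of ten frame extents; blow-up or non-convergence is recorded as
instability, not raised.

Lengths in millimetres; areas mm^2; volumes mm^3 (measured against the
z = 0 boundary plane).  Gravity is excluded, consistent with the reduced
thermodynamic model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import trimesh as _trimesh
from scipy.spatial import Delaunay

from .wetting import FrameShape, FrameSpec

__all__ = [
    "TriMesh",
    "Frame",
    "SimulationResult",
    "SweepProtocol",
    "build_frame",
    "init_film",
    "refine",
    "relax",
    "stability_sweep",
    "spherical_cap_area",
    "spherical_cap_volume",
    "export_mesh",
    "load_obj",
]


@dataclass
class TriMesh:
    """Triangulated film surface with pinned-boundary flags.

    ``vertices``: (n, 3) float64 positions; ``triangles``: (m, 3) integer
    vertex triples, counter-clockwise seen from +z for the initial planar
    film; ``pinned``: (n,) bool, True for vertices fixed on the frame.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    pinned: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        self.pinned = np.ascontiguousarray(self.pinned, dtype=bool)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be an (n, 3) array")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be an (m, 3) array")
        if self.pinned.shape != (len(self.vertices),):
            raise ValueError("pinned must be a per-vertex boolean array")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise ValueError("triangles reference invalid vertex indices")

    def validate(self) -> None:
        """Check manifoldness-with-boundary and that boundary vertices are pinned."""
        edges, counts = _edge_counts(self.triangles)
        if np.any(counts > 2):
            raise ValueError("non-manifold mesh: an edge is shared by >2 triangles")
        boundary = edges[counts == 1]
        if boundary.size and not self.pinned[np.unique(boundary)].all():
            raise ValueError("boundary edge endpoints must all be pinned")

    def area(self) -> float:
        return float(_triangle_areas(self.vertices, self.triangles).sum())

    def volume(self) -> float:
        """Signed volume enclosed between the film and the z = 0 boundary plane."""
        a, b, c = (self.vertices[self.triangles[:, k]] for k in range(3))
        return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.triangles.copy(), self.pinned.copy())


@dataclass(frozen=True)
class Frame:
    """Closed boundary loop of one fenestrated window.

    The loop sits at the window's inner-edge midline in the z = 0 plane,
    centred on the origin; the pipe diameter ``h`` is carried as metadata
    (it offsets the midline by h/2 from the nominal lattice line but does
    not change the loop geometry).
    """

    spec: FrameSpec
    loop: np.ndarray  # (k, 3) closed polyline vertices (last != first)

    @property
    def perimeter(self) -> float:
        if self.spec.shape is FrameShape.square:
            return 4.0 * self.spec.l
        return math.pi * self.spec.l

    @property
    def extent(self) -> float:
        return float(self.spec.l)


def build_frame(spec: FrameSpec) -> Frame:
    """Boundary loop for a frame specification (square side l or circle diameter l)."""
    l = spec.l
    if spec.shape is FrameShape.square:
        s = l / 2.0
        loop = np.array(
            [[-s, -s, 0.0], [s, -s, 0.0], [s, s, 0.0], [-s, s, 0.0]], dtype=float
        )
    else:
        phi = np.linspace(0.0, 2.0 * math.pi, 257)[:-1]
        loop = np.column_stack(
            (0.5 * l * np.cos(phi), 0.5 * l * np.sin(phi), np.zeros_like(phi))
        )
    return Frame(spec=spec, loop=loop)


def init_film(
    frame: Frame,
    subdivisions: int,
    perturb_amplitude: float = 0.0,
    seed: int = 0,
) -> TriMesh:
    """Planar triangulation spanning the frame, boundary pinned.

    ``subdivisions`` counts grid divisions per side (square) or rings
    (circle).  Interior vertices are optionally displaced out of plane by
    uniform noise of the given amplitude, seeded for reproducibility.
    """
    if subdivisions < 1:
        raise ValueError("subdivisions must be >= 1")
    l = frame.spec.l
    if frame.spec.shape is FrameShape.square:
        mesh = _square_mesh(l, subdivisions)
    else:
        mesh = _disk_mesh(l / 2.0, subdivisions)
    if perturb_amplitude:
        rng = np.random.default_rng(seed)
        free = ~mesh.pinned
        mesh.vertices[free, 2] += rng.uniform(
            -perturb_amplitude, perturb_amplitude, int(free.sum())
        )
    mesh.validate()
    return mesh


def _square_mesh(l: float, n: int) -> TriMesh:
    xs = np.linspace(-l / 2.0, l / 2.0, n + 1)
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack((gx.ravel(), gy.ravel(), np.zeros(gx.size)))
    idx = np.arange((n + 1) * (n + 1)).reshape(n + 1, n + 1)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    tris = np.vstack((np.column_stack((a, b, c)), np.column_stack((a, c, d))))
    pinned = np.zeros(len(verts), dtype=bool)
    border = np.zeros((n + 1, n + 1), dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    pinned[idx[border]] = True
    return TriMesh(verts, tris, pinned)


def _disk_mesh(radius: float, n_rings: int) -> TriMesh:
    pts = [(0.0, 0.0)]
    for j in range(1, n_rings + 1):
        r = radius * j / n_rings
        m = 6 * j
        phi = 2.0 * math.pi * np.arange(m) / m
        pts.extend(zip(r * np.cos(phi), r * np.sin(phi)))
    pts2d = np.asarray(pts, dtype=float)
    tris = Delaunay(pts2d).simplices.astype(np.int64)
    # enforce counter-clockwise orientation (normals along +z)
    p = pts2d[tris]
    cross = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 1, 1] - p[:, 0, 1]
    ) * (p[:, 2, 0] - p[:, 0, 0])
    flip = cross < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]
    verts = np.column_stack((pts2d, np.zeros(len(pts2d))))
    rr = np.hypot(pts2d[:, 0], pts2d[:, 1])
    pinned = rr >= radius * (n_rings - 0.5) / n_rings
    return TriMesh(verts, tris, pinned)


def _edge_counts(tris: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    e = np.vstack((tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]))
    e = np.sort(e, axis=1)
    return np.unique(e, axis=0, return_counts=True)


def _triangle_areas(v: np.ndarray, t: np.ndarray) -> np.ndarray:
    a, b, c = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
    return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)


def _area_and_gradient(v: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    a, b, c = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
    n = np.cross(b - a, c - a)
    nn = np.linalg.norm(n, axis=1)
    area = 0.5 * nn.sum()
    safe = np.where(nn > 0.0, nn, 1.0)
    nhat = n / safe[:, None]
    grad = np.zeros_like(v)
    np.add.at(grad, t[:, 0], 0.5 * np.cross(b - c, nhat))
    np.add.at(grad, t[:, 1], 0.5 * np.cross(c - a, nhat))
    np.add.at(grad, t[:, 2], 0.5 * np.cross(a - b, nhat))
    return float(area), grad


def _volume_and_gradient(v: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    a, b, c = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
    vol = float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)
    grad = np.zeros_like(v)
    np.add.at(grad, t[:, 0], np.cross(b, c) / 6.0)
    np.add.at(grad, t[:, 1], np.cross(c, a) / 6.0)
    np.add.at(grad, t[:, 2], np.cross(a, b) / 6.0)
    return vol, grad


@dataclass
class SimulationResult:
    """Outcome of one relaxation run."""

    converged: bool
    final_area: float
    final_volume: float
    iterations: int
    energy_history: np.ndarray
    mesh: TriMesh
    stable: bool


def _project_volume(
    v: np.ndarray,
    t: np.ndarray,
    free: np.ndarray,
    target: float,
    rel_tol: float = 1e-6,
    max_newton: int = 30,
) -> np.ndarray:
    atol = rel_tol * max(abs(target), 1e-9)
    for _ in range(max_newton):
        vol, g = _volume_and_gradient(v, t)
        err = target - vol
        if abs(err) <= atol:
            break
        g[~free] = 0.0
        denom = float(np.einsum("ij,ij->", g, g))
        if denom <= 0.0 or not np.isfinite(denom):
            break
        v = v + (err / denom) * g
    return v


def relax(
    mesh: TriMesh,
    target_volume: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 20_000,
    window: int = 50,
    two_sided: bool = False,
    frame_extent: float | None = None,
) -> SimulationResult:
    """Relax a film to its minimal-area state by projected gradient descent.

    The reduced energy is the surface area (doubled under ``two_sided``,
    which changes no verdict).  With ``target_volume`` the enclosed volume
    is restored each step by Newton projection along the volume gradient to
    a relative tolerance of 1e-6.  Convergence: the relative energy decrease
    over the trailing ``window`` accepted iterations falls below ``tol``.
    NaN/blow-up is reported as an unstable, non-converged result rather than
    raised.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    mesh.validate()
    side = 2.0 if two_sided else 1.0
    v = mesh.vertices.copy()
    t = mesh.triangles
    free = ~mesh.pinned
    if frame_extent is None:
        span = v[:, :2].max(axis=0) - v[:, :2].min(axis=0)
        frame_extent = float(max(span.max(), 1e-12))
    if target_volume is not None:
        v = _project_volume(v, t, free, target_volume)

    energy, grad = _area_and_gradient(v, t)
    history = [side * energy]
    grad[~free] = 0.0
    prev_v = None
    prev_grad = None
    step = None
    converged = False
    blew_up = False
    it = 0
    grad_floor = 1e-13 * max(energy, 1e-12) / frame_extent

    for it in range(1, max_iter + 1):
        if target_volume is not None:
            vol, gv = _volume_and_gradient(v, t)
            gv[~free] = 0.0
            denom = float(np.einsum("ij,ij->", gv, gv))
            if denom > 0.0:
                grad = grad - (np.einsum("ij,ij->", grad, gv) / denom) * gv
        gnorm2 = float(np.einsum("ij,ij->", grad, grad))
        if not np.isfinite(gnorm2):
            blew_up = True
            break
        if math.sqrt(gnorm2) <= grad_floor:
            converged = True
            break
        # Barzilai-Borwein step with fallback for the first iteration
        if prev_v is not None:
            s = v - prev_v
            y = grad - prev_grad
            sy = float(np.einsum("ij,ij->", s, y))
            if sy > 0.0:
                step = float(np.einsum("ij,ij->", s, s)) / sy
        if step is None or not np.isfinite(step) or step <= 0.0:
            gmax = float(np.abs(grad).max())
            step = 0.01 * frame_extent / max(gmax, 1e-30)
        prev_v, prev_grad = v, grad

        accepted = False
        st = step
        for _ in range(40):
            cand = v - st * grad
            if target_volume is not None:
                cand = _project_volume(cand, t, free, target_volume)
            e_new, g_new = _area_and_gradient(cand, t)
            if not np.isfinite(e_new):
                st *= 0.5
                continue
            if e_new <= energy - 1e-4 * st * gnorm2:
                v, energy = cand, e_new
                grad = g_new
                grad[~free] = 0.0
                accepted = True
                break
            st *= 0.5
        history.append(side * energy)
        if not accepted:
            # line search stalled: at the resolution of float area evaluation
            # the film is at its minimum
            converged = True
            break
        if len(history) > window:
            drop = history[-window - 1] - history[-1]
            if drop <= tol * max(abs(history[-1]), 1e-300):
                converged = True
                break

    out_mesh = TriMesh(v, t.copy(), mesh.pinned.copy())
    final_area = side * energy if np.isfinite(energy) else math.nan
    final_volume = out_mesh.volume() if np.isfinite(energy) else math.nan
    inside = bool(
        np.isfinite(v).all() and np.abs(v).max() <= 10.0 * frame_extent
    )
    if blew_up:
        converged = False
    return SimulationResult(
        converged=converged,
        final_area=final_area,
        final_volume=final_volume,
        iterations=it,
        energy_history=np.asarray(history),
        mesh=out_mesh,
        stable=bool(converged and inside and not blew_up),
    )


def refine(mesh: TriMesh) -> TriMesh:
    """Split every triangle 4-way at edge midpoints.

    Midpoints of boundary edges inherit pinned status; the surface (and its
    area) is unchanged at the moment of refinement.
    """
    v, t = mesh.vertices, mesh.triangles
    edges = np.vstack((t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]))
    edges_sorted = np.sort(edges, axis=1)
    uniq, inverse, counts = np.unique(
        edges_sorted, axis=0, return_inverse=True, return_counts=True
    )
    mid = 0.5 * (v[uniq[:, 0]] + v[uniq[:, 1]])
    mid_idx = len(v) + np.arange(len(uniq))
    new_v = np.vstack((v, mid))
    boundary_edge = counts == 1
    mid_pinned = boundary_edge & mesh.pinned[uniq[:, 0]] & mesh.pinned[uniq[:, 1]]
    new_pinned = np.concatenate((mesh.pinned, mid_pinned))
    m = len(t)
    e_ab = mid_idx[inverse[:m]]
    e_bc = mid_idx[inverse[m : 2 * m]]
    e_ca = mid_idx[inverse[2 * m :]]
    a, b, c = t[:, 0], t[:, 1], t[:, 2]
    new_t = np.vstack(
        (
            np.column_stack((a, e_ab, e_ca)),
            np.column_stack((b, e_bc, e_ab)),
            np.column_stack((c, e_ca, e_bc)),
            np.column_stack((e_ab, e_bc, e_ca)),
        )
    )
    return TriMesh(new_v, new_t, new_pinned)


@dataclass(frozen=True)
class SweepProtocol:
    """Relaxation schedule for stability sweeps.

    ``volume_fraction`` scales the enclosed target volume as a fraction of
    l^3 (0 means an unconstrained flat film, the default: the liquid volume
    per window is not prescribed by the coating process itself).
    """

    subdivisions: int = 5
    refine_rounds: int = 3
    perturb_rel: float = 0.02
    seed: int = 0
    tol: float = 1e-8
    max_iter: int = 20_000
    volume_fraction: float = 0.0


def stability_sweep(
    l_values,
    h_values,
    protocol: SweepProtocol | None = None,
) -> pd.DataFrame:
    """Relax one film per (l, h) pair and tabulate stability.

    Each cell runs init -> (relax -> refine) x rounds -> relax; a failure in
    any cell is recorded as unstable and the sweep continues.  Returns a
    DataFrame with columns ``l``, ``h``, ``stable``, ``final_area``.
    """
    l_values = list(l_values)
    h_values = list(h_values)
    if not l_values or not h_values:
        raise ValueError("l_values and h_values must be non-empty")
    proto = protocol or SweepProtocol()
    rows = []
    cell = 0
    for l in l_values:
        for h in h_values:
            cell += 1
            try:
                spec = FrameSpec(l=float(l), h=float(h), shape=FrameShape.square)
                frame = build_frame(spec)
                mesh = init_film(
                    frame,
                    proto.subdivisions,
                    perturb_amplitude=proto.perturb_rel * l,
                    seed=proto.seed + cell,
                )
                target = (
                    proto.volume_fraction * l**3 if proto.volume_fraction else None
                )
                res = relax(
                    mesh,
                    target_volume=target,
                    tol=proto.tol,
                    max_iter=proto.max_iter,
                    frame_extent=l,
                )
                for _ in range(proto.refine_rounds):
                    mesh = refine(res.mesh)
                    res = relax(
                        mesh,
                        target_volume=target,
                        tol=proto.tol,
                        max_iter=proto.max_iter,
                        frame_extent=l,
                    )
                rows.append(
                    {
                        "l": float(l),
                        "h": float(h),
                        "stable": bool(res.stable),
                        "final_area": float(res.final_area),
                    }
                )
            except Exception:
                rows.append(
                    {"l": float(l), "h": float(h), "stable": False, "final_area": math.nan}
                )
    return pd.DataFrame(rows, columns=["l", "h", "stable", "final_area"])


def spherical_cap_area(a: float, h: float) -> float:
    """Curved surface area of a spherical cap of base radius a and height h."""
    return math.pi * (a * a + h * h)


def spherical_cap_volume(a: float, h: float) -> float:
    """Volume of a spherical cap of base radius a and height h."""
    return math.pi * h * (3.0 * a * a + h * h) / 6.0


def export_mesh(mesh: TriMesh, path: str) -> None:
    """Write a mesh as OBJ (1-based indices) or binary little-endian PLY."""
    tm = _trimesh.Trimesh(
        vertices=mesh.vertices, faces=mesh.triangles, process=False
    )
    tm.export(path)


def load_obj(path: str) -> TriMesh:
    """Load an OBJ mesh for restart; boundary vertices are re-pinned."""
    tm = _trimesh.load(path, process=False, force="mesh")
    verts = np.asarray(tm.vertices, dtype=float)
    tris = np.asarray(tm.faces, dtype=np.int64)
    edges, counts = _edge_counts(tris)
    pinned = np.zeros(len(verts), dtype=bool)
    boundary = edges[counts == 1]
    if boundary.size:
        pinned[np.unique(boundary)] = True
    return TriMesh(verts, tris, pinned)
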