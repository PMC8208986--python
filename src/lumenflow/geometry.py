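"""Artery lumen geometry: idealized stenoses, contour-frame stacking,
inlet/outlet extensions, and point-membership queries.

All lengths in this module are millimetres.  A lumen surface is represented
as a star-shaped radius map r(s, theta) about a 3D centerline, where ``s``
is arclength measured from the first clinical frame (extensions carry
negative / beyond-last ``s``) and ``theta`` is the azimuth in the local
cross-section plane, measured counterclockwise about the forward tangent
from a rotation-minimizing reference direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

__all__ = [
    "GeometryError",
    "ContourFrame",
    "Centerline",
    "IdealStenosisSpec",
    "ArterySurface",
    "frame_area",
    "frame_perimeter",
    "tortuosity",
    "build_ideal_stenosis",
    "stack_frames",
    "straighten",
    "add_extensions",
    "signed_distance",
]

# segment flags
SEG_INLET = 0
SEG_FRAMES = 1
SEG_OUTLET = 2


class GeometryError(ValueError):
    """Raised for invalid or degenerate geometric input."""


# ---------------------------------------------------------------------------
# contour frames
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContourFrame:
    """One lumen cross-section: M radial samples at uniform azimuths.

    Radii are measured from the frame centroid in the frame's local plane;
    azimuth ``theta_k = 2*pi*k/M``.
    """

    index: int
    s: float                      # arclength position [mm]
    radii: np.ndarray             # (M,) radial distances [mm]

    def __post_init__(self):
        radii = np.asarray(self.radii, dtype=float)
        object.__setattr__(self, "radii", radii)
        if radii.ndim != 1 or radii.size < 16:
            raise GeometryError(
                f"frame {self.index}: need >= 16 radial samples, got {radii.size}")
        if not np.all(np.isfinite(radii)) or np.any(radii <= 0):
            raise GeometryError(f"frame {self.index}: radii must be finite and > 0")

    @property
    def m(self) -> int:
        return self.radii.size

    @property
    def theta(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.m) / self.m

    def points2d(self) -> np.ndarray:
        """Contour polygon vertices in the local plane, shape (M, 2)."""
        th = self.theta
        return np.column_stack([self.radii * np.cos(th), self.radii * np.sin(th)])

    def mean_radius(self) -> float:
        return float(np.mean(self.radii))


def frame_area(frame: ContourFrame) -> float:
    """Area [mm^2] of the closed polygon through the contour points.

    The polygon is star-shaped about the centroid by construction (positive
    radii at strictly increasing azimuths), so it is always simple; the
    shoelace sum reduces to ``1/2 * sum r_k r_{k+1} sin(dtheta)``.
    """
    r = frame.radii
    rn = np.roll(r, -1)
    dth = 2.0 * np.pi / frame.m
    area = 0.5 * float(np.sum(r * rn) * np.sin(dth))
    if area <= 0:
        raise GeometryError(f"frame {frame.index}: degenerate contour (area <= 0)")
    return area


def frame_perimeter(frame: ContourFrame) -> float:
    """Perimeter [mm] of the contour polygon."""
    p = frame.points2d()
    d = np.diff(np.vstack([p, p[:1]]), axis=0)
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


# ---------------------------------------------------------------------------
# centerline
# ---------------------------------------------------------------------------

class Centerline:
    """Ordered 3D polyline with cumulative arclength and C1 interpolation."""

    def __init__(self, points: np.ndarray, s0: float = 0.0):
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if points.shape[0] < 2 or points.shape[1] != 3:
            raise GeometryError("centerline needs >= 2 points of dimension 3")
        seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
        if np.any(seg <= 0):
            raise GeometryError("centerline arclength must be strictly increasing")
        self.points = points
        self.s = s0 + np.concatenate([[0.0], np.cumsum(seg)])
        self._spl = CubicSpline(self.s, points, axis=0)

    @classmethod
    def straight(cls, length: float, origin=(0.0, 0.0, 0.0),
                 direction=(1.0, 0.0, 0.0), n: int = 2, s0: float = 0.0) -> "Centerline":
        o = np.asarray(origin, float)
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
        t = np.linspace(0.0, length, max(n, 2))
        return cls(o[None, :] + t[:, None] * d[None, :], s0=s0)

    @property
    def length(self) -> float:
        return float(self.s[-1] - self.s[0])

    def position(self, s) -> np.ndarray:
        return self._spl(np.clip(s, self.s[0], self.s[-1]))

    def tangent(self, s) -> np.ndarray:
        d = self._spl(np.clip(s, self.s[0], self.s[-1]), 1)
        d = np.atleast_2d(d)
        t = d / np.linalg.norm(d, axis=-1, keepdims=True)
        return t[0] if np.isscalar(s) else t


def tortuosity(centerline: Centerline) -> float:
    """Arclength over endpoint chord length (>= 1)."""
    chord = float(np.linalg.norm(centerline.points[-1] - centerline.points[0]))
    if chord <= 0:
        raise GeometryError("coincident centerline endpoints: tortuosity undefined")
    return centerline.length / chord


def _parallel_transport(tangents: np.ndarray, e1_0: np.ndarray | None = None):
    """Rotation-minimizing frames along a sampled curve.

    Returns (e1, e2) with e1 x e2 = tangent at every sample.  The initial
    reference direction is chosen deterministically orthogonal to the first
    tangent unless given.
    """
    t = tangents
    n = t.shape[0]
    if e1_0 is None:
        a = np.zeros(3)
        a[np.argmin(np.abs(t[0]))] = 1.0
        e1_0 = np.cross(t[0], a)
    e1 = np.empty_like(t)
    e1[0] = e1_0 / np.linalg.norm(e1_0)
    for i in range(1, n):
        v = e1[i - 1] - np.dot(e1[i - 1], t[i]) * t[i]
        nv = np.linalg.norm(v)
        if nv < 1e-12:   # pathological kink; restart reference
            a = np.zeros(3)
            a[np.argmin(np.abs(t[i]))] = 1.0
            v = np.cross(t[i], a)
            nv = np.linalg.norm(v)
        e1[i] = v / nv
    e2 = np.cross(t, e1)
    return e1, e2


# ---------------------------------------------------------------------------
# artery surface
# ---------------------------------------------------------------------------

@dataclass
class ArterySurface:
    """Watertight lumen surface parameterized by (s, theta).

    ``s_nodes``/``radii`` carry the cross-section radius map; the fine
    centerline arrays (``s_f``, ``c_f``, ``t_f``, ``e1_f``, ``e2_f``) carry
    the rotation-minimizing local frames used to embed sections in 3D and
    answer point-membership queries.
    """

    s_nodes: np.ndarray          # (Ns,) arclength of sections [mm]
    radii: np.ndarray            # (Ns, M) radius map [mm]
    flags: np.ndarray            # (Ns,) segment flag per section
    s_f: np.ndarray              # (Nf,) fine centerline arclength [mm]
    c_f: np.ndarray              # (Nf, 3) fine centerline points [mm]
    t_f: np.ndarray              # (Nf, 3) unit tangents
    e1_f: np.ndarray             # (Nf, 3) transported reference directions
    e2_f: np.ndarray             # (Nf, 3)
    frame_spacing: float = 0.5
    _tree: cKDTree | None = field(default=None, repr=False, compare=False)

    # -- construction -----------------------------------------------------

    @staticmethod
    def _build(centerline: Centerline, s_nodes, radii, flags,
               frame_spacing: float, ds_fine: float = 0.05,
               s_origin_shift: float = 0.0) -> "ArterySurface":
        s_nodes = np.asarray(s_nodes, float)
        radii = np.asarray(radii, float)
        s_lo, s_hi = s_nodes[0], s_nodes[-1]
        n_f = max(int(np.ceil((s_hi - s_lo) / ds_fine)) + 1, 8)
        # centerline parameterized with the same s coordinate as the nodes
        s_f = np.linspace(s_lo, s_hi, n_f)
        c_f = centerline.position(s_f + s_origin_shift)
        t_f = centerline.tangent(s_f + s_origin_shift)
        e1_f, e2_f = _parallel_transport(t_f)
        return ArterySurface(s_nodes=s_nodes, radii=radii,
                             flags=np.asarray(flags, int), s_f=s_f, c_f=c_f,
                             t_f=t_f, e1_f=e1_f, e2_f=e2_f,
                             frame_spacing=float(frame_spacing))

    # -- basic queries ----------------------------------------------------

    @property
    def n_theta(self) -> int:
        return self.radii.shape[1]

    @property
    def theta(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.n_theta) / self.n_theta

    def section_areas(self) -> np.ndarray:
        """Polygon area of every stored cross-section."""
        r = self.radii
        rn = np.roll(r, -1, axis=1)
        dth = 2.0 * np.pi / self.n_theta
        return 0.5 * np.sum(r * rn, axis=1) * np.sin(dth)

    @property
    def mean_diameter(self) -> float:
        """Mean lumen diameter D across the clinical-frame segment [mm]."""
        sel = self.flags == SEG_FRAMES
        if not np.any(sel):
            sel = slice(None)
        areas = self.section_areas()[sel]
        return float(2.0 * np.mean(np.sqrt(areas / np.pi)))

    def radius_at(self, s, theta) -> np.ndarray:
        """Bilinear interpolation of the radius map (periodic in theta)."""
        s = np.asarray(s, float)
        theta = np.mod(np.asarray(theta, float), 2.0 * np.pi)
        i = np.clip(np.searchsorted(self.s_nodes, s) - 1, 0, len(self.s_nodes) - 2)
        ds = self.s_nodes[i + 1] - self.s_nodes[i]
        ws = np.clip((s - self.s_nodes[i]) / ds, 0.0, 1.0)
        m = self.n_theta
        ft = theta / (2.0 * np.pi / m)
        j = np.floor(ft).astype(int) % m
        wt = ft - np.floor(ft)
        r0 = self.radii[i, j] * (1 - wt) + self.radii[i, (j + 1) % m] * wt
        r1 = self.radii[i + 1, j] * (1 - wt) + self.radii[i + 1, (j + 1) % m] * wt
        return r0 * (1 - ws) + r1 * ws

    def centerline_at(self, s):
        """Interpolated centerline point, tangent, and local frame at s."""
        s = np.clip(np.asarray(s, float), self.s_f[0], self.s_f[-1])
        c = np.stack([np.interp(s, self.s_f, self.c_f[:, k]) for k in range(3)], axis=-1)
        t = np.stack([np.interp(s, self.s_f, self.t_f[:, k]) for k in range(3)], axis=-1)
        e1 = np.stack([np.interp(s, self.s_f, self.e1_f[:, k]) for k in range(3)], axis=-1)
        t /= np.linalg.norm(t, axis=-1, keepdims=True)
        e1 -= np.sum(e1 * t, axis=-1, keepdims=True) * t
        e1 /= np.linalg.norm(e1, axis=-1, keepdims=True)
        e2 = np.cross(t, e1)
        return c, t, e1, e2

    # -- membership -------------------------------------------------------

    def local_coords(self, points: np.ndarray):
        """Map 3D points [mm] to (s, theta, rho) via nearest-centerline
        projection.  Vectorized; s clamped to the surface span."""
        pts = np.atleast_2d(np.asarray(points, float))
        if self._tree is None:
            self._tree = cKDTree(self.c_f)
        _, idx = self._tree.query(pts)
        # refine s by projecting onto the local tangent
        s = self.s_f[idx] + np.sum((pts - self.c_f[idx]) * self.t_f[idx], axis=1)
        s = np.clip(s, self.s_f[0], self.s_f[-1])
        c, t, e1, e2 = self.centerline_at(s)
        d = pts - c
        d -= np.sum(d * t, axis=1, keepdims=True) * t
        x1 = np.sum(d * e1, axis=1)
        x2 = np.sum(d * e2, axis=1)
        rho = np.hypot(x1, x2)
        theta = np.mod(np.arctan2(x2, x1), 2.0 * np.pi)
        return s, theta, rho

    def sdf(self, points: np.ndarray) -> np.ndarray:
        """Signed distance [mm]: negative inside the lumen, positive outside,
        zero on the surface (radial pseudo-distance, exact for straight
        circular sections and accurate to mesh resolution elsewhere)."""
        pts = np.atleast_2d(np.asarray(points, float))
        s, theta, rho = self.local_coords(pts)
        r_surf = self.radius_at(s, theta)
        out = rho - r_surf
        return out[0] if np.asarray(points).ndim == 1 else out

    def surface_points(self, s_values=None, n_theta: int | None = None) -> np.ndarray:
        """Structured (s, theta) quadrilateral mesh vertices, shape (Ns, M, 3)."""
        s_values = self.s_nodes if s_values is None else np.asarray(s_values, float)
        m = self.n_theta if n_theta is None else int(n_theta)
        th = 2.0 * np.pi * np.arange(m) / m
        c, t, e1, e2 = self.centerline_at(s_values)
        r = np.stack([self.radius_at(np.full(m, sv), th) for sv in s_values])
        dir_vec = (np.cos(th)[None, :, None] * e1[:, None, :]
                   + np.sin(th)[None, :, None] * e2[:, None, :])
        return c[:, None, :] + r[:, :, None] * dir_vec

    def frames(self) -> list[ContourFrame]:
        """Stored clinical-segment sections as ContourFrame objects."""
        out = []
        for i in np.flatnonzero(self.flags == SEG_FRAMES):
            out.append(ContourFrame(index=int(i), s=float(self.s_nodes[i]),
                                    radii=self.radii[i].copy()))
        return out


def signed_distance(surface: ArterySurface, point) -> float | np.ndarray:
    """Signed distance [mm] of a point to the lumen surface (negative inside)."""
    pts = np.asarray(point, float)
    if not np.all(np.isfinite(pts)):
        raise GeometryError("signed_distance: point must be finite")
    return surface.sdf(pts)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IdealStenosisSpec:
    """Straight circular tube with an axisymmetric constriction.

    ``severity`` is the fractional area reduction 1 - A_min/A_healthy; the
    minimum lumen area sits at axial position ``position`` (x = 0 by
    default). The radius profile is a cosine-squared dip over ``extent``
    on each side of the minimum (C1 smooth).
    """

    diameter: float = 2.0        # healthy diameter D [mm]
    severity: float = 0.5        # 1 - A_min / A_healthy
    extent: float = 2.0          # axial half-width of the constriction [mm]
    position: float = 0.0        # axial location of minimum lumen area [mm]
    length: float = 12.0         # total tube length [mm]

    def __post_init__(self):
        if not (0.0 <= self.severity < 1.0):
            raise GeometryError("severity must satisfy 0 <= severity < 1 "
                                "(full occlusion is rejected)")
        if self.extent <= 0 or self.diameter <= 0 or self.length <= 0:
            raise GeometryError("diameter, extent and length must be positive")

    def radius_profile(self, x) -> np.ndarray:
        """Lumen radius [mm] at axial position(s) x."""
        x = np.asarray(x, float)
        u = (x - self.position) / self.extent
        g = np.where(np.abs(u) < 1.0, np.cos(0.5 * np.pi * u) ** 2, 0.0)
        return 0.5 * self.diameter * np.sqrt(1.0 - self.severity * g)


def build_ideal_stenosis(spec: IdealStenosisSpec, frame_spacing: float = 0.5,
                         n_theta: int = 64) -> ArterySurface:
    """Circular-section tube with an axisymmetric area constriction."""
    if frame_spacing <= 0:
        raise GeometryError("frame_spacing must be positive")
    half = 0.5 * spec.length
    n = int(np.floor(half / frame_spacing))
    s_nodes = spec.position + frame_spacing * np.arange(-n, n + 1)
    r = spec.radius_profile(s_nodes)
    radii = np.repeat(r[:, None], n_theta, axis=1)
    cl = Centerline.straight(spec.length + 2 * frame_spacing,
                             origin=(s_nodes[0] - frame_spacing, 0.0, 0.0),
                             s0=s_nodes[0] - frame_spacing)
    return ArterySurface._build(cl, s_nodes, radii,
                                np.full(len(s_nodes), SEG_FRAMES),
                                frame_spacing)


def _validate_frames(frames: Sequence[ContourFrame]) -> np.ndarray:
    if len(frames) < 2:
        raise GeometryError("need at least two contour frames")
    s = np.array([f.s for f in frames], float)
    if np.any(np.diff(s) <= 0):
        raise GeometryError("frames out of order: s positions must strictly increase")
    m = frames[0].m
    if any(f.m != m for f in frames):
        raise GeometryError("all frames must share the same azimuth grid")
    return s


def stack_frames(frames: Sequence[ContourFrame], centerline: Centerline,
                 ds_fine: float = 0.05) -> ArterySurface:
    """Embed each contour in the plane normal to the centerline tangent at
    its arclength position, orientation propagated by parallel transport."""
    s = _validate_frames(frames)
    if s[0] < centerline.s[0] - 1e-9 or s[-1] > centerline.s[-1] + 1e-9:
        raise GeometryError(
            f"frame s range [{s[0]}, {s[-1]}] outside centerline span "
            f"[{centerline.s[0]}, {centerline.s[-1]}]")
    radii = np.stack([f.radii for f in frames])
    surf = ArterySurface._build(centerline, s, radii,
                                np.full(len(s), SEG_FRAMES),
                                float(np.median(np.diff(s))), ds_fine=ds_fine)
    # adjacent cross-section planes must not intersect inside the lumen
    kappa = _curvature(surf.s_f, surf.t_f)
    r_max = np.max(surf.radius_at(
        np.repeat(surf.s_f, 8), np.tile(np.linspace(0, 2 * np.pi, 8, False),
                                        len(surf.s_f))).reshape(len(surf.s_f), 8),
        axis=1)
    bad = kappa * r_max >= 1.0
    if np.any(bad):
        s_bad = surf.s_f[np.argmax(bad)]
        raise GeometryError(
            f"centerline curvature too high at s = {s_bad:.3f} mm: "
            "adjacent section planes intersect within the lumen")
    return surf


def _curvature(s_f: np.ndarray, t_f: np.ndarray) -> np.ndarray:
    dt = np.gradient(t_f, s_f, axis=0)
    return np.linalg.norm(dt, axis=1)


def straighten(frames: Sequence[ContourFrame]) -> ArterySurface:
    """Stack the same contours along a straight x-axis centerline with
    identical s positions (per-frame areas are preserved exactly)."""
    s = _validate_frames(frames)
    pad = max(float(np.median(np.diff(s))), 1e-3)
    cl = Centerline.straight(s[-1] - s[0] + 2 * pad,
                             origin=(s[0] - pad, 0.0, 0.0), s0=s[0] - pad)
    return stack_frames(frames, cl)


def add_extensions(surface: ArterySurface, inlet_length: float | None = None,
                   outlet_length: float | None = None) -> ArterySurface:
    """Prepend a straight inflow channel (circular inlet of radius equal to
    the first frame's mean radius, blending into the first frame over its
    final 2D) and append an outflow channel that bends the centerline until
    the tangent is x-axis-parallel while the section relaxes to circular.

    Defaults: inlet 5D, outlet 8D.
    """
    d = surface.mean_diameter
    inlet_length = 5.0 * d if inlet_length is None else float(inlet_length)
    outlet_length = 8.0 * d if outlet_length is None else float(outlet_length)
    if inlet_length <= 0 or outlet_length <= 0:
        raise GeometryError("extension lengths must be positive")

    s0, s1 = surface.s_nodes[0], surface.s_nodes[-1]
    ds_node = surface.frame_spacing
    m = surface.n_theta
    r_first = surface.radii[0]
    r_last = surface.radii[-1]
    r0_mean = float(np.mean(r_first))
    r1_mean = float(np.mean(r_last))

    ds_f = float(np.mean(np.diff(surface.s_f)))
    t_start = surface.t_f[0]
    t_end = surface.t_f[-1]

    # --- fine centerline: inlet (straight), body (as-is), outlet (bend) ---
    n_in = max(int(np.ceil(inlet_length / ds_f)), 4)
    sin_f = s0 - inlet_length + np.arange(n_in) * (inlet_length / n_in)
    cin_f = surface.c_f[0] + (sin_f - s0)[:, None] * t_start[None, :]

    n_out = max(int(np.ceil(outlet_length / ds_f)), 8)
    dl = outlet_length / n_out
    xhat = np.array([1.0, 0.0, 0.0])
    cout, tout = [], []
    p = surface.c_f[-1].copy()
    for i in range(1, n_out + 1):
        u = i / n_out
        w = 3 * u * u - 2 * u ** 3          # cubic easing of the tangent
        tv = (1 - w) * t_end + w * xhat
        tv = tv / np.linalg.norm(tv)
        p = p + tv * dl
        cout.append(p.copy())
        tout.append(tv)
    sout_f = s1 + dl * np.arange(1, n_out + 1)

    s_f = np.concatenate([sin_f, surface.s_f, sout_f])
    c_f = np.vstack([cin_f, surface.c_f, np.array(cout)])
    # tangents: straight inlet, original body, eased outlet
    t_f = np.vstack([np.repeat(t_start[None, :], n_in, axis=0),
                     surface.t_f, np.array(tout)])
    # parallel transport over the extended line, anchored so the clinical
    # segment keeps its original frames: transport the inlet backwards from
    # the first body frame, and the outlet forwards from the last one.
    e1_in = np.repeat(surface.e1_f[:1], n_in, axis=0)  # straight: no rotation
    e1_out, _ = _parallel_transport(np.vstack([surface.t_f[-1:], np.array(tout)]),
                                    e1_0=surface.e1_f[-1])
    e1_f = np.vstack([e1_in, surface.e1_f, e1_out[1:]])
    e2_f = np.cross(t_f, e1_f)

    # --- section nodes and radius map ---
    n_in_nodes = max(int(np.ceil(inlet_length / ds_node)), 2)
    s_in_nodes = np.linspace(s0 - inlet_length, s0, n_in_nodes + 1)[:-1]
    blend_in = min(2.0 * d, inlet_length)
    lam = np.clip((s_in_nodes - (s0 - blend_in)) / blend_in, 0.0, 1.0)
    r_in = (1 - lam)[:, None] * r0_mean + lam[:, None] * r_first[None, :]

    n_out_nodes = max(int(np.ceil(outlet_length / ds_node)), 2)
    s_out_nodes = np.linspace(s1, s1 + outlet_length, n_out_nodes + 1)[1:]
    blend_out = min(2.0 * d, outlet_length)
    lam = np.clip((s_out_nodes - s1) / blend_out, 0.0, 1.0)
    r_out = (1 - lam)[:, None] * r_last[None, :] + lam[:, None] * r1_mean

    s_nodes = np.concatenate([s_in_nodes, surface.s_nodes, s_out_nodes])
    radii = np.vstack([r_in, surface.radii, r_out])
    flags = np.concatenate([np.full(len(s_in_nodes), SEG_INLET),
                            surface.flags,
                            np.full(len(s_out_nodes), SEG_OUTLET)])
    return ArterySurface(s_nodes=s_nodes, radii=radii, flags=flags,
                         s_f=s_f, c_f=c_f, t_f=t_f, e1_f=e1_f, e2_f=e2_f,
                         frame_spacing=surface.frame_spacing)
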