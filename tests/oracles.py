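"""Independent oracles used by the test suite.

These implementations deliberately avoid the package's own code paths:
closed forms, brute-force scans, dense quadrature, and textbook reference
implementations.
"""

from __future__ import annotations

import numpy as np
from scipy.special import jv


def pearson_population(x, y):
    """Textbook population Pearson coefficient (plain sums)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    mx = x.sum() / n
    my = y.sum() / n
    cov = ((x - mx) * (y - my)).sum() / n
    sx = np.sqrt(((x - mx) ** 2).sum() / n)
    sy = np.sqrt(((y - my) ** 2).sum() / n)
    return cov / (sx * sy)


def polygon_area_quadrature(radius_fn, n=200001):
    """Dense quadrature of 1/2 * integral r(theta)^2 dtheta."""
    th = np.linspace(0.0, 2.0 * np.pi, n)
    r = radius_fn(th)
    return 0.5 * np.trapezoid(r * r, th)


def torus_inside(points, rc, a):
    """Analytic inclusion test for a torus with centerline circle of radius
    rc in the z=0 plane and tube radius a."""
    pts = np.atleast_2d(points)
    rad = np.hypot(pts[:, 0], pts[:, 1])
    return (rad - rc) ** 2 + pts[:, 2] ** 2 < a * a


def helix_tortuosity(radius, pitch, turns):
    """Closed-form arc/chord ratio for a helix r(cos t, sin t, ct)."""
    c = pitch / (2.0 * np.pi)
    t = 2.0 * np.pi * turns
    arc = t * np.sqrt(radius**2 + c**2)
    chord = np.sqrt((radius * (np.cos(t) - 1)) ** 2
                    + (radius * np.sin(t)) ** 2 + (c * t) ** 2)
    return arc / chord


def womersley_centerline_ratio(alpha):
    """Complex ratio (centerline velocity) / (bulk velocity) for
    oscillatory flow at Womersley number alpha (Bessel-series solution)."""
    lam = alpha * np.exp(1j * 3.0 * np.pi / 4.0)
    j0 = jv(0, lam)
    j1 = jv(1, lam)
    return (1.0 - 1.0 / j0) / (1.0 - 2.0 * j1 / (lam * j0))


def ray_cast_inside(points, tri_v0, tri_v1, tri_v2, direction=(1.0, 0.0, 0.0)):
    """Parity ray casting against a triangle soup (Moller-Trumbore,
    vectorized over triangles per query point)."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    e1 = tri_v1 - tri_v0
    e2 = tri_v2 - tri_v0
    out = np.zeros(len(points), bool)
    for i, p in enumerate(np.atleast_2d(points)):
        pvec = np.cross(d, e2)
        det = np.einsum("ij,ij->i", e1, pvec)
        ok = np.abs(det) > 1e-14
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        tvec = p - tri_v0
        u = np.einsum("ij,ij->i", tvec, pvec) * inv
        qvec = np.cross(tvec, e1)
        v = np.einsum("ij,j->i", qvec, d) * inv
        t = np.einsum("ij,ij->i", qvec, e2) * inv
        hit = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 1e-12)
        out[i] = np.count_nonzero(hit) % 2 == 1
    return out


def surface_triangles(surface_points):
    """Triangulate a structured (Ns, Mt, 3) tube mesh (theta wraps)."""
    p = surface_points
    ns, mt, _ = p.shape
    a = p[:-1, :, :]
    b = p[1:, :, :]
    a2 = np.roll(a, -1, axis=1)
    b2 = np.roll(b, -1, axis=1)
    v0 = np.concatenate([a.reshape(-1, 3), a2.reshape(-1, 3)])
    v1 = np.concatenate([b.reshape(-1, 3), b.reshape(-1, 3)])
    v2 = np.concatenate([a2.reshape(-1, 3), b2.reshape(-1, 3)])
    return v0, v1, v2


def brute_force_point_surface_distance(point, surface_points):
    """Minimum distance from a point to all mesh vertices (facet-scale
    accurate for fine meshes)."""
    return float(np.min(np.linalg.norm(
        surface_points.reshape(-1, 3) - np.asarray(point, float), axis=1)))
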