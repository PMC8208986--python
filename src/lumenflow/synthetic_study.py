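"""Synthetic-study generator: baseline contour frames with a localized
stenosis on a tortuous centerline, plus follow-up frames whose area change
is a controlled function of a supplied adhesion profile plus noise.

Everything is deterministic under the spec's seed so pipelines are testable
end-to-end without clinical data.  Frames are emitted at the standard
0.5 mm pullback spacing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import Centerline, ContourFrame, GeometryError, frame_area

__all__ = ["SyntheticStudySpec", "synth_baseline", "synth_followup"]


@dataclass(frozen=True)
class SyntheticStudySpec:
    diameter: float = 2.0             # healthy lumen diameter D [mm]
    n_frames: int = 40                # frames at frame_spacing
    frame_spacing: float = 0.5        # pullback step [mm]
    n_theta: int = 64
    stenosis_center: float = 10.0     # s0 [mm]
    stenosis_severity: float = 0.5    # 1 - A_min/A_healthy
    stenosis_extent: float = 3.0      # half-width [mm]
    tortuosity_amplitude: float = 0.0  # transverse offset amplitude [mm]
    tortuosity_wavelength: float = 10.0  # [mm]
    contour_noise: float = 0.0        # relative radius perturbation amplitude
    growth_gain: float = 0.0          # alpha [mm^2 per unit adhesion]
    growth_noise: float = 0.0         # sigma_g [mm^2]
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.stenosis_severity < 1.0):
            raise GeometryError("stenosis severity must lie in [0, 1)")
        if self.contour_noise < 0 or self.growth_noise < 0 or self.growth_gain < 0:
            raise GeometryError("noise amplitudes and growth gain must be >= 0")
        if self.n_frames < 3 or self.frame_spacing <= 0:
            raise GeometryError("need >= 3 frames at positive spacing")

    @property
    def length(self) -> float:
        return (self.n_frames - 1) * self.frame_spacing


def _radius_profile(spec: SyntheticStudySpec, s: np.ndarray) -> np.ndarray:
    u = (s - spec.stenosis_center) / spec.stenosis_extent
    g = np.where(np.abs(u) < 1.0, np.cos(0.5 * np.pi * u) ** 2, 0.0)
    return 0.5 * spec.diameter * np.sqrt(1.0 - spec.stenosis_severity * g)


def _tortuous_centerline(spec: SyntheticStudySpec):
    """Smooth 3D curve, x-aligned tangents at both ends (sin^2 window), with
    arclength resampled so frame positions land at exact pullback spacing."""
    length = spec.length
    amp = spec.tortuosity_amplitude
    # generous parameter span; trimmed to arclength `length` after resampling
    x = np.linspace(0.0, length * 1.5 + 2.0, 4000)
    win = np.sin(np.pi * np.clip(x / (length * 1.2), 0.0, 1.0)) ** 2
    y = amp * np.sin(2.0 * np.pi * x / spec.tortuosity_wavelength) * win
    z = 0.5 * amp * np.sin(2.0 * np.pi * x / spec.tortuosity_wavelength
                           + 0.5 * np.pi) * win
    pts = np.column_stack([x, y, z])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    # resample to uniform arclength, keep a one-spacing pad past the last frame
    s_new = np.arange(0.0, length + spec.frame_spacing, 0.01)
    pts_new = np.column_stack([np.interp(s_new, s, pts[:, k]) for k in range(3)])
    return Centerline(pts_new, s0=0.0)


def synth_baseline(spec: SyntheticStudySpec):
    """(frames, centerline): smooth perturbed-circle contours with the
    prescribed healthy -> stenotic -> healthy area profile."""
    rng = np.random.default_rng(spec.seed)
    centerline = _tortuous_centerline(spec)
    s = spec.frame_spacing * np.arange(spec.n_frames)
    base_r = _radius_profile(spec, s)
    th = 2.0 * np.pi * np.arange(spec.n_theta) / spec.n_theta
    frames = []
    # smooth azimuthal perturbation: low Fourier modes, slow s modulation
    modes = (2, 3, 4)
    a_m = spec.contour_noise * rng.uniform(0.3, 1.0, len(modes)) / len(modes)
    ph_m = rng.uniform(0, 2 * np.pi, len(modes))
    q_m = rng.uniform(0.5, 1.5, len(modes))
    for j, sj in enumerate(s):
        pert = np.zeros_like(th)
        for (m, a, ph, q) in zip(modes, a_m, ph_m, q_m):
            mod = np.sin(2.0 * np.pi * q * sj / max(spec.length, 1e-9) + m)
            pert += a * mod * np.cos(m * th + ph)
        radii = base_r[j] * (1.0 + pert)
        if np.any(radii <= 0.05 * base_r[j]):
            raise GeometryError(
                f"contour noise too large: self-intersecting frame at s = {sj}")
        frames.append(ContourFrame(index=j, s=float(sj), radii=radii))
    return frames, centerline


def synth_followup(frames, adhesion_profile: np.ndarray,
                   spec: SyntheticStudySpec,
                   azimuthal: bool = False,
                   theta_center: float = np.pi):
    """Follow-up frames with A_f = A_b - alpha * Rbar - eps, eps ~ N(0,
    sigma_g), truncated so A_f > 0.05 A_b.  Contours shrink isotropically
    (or azimuthally localized around ``theta_center`` when requested)."""
    adhesion_profile = np.asarray(adhesion_profile, float)
    if adhesion_profile.size != len(frames):
        raise GeometryError("adhesion profile must cover every frame")
    rng = np.random.default_rng(spec.seed + 1)
    eps = rng.normal(0.0, spec.growth_noise, len(frames)) \
        if spec.growth_noise > 0 else np.zeros(len(frames))
    out = []
    truncated = 0
    for f, rbar, e in zip(frames, adhesion_profile, eps):
        a_b = frame_area(f)
        a_f = a_b - spec.growth_gain * rbar - e
        if a_f < 0.05 * a_b:
            a_f = 0.05 * a_b
            truncated += 1
        scale = np.sqrt(a_f / a_b)
        if azimuthal:
            w = 0.5 * (1.0 + np.cos(f.theta - theta_center))
            shrink = 1.0 - (1.0 - scale) * 2.0 * w
            radii = f.radii * np.clip(shrink, 0.05, None)
        else:
            radii = f.radii * scale
        out.append(ContourFrame(index=f.index, s=f.s, radii=radii))
    if truncated > 0.2 * len(frames):
        warnings.warn(
            f"growth gain truncated {truncated}/{len(frames)} frames at the "
            "positivity floor", RuntimeWarning, stacklevel=2)
    return out
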