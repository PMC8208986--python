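"""Baseline vs follow-up lumen-area change and its correlation with the
predicted adhesion profile.

The correlation coefficient is a Pearson coefficient with population (1/N)
normalization of both the covariance and the standard deviations; zero
variance in either input is an explicit error, never a silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import ContourFrame, frame_area

__all__ = [
    "AnalysisError",
    "ZeroVarianceError",
    "LumenSeries",
    "CorrelationResult",
    "delta_lumen",
    "correlate",
    "summarize_change",
    "bin_profile_to_frames",
]


class AnalysisError(ValueError):
    pass


class ZeroVarianceError(AnalysisError):
    """Correlation against a constant input is undefined."""


@dataclass(frozen=True)
class LumenSeries:
    """Per-frame lumen areas at baseline and follow-up.

    delta = A_baseline - A_followup; positive where the lumen narrowed.
    """

    s_mm: np.ndarray
    area_baseline_mm2: np.ndarray
    area_followup_mm2: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.s_mm, float)
        ab = np.asarray(self.area_baseline_mm2, float)
        af = np.asarray(self.area_followup_mm2, float)
        object.__setattr__(self, "s_mm", s)
        object.__setattr__(self, "area_baseline_mm2", ab)
        object.__setattr__(self, "area_followup_mm2", af)
        if s.size < 3:
            raise AnalysisError("need at least 3 frames in a lumen series")
        if not (s.size == ab.size == af.size):
            raise AnalysisError("lumen series arrays must share length")
        if np.any(np.diff(s) <= 0):
            raise AnalysisError("frame positions must strictly increase")
        if np.any(ab <= 0) or np.any(af <= 0):
            raise AnalysisError("lumen areas must be positive")

    @property
    def delta(self) -> np.ndarray:
        return self.area_baseline_mm2 - self.area_followup_mm2

    @property
    def n(self) -> int:
        return int(self.s_mm.size)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    mean_x: float
    mean_y: float
    sigma_x: float
    sigma_y: float
    n: int


def delta_lumen(baseline: Sequence[ContourFrame],
                followup: Sequence[ContourFrame]) -> LumenSeries:
    """Areas from both exams on the baseline frame grid (follow-up areas
    linearly interpolated in s over the overlapping range)."""
    sb = np.array([f.s for f in baseline], float)
    ab = np.array([frame_area(f) for f in baseline])
    sf = np.array([f.s for f in followup], float)
    af = np.array([frame_area(f) for f in followup])
    lo = max(sb.min(), sf.min())
    hi = min(sb.max(), sf.max())
    if hi <= lo:
        raise AnalysisError("baseline and follow-up s ranges do not overlap")
    sel = (sb >= lo - 1e-9) & (sb <= hi + 1e-9)
    if np.count_nonzero(sel) < 3:
        raise AnalysisError("fewer than 3 frames in the common s range")
    s = sb[sel]
    return LumenSeries(s, ab[sel], np.interp(s, sf, af))


def correlate(adhesion: np.ndarray, series: LumenSeries) -> CorrelationResult:
    """Pearson correlation (population normalization) between the adhesion
    profile sampled at the frame positions and the lumen-area change."""
    x = np.asarray(adhesion, float)
    y = series.delta
    if x.size != series.n:
        raise AnalysisError(
            f"adhesion profile length {x.size} != number of frames {series.n}")
    n = x.size
    mx, my = float(np.mean(x)), float(np.mean(y))
    sx = float(np.sqrt(np.mean((x - mx) ** 2)))
    sy = float(np.sqrt(np.mean((y - my) ** 2)))
    if sx == 0.0 or sy == 0.0:
        raise ZeroVarianceError(
            "correlation undefined: zero standard deviation "
            f"(sigma_R = {sx:.3g}, sigma_dA = {sy:.3g})")
    rho = float(np.mean((x - mx) * (y - my)) / (sx * sy))
    return CorrelationResult(rho=rho, mean_x=mx, mean_y=my,
                             sigma_x=sx, sigma_y=sy, n=n)


def summarize_change(series: LumenSeries) -> tuple[float, float]:
    """(mean delta-A along the centerline, maximum delta-A) in mm^2."""
    d = series.delta
    return float(np.mean(d)), float(np.max(d))


def bin_profile_to_frames(s_profile: np.ndarray, values: np.ndarray,
                          frame_s: np.ndarray) -> np.ndarray:
    """Average a finely sampled profile into each frame's s-bin
    (+- half frame spacing); empty bins fall back to linear interpolation."""
    s_profile = np.asarray(s_profile, float)
    values = np.asarray(values, float)
    frame_s = np.asarray(frame_s, float)
    if frame_s.size < 2:
        raise AnalysisError("need >= 2 frame positions")
    half = 0.5 * np.median(np.diff(frame_s))
    out = np.empty(frame_s.size)
    for i, sj in enumerate(frame_s):
        sel = (s_profile >= sj - half) & (s_profile < sj + half)
        if np.any(sel):
            out[i] = np.mean(values[sel])
        else:
            out[i] = np.interp(sj, s_profile, values)
    return out
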