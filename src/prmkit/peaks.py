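"""Chromatogram processing: baseline, peak boundaries, integration, top-k roll-up.

The boundary policy mirrors manual review of scheduled-acquisition traces: the
apex is the raw maximum inside the expected-RT window, and boundaries extend
outward to the first point at <=1% of the baseline-subtracted apex or to the
first local minimum, whichever comes first.  The local-minimum test runs on a
short moving-average copy of the trace so that point-to-point multiplicative
noise does not truncate peaks; integration always uses the raw trace.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

FLAG_OK = "ok"
FLAG_NO_PEAK = "no_peak"


@dataclass
class Chromatogram:
    """Time/intensity trace for one transition in one sample."""

    sample_id: str
    transition_id: str
    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.size < 5:
            raise ValueError("chromatogram needs at least 5 points")
        if self.times.size != self.intensities.size:
            raise ValueError("times and intensities differ in length")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("time grid must be strictly increasing")


@dataclass
class PeakResult:
    start: float
    end: float
    apex_time: float
    background: float
    area: float
    flag: str = FLAG_OK

    def __post_init__(self):
        if self.flag == FLAG_OK and not (self.start < self.apex_time < self.end):
            raise ValueError("peak boundaries must bracket the apex")
        if self.area < 0:
            raise ValueError("area must be >= 0")


def estimate_baseline(xic: Chromatogram, window: tuple[float, float] | None = None) -> float:
    """Mean of the lowest decile of intensities in the window, clipped at 0."""
    if window is None:
        window = (xic.times[0], xic.times[-1])
    lo, hi = window
    mask = (xic.times >= lo) & (xic.times <= hi)
    if not mask.any():
        raise ValueError("baseline window does not overlap the time grid")
    vals = np.sort(xic.intensities[mask])
    n = max(1, int(np.ceil(vals.size / 10)))
    return max(0.0, float(vals[:n].mean()))


def _smooth(y: np.ndarray, points: int) -> np.ndarray:
    if points <= 1 or y.size < points:
        return y
    kernel = np.full(points, 1.0 / points)
    out = np.convolve(y, kernel, mode="same")
    # edges: renormalise by actual kernel coverage
    cov = np.convolve(np.ones_like(y), kernel, mode="same")
    return out / cov


def detect_peak(
    xic: Chromatogram,
    expected_rt: float,
    window: float,
    background: float | None = None,
    snr: float = 3.0,
    smooth_points: int = 5,
) -> PeakResult:
    """Locate a peak near ``expected_rt`` and integrate it.

    Returns a ``no_peak`` result (area 0) when the apex does not exceed the
    background by ``snr`` times the robust trace noise (MAD); this is distinct
    from an error and keeps downstream sums defined.
    """
    t, y = xic.times, xic.intensities
    region = np.abs(t - expected_rt) <= window / 2
    if not region.any():
        raise ValueError("search window outside the time grid")
    if background is None:
        background = estimate_baseline(xic)

    idx_region = np.flatnonzero(region)
    apex = idx_region[np.argmax(y[idx_region])]
    mad = 1.4826 * float(np.median(np.abs(y - np.median(y))))
    apex_height = y[apex] - background
    if apex_height <= snr * mad or apex_height <= 0:
        return PeakResult(
            start=t[0], end=t[-1], apex_time=t[apex], background=background,
            area=0.0, flag=FLAG_NO_PEAK,
        )

    ys = _smooth(y, smooth_points)
    threshold = background + 0.01 * (y[apex] - background)

    def walk(step: int) -> int:
        i = apex
        while True:
            j = i + step
            if j <= 0 or j >= y.size - 1:
                return int(np.clip(j, 0, y.size - 1))
            if ys[j] <= threshold:
                return j
            # local minimum on the smoothed trace
            if ys[j] < ys[j - 1] and ys[j] < ys[j + 1]:
                return j
            i = j

    left = walk(-1)
    right = walk(+1)
    left = min(left, apex - 1)
    right = max(right, apex + 1)
    left = max(left, 0)
    right = min(right, y.size - 1)
    area = integrate(xic, (t[left], t[right]), background)
    return PeakResult(
        start=float(t[left]), end=float(t[right]), apex_time=float(t[apex]),
        background=background, area=area,
    )


def integrate(xic: Chromatogram, bounds: tuple[float, float], background: float) -> float:
    """Trapezoidal integral of (intensity - background), clipped at 0."""
    lo, hi = bounds
    if lo >= hi:
        raise ValueError("inverted integration bounds")
    mask = (xic.times >= lo) & (xic.times <= hi)
    if mask.sum() < 2:
        return 0.0
    y = np.clip(xic.intensities[mask] - background, 0.0, None)
    return float(np.trapezoid(y, xic.times[mask]))


def top_k_fragments(areas: dict[str, float], k: int = 3) -> list[str]:
    """The k fragment labels with the largest areas; ties break by label."""
    if any(a < 0 for a in areas.values()):
        raise ValueError("areas must be non-negative")
    ordered = sorted(areas, key=lambda f: (-areas[f], f))
    if len(ordered) < k:
        warnings.warn(
            f"only {len(ordered)} fragments available (requested {k})", stacklevel=2
        )
        return ordered
    return ordered[:k]
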