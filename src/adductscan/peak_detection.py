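"""Chromatographic peak detection on PICs with a zero-area matched filter.

The detector correlates each PIC's intensity trace with a zero-sum kernel — a
Gaussian of width ``kernel_sigma_scans`` minus its own mean over a ±3σ support.
Because the kernel sums to zero it annihilates any constant baseline, and as a
matched filter it responds maximally where the trace locally looks like the
kernel's Gaussian.  At the trace edges the kernel is truncated to the available
support and re-centred to zero sum, so a constant trace still yields an
identically zero response.

Candidate apexes are local maxima of the response exceeding
``snr_threshold`` times a robust noise scale — the point-noise sigma estimated
from the MAD of the trace's first differences, propagated through the kernel.  Each candidate must show a rising-then-falling slope on the
raw trace.  Boundaries are then refined by smoothing the trace with a centred
moving average and intersecting the nearest local minima flanking the apex;
quality flags record noisy surroundings (a comparable smoothed maximum close
by) and irregular (non-unimodal) shapes.  Peak area is the trapezoidal
integral of the raw intensity over retention time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import argrelextrema, find_peaks

from .errors import ParameterError
from .pic_extraction import PIC

__all__ = [
    "ZAFParams",
    "Peak",
    "zaf_response",
    "smooth_trace",
    "detect_peaks",
    "refine_peak",
    "integrate_peak",
    "find_and_refine",
]

MAD_TO_SIGMA = 1.4826


@dataclass(frozen=True)
class ZAFParams:
    """Detection parameters.

    kernel_sigma_scans : Gaussian width of the zero-area kernel, in scans.
    snr_threshold : minimum response-to-noise ratio at a candidate apex;
        noise is the robust (MAD-based) sigma of the response under the
        trace's estimated point noise.
    min_peak_points : minimum points per peak.  Five is recommended for
        reliable identification; three admits poorly resolved peaks.
    smooth_window_scans : odd width of the moving-average smoother used for
        boundary refinement.
    """

    kernel_sigma_scans: float = 2.0
    snr_threshold: float = 5.0
    min_peak_points: int = 5
    smooth_window_scans: int = 5

    def __post_init__(self) -> None:
        if self.kernel_sigma_scans <= 0:
            raise ParameterError("kernel_sigma_scans must be positive")
        if self.snr_threshold <= 0:
            raise ParameterError("snr_threshold must be positive")
        if self.min_peak_points < 3:
            raise ParameterError("min_peak_points must be >= 3")
        if self.smooth_window_scans < 3 or self.smooth_window_scans % 2 == 0:
            raise ParameterError("smooth_window_scans must be odd and >= 3")


@dataclass
class Peak:
    """A detected peak on a PIC, with inclusive point-index boundaries."""

    pic_ref: str
    apex_index: int
    apex_rt: float
    apex_intensity: float
    left_index: int
    right_index: int
    area: float = 0.0
    noisy_surroundings: bool = False
    irregular_shape: bool = False
    edge_clamped: bool = False

    @property
    def n_points(self) -> int:
        return self.right_index - self.left_index + 1


def zero_sum_kernel(sigma: float) -> np.ndarray:
    """The interior kernel: Gaussian minus its mean over a ±3σ support."""
    half = max(1, int(np.ceil(3.0 * sigma)))
    x = np.arange(-half, half + 1, dtype=float)
    g = np.exp(-0.5 * (x / sigma) ** 2)
    return g - g.mean()


def zaf_response(pic: PIC, params: ZAFParams | None = None) -> np.ndarray:
    """Correlation of the PIC intensity trace with the zero-sum kernel.

    Edges use the truncated kernel re-normalised to zero sum, so the response
    to a constant trace is 0 everywhere (to numerical tolerance).
    """
    params = params or ZAFParams()
    y = np.asarray(pic.intensity, dtype=float)
    n = len(y)
    half = max(1, int(np.ceil(3.0 * params.kernel_sigma_scans)))
    # plain Gaussian; each window subtracts its own mean below, which yields
    # the zero-sum kernel in the interior and the re-zeroed truncation at edges
    g = np.exp(-0.5 * (np.arange(-half, half + 1) / params.kernel_sigma_scans) ** 2)
    resp = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        seg = g[lo - i + half : hi - i + half]
        k = seg - seg.mean()
        resp[i] = float(np.dot(k, y[lo:hi]))
    return resp


def smooth_trace(y: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average; the window shrinks symmetrically at the edges."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = y[i - h : i + h + 1].mean()
    return out


def _noise_scale(y: np.ndarray, kernel_sigma: float) -> float:
    """Robust sigma of the filter response under the trace's noise.

    The point noise sigma is estimated from the MAD of the first differences
    of the raw trace (differencing suppresses the smooth peak structure, so
    the peaks themselves do not inflate the estimate even when they cover
    most of a short trace) and propagated through the kernel's L2 norm."""
    d = np.diff(y)
    if len(d) == 0:
        return 0.0
    mad = float(np.median(np.abs(d - np.median(d))))
    sigma_point = mad * MAD_TO_SIGMA / np.sqrt(2.0)
    k = zero_sum_kernel(kernel_sigma)
    return sigma_point * float(np.sqrt(np.dot(k, k)))


def _rising_falling(y: np.ndarray, idx: int) -> bool:
    """Increasing slope into idx and decreasing slope out of it."""
    if idx <= 0 or idx >= len(y) - 1:
        return False
    return y[idx] >= y[idx - 1] and y[idx] >= y[idx + 1] and (
        y[idx] > y[idx - 1] or y[idx] > y[idx + 1]
    )


def _initial_bounds(y: np.ndarray, apex: int) -> tuple[int, int]:
    """Descend from the apex to the flanking minima of the raw trace.

    Descent is strict so a flat baseline bounds the peak instead of being
    swallowed into it."""
    left = apex
    while left > 0 and y[left - 1] < y[left]:
        left -= 1
    right = apex
    while right < len(y) - 1 and y[right + 1] < y[right]:
        right += 1
    return left, right


def detect_peaks(pic: PIC, params: ZAFParams | None = None) -> list[Peak]:
    """Detect candidate peaks on a PIC (boundaries unrefined).

    A candidate is a local maximum of the zero-area-filter response at
    ``snr_threshold`` times the robust noise scale, showing a
    rising-then-falling raw-intensity profile and supported by at least
    ``min_peak_points`` points between the flanking raw minima.
    """
    params = params or ZAFParams()
    y = np.asarray(pic.intensity, dtype=float)
    if len(y) < params.min_peak_points:
        return []
    resp = zaf_response(pic, params)
    noise = _noise_scale(y, params.kernel_sigma_scans)
    # floor well above float rounding noise but far below any real signal,
    # so noiseless flat-baseline traces still yield their peaks while a
    # constant trace yields none
    floor = 1e-9 * max(1.0, float(np.max(np.abs(y))))
    threshold = max(params.snr_threshold * noise, floor)
    cand, _ = find_peaks(resp, height=threshold)
    peaks: list[Peak] = []
    taken: set[int] = set()
    for c in cand:
        # snap to the nearest raw local maximum (response apex can be off by
        # a sample on asymmetric peaks)
        lo = max(0, c - 2)
        hi = min(len(y), c + 3)
        apex = lo + int(np.argmax(y[lo:hi]))
        if apex in taken or not _rising_falling(y, apex):
            continue
        left, right = _initial_bounds(y, apex)
        # supporting points are those strictly between the flanking minima;
        # a boundary clamped at the trace edge is itself part of the peak
        support = (right - left + 1) - (left > 0) - (right < len(y) - 1)
        if support < params.min_peak_points:
            continue
        taken.add(apex)
        peaks.append(
            Peak(
                pic_ref=pic.dataset_id,
                apex_index=apex,
                apex_rt=float(pic.rt[apex]),
                apex_intensity=float(y[apex]),
                left_index=left,
                right_index=right,
            )
        )
    peaks.sort(key=lambda p: p.apex_index)
    return peaks


def refine_peak(pic: PIC, peak: Peak, params: ZAFParams | None = None) -> Peak:
    """Refine boundaries to the nearest local minima of the smoothed trace and
    set the quality flags.

    ``noisy_surroundings``: another smoothed local maximum above 50% of the
    apex lies within twice the peak width of either boundary.
    ``irregular_shape``: the refined segment of the smoothed trace is not
    unimodal.
    """
    params = params or ZAFParams()
    y = np.asarray(pic.intensity, dtype=float)
    s = smooth_trace(y, params.smooth_window_scans)
    n = len(s)
    apex = peak.apex_index

    minima = argrelextrema(s, np.less_equal, order=1)[0]
    minima = minima[(minima > 0) & (minima < n - 1)]  # interior minima only
    left_candidates = minima[minima < apex]
    right_candidates = minima[minima > apex]
    clamped = False
    if len(left_candidates):
        left = int(left_candidates[-1])
    else:
        left, clamped = 0, True
    if len(right_candidates):
        right = int(right_candidates[0])
    else:
        right, clamped = n - 1, True

    width = max(right - left, 1)
    smoothed_apex = s[apex]
    smax, _ = find_peaks(s)
    noisy = False
    for m in smax:
        if left <= m <= right:
            continue
        dist = (left - m) if m < left else (m - right)
        if dist <= 2 * width and s[m] >= 0.5 * smoothed_apex:
            noisy = True
            break

    interior = find_peaks(s[left : right + 1])[0]
    irregular = len(interior) > 1

    refined = replace(
        peak,
        left_index=left,
        right_index=right,
        noisy_surroundings=noisy,
        irregular_shape=irregular,
        edge_clamped=clamped,
    )
    refined.area = integrate_peak(pic, refined)
    return refined


def integrate_peak(pic: PIC, peak: Peak) -> float:
    """Trapezoidal integral of raw intensity over RT across the peak bounds
    (counts·seconds).  A single-point range integrates to zero."""
    l, r = peak.left_index, peak.right_index
    if r <= l:
        return 0.0
    return float(np.trapezoid(pic.intensity[l : r + 1], pic.rt[l : r + 1]))


def find_and_refine(pic: PIC, params: ZAFParams | None = None) -> list[Peak]:
    """Detect, refine and integrate all peaks on a PIC, dropping degenerate
    (zero-area or under-supported) refined peaks."""
    params = params or ZAFParams()
    out = []
    for pk in detect_peaks(pic, params):
        refined = refine_peak(pic, pk, params)
        if refined.area > 0 and refined.n_points >= params.min_peak_points:
            out.append(refined)
    return out
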