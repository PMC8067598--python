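"""Zero-area filter detection, boundary refinement, integration."""

import numpy as np
import pytest
from scipy.signal import find_peaks

from adductscan import (ZAFParams, detect_peaks, find_and_refine,
                        integrate_peak, refine_peak, zaf_response)
from adductscan.peak_detection import Peak, smooth_trace, zero_sum_kernel

from conftest import gaussian_trace, make_pic


def test_kernel_sums_to_zero():
    for sigma in (1.0, 2.0, 3.5):
        assert zero_sum_kernel(sigma).sum() == pytest.approx(0.0, abs=1e-12)


def test_constant_trace_gives_zero_response_and_no_peaks():
    pic = make_pic(np.full(30, 500.0))
    resp = zaf_response(pic, ZAFParams())
    np.testing.assert_allclose(resp, 0.0, atol=1e-9 * 500)
    assert detect_peaks(pic, ZAFParams()) == []


def test_matched_gaussian_response_peaks_at_apex():
    params = ZAFParams(kernel_sigma_scans=2.0)
    pic = make_pic(gaussian_trace(41, apex=20, sigma=2.0, amplitude=1000.0))
    resp = zaf_response(pic, params)
    assert int(np.argmax(resp)) == 20
    # direct correlation oracle on the interior (full kernel support)
    k = zero_sum_kernel(2.0)
    half = len(k) // 2
    direct = np.correlate(pic.intensity, k, mode="valid")
    np.testing.assert_allclose(resp[half:-half], direct, rtol=1e-10)


def test_two_separated_gaussians_detected_at_their_apexes():
    y = (gaussian_trace(60, apex=15, sigma=2.0, amplitude=1000.0)
         + gaussian_trace(60, apex=45, sigma=2.0, amplitude=700.0))
    peaks = detect_peaks(make_pic(y), ZAFParams())
    assert [p.apex_index for p in peaks] == [15, 45]


def test_monotone_ramp_has_no_peaks():
    pic = make_pic(np.linspace(0, 1000, 30))
    assert detect_peaks(pic, ZAFParams()) == []


def test_min_peak_points_five_vs_three():
    # narrow peak supported by ~4 points on a flat baseline
    y = np.full(20, 10.0)
    y[9:12] = [400.0, 1000.0, 400.0]
    pic = make_pic(y)
    assert detect_peaks(pic, ZAFParams(min_peak_points=5)) == []
    got = detect_peaks(pic, ZAFParams(min_peak_points=3))
    assert len(got) == 1 and got[0].apex_index == 10


# --- integration closed forms ---------------------------------------------

def _peak(l, a, r):
    return Peak(pic_ref="t", apex_index=a, apex_rt=0.0, apex_intensity=0.0,
                left_index=l, right_index=r)


def test_trapezoid_rectangle_and_triangle():
    delta = 2.0
    rect = make_pic([5.0, 5.0, 5.0], rt_step=delta)
    assert integrate_peak(rect, _peak(0, 1, 2)) == pytest.approx(2 * delta * 5.0)
    tri = make_pic([0.0, 7.0, 0.0], rt_step=delta)
    assert integrate_peak(tri, _peak(0, 1, 2)) == pytest.approx(delta * 7.0)


def test_dense_gaussian_integral_approaches_analytic():
    A, sigma = 1000.0, 5.0
    rt = np.linspace(-40, 40, 801)
    y = A * np.exp(-0.5 * (rt / sigma) ** 2)
    pic = make_pic(y, rt=rt)
    area = integrate_peak(pic, _peak(0, 400, 800))
    assert area == pytest.approx(A * sigma * np.sqrt(2 * np.pi), rel=0.01)


def test_single_point_range_integrates_to_zero():
    pic = make_pic([1.0, 2.0, 3.0])
    assert integrate_peak(pic, _peak(1, 1, 1)) == 0.0


# --- refinement ------------------------------------------------------------

def test_isolated_gaussian_refines_cleanly():
    y = gaussian_trace(61, apex=30, sigma=3.0, amplitude=1000.0, baseline=5.0)
    pic = make_pic(y)
    peaks = detect_peaks(pic, ZAFParams())
    assert len(peaks) == 1
    refined = refine_peak(pic, peaks[0], ZAFParams())
    assert refined.left_index <= 30 <= refined.right_index
    assert not refined.noisy_surroundings
    assert not refined.irregular_shape
    assert refined.area > 0
    # symmetric peak: apex RT near the midpoint of boundary RTs
    mid = 0.5 * (pic.rt[refined.left_index] + pic.rt[refined.right_index])
    width = pic.rt[refined.right_index] - pic.rt[refined.left_index]
    assert abs(refined.apex_rt - mid) <= 0.25 * width


def test_adjacent_shoulder_flags_noisy_surroundings():
    y = (gaussian_trace(60, apex=25, sigma=2.5, amplitude=1000.0)
         + gaussian_trace(60, apex=35, sigma=2.5, amplitude=950.0))
    pic = make_pic(y)
    peaks = detect_peaks(pic, ZAFParams())
    assert peaks, "both shoulder peaks should be detectable"
    refined = [refine_peak(pic, p, ZAFParams()) for p in peaks]
    assert any(r.noisy_surroundings for r in refined)


def test_apex_at_edge_is_clamped_and_flagged():
    y = gaussian_trace(20, apex=2, sigma=2.0, amplitude=1000.0)
    pic = make_pic(y)
    refined = refine_peak(pic, _peak(0, 2, 6), ZAFParams())
    assert refined.left_index == 0
    assert refined.edge_clamped


# --- invariances -----------------------------------------------------------

def test_translation_equivariance_and_intensity_scaling():
    rng = np.random.default_rng(5)
    y = gaussian_trace(50, apex=25, sigma=2.5, amplitude=2000.0,
                       baseline=20.0) + rng.normal(0, 10, 50)
    y = np.maximum(y, 0)
    base = find_and_refine(make_pic(y), ZAFParams())
    shifted = find_and_refine(make_pic(y, rt=np.arange(50) + 777.0), ZAFParams())
    scaled = find_and_refine(make_pic(y * 3.0), ZAFParams())
    assert len(base) == len(shifted) == len(scaled) == 1
    assert shifted[0].apex_rt == pytest.approx(base[0].apex_rt + 777.0)
    assert shifted[0].area == pytest.approx(base[0].area, rel=1e-9)
    assert scaled[0].apex_index == base[0].apex_index
    assert scaled[0].area == pytest.approx(3.0 * base[0].area, rel=1e-9)


def test_false_positive_rate_on_pure_noise():
    rng = np.random.default_rng(42)
    n_with_peaks = 0
    for _ in range(100):
        y = np.maximum(rng.normal(100, 10, 60), 0)
        if find_and_refine(make_pic(y), ZAFParams()):
            n_with_peaks += 1
    assert n_with_peaks <= 1  # <= 1% of noise PICs


def _oracle_apexes(y, params, noise_sigma):
    """Brute-force reference: local maxima of the smoothed trace with
    prominence >= snr_threshold * noise_sigma."""
    s = smooth_trace(np.asarray(y, float), params.smooth_window_scans)
    idx, _ = find_peaks(s, prominence=params.snr_threshold * noise_sigma)
    return sorted(idx)


def oracle_disagreements(seed, n_traces=200):
    """Count traces where ZAF detection and the independent
    smoothed-local-maximum oracle disagree on the apex set (beyond +-1)."""
    rng = np.random.default_rng(seed)
    params = ZAFParams()
    noise_sigma = 1.0
    disagreements = 0
    for _ in range(n_traces):
        n = int(rng.integers(26, 31))
        n_peaks = int(rng.integers(0, 3))
        centers = []
        y = np.full(n, 50.0)
        for _ in range(n_peaks):
            for _attempt in range(50):
                c = int(rng.integers(7, n - 7))
                if all(abs(c - e) >= 11 for e in centers):
                    centers.append(c)
                    y = y + gaussian_trace(n, apex=c, sigma=2.0,
                                           amplitude=float(rng.uniform(40, 100)))
                    break
        y = y + rng.normal(0, noise_sigma, n)
        got = sorted(p.apex_index for p in detect_peaks(make_pic(y), params))
        want = _oracle_apexes(y, params, noise_sigma)
        ok = len(got) == len(want) and all(
            abs(a - b) <= 1 for a, b in zip(got, want)
        )
        if not ok:
            disagreements += 1
    return disagreements


def test_zaf_agrees_with_smoothed_prominence_oracle():
    """On 200 short traces with well-formed peaks, ZAF detection and an
    independent smoothed-local-maximum oracle find the same apexes (+-1)."""
    assert oracle_disagreements(0) == 0
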