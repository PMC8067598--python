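"""Neutral-loss pair evaluation: filter truth table, scoping, conservation."""

import numpy as np
import pytest

from adductscan import (DIAWindow, MatchParams, deoxyribose_loss_mass,
                        evaluate_pair, filter_matches, match_run, match_window)
from adductscan.peak_detection import Peak

from conftest import make_pic

LOSS = deoxyribose_loss_mass()
WINDOW = DIAWindow(260.0, 280.0, 0)


def make_peak_pair(mz, apex_rt, half_width_s=15.0, area=2e4, irregular=False,
                   apex_intensity=1e4, n=11):
    """A PIC + refined Peak centred at apex_rt spanning +-half_width_s."""
    rt = np.linspace(apex_rt - half_width_s, apex_rt + half_width_s, n)
    x = np.linspace(-2, 2, n)
    pic = make_pic(apex_intensity * np.exp(-0.5 * x**2), rt=rt, mz=mz)
    peak = Peak(pic_ref="t", apex_index=n // 2, apex_rt=float(apex_rt),
                apex_intensity=apex_intensity, left_index=0, right_index=n - 1,
                area=area, irregular_shape=irregular)
    return pic, peak


def base_pair(**prec_kw):
    prec = make_peak_pair(268.1040, 300.0, **prec_kw)
    frag = make_peak_pair(268.1040 - LOSS, 300.0)
    return prec, frag


def test_ideal_pair_is_accepted_with_zero_loss_error():
    (ppic, ppeak), (fpic, fpeak) = base_pair()
    m = evaluate_pair(ppic, ppeak, fpic, fpeak, WINDOW)
    assert m.accepted and m.reject_reasons == []
    assert m.loss_error_ppm == pytest.approx(0.0, abs=1e-9)
    assert m.delta_da == pytest.approx(LOSS, abs=1e-9)
    assert m.overlap_frac == pytest.approx(1.0)


@pytest.mark.parametrize(
    "precursor, fragment, window, expected_reason",
    [
        # area just below the 1e4 counts*s floor
        (dict(mz=268.1040, rt=300.0, area=9e3),
         dict(mz=268.1040 - LOSS, rt=300.0), WINDOW, "low_area"),
        # mass difference off by 10 mDa (~37 ppm at m/z 268)
        (dict(mz=268.1040, rt=300.0),
         dict(mz=268.1040 - LOSS - 0.010, rt=300.0), WINDOW, "loss_out_of_tol"),
        # fragment elutes 60 s later
        (dict(mz=268.1040, rt=300.0),
         dict(mz=268.1040 - LOSS, rt=360.0), WINDOW, "rt_mismatch"),
        # precursor outside the window
        (dict(mz=290.0, rt=300.0),
         dict(mz=290.0 - LOSS, rt=300.0), WINDOW, "wrong_window"),
    ],
)
def test_single_filter_failures(precursor, fragment, window, expected_reason):
    ppic, ppeak = make_peak_pair(precursor["mz"], precursor["rt"],
                                 area=precursor.get("area", 2e4))
    fpic, fpeak = make_peak_pair(fragment["mz"], fragment["rt"])
    m = evaluate_pair(ppic, ppeak, fpic, fpeak, window)
    assert not m.accepted
    assert expected_reason in m.reject_reasons


def test_low_overlap_with_close_apexes():
    # precursor narrow and early within the fragment's long extent
    ppic, ppeak = make_peak_pair(268.1040, 300.0, half_width_s=4.0)
    frt = np.linspace(303.0, 362.0, 33)
    x = np.linspace(-0.1, 3.0, 33)
    fpic = make_pic(1e4 * np.exp(-0.5 * x**2), rt=frt, mz=268.1040 - LOSS)
    fpeak = Peak(pic_ref="t", apex_index=0, apex_rt=303.0, apex_intensity=1e4,
                 left_index=0, right_index=32, area=2e4)
    m = evaluate_pair(ppic, ppeak, fpic, fpeak, WINDOW)
    assert abs(m.rt_delta_s) <= 6.0
    assert m.overlap_frac < 0.5
    assert "low_overlap" in m.reject_reasons and not m.accepted


def test_irregular_shape_rejected_by_shape_filter():
    ppic, ppeak = make_peak_pair(268.1040, 300.0)
    fpic, fpeak = make_peak_pair(268.1040 - LOSS, 300.0, irregular=True)
    m = evaluate_pair(ppic, ppeak, fpic, fpeak, WINDOW)
    assert "bad_shape" in m.reject_reasons
    assert filter_matches([m]) == []


def test_accepted_iff_no_reject_reasons_conservation():
    pairs = []
    for d_area, d_mz, d_rt in [(0, 0, 0), (-1.5e4, 0, 0), (0, 0.02, 0),
                               (0, 0, 30.0), (0, 0.02, 30.0)]:
        ppic, ppeak = make_peak_pair(268.1040, 300.0, area=2e4 + d_area)
        fpic, fpeak = make_peak_pair(268.1040 - LOSS + d_mz, 300.0 + d_rt)
        pairs.append(evaluate_pair(ppic, ppeak, fpic, fpeak, WINDOW))
    accepted = filter_matches(pairs)
    rejected = [m for m in pairs if not m.accepted]
    assert len(accepted) + len(rejected) == len(pairs)
    assert all(m.reject_reasons for m in rejected)
    assert all(m.reject_reasons == [] for m in accepted)


def test_window_scoping_prevents_cross_window_pairs():
    prec = make_peak_pair(268.1040, 300.0)
    frag = make_peak_pair(268.1040 - LOSS, 300.0)
    # fragment listed under a different window's dataset: no candidates there
    other = DIAWindow(280.0, 300.0, 1)
    assert match_window([prec], [frag], other) == []
    # in the right window it matches
    got = match_window([prec], [frag], WINDOW)
    assert len(got) == 1 and got[0].accepted


def test_near_miss_recorded_as_rejected_candidate():
    # off by ~2x tolerance: still enumerated, rejected with provenance
    ppic, ppeak = make_peak_pair(268.1040, 300.0)
    off = 268.1040 * 20e-6  # 20 ppm in Da
    fpic, fpeak = make_peak_pair(268.1040 - LOSS - off, 300.0)
    got = match_window([(ppic, ppeak)], [(fpic, fpeak)], WINDOW)
    assert len(got) == 1
    assert not got[0].accepted
    assert got[0].reject_reasons == ["loss_out_of_tol"]


def test_multiplets_kept_and_ranked_by_loss_error():
    prec = make_peak_pair(268.1040, 300.0)
    frag_good = make_peak_pair(268.1040 - LOSS, 300.0)
    frag_worse = make_peak_pair(268.1040 - LOSS + 0.0015, 300.0)
    got = match_run([prec], {WINDOW: [frag_worse, frag_good]})
    assert len(got) == 2
    assert [m.multiplet_size for m in got] == [2, 2]
    assert abs(got[0].loss_error_ppm) <= abs(got[1].loss_error_ppm)


def test_widening_tolerances_never_loses_accepted_matches():
    prec = make_peak_pair(268.1040, 300.0)
    frag_off = make_peak_pair(268.1040 - LOSS - 0.002, 304.0)
    ms2 = {WINDOW: [frag_off]}
    counts = []
    for ppm, rt_tol in [(5, 2.0), (10, 6.0), (40, 12.0)]:
        params = MatchParams(loss_tol_ppm=ppm, rt_apex_tol_s=rt_tol)
        counts.append(len(filter_matches(match_run([prec], ms2, params), params)))
    assert counts == sorted(counts)
    assert counts[-1] == 1


def test_empty_inputs_give_empty_output():
    assert match_run([], {}) == []
    assert match_window([], [], WINDOW) == []
    assert filter_matches([]) == []
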