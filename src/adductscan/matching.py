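"""Neutral-loss matching of MS1 precursor peaks to MS2 fragment peaks.

A putative DNA adduct is a precursor peak in MS1 and a fragment peak in the
MS2 dataset of the isolation window containing the precursor, whose m/z
difference equals the deoxyribose neutral loss (C5H8O3, 116.0473 Da) within a
mass tolerance, and whose chromatographic peaks co-elute.  Every candidate
pair is evaluated exhaustively and kept with full accept/reject provenance, so
downstream review can see why each pair survived or fell.

Acceptance requires all of:

* loss error within ``loss_tol_ppm`` (ppm of the precursor m/z; an absolute
  mDa alternative is available),
* apex RT difference within ``rt_apex_tol_s``,
* RT-extent overlap of at least ``min_overlap_frac`` of the shorter peak,
* precursor peak area of at least ``min_precursor_area`` (default 1e4
  counts*s, which suppresses trace-level precursors),
* precursor m/z inside the window,
* neither peak flagged as irregular in shape.

Charge state is assumed z=1 throughout; neutral losses from multiply charged
precursors are a known false-positive class and are not corrected here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import deoxyribose_loss_mass
from .errors import ParameterError
from .msdata_io import DIAWindow
from .peak_detection import Peak
from .pic_extraction import PIC

__all__ = ["MatchParams", "NLMatch", "evaluate_pair", "match_window",
           "match_run", "filter_matches"]

#: factor widening the candidate-enumeration envelope beyond the acceptance
#: tolerance, so near-misses are recorded (rejected) instead of invisible
CANDIDATE_FACTOR = 3.0


@dataclass(frozen=True)
class MatchParams:
    """Matching thresholds.

    neutral_loss_da : the targeted neutral-loss mass; defaults to the
        computed C5H8O3 monoisotopic mass.
    loss_tol_ppm : tolerance on (precursor - fragment - loss), relative to the
        precursor m/z.  ``loss_tol_mda`` (absolute) overrides it when set.
    rt_apex_tol_s : maximum apex RT difference between the two peaks.
    min_overlap_frac : minimum fraction of the shorter peak's RT extent
        covered by the intersection of the two extents.
    min_precursor_area : precursor peak-area floor in counts*seconds.
    """

    neutral_loss_da: float = field(default_factory=deoxyribose_loss_mass)
    loss_tol_ppm: float = 10.0
    loss_tol_mda: float | None = None
    rt_apex_tol_s: float = 6.0
    min_overlap_frac: float = 0.5
    min_precursor_area: float = 1e4

    def __post_init__(self) -> None:
        if self.neutral_loss_da <= 0:
            raise ParameterError("neutral_loss_da must be positive")
        if self.loss_tol_mda is None and self.loss_tol_ppm <= 0:
            raise ParameterError("loss_tol_ppm must be positive")
        if self.loss_tol_mda is not None and self.loss_tol_mda <= 0:
            raise ParameterError("loss_tol_mda must be positive")
        if self.rt_apex_tol_s <= 0:
            raise ParameterError("rt_apex_tol_s must be positive")
        if not 0 < self.min_overlap_frac <= 1:
            raise ParameterError("min_overlap_frac must be in (0, 1]")
        if self.min_precursor_area < 0:
            raise ParameterError("min_precursor_area must be nonnegative")

    def loss_tol_da(self, precursor_mz: float) -> float:
        if self.loss_tol_mda is not None:
            return self.loss_tol_mda * 1e-3
        return precursor_mz * self.loss_tol_ppm * 1e-6


@dataclass
class NLMatch:
    """One evaluated precursor/fragment pair with full filter provenance."""

    precursor_pic: PIC
    precursor: Peak
    fragment_pic: PIC
    fragment: Peak
    window: DIAWindow
    delta_da: float
    loss_error_ppm: float
    rt_delta_s: float
    overlap_frac: float
    accepted: bool
    reject_reasons: list[str]
    multiplet_size: int = 1

    @property
    def precursor_mz(self) -> float:
        return self.precursor_pic.mz_mean

    @property
    def fragment_mz(self) -> float:
        return self.fragment_pic.mz_mean


def _overlap_frac(p: Peak, p_pic: PIC, f: Peak, f_pic: PIC) -> float:
    a0, a1 = p_pic.rt[p.left_index], p_pic.rt[p.right_index]
    b0, b1 = f_pic.rt[f.left_index], f_pic.rt[f.right_index]
    inter = min(a1, b1) - max(a0, b0)
    shorter = min(a1 - a0, b1 - b0)
    if shorter <= 0:
        return 0.0
    return max(0.0, float(inter / shorter))


def evaluate_pair(
    precursor_pic: PIC,
    precursor: Peak,
    fragment_pic: PIC,
    fragment: Peak,
    window: DIAWindow,
    params: MatchParams | None = None,
) -> NLMatch:
    """Evaluate one precursor/fragment pair against every acceptance filter,
    recording each failed criterion in ``reject_reasons``."""
    params = params or MatchParams()
    pmz = precursor_pic.mz_mean
    fmz = fragment_pic.mz_mean
    delta = pmz - fmz
    loss_err_ppm = (delta - params.neutral_loss_da) / pmz * 1e6
    rt_delta = precursor.apex_rt - fragment.apex_rt
    ov = _overlap_frac(precursor, precursor_pic, fragment, fragment_pic)

    reasons: list[str] = []
    if abs(delta - params.neutral_loss_da) > params.loss_tol_da(pmz):
        reasons.append("loss_out_of_tol")
    if abs(rt_delta) > params.rt_apex_tol_s:
        reasons.append("rt_mismatch")
    if ov < params.min_overlap_frac:
        reasons.append("low_overlap")
    if precursor.area < params.min_precursor_area:
        reasons.append("low_area")
    if precursor.irregular_shape or fragment.irregular_shape:
        reasons.append("bad_shape")
    if not window.contains(pmz):
        reasons.append("wrong_window")

    return NLMatch(
        precursor_pic=precursor_pic,
        precursor=precursor,
        fragment_pic=fragment_pic,
        fragment=fragment,
        window=window,
        delta_da=float(delta),
        loss_error_ppm=float(loss_err_ppm),
        rt_delta_s=float(rt_delta),
        overlap_frac=float(ov),
        accepted=not reasons,
        reject_reasons=reasons,
    )


def match_window(
    ms1_peaks: list[tuple[PIC, Peak]],
    ms2_peaks: list[tuple[PIC, Peak]],
    window: DIAWindow,
    params: MatchParams | None = None,
) -> list[NLMatch]:
    """Evaluate all precursor/fragment pairs for one isolation window.

    Precursors are restricted to those with mean m/z inside the window (the
    others can never have been fragmented into this window's MS2 scans).
    Candidate pairs are enumerated within ``CANDIDATE_FACTOR`` times the loss
    tolerance so near-misses appear in the output as rejected matches;
    enumeration is exhaustive within that envelope.
    """
    params = params or MatchParams()
    out: list[NLMatch] = []
    for p_pic, p_peak in ms1_peaks:
        pmz = p_pic.mz_mean
        if not window.contains(pmz):
            continue
        envelope = CANDIDATE_FACTOR * params.loss_tol_da(pmz)
        for f_pic, f_peak in ms2_peaks:
            delta = pmz - f_pic.mz_mean
            if abs(delta - params.neutral_loss_da) > envelope:
                continue
            out.append(
                evaluate_pair(p_pic, p_peak, f_pic, f_peak, window, params)
            )
    return out


def match_run(
    ms1_peaks: list[tuple[PIC, Peak]],
    ms2_peaks_by_window: dict[DIAWindow, list[tuple[PIC, Peak]]],
    params: MatchParams | None = None,
) -> list[NLMatch]:
    """Match over all windows, annotate multiplets, and order the result.

    When one precursor peak pairs with several fragment peaks (or vice versa)
    all pairs are kept, each annotated with its multiplet group size; the list
    is sorted by precursor m/z, then by absolute loss error so that within a
    multiplet the best mass match comes first.
    """
    params = params or MatchParams()
    matches: list[NLMatch] = []
    for window in sorted(ms2_peaks_by_window):
        matches.extend(
            match_window(ms1_peaks, ms2_peaks_by_window[window], window, params)
        )
    by_prec: dict[int, int] = {}
    by_frag: dict[int, int] = {}
    for m in matches:
        by_prec[id(m.precursor)] = by_prec.get(id(m.precursor), 0) + 1
        by_frag[id(m.fragment)] = by_frag.get(id(m.fragment), 0) + 1
    for m in matches:
        m.multiplet_size = max(by_prec[id(m.precursor)], by_frag[id(m.fragment)])
    matches.sort(key=lambda m: (m.precursor_mz, abs(m.loss_error_ppm)))
    return matches


def filter_matches(
    matches: list[NLMatch], params: MatchParams | None = None
) -> list[NLMatch]:
    """Accepted matches only: every numeric filter passed and neither peak has
    an irregular shape.  Every exclusion is attributable to a recorded
    reject reason."""
    return [m for m in matches if m.accepted]
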