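"""In-memory pipeline driver: run -> PICs -> peaks -> matches.

`analyze_run` is the library-level counterpart of the file-based
:func:`adductscan.reporting.run_pipeline`: it takes a parsed run and returns
every intermediate product, which is what scripted analyses and the recovery
benchmark want.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .matching import MatchParams, NLMatch, filter_matches, match_run
from .msdata_io import DIARun, DIAWindow, split_datasets
from .peak_detection import Peak, ZAFParams, find_and_refine
from .pic_extraction import PIC, PICParams, extract_pics

__all__ = ["RunAnalysis", "analyze_run"]


@dataclass
class RunAnalysis:
    """All intermediate and final products of one processed run."""

    ms1_pics: list[PIC]
    ms2_pics: dict[DIAWindow, list[PIC]]
    ms1_peaks: list[tuple[PIC, Peak]]
    ms2_peaks: dict[DIAWindow, list[tuple[PIC, Peak]]]
    candidates: list[NLMatch]
    accepted: list[NLMatch] = field(default_factory=list)

    @property
    def n_ms2_pics(self) -> int:
        return sum(len(v) for v in self.ms2_pics.values())

    @property
    def n_ms2_peaks(self) -> int:
        return sum(len(v) for v in self.ms2_peaks.values())


def _peaks_of(pics: list[PIC], params: ZAFParams) -> list[tuple[PIC, Peak]]:
    return [(pic, peak) for pic in pics for peak in find_and_refine(pic, params)]


def analyze_run(
    run: DIARun,
    pic_params: PICParams | None = None,
    zaf_params: ZAFParams | None = None,
    match_params: MatchParams | None = None,
) -> RunAnalysis:
    """Process a parsed DIA run through the full neutral-loss workflow."""
    pic_params = pic_params or PICParams()
    zaf_params = zaf_params or ZAFParams()
    match_params = match_params or MatchParams()
    ms1, ms2 = split_datasets(run)
    ms1_pics = extract_pics(ms1, pic_params, dataset_id="MS1")
    ms2_pics = {
        w: extract_pics(scans, pic_params, dataset_id=f"MS2[{w.lo:g},{w.hi:g})")
        for w, scans in ms2.items()
    }
    ms1_peaks = _peaks_of(ms1_pics, zaf_params)
    ms2_peaks = {w: _peaks_of(pics, zaf_params) for w, pics in ms2_pics.items()}
    candidates = match_run(ms1_peaks, ms2_peaks, match_params)
    accepted = filter_matches(candidates, match_params)
    return RunAnalysis(
        ms1_pics=ms1_pics,
        ms2_pics=ms2_pics,
        ms1_peaks=ms1_peaks,
        ms2_peaks=ms2_peaks,
        candidates=candidates,
        accepted=accepted,
    )
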