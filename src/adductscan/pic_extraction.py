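"""Pure-ion chromatogram (PIC) extraction.

A PIC is the intensity-vs-time trace of centroids that share one m/z (within a
mass tolerance) across consecutive scans of a single dataset.  Tracking is
greedy and deterministic: open traces, visited in order of accumulated
intensity (highest first), each claim the unclaimed centroid of the current
scan nearest in ppm to the trace's running intensity-weighted mean m/z; ties
break toward higher intensity, then lower m/z.  The running weighted mean (not
the last point) is the matching reference, which damps centroid jitter.

A trace survives up to ``max_gap`` consecutive dataset scans without a match;
traces shorter than ``min_points`` are discarded.  The mass tolerance is
relative (ppm) by default, with an absolute-mDa alternative for instruments
whose error is not mass-proportional.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .msdata_io import CentroidScan

__all__ = ["PICParams", "PIC", "extract_pics"]


@dataclass(frozen=True)
class PICParams:
    """Tracking parameters.

    mz_tol_ppm : relative tolerance for joining a centroid to a trace.
        Ignored when ``mz_tol_mda`` is set.
    max_gap : maximum consecutive dataset scans a trace may miss before it is
        closed (0 = must be present in every scan).
    min_points : minimum trace length for a PIC to be emitted.
    mz_tol_mda : optional absolute tolerance in milli-Da, overriding ppm.
    """

    mz_tol_ppm: float = 10.0
    max_gap: int = 1
    min_points: int = 5
    mz_tol_mda: float | None = None

    def __post_init__(self) -> None:
        if self.mz_tol_mda is None and self.mz_tol_ppm <= 0:
            raise ParameterError("mz_tol_ppm must be positive")
        if self.mz_tol_mda is not None and self.mz_tol_mda <= 0:
            raise ParameterError("mz_tol_mda must be positive")
        if self.max_gap < 0:
            raise ParameterError("max_gap must be >= 0")
        if self.min_points < 2:
            raise ParameterError("min_points must be >= 2")

    def tol_da(self, mz: float) -> float:
        """Tolerance half-width in Da at a given m/z."""
        if self.mz_tol_mda is not None:
            return self.mz_tol_mda * 1e-3
        return mz * self.mz_tol_ppm * 1e-6


@dataclass
class PIC:
    """One extracted trace.

    Point arrays are parallel and ordered by scan; ``scan_index`` is the
    position within the dataset (used for gap accounting), ``scan_ordinal``
    the position within the whole run.
    """

    dataset_id: str
    scan_ordinal: np.ndarray
    scan_index: np.ndarray
    rt: np.ndarray
    mz: np.ndarray
    intensity: np.ndarray

    @property
    def mz_mean(self) -> float:
        """Intensity-weighted mean m/z of the trace."""
        w = self.intensity.sum()
        if w <= 0:
            return float(self.mz.mean())
        return float(np.dot(self.mz, self.intensity) / w)

    def __len__(self) -> int:
        return len(self.mz)

    @property
    def rt_span(self) -> tuple[float, float]:
        return float(self.rt[0]), float(self.rt[-1])


class _Trace:
    __slots__ = ("scan_ordinal", "scan_index", "rt", "mz", "intensity",
                 "_wsum", "_wmzsum", "birth")

    def __init__(self, birth: int) -> None:
        self.scan_ordinal: list[int] = []
        self.scan_index: list[int] = []
        self.rt: list[float] = []
        self.mz: list[float] = []
        self.intensity: list[float] = []
        self._wsum = 0.0
        self._wmzsum = 0.0
        self.birth = birth

    def add(self, ordinal: int, index: int, rt: float, mz: float, inten: float) -> None:
        self.scan_ordinal.append(ordinal)
        self.scan_index.append(index)
        self.rt.append(rt)
        self.mz.append(mz)
        self.intensity.append(inten)
        self._wsum += inten
        self._wmzsum += inten * mz

    @property
    def ref_mz(self) -> float:
        if self._wsum <= 0:
            return self.mz[-1]
        return self._wmzsum / self._wsum

    @property
    def total_intensity(self) -> float:
        return self._wsum


def extract_pics(
    dataset: list[CentroidScan],
    params: PICParams | None = None,
    dataset_id: str = "",
) -> list[PIC]:
    """Trace PICs through one dataset (the MS1 scans, or one window's MS2
    scans), returning them sorted by mean m/z.

    Each centroid is assigned to at most one trace.  An empty dataset yields
    an empty list.
    """
    params = params or PICParams()
    open_traces: list[_Trace] = []
    done: list[_Trace] = []

    for idx, scan in enumerate(dataset):
        # retire traces that have exceeded the permitted gap
        still_open = []
        for tr in open_traces:
            if idx - tr.scan_index[-1] > params.max_gap + 1:
                done.append(tr)
            else:
                still_open.append(tr)
        open_traces = still_open

        mzs = scan.mz
        intens = scan.intensity
        claimed = np.zeros(len(mzs), dtype=bool)

        # strongest traces choose first
        order = sorted(
            range(len(open_traces)),
            key=lambda i: (-open_traces[i].total_intensity, open_traces[i].birth),
        )
        for ti in order:
            tr = open_traces[ti]
            ref = tr.ref_mz
            tol = params.tol_da(ref)
            lo = np.searchsorted(mzs, ref - tol, side="left")
            hi = np.searchsorted(mzs, ref + tol, side="right")
            best = -1
            best_key = None
            for j in range(lo, hi):
                if claimed[j]:
                    continue
                key = (abs(mzs[j] - ref), -intens[j], mzs[j])
                if best < 0 or key < best_key:
                    best, best_key = j, key
            if best >= 0:
                claimed[best] = True
                tr.add(scan.scan_ordinal, idx, scan.rt, float(mzs[best]),
                       float(intens[best]))

        # unclaimed centroids seed new traces
        for j in range(len(mzs)):
            if not claimed[j]:
                tr = _Trace(birth=len(done) + len(open_traces))
                tr.add(scan.scan_ordinal, idx, scan.rt, float(mzs[j]),
                       float(intens[j]))
                open_traces.append(tr)

    done.extend(open_traces)
    pics = [
        PIC(
            dataset_id=dataset_id,
            scan_ordinal=np.array(tr.scan_ordinal, dtype=int),
            scan_index=np.array(tr.scan_index, dtype=int),
            rt=np.array(tr.rt, dtype=float),
            mz=np.array(tr.mz, dtype=float),
            intensity=np.array(tr.intensity, dtype=float),
        )
        for tr in done
        if len(tr.mz) >= params.min_points
    ]
    pics.sort(key=lambda p: p.mz_mean)
    return pics
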