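"""Reading centroided DIA runs (mzXML/mzML) and splitting them into datasets.

A DIA acquisition cycles through one MS1 full scan followed by ``n`` MS2 scans,
each fragmenting everything inside one precursor isolation window.  The first
processing step is purely structural: group the scans into one MS1 dataset and
one MS2 dataset per window, so that chromatogram extraction can treat each
dataset as an independent, regularly revisited time series.

mzXML is read through :mod:`pyteomics.mzxml`.  mzML is read by a small
cvParam-aware reader built on lxml (see `_read_mzml`); it understands the
spectrum-level accessions needed here: ms level, centroid/profile mode, scan
start time with units, the precursor isolation window, and uncompressed or
zlib-compressed 32/64-bit float binary arrays.

Retention times are normalised to seconds on read regardless of dialect.
MS2 datasets are keyed by the isolation window (center, width) rounded to
4 decimal places, not by position within the cycle, so a dropped scan does not
shift window assignment.  Window intervals are half-open ``[lo, hi)``.
"""

from __future__ import annotations

import base64
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree

from .errors import FormatError, ParameterError, StructureError

__all__ = [
    "CentroidScan",
    "DIAWindow",
    "DIARun",
    "read_run",
    "split_datasets",
    "make_windows",
    "run_info",
]

_ROUND_DP = 4  # isolation (center, width) rounding for window keying


@dataclass(frozen=True)
class CentroidScan:
    """One centroided scan.

    ``isolation`` is the ``(center, width)`` of the precursor isolation window
    and is present exactly when ``ms_level == 2``.
    """

    scan_ordinal: int
    rt: float  # seconds
    ms_level: int
    mz: np.ndarray
    intensity: np.ndarray
    isolation: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.shape != inten.shape or mz.ndim != 1:
            raise StructureError(
                f"scan {self.scan_ordinal}: m/z and intensity arrays differ in shape"
            )
        if mz.size > 1 and not np.all(np.diff(mz) > 0):
            raise StructureError(f"scan {self.scan_ordinal}: m/z not strictly ascending")
        if np.any(inten < 0):
            raise StructureError(f"scan {self.scan_ordinal}: negative intensity")
        if self.rt < 0:
            raise StructureError(f"scan {self.scan_ordinal}: negative retention time")
        if self.ms_level == 2 and self.isolation is None:
            raise StructureError(
                f"scan {self.scan_ordinal}: MS2 scan lacks isolation window metadata"
            )
        if self.ms_level == 1 and self.isolation is not None:
            raise StructureError(f"scan {self.scan_ordinal}: MS1 scan carries isolation")


@dataclass(frozen=True, order=True)
class DIAWindow:
    """Half-open precursor isolation interval ``[lo, hi)``."""

    lo: float
    hi: float
    ordinal: int = field(compare=False, default=0)

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ParameterError(f"window lo ({self.lo}) must be < hi ({self.hi})")

    def contains(self, mz: float) -> bool:
        return self.lo <= mz < self.hi

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)

    @property
    def width(self) -> float:
        return self.hi - self.lo


@dataclass
class DIARun:
    """A parsed acquisition: ordered scans plus the inferred window table."""

    scans: list[CentroidScan]
    windows: list[DIAWindow]
    source: str = ""

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def n_cycles(self) -> int:
        return sum(1 for s in self.scans if s.ms_level == 1)

    @property
    def rt_range(self) -> tuple[float, float]:
        rts = [s.rt for s in self.scans]
        return (min(rts), max(rts)) if rts else (0.0, 0.0)

    def window_for(self, scan: CentroidScan) -> DIAWindow:
        """Map an MS2 scan's isolation metadata to its DIAWindow."""
        key = _window_key(scan.isolation)
        try:
            return self._window_index[key]
        except (AttributeError, KeyError):
            self._build_index()
            return self._window_index[key]

    def _build_index(self) -> None:
        self._window_index = {
            _window_key((w.center, w.width)): w for w in self.windows
        }


def _window_key(isolation: tuple[float, float]) -> tuple[float, float]:
    center, width = isolation
    return (round(center, _ROUND_DP), round(width, _ROUND_DP))


def _infer_windows(scans: list[CentroidScan]) -> list[DIAWindow]:
    seen: dict[tuple[float, float], None] = {}
    for s in scans:
        if s.ms_level == 2:
            seen.setdefault(_window_key(s.isolation), None)
    if not seen:
        raise StructureError("no MS2 scans: not a DIA run")
    intervals = sorted((c - w / 2.0, c + w / 2.0) for c, w in seen)
    for (lo1, hi1), (lo2, _) in zip(intervals, intervals[1:]):
        if lo2 < hi1 - 10 ** (-_ROUND_DP):
            raise StructureError(
                f"overlapping isolation windows: [{lo1}, {hi1}) and lo {lo2}"
            )
    return [DIAWindow(lo, hi, ordinal=i) for i, (lo, hi) in enumerate(intervals)]


# ---------------------------------------------------------------------------
# mzXML (pyteomics)
# ---------------------------------------------------------------------------

def _rt_seconds(rt) -> float:
    """pyteomics returns retentionTime as a unitfloat; normalise to seconds."""
    unit = getattr(rt, "unit_info", None)
    if unit and "second" in str(unit):
        return float(rt)
    # mzXML retentionTime is reported in minutes by pyteomics
    return float(rt) * 60.0


def _read_mzxml(path: str) -> list[CentroidScan]:
    from pyteomics import mzxml

    scans: list[CentroidScan] = []
    try:
        reader = mzxml.MzXML(path)
    except Exception as exc:  # unparseable under the standard
        raise FormatError(f"cannot parse {path} as mzXML: {exc}") from exc
    with reader:
        for i, rec in enumerate(reader):
            if rec.get("centroided") is False:
                raise FormatError(
                    f"scan {rec.get('num', i)} is profile-mode; centroided data required"
                )
            level = int(rec["msLevel"])
            isolation = None
            if level == 2:
                prec = rec.get("precursorMz")
                if not prec:
                    raise StructureError(
                        f"MS2 scan {rec.get('num', i)} lacks precursor isolation metadata"
                    )
                center = float(prec[0]["precursorMz"])
                width = float(prec[0].get("windowWideness", 0.0))
                if width <= 0:
                    raise StructureError(
                        f"MS2 scan {rec.get('num', i)}: missing/zero isolation window width"
                    )
                isolation = (center, width)
            scans.append(
                CentroidScan(
                    scan_ordinal=i,
                    rt=_rt_seconds(rec["retentionTime"]),
                    ms_level=level,
                    mz=rec["m/z array"],
                    intensity=rec["intensity array"],
                    isolation=isolation,
                )
            )
    return scans


# ---------------------------------------------------------------------------
# mzML (lxml)
# ---------------------------------------------------------------------------

_ACC_MS_LEVEL = "MS:1000511"
_ACC_CENTROID = "MS:1000127"
_ACC_PROFILE = "MS:1000128"
_ACC_SCAN_START = "MS:1000016"
_ACC_ISO_TARGET = "MS:1000827"
_ACC_ISO_LOWER = "MS:1000828"
_ACC_ISO_UPPER = "MS:1000829"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"


def _cv(elem, accession):
    """First cvParam with the given accession anywhere under elem, else None."""
    for cv in elem.iter("{*}cvParam"):
        if cv.get("accession") == accession:
            return cv
    return None


def _decode_binary(bda) -> np.ndarray:
    raw = base64.b64decode((bda.findtext("{*}binary") or "").strip())
    if _cv(bda, _ACC_ZLIB) is not None:
        raw = zlib.decompress(raw)
    dtype = "<f8" if _cv(bda, _ACC_F64) is not None else "<f4"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml(path: str) -> list[CentroidScan]:
    scans: list[CentroidScan] = []
    try:
        context = etree.iterparse(path, events=("end",), tag="{*}spectrum")
        i = 0
        for _, spec in context:
            level_cv = _cv(spec, _ACC_MS_LEVEL)
            if level_cv is None:
                spec.clear()
                continue
            level = int(level_cv.get("value"))
            if _cv(spec, _ACC_PROFILE) is not None:
                raise FormatError(
                    f"spectrum {spec.get('id', i)} is profile-mode; centroided data required"
                )
            rt_cv = None
            for scan_el in spec.iter("{*}scan"):
                rt_cv = _cv(scan_el, _ACC_SCAN_START)
                if rt_cv is not None:
                    break
            if rt_cv is None:
                raise StructureError(f"spectrum {spec.get('id', i)}: no scan start time")
            rt = float(rt_cv.get("value"))
            if "minute" in (rt_cv.get("unitName") or ""):
                rt *= 60.0
            isolation = None
            if level == 2:
                iso_el = next(spec.iter("{*}isolationWindow"), None)
                if iso_el is None:
                    raise StructureError(
                        f"MS2 spectrum {spec.get('id', i)} lacks an isolation window"
                    )
                target = _cv(iso_el, _ACC_ISO_TARGET)
                lower = _cv(iso_el, _ACC_ISO_LOWER)
                upper = _cv(iso_el, _ACC_ISO_UPPER)
                if target is None or lower is None or upper is None:
                    raise StructureError(
                        f"MS2 spectrum {spec.get('id', i)}: incomplete isolation window"
                    )
                center = float(target.get("value"))
                width = float(lower.get("value")) + float(upper.get("value"))
                isolation = (center, width)
            mz_arr = inten_arr = None
            for bda in spec.iter("{*}binaryDataArray"):
                if _cv(bda, _ACC_MZ_ARRAY) is not None:
                    mz_arr = _decode_binary(bda)
                elif _cv(bda, _ACC_INT_ARRAY) is not None:
                    inten_arr = _decode_binary(bda)
            if mz_arr is None or inten_arr is None:
                raise StructureError(
                    f"spectrum {spec.get('id', i)}: missing m/z or intensity array"
                )
            scans.append(
                CentroidScan(
                    scan_ordinal=i,
                    rt=rt,
                    ms_level=level,
                    mz=mz_arr,
                    intensity=inten_arr,
                    isolation=isolation,
                )
            )
            i += 1
            spec.clear()
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"cannot parse {path} as mzML: {exc}") from exc
    return scans


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def read_run(path: str | Path, format: str | None = None) -> DIARun:
    """Read a centroided DIA run from mzXML or mzML.

    Parameters
    ----------
    path
        Input file.  ``format`` is inferred from the extension when omitted.
    format
        ``"mzXML"`` or ``"mzML"`` (case-insensitive).

    Raises
    ------
    FormatError
        File not parseable under the named standard, or profile-mode spectra.
    StructureError
        No MS2 scans, or an MS2 scan without isolation metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "mzxml":
        scans = _read_mzxml(str(path))
    elif fmt == "mzml":
        scans = _read_mzml(str(path))
    else:
        raise ParameterError(f"unknown format {format!r}: expected mzXML or mzML")
    if not scans:
        raise StructureError(f"{path}: no scans")
    rts = [s.rt for s in scans]
    if any(b < a - 1e-9 for a, b in zip(rts, rts[1:])):
        raise StructureError(f"{path}: retention times not nondecreasing")
    windows = _infer_windows(scans)
    run = DIARun(scans=scans, windows=windows, source=str(path))
    run._build_index()
    return run


def split_datasets(
    run: DIARun,
) -> tuple[list[CentroidScan], dict[DIAWindow, list[CentroidScan]]]:
    """Partition the run's scans into the MS1 dataset and one MS2 dataset per
    isolation window, preserving acquisition order.

    The outputs are a partition: every scan lands in exactly one dataset.
    """
    ms1 = [s for s in run.scans if s.ms_level == 1]
    ms2: dict[DIAWindow, list[CentroidScan]] = {w: [] for w in run.windows}
    for s in run.scans:
        if s.ms_level == 2:
            ms2[run.window_for(s)].append(s)
    return ms1, ms2


def make_windows(range_lo: float, range_hi: float, width: float) -> list[DIAWindow]:
    """Tile ``[range_lo, range_hi)`` with contiguous windows of equal width.

    The span must be an integer multiple of the width.
    """
    if not range_hi > range_lo:
        raise ParameterError("range_hi must exceed range_lo")
    if width <= 0:
        raise ParameterError("width must be positive")
    span = range_hi - range_lo
    n = round(span / width)
    if n < 1 or abs(n * width - span) > 1e-6 * max(1.0, span):
        raise ParameterError(
            f"precursor range {range_lo}-{range_hi} is not an integer multiple "
            f"of window width {width}"
        )
    edges = range_lo + width * np.arange(n + 1)
    edges[-1] = range_hi
    return [
        DIAWindow(float(edges[i]), float(edges[i + 1]), ordinal=i) for i in range(n)
    ]


def run_info(run: DIARun) -> dict:
    """Run metadata for display: window table, cycle count, RT range."""
    lo, hi = run.rt_range
    return {
        "source": run.source,
        "n_scans": len(run.scans),
        "n_ms1": sum(1 for s in run.scans if s.ms_level == 1),
        "n_ms2": sum(1 for s in run.scans if s.ms_level == 2),
        "n_windows": run.n_windows,
        "n_cycles": run.n_cycles,
        "rt_start_s": lo,
        "rt_end_s": hi,
        "windows": [(w.lo, w.hi) for w in run.windows],
    }
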