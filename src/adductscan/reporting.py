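"""Match-table export, the adductome map, and the end-to-end pipeline.

The exported CSV has one row per evaluated precursor/fragment pair, with the
retention time, m/z, apex intensity, peak area and point count of both peaks,
the window, the mass-difference diagnostics, and the accept/reject provenance.
The adductome map is the sample's adduct fingerprint: precursor m/z against
elution time for accepted matches, marker area linear in precursor peak area.

`run_pipeline` drives read -> split -> PIC extraction -> peak detection ->
matching -> filtering -> export.  Given the same input file and configuration
it is deterministic: repeated runs produce byte-identical outputs; wall-clock
timing appears only in the log.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd
import yaml

from .errors import AdductScanError, ParameterError
from .matching import MatchParams, NLMatch, filter_matches, match_run
from .msdata_io import read_run, split_datasets
from .peak_detection import ZAFParams, find_and_refine
from .pic_extraction import PICParams, extract_pics

__all__ = [
    "CSV_COLUMNS",
    "match_records",
    "export_csv",
    "sort_matches",
    "adductome_map",
    "PipelineConfig",
    "run_pipeline",
]

CSV_COLUMNS = [
    "precursor_rt_s",
    "precursor_mz",
    "precursor_intensity",
    "precursor_area",
    "precursor_n_points",
    "fragment_rt_s",
    "fragment_mz",
    "fragment_intensity",
    "fragment_area",
    "fragment_n_points",
    "window_lo",
    "window_hi",
    "delta_da",
    "loss_error_ppm",
    "overlap_frac",
    "accepted",
    "reject_reasons",
]


def match_records(matches: list[NLMatch]) -> pd.DataFrame:
    """Flatten matches into the fixed-schema export table."""
    rows = []
    for m in matches:
        rows.append(
            {
                "precursor_rt_s": m.precursor.apex_rt,
                "precursor_mz": m.precursor_mz,
                "precursor_intensity": m.precursor.apex_intensity,
                "precursor_area": m.precursor.area,
                "precursor_n_points": m.precursor.n_points,
                "fragment_rt_s": m.fragment.apex_rt,
                "fragment_mz": m.fragment_mz,
                "fragment_intensity": m.fragment.apex_intensity,
                "fragment_area": m.fragment.area,
                "fragment_n_points": m.fragment.n_points,
                "window_lo": m.window.lo,
                "window_hi": m.window.hi,
                "delta_da": m.delta_da,
                "loss_error_ppm": m.loss_error_ppm,
                "overlap_frac": m.overlap_frac,
                "accepted": m.accepted,
                "reject_reasons": ";".join(m.reject_reasons),
            }
        )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def export_csv(matches: list[NLMatch], path: str | Path) -> None:
    """Write the match table as UTF-8 RFC-4180-style CSV with a header row.

    Output is deterministic; writing the same matches twice yields
    byte-identical files.
    """
    match_records(matches).to_csv(path, index=False, lineterminator="\n")


_SORT_KEYS = {"rt", "mz", "intensity"}


def sort_matches(matches: list[NLMatch], key: str = "rt") -> list[NLMatch]:
    """Stable sort by a precursor attribute: ``rt`` and ``mz`` ascending,
    ``intensity`` descending (most intense first)."""
    if key not in _SORT_KEYS:
        raise ParameterError(f"unknown sort key {key!r}: expected one of {_SORT_KEYS}")
    if key == "rt":
        return sorted(matches, key=lambda m: m.precursor.apex_rt)
    if key == "mz":
        return sorted(matches, key=lambda m: m.precursor_mz)
    return sorted(matches, key=lambda m: -m.precursor.apex_intensity)


def marker_sizes(areas: list[float], max_marker_pt2: float = 300.0) -> list[float]:
    """Marker areas (pt^2) linear in peak area, largest peak at the cap."""
    amax = max(areas)
    return [max_marker_pt2 * a / amax for a in areas]


def adductome_map(
    matches: list[NLMatch],
    path: str | Path,
    max_marker_pt2: float = 300.0,
) -> None:
    """Scatter of precursor m/z against elution time; marker area linear in
    precursor peak area, with the reference scale stated in the legend."""
    fig, ax = plt.subplots(figsize=(7, 5))
    if matches:
        rts = [m.precursor.apex_rt for m in matches]
        mzs = [m.precursor_mz for m in matches]
        areas = [m.precursor.area for m in matches]
        amax = max(areas)
        sizes = marker_sizes(areas, max_marker_pt2)
        ax.scatter(
            rts,
            mzs,
            s=sizes,
            alpha=0.55,
            edgecolors="navy",
            facecolors="steelblue",
            label=f"marker area scale: {amax:.3g} counts·s = {max_marker_pt2:g} pt²",
        )
        ax.legend(loc="best", fontsize=8)
    ax.set_xlabel("elution time (s)")
    ax.set_ylabel("precursor m/z")
    ax.set_title("Adductome map")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class PipelineConfig:
    """Flat run configuration; every value is echoed into the run report."""

    input: str = ""
    out_dir: str = "adductscan_out"
    input_format: str | None = None
    # PIC extraction (shared by MS1 and MS2 datasets unless ms2_* given)
    mz_tol_ppm: float = 10.0
    max_gap: int = 1
    min_points: int = 5
    # peak detection
    kernel_sigma_scans: float = 2.0
    snr_threshold: float = 5.0
    min_peak_points: int = 5
    smooth_window_scans: int = 5
    # matching
    loss_tol_ppm: float = 10.0
    rt_apex_tol_s: float = 6.0
    min_overlap_frac: float = 0.5
    min_precursor_area: float = 1e4
    sort_key: str = "rt"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def pic_params(self) -> PICParams:
        return PICParams(
            mz_tol_ppm=self.mz_tol_ppm, max_gap=self.max_gap,
            min_points=self.min_points,
        )

    def zaf_params(self) -> ZAFParams:
        return ZAFParams(
            kernel_sigma_scans=self.kernel_sigma_scans,
            snr_threshold=self.snr_threshold,
            min_peak_points=self.min_peak_points,
            smooth_window_scans=self.smooth_window_scans,
        )

    def match_params(self) -> MatchParams:
        return MatchParams(
            loss_tol_ppm=self.loss_tol_ppm,
            rt_apex_tol_s=self.rt_apex_tol_s,
            min_overlap_frac=self.min_overlap_frac,
            min_precursor_area=self.min_precursor_area,
        )


def _detect_all(pics, params):
    out = []
    for pic in pics:
        for peak in find_and_refine(pic, params):
            out.append((pic, peak))
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write matches.csv, adductome_map.png,
    run_report.yaml and log.txt into the output directory.

    Returns the run report (parameter echo plus per-stage counts).  On a
    stage failure, partial outputs are removed and the error is re-raised
    with the stage name.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = [
        out_dir / "matches.csv",
        out_dir / "adductome_map.png",
        out_dir / "run_report.yaml",
    ]
    log_path = out_dir / "log.txt"
    log_lines: list[str] = []
    t0 = time.monotonic()

    def log(msg: str) -> None:
        log_lines.append(f"[{time.strftime('%Y-%m-%dT%H:%M:%S')}] {msg}")

    stage = "read"
    try:
        log(f"reading {config.input}")
        run = read_run(config.input, config.input_format)

        stage = "split"
        ms1, ms2 = split_datasets(run)
        log(f"{len(run.scans)} scans, {run.n_windows} windows, "
            f"{run.n_cycles} cycles")

        stage = "pic_extraction"
        pic_params = config.pic_params()
        ms1_pics = extract_pics(ms1, pic_params, dataset_id="MS1")
        ms2_pics = {
            w: extract_pics(scans, pic_params, dataset_id=f"MS2[{w.lo:g},{w.hi:g})")
            for w, scans in ms2.items()
        }
        n_ms2_pics = sum(len(p) for p in ms2_pics.values())
        log(f"PICs: {len(ms1_pics)} MS1, {n_ms2_pics} MS2")

        stage = "peak_detection"
        zaf = config.zaf_params()
        ms1_peaks = _detect_all(ms1_pics, zaf)
        ms2_peaks = {w: _detect_all(pics, zaf) for w, pics in ms2_pics.items()}
        n_ms2_peaks = sum(len(p) for p in ms2_peaks.values())
        log(f"peaks: {len(ms1_peaks)} MS1, {n_ms2_peaks} MS2")

        stage = "matching"
        mparams = config.match_params()
        candidates = match_run(ms1_peaks, ms2_peaks, mparams)
        accepted = filter_matches(candidates, mparams)
        log(f"candidates: {len(candidates)}, accepted: {len(accepted)}")

        stage = "export"
        ordered = sort_matches(candidates, config.sort_key)
        export_csv(ordered, out_dir / "matches.csv")
        adductome_map(accepted, out_dir / "adductome_map.png")

        report = {
            "parameters": asdict(config),
            "counts": {
                "n_scans": len(run.scans),
                "n_ms1_scans": len(ms1),
                "n_ms2_scans": sum(len(v) for v in ms2.values()),
                "n_windows": run.n_windows,
                "n_cycles": run.n_cycles,
                "n_ms1_pics": len(ms1_pics),
                "n_ms2_pics": n_ms2_pics,
                "n_ms1_peaks": len(ms1_peaks),
                "n_ms2_peaks": n_ms2_peaks,
                "n_candidates": len(candidates),
                "n_accepted": len(accepted),
                "n_rejected": len(candidates) - len(accepted),
            },
        }
        (out_dir / "run_report.yaml").write_text(
            yaml.safe_dump(report, sort_keys=True)
        )
        log(f"done in {time.monotonic() - t0:.2f} s")
        log_path.write_text("\n".join(log_lines) + "\n")
        return report
    except Exception as exc:
        for p in outputs:
            p.unlink(missing_ok=True)
        log(f"stage '{stage}' failed: {exc}")
        log_path.write_text("\n".join(log_lines) + "\n")
        if isinstance(exc, AdductScanError):
            raise type(exc)(f"stage '{stage}': {exc}") from exc
        raise AdductScanError(f"stage '{stage}': {exc}") from exc
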