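"""Synthetic DIA runs with known ground truth.

The generator emulates the acquisition this package targets: interleaved
cycles of one MS1 full scan followed by one MS2 scan per precursor isolation
window.  Spiked species are nucleoside-adduct-like precursor/fragment pairs
("true" specs, whose m/z difference is exactly the deoxyribose neutral loss)
and decoys (whose difference deliberately is not).  Each species elutes as a
Gaussian over a constant baseline sampled in every scan of its dataset;
centroid m/z values carry ppm-scale jitter; chemical noise centroids with
log-normal intensities are sprinkled uniformly over the mass range.

Everything is reproducible from the seed, and a ground-truth manifest records
each spec with its expected window and apex so recovery can be scored.

Runs are written as mzXML (the dialect vendor converters commonly produce) or
mzML; both writers emit centroided 64-bit uncompressed peak data and
round-trip exactly through :func:`adductscan.msdata_io.read_run`.
"""

from __future__ import annotations

import base64
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import deoxyribose_loss_mass, nucleoside_ion_table
from .errors import ParameterError
from .matching import NLMatch
from .msdata_io import CentroidScan, DIAWindow, make_windows

__all__ = [
    "AdductSpec",
    "SimConfig",
    "GroundTruth",
    "builtin_adduct_library",
    "default_manifest",
    "generate_run",
    "generate_scans",
    "write_mzxml",
    "write_mzml",
    "score_recovery",
]


@dataclass(frozen=True)
class AdductSpec:
    """One spiked species.

    For true adducts ``fragment_mz == precursor_mz - 116.0473`` (the
    deoxyribose loss); decoys carry an arbitrary fragment m/z.  Charge is
    assumed 1.
    """

    name: str
    precursor_mz: float
    fragment_mz: float
    rt_center: float  # seconds
    rt_sigma: float = 5.0  # seconds
    amplitude: float = 5e4  # counts at apex
    is_true: bool = True
    fragment_fraction: float = 0.4  # fragment apex relative to precursor

    def __post_init__(self) -> None:
        if self.rt_sigma <= 0 or self.amplitude <= 0:
            raise ParameterError("rt_sigma and amplitude must be positive")
        if self.is_true:
            expected = self.precursor_mz - deoxyribose_loss_mass()
            if abs(self.fragment_mz - expected) > 1e-4:
                raise ParameterError(
                    f"{self.name}: true spec fragment m/z must equal precursor "
                    f"minus the deoxyribose loss (got {self.fragment_mz}, "
                    f"expected {expected:.4f})"
                )


@dataclass(frozen=True)
class SimConfig:
    """Acquisition geometry and noise model for one simulated run."""

    windows: tuple[DIAWindow, ...] = tuple(make_windows(190.0, 370.0, 20.0))
    cycle_period_s: float = 3.5
    run_length_s: float = 240.0
    mz_jitter_ppm: float = 2.0
    noise_peaks_per_scan: float = 8.0
    noise_intensity_scale: float = 300.0
    baseline: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.windows:
            raise ParameterError("at least one DIA window required")
        for v in (self.cycle_period_s, self.run_length_s, self.mz_jitter_ppm,
                  self.noise_peaks_per_scan, self.noise_intensity_scale,
                  self.baseline):
            if v < 0:
                raise ParameterError("SimConfig values must be nonnegative")


@dataclass
class GroundTruth:
    """Manifest of everything spiked into one generated run."""

    specs: list[AdductSpec]
    config: SimConfig
    detectable: dict[str, bool] = field(default_factory=dict)
    window_of: dict[str, DIAWindow | None] = field(default_factory=dict)

    @property
    def true_specs(self) -> list[AdductSpec]:
        return [s for s in self.specs if s.is_true]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.specs:
            w = self.window_of.get(s.name)
            rows.append(
                {
                    "name": s.name,
                    "is_true": s.is_true,
                    "precursor_mz": s.precursor_mz,
                    "fragment_mz": s.fragment_mz,
                    "rt_center_s": s.rt_center,
                    "rt_sigma_s": s.rt_sigma,
                    "amplitude": s.amplitude,
                    "window_lo": w.lo if w else np.nan,
                    "window_hi": w.hi if w else np.nan,
                    "detectable": self.detectable.get(s.name, False),
                    "seed": self.config.seed,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def builtin_adduct_library() -> list[AdductSpec]:
    """Template specs for the four canonical deoxynucleosides plus 5-me-dC,
    N6-me-dA and 8-oxo-dG, with ion m/z computed from molecular formulas.

    RT centers/amplitudes are placeholders; callers reposition them.
    """
    out = []
    for i, ion in enumerate(nucleoside_ion_table()):
        out.append(
            AdductSpec(
                name=ion.name,
                precursor_mz=ion.precursor_mz,
                fragment_mz=ion.fragment_mz,
                rt_center=60.0 + 20.0 * i,
                rt_sigma=5.0,
                amplitude=1e5,
                is_true=True,
            )
        )
    return out


def _window_containing(windows, mz: float) -> DIAWindow | None:
    for w in windows:
        if w.contains(mz):
            return w
    return None


def default_manifest(
    seed: int,
    n_true: int = 10,
    n_decoy: int = 10,
    cfg: SimConfig | None = None,
) -> list[AdductSpec]:
    """A study-condition spec set: the four unmodified nucleosides as dominant
    background species, modified nucleosides and random adduct-like pairs up
    to ``n_true``, plus ``n_decoy`` decoys whose precursor/fragment difference
    is kept at least 0.03 Da away from the neutral loss.

    All precursor m/z are mutually separated by >= 0.05 Da (and likewise
    fragments within one window) so species produce distinct chromatograms,
    and no cross-pairing of any precursor with any fragment accidentally
    reproduces the neutral loss.
    """
    cfg = cfg or SimConfig(seed=seed)
    rng = np.random.default_rng(seed)
    loss = deoxyribose_loss_mass()
    lo = min(w.lo for w in cfg.windows)
    hi = max(w.hi for w in cfg.windows)
    margin = min(30.0, cfg.run_length_s / 4.0)
    rt_lo, rt_hi = margin, cfg.run_length_s - margin

    library = builtin_adduct_library()
    specs: list[AdductSpec] = []
    used_pmz: list[float] = []
    used_fmz: list[float] = []

    def clashes(pmz: float, fmz: float) -> bool:
        if any(abs(pmz - u) < 0.05 for u in used_pmz):
            return True
        if any(abs(fmz - u) < 0.05 for u in used_fmz):
            return True
        # no accidental neutral-loss relation across species
        for u in used_fmz:
            if abs((pmz - u) - loss) < 0.03:
                return True
        for u in used_pmz:
            if abs((u - fmz) - loss) < 0.03:
                return True
        return False

    def add(spec: AdductSpec) -> None:
        specs.append(spec)
        used_pmz.append(spec.precursor_mz)
        used_fmz.append(spec.fragment_mz)

    # dominant unmodified nucleosides first (dG, dA, dC, dT)
    for tmpl in library[:4]:
        if len(specs) >= n_true:
            break
        if not (lo <= tmpl.precursor_mz < hi):
            continue
        add(replace(
            tmpl,
            rt_center=float(rng.uniform(rt_lo, rt_hi)),
            amplitude=float(rng.uniform(5e5, 2e6)),
        ))
    # modified nucleosides, then random adduct-like pairs
    for tmpl in library[4:]:
        if len(specs) >= n_true:
            break
        if not (lo <= tmpl.precursor_mz < hi) or clashes(
            tmpl.precursor_mz, tmpl.fragment_mz
        ):
            continue
        add(replace(
            tmpl,
            rt_center=float(rng.uniform(rt_lo, rt_hi)),
            amplitude=float(rng.uniform(2e4, 2e5)),
        ))
    k = 0
    while len(specs) < n_true:
        pmz = float(rng.uniform(lo + 1.0, hi - 1.0))
        fmz = pmz - loss
        if clashes(pmz, fmz):
            continue
        k += 1
        add(AdductSpec(
            name=f"adduct-{k}",
            precursor_mz=pmz,
            fragment_mz=fmz,
            rt_center=float(rng.uniform(rt_lo, rt_hi)),
            amplitude=float(rng.uniform(2e4, 2e5)),
            is_true=True,
        ))
    d = 0
    while d < n_decoy:
        pmz = float(rng.uniform(lo + 1.0, hi - 1.0))
        offset = float(rng.uniform(0.05, 1.0)) * (1 if rng.random() < 0.5 else -1)
        fmz = pmz - loss + offset
        if fmz < 50.0 or clashes(pmz, fmz):
            continue
        d += 1
        add(AdductSpec(
            name=f"decoy-{d}",
            precursor_mz=pmz,
            fragment_mz=fmz,
            rt_center=float(rng.uniform(rt_lo, rt_hi)),
            amplitude=float(rng.uniform(2e4, 2e5)),
            is_true=False,
        ))
    return specs


# ---------------------------------------------------------------------------
# Signal synthesis
# ---------------------------------------------------------------------------

def _gauss(t: float, center: float, sigma: float) -> float:
    return float(np.exp(-0.5 * ((t - center) / sigma) ** 2))


def _finalize(mz: list[float], inten: list[float]) -> tuple[np.ndarray, np.ndarray]:
    if not mz:
        return np.empty(0), np.empty(0)
    m = np.asarray(mz)
    v = np.asarray(inten)
    order = np.argsort(m, kind="stable")
    m, v = m[order], v[order]
    # force strict ascent on (vanishingly rare) exact collisions
    for i in range(1, len(m)):
        if m[i] <= m[i - 1]:
            m[i] = np.nextafter(m[i - 1], np.inf)
    return m, np.maximum(v, 0.0)


def generate_scans(
    specs: list[AdductSpec], cfg: SimConfig
) -> tuple[list[CentroidScan], GroundTruth]:
    """Synthesize the scan list and ground-truth manifest (no file I/O)."""
    rng = np.random.default_rng(cfg.seed)
    windows = list(cfg.windows)
    n = len(windows)
    loss_support = 3.0  # sigmas of elution profile emitted above baseline
    mz_lo = min(w.lo for w in windows)
    mz_hi = max(w.hi for w in windows)

    gt = GroundTruth(specs=list(specs), config=cfg)
    for s in specs:
        w = _window_containing(windows, s.precursor_mz)
        gt.window_of[s.name] = w
        gt.detectable[s.name] = (
            w is not None and 0.0 <= s.rt_center <= cfg.run_length_s
        )

    def jitter(mz: float) -> float:
        return mz * (1.0 + rng.normal(0.0, cfg.mz_jitter_ppm * 1e-6))

    scans: list[CentroidScan] = []
    ordinal = 0
    t_cycle = 0.0
    while t_cycle <= cfg.run_length_s:
        # MS1 full scan
        mzs: list[float] = []
        vals: list[float] = []
        for s in specs:
            level = cfg.baseline + s.amplitude * _gauss(t_cycle, s.rt_center, s.rt_sigma)
            level += rng.normal(0.0, cfg.noise_intensity_scale)
            if abs(t_cycle - s.rt_center) > loss_support * s.rt_sigma:
                level = cfg.baseline + rng.normal(0.0, cfg.noise_intensity_scale * 0.2)
            mzs.append(jitter(s.precursor_mz))
            vals.append(level)
        if cfg.noise_intensity_scale > 0:
            for _ in range(rng.poisson(cfg.noise_peaks_per_scan)):
                mzs.append(float(rng.uniform(mz_lo, mz_hi)))
                vals.append(
                    float(rng.lognormal(np.log(cfg.noise_intensity_scale), 0.5))
                )
        m, v = _finalize(mzs, vals)
        scans.append(CentroidScan(ordinal, t_cycle, 1, m, v))
        ordinal += 1
        # MS2 scans, one per window
        for j, w in enumerate(windows):
            t = t_cycle + (j + 1) * cfg.cycle_period_s / (n + 1)
            mzs, vals = [], []
            for s in specs:
                if gt.window_of[s.name] != w:
                    continue
                amp = s.amplitude * s.fragment_fraction
                level = cfg.baseline + amp * _gauss(t, s.rt_center, s.rt_sigma)
                level += rng.normal(0.0, cfg.noise_intensity_scale)
                if abs(t - s.rt_center) > loss_support * s.rt_sigma:
                    level = cfg.baseline + rng.normal(
                        0.0, cfg.noise_intensity_scale * 0.2
                    )
                mzs.append(jitter(s.fragment_mz))
                vals.append(level)
            if cfg.noise_intensity_scale > 0:
                for _ in range(rng.poisson(cfg.noise_peaks_per_scan)):
                    mzs.append(float(rng.uniform(50.0, w.hi)))
                    vals.append(
                        float(rng.lognormal(np.log(cfg.noise_intensity_scale), 0.5))
                    )
            m, v = _finalize(mzs, vals)
            scans.append(
                CentroidScan(ordinal, t, 2, m, v, isolation=(w.center, w.width))
            )
            ordinal += 1
        t_cycle += cfg.cycle_period_s
    return scans, gt


def generate_run(
    specs: list[AdductSpec],
    cfg: SimConfig,
    path: str | Path,
    fmt: str = "mzXML",
) -> GroundTruth:
    """Generate a run, write it to ``path`` in mzXML or mzML, and return the
    ground-truth manifest.  Identical (specs, cfg) yield byte-identical files."""
    scans, gt = generate_scans(specs, cfg)
    fmt_l = fmt.lower()
    if fmt_l == "mzxml":
        write_mzxml(path, scans)
    elif fmt_l == "mzml":
        write_mzml(path, scans)
    else:
        raise ParameterError(f"unknown format {fmt!r}: expected mzXML or mzML")
    return gt


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _b64(arr_interleaved: np.ndarray, dtype: str) -> str:
    return base64.b64encode(np.asarray(arr_interleaved, dtype=dtype).tobytes()).decode()


def write_mzxml(path: str | Path, scans: list[CentroidScan]) -> None:
    """Minimal centroided mzXML 3.2 (64-bit, network byte order, no
    compression); MS2 scans carry precursorMz with windowWideness."""
    lines = [
        '<?xml version="1.0" encoding="ISO-8859-1"?>',
        '<mzXML xmlns="http://sashimi.sourceforge.net/schema_revision/mzXML_3.2">',
        f' <msRun scanCount="{len(scans)}">',
    ]
    for s in scans:
        inter = np.empty(2 * len(s.mz))
        inter[0::2] = s.mz
        inter[1::2] = s.intensity
        b64 = _b64(inter, ">f8")
        lines.append(
            f'  <scan num="{s.scan_ordinal + 1}" msLevel="{s.ms_level}" '
            f'retentionTime="PT{s.rt!r}S" peaksCount="{len(s.mz)}" centroided="1">'
        )
        if s.ms_level == 2:
            center, width = s.isolation
            lines.append(
                f'   <precursorMz precursorIntensity="0" '
                f'windowWideness="{width!r}">{center!r}</precursorMz>'
            )
        lines.append(
            '   <peaks compressionType="none" compressedLen="0" precision="64" '
            f'byteOrder="network" contentType="m/z-int">{b64}</peaks>'
        )
        lines.append("  </scan>")
    lines += [" </msRun>", "</mzXML>", ""]
    Path(path).write_text("\n".join(lines), encoding="ascii")


def write_mzml(path: str | Path, scans: list[CentroidScan]) -> None:
    """Minimal centroided mzML 1.1 (64-bit little-endian, no compression)."""
    parts = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        '<run id="run">',
        f'<spectrumList count="{len(scans)}">',
    ]
    for i, s in enumerate(scans):
        mz_b64 = _b64(s.mz, "<f8")
        int_b64 = _b64(s.intensity, "<f8")
        parts.append(
            f'<spectrum index="{i}" id="scan={i + 1}" '
            f'defaultArrayLength="{len(s.mz)}">'
        )
        parts.append(
            f'<cvParam cvRef="MS" accession="MS:1000511" name="ms level" '
            f'value="{s.ms_level}"/>'
        )
        parts.append(
            '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>'
        )
        parts.append(
            '<scanList count="1"><scan>'
            f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" '
            f'value="{s.rt!r}" unitCvRef="UO" unitAccession="UO:0000010" '
            'unitName="second"/></scan></scanList>'
        )
        if s.ms_level == 2:
            center, width = s.isolation
            half = width / 2.0
            parts.append(
                "<precursorList count=\"1\"><precursor><isolationWindow>"
                f'<cvParam cvRef="MS" accession="MS:1000827" '
                f'name="isolation window target m/z" value="{center!r}" unitName="m/z"/>'
                f'<cvParam cvRef="MS" accession="MS:1000828" '
                f'name="isolation window lower offset" value="{half!r}" unitName="m/z"/>'
                f'<cvParam cvRef="MS" accession="MS:1000829" '
                f'name="isolation window upper offset" value="{half!r}" unitName="m/z"/>'
                "</isolationWindow></precursor></precursorList>"
            )
        for accession, name, b64 in (
            ("MS:1000514", "m/z array", mz_b64),
            ("MS:1000515", "intensity array", int_b64),
        ):
            parts.append(
                f'<binaryDataArray encodedLength="{len(b64)}">'
                '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
                '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
                f'<cvParam cvRef="MS" accession="{accession}" name="{name}" value=""/>'
                f"<binary>{b64}</binary></binaryDataArray>"
            )
        parts.append("</spectrum>")
    parts += ["</spectrumList>", "</run>", "</mzML>", ""]
    Path(path).write_text("\n".join(parts), encoding="ascii")


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_recovery(
    matches: list[NLMatch],
    manifest: GroundTruth,
    mz_tol_ppm: float = 10.0,
    rt_tol_s: float = 10.0,
) -> dict:
    """Score accepted matches against the ground truth.

    A match is credited to a spec when its precursor m/z is within
    ``mz_tol_ppm`` and its precursor apex RT within ``rt_tol_s`` of the spec.
    Duplicate matches to one spec count once for recall; each accepted match
    is judged individually for precision.
    """
    if not manifest.specs:
        raise ParameterError("manifest is empty; nothing to score against")
    true_specs = manifest.true_specs
    if not true_specs:
        raise ParameterError("manifest contains no true specs")

    def credited(spec: AdductSpec, m: NLMatch) -> bool:
        return (
            abs(m.precursor_mz - spec.precursor_mz)
            <= spec.precursor_mz * mz_tol_ppm * 1e-6
            and abs(m.precursor.apex_rt - spec.rt_center) <= rt_tol_s
        )

    verdicts: dict[str, bool] = {}
    for spec in true_specs:
        verdicts[spec.name] = any(credited(spec, m) for m in matches)
    n_credit_match = sum(
        1 for m in matches if any(credited(s, m) for s in true_specs)
    )
    decoy_hits = [
        m
        for m in matches
        if any(credited(s, m) for s in manifest.specs if not s.is_true)
    ]
    expected = [s for s in true_specs if manifest.detectable.get(s.name, False)]
    recall = (
        sum(verdicts[s.name] for s in expected) / len(expected) if expected else 0.0
    )
    precision = n_credit_match / len(matches) if matches else 1.0
    return {
        "recall": recall,
        "precision": precision,
        "n_true": len(expected),
        "n_accepted": len(matches),
        "n_decoy_accepted": len(decoy_hits),
        "verdicts": verdicts,
    }
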