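import numpy as np
import pytest

from adductscan import (CentroidScan, PIC, SimConfig, default_manifest,
                        generate_run, read_run)


def make_pic(intensity, rt=None, mz=268.104, dataset_id="t", rt_step=1.0):
    """Build a PIC directly from an intensity trace (testing helper)."""
    intensity = np.asarray(intensity, dtype=float)
    n = len(intensity)
    rt = np.arange(n) * rt_step if rt is None else np.asarray(rt, dtype=float)
    return PIC(
        dataset_id=dataset_id,
        scan_ordinal=np.arange(n),
        scan_index=np.arange(n),
        rt=rt,
        mz=np.full(n, float(mz)),
        intensity=intensity,
    )


def gaussian_trace(n, apex, sigma, amplitude, baseline=0.0):
    x = np.arange(n, dtype=float)
    return baseline + amplitude * np.exp(-0.5 * ((x - apex) / sigma) ** 2)


def make_scans(rows, window=None):
    """rows: list of (rt, ms_level, [mz...], [intensity...])."""
    scans = []
    for i, (rt, level, mzs, intens) in enumerate(rows):
        iso = window if level == 2 else None
        scans.append(CentroidScan(i, rt, level, np.asarray(mzs, float),
                                  np.asarray(intens, float), isolation=iso))
    return scans


@pytest.fixture(scope="session")
def seeded_run(tmp_path_factory):
    """One default synthetic run (seed 7) with its manifest, read back."""
    path = tmp_path_factory.mktemp("runs") / "run7.mzXML"
    cfg = SimConfig(seed=7)
    specs = default_manifest(7, cfg=cfg)
    gt = generate_run(specs, cfg, path)
    return read_run(path), gt, path
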