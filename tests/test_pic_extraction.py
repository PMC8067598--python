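"""PIC tracking: gap tolerance, ppm grouping, oracle equivalence."""

import numpy as np
import pytest

from adductscan import CentroidScan, PICParams, extract_pics


def dataset_from_species(species, n_scans, rng=None, jitter_ppm=0.0):
    """species: dict name -> (mz, {scan_index: intensity}).  Missing scans
    simply omit the centroid."""
    scans = []
    for i in range(n_scans):
        mzs, intens = [], []
        for mz, per_scan in species.values():
            if i in per_scan:
                m = mz
                if jitter_ppm and rng is not None:
                    m = mz * (1 + rng.normal(0, jitter_ppm * 1e-6))
                mzs.append(m)
                intens.append(per_scan[i])
        order = np.argsort(mzs)
        scans.append(
            CentroidScan(i, float(i), 1, np.asarray(mzs)[order],
                         np.asarray(intens)[order])
        )
    return scans


def test_single_species_single_pic():
    species = {"a": (268.104, {i: 1000.0 for i in range(10)})}
    pics = extract_pics(dataset_from_species(species, 10), PICParams())
    assert len(pics) == 1
    assert len(pics[0]) == 10
    assert pics[0].mz_mean == pytest.approx(268.104, rel=1e-6)


def test_gap_rule_splits_or_bridges():
    per_scan = {i: 1000.0 for i in range(10) if i != 5}
    species = {"a": (268.104, per_scan)}
    bridged = extract_pics(dataset_from_species(species, 10),
                           PICParams(max_gap=1, min_points=3))
    assert len(bridged) == 1 and len(bridged[0]) == 9

    split = extract_pics(dataset_from_species(species, 10),
                         PICParams(max_gap=0, min_points=3))
    assert sorted(len(p) for p in split) == [4, 5]
    # with min_points=5 only the longer fragment survives
    split5 = extract_pics(dataset_from_species(species, 10),
                          PICParams(max_gap=0, min_points=5))
    assert [len(p) for p in split5] == [5]


def test_coeluting_species_50ppm_apart_stay_separate():
    mz = 268.104
    species = {
        "a": (mz, {i: 1000.0 for i in range(10)}),
        "b": (mz * (1 + 50e-6), {i: 800.0 for i in range(10)}),
    }
    pics = extract_pics(dataset_from_species(species, 10),
                        PICParams(mz_tol_ppm=10))
    assert len(pics) == 2
    means = sorted(p.mz_mean for p in pics)
    assert means[0] == pytest.approx(mz, rel=1e-6)
    assert means[1] == pytest.approx(mz * (1 + 50e-6), rel=1e-6)


def test_points_within_tolerance_of_mean():
    rng = np.random.default_rng(0)
    species = {"a": (268.104, {i: float(rng.uniform(500, 2000)) for i in range(20)})}
    params = PICParams(mz_tol_ppm=10)
    pics = extract_pics(dataset_from_species(species, 20, rng, jitter_ppm=2.0),
                        params)
    assert len(pics) == 1
    p = pics[0]
    assert np.all(np.abs(p.mz - p.mz_mean) / p.mz_mean <= params.mz_tol_ppm * 1e-6)
    # points strictly increasing in scan, gaps within limit
    assert np.all(np.diff(p.scan_index) >= 1)
    assert np.all(np.diff(p.scan_index) <= params.max_gap + 1)


def test_empty_dataset_gives_empty_list():
    assert extract_pics([], PICParams()) == []


def _brute_force_pics(scans, params):
    """Independent grouping oracle for well-separated species: cluster all
    centroids by ppm connectivity on m/z alone, then chain each cluster in
    scan order, splitting on gaps beyond max_gap and dropping short traces."""
    allpts = [
        (i, float(mz), float(v))
        for i, s in enumerate(scans)
        for mz, v in zip(s.mz, s.intensity)
    ]
    allpts.sort(key=lambda t: t[1])
    clusters, current = [], []
    for pt in allpts:
        if current and (pt[1] - current[-1][1]) / pt[1] > 2 * params.mz_tol_ppm * 1e-6:
            clusters.append(current)
            current = []
        current.append(pt)
    if current:
        clusters.append(current)
    traces = []
    for cl in clusters:
        cl.sort(key=lambda t: t[0])
        run = [cl[0]]
        for pt in cl[1:]:
            if pt[0] - run[-1][0] > params.max_gap + 1:
                traces.append(run)
                run = []
            run.append(pt)
        traces.append(run)
    return sorted(
        frozenset((i, mz) for i, mz, _ in tr)
        for tr in traces
        if len(tr) >= params.min_points
    )


@pytest.mark.parametrize("seed", range(5))
def test_matches_brute_force_oracle_on_small_instances(seed):
    rng = np.random.default_rng(seed)
    params = PICParams(mz_tol_ppm=10, max_gap=1, min_points=4)
    n_scans = int(rng.integers(8, 20))
    n_species = int(rng.integers(2, 10))
    # species separated by >= 100 ppm so any correct grouping is unique
    base = 200.0
    species = {}
    for k in range(n_species):
        base *= 1 + 150e-6
        present = {i: float(rng.uniform(100, 5000))
                   for i in range(n_scans) if rng.random() > 0.2}
        species[f"s{k}"] = (base, present)
    scans = dataset_from_species(species, n_scans, rng, jitter_ppm=1.0)
    pics = extract_pics(scans, params)
    got = {frozenset(zip(p.scan_index.tolist(), p.mz.tolist())) for p in pics}
    assert got == set(_brute_force_pics(scans, params))


def test_loosening_parameters_never_unassigns_centroids():
    rng = np.random.default_rng(3)
    species = {
        f"s{k}": (200.0 * (1 + 200e-6) ** k,
                  {i: float(rng.uniform(100, 5000))
                   for i in range(15) if rng.random() > 0.25})
        for k in range(6)
    }
    scans = dataset_from_species(species, 15, rng, jitter_ppm=1.0)

    def assigned(params):
        return sum(len(p) for p in extract_pics(scans, params))

    tight = assigned(PICParams(mz_tol_ppm=5, max_gap=0, min_points=5))
    looser_tol = assigned(PICParams(mz_tol_ppm=20, max_gap=0, min_points=5))
    looser_gap = assigned(PICParams(mz_tol_ppm=5, max_gap=2, min_points=5))
    lower_min = assigned(PICParams(mz_tol_ppm=5, max_gap=0, min_points=3))
    assert looser_tol >= tight
    assert looser_gap >= tight
    assert lower_min >= tight
    # assignment is a partial function of the centroids
    total = sum(len(s.mz) for s in scans)
    for params in (PICParams(), PICParams(mz_tol_ppm=20, max_gap=2, min_points=2)):
        assert sum(len(p) for p in extract_pics(scans, params)) <= total
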