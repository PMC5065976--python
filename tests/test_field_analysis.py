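"""Field derivation and dose metrics against independent brute-force oracles."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voxdcs import (
    GridSpec,
    LabelVolume,
    build_sigma_volume,
    current_density,
    default_catalogue,
    electric_field,
    icnirp_average,
    longitudinal_ratio,
    match_peak_dose,
    slice_cv,
    spread_to_structure,
    spread_within,
    tissue_stats,
)
from voxdcs.field_analysis import AnalysisError, VectorField
from voxdcs.solver import PotentialField
from voxdcs.volume import ConductivityVolume

from conftest import random_field_fixture

GRAY = default_catalogue().tissue_id("Brain gray matter")
NERVE = default_catalogue().tissue_id("Nerve")
CEREB = default_catalogue().tissue_id("Cerebellum")


def _uniform_phi(shape, fn, tissue="Muscle", spacing=1.0):
    """PotentialField with phi = fn(x, y, z in mm) on a single-tissue block."""
    cat = default_catalogue()
    grid = GridSpec(shape=shape, spacing=spacing)
    labels = np.full(shape, cat.tissue_id(tissue), dtype=np.int16)
    vol = LabelVolume(grid=grid, labels=labels)
    x, y, z = np.meshgrid(*(grid.coords(a) for a in range(3)), indexing="ij")
    phi = PotentialField(
        grid=grid, phi=fn(x, y, z), anode=np.zeros(shape, bool),
        cathode=np.zeros(shape, bool), residual=0.0, iterations=0, voltage=1.0,
    )
    return vol, phi


# --- gradient --------------------------------------------------------------


def test_linear_potential_gives_uniform_field():
    vol, phi = _uniform_phi((8, 8, 8), lambda x, y, z: -x)  # phi in V, x in mm
    sigma = build_sigma_volume(vol)
    E = electric_field(phi, sigma, vol)
    assert np.allclose(E.components[0], 1000.0)  # -d(-x)/dx = 1 V/mm = 1000 V/m
    assert np.allclose(E.components[1], 0.0)
    assert np.allclose(E.components[2], 0.0)


def test_constant_potential_gives_zero_field():
    vol, phi = _uniform_phi((6, 6, 6), lambda x, y, z: np.ones_like(x))
    E = electric_field(phi, build_sigma_volume(vol), vol)
    assert np.all(E.magnitude() == 0.0)


def test_quadratic_potential_central_difference_exact():
    """Central differences are exact for quadratics at interior voxels."""
    vol, phi = _uniform_phi((12, 4, 4), lambda x, y, z: x**2 / 1000.0)
    E = electric_field(phi, build_sigma_volume(vol), vol)
    x = vol.grid.coords(0)
    expected = -2.0 * x  # -d(x^2)/dx in V/m given the mm/V scaling used
    interior = slice(1, -1)
    assert np.allclose(E.components[0][interior, 2, 2], expected[interior])


def test_gradient_respects_tissue_boundaries():
    """One-sided differences keep interface jumps out of each tissue."""
    cat = default_catalogue()
    grid = GridSpec(shape=(10, 3, 3), spacing=1.0)
    labels = np.full(grid.shape, cat.tissue_id("Muscle"), dtype=np.int16)
    labels[5:] = cat.tissue_id("Fat")
    vol = LabelVolume(grid=grid, labels=labels)
    # piecewise-linear potential with a slope break at the interface
    phi_arr = np.where(
        np.arange(10)[:, None, None] < 5,
        0.001 * np.arange(10)[:, None, None],
        0.005 + 0.003 * (np.arange(10)[:, None, None] - 5),
    ).astype(float) * np.ones(grid.shape)
    phi = PotentialField(grid=grid, phi=phi_arr, anode=np.zeros(grid.shape, bool),
                         cathode=np.zeros(grid.shape, bool), residual=0.0,
                         iterations=0, voltage=1.0)
    E = electric_field(phi, build_sigma_volume(vol), vol)
    ex = E.components[0]
    assert np.allclose(ex[:5], -1.0)   # 0.001 V/mm slope
    assert np.allclose(ex[5:], -3.0)


# --- current density -------------------------------------------------------


def test_current_density_is_sigma_times_field():
    cat = default_catalogue()
    grid = GridSpec(shape=(4, 4, 4), spacing=1.0)
    labels = np.full(grid.shape, cat.tissue_id("Cerebro spinal fluid (CSF)"),
                     dtype=np.int16)
    vol = LabelVolume(grid=grid, labels=labels)
    sigma = build_sigma_volume(vol)
    E = VectorField(grid=grid,
                    components=(np.ones(grid.shape), np.zeros(grid.shape),
                                np.zeros(grid.shape)),
                    mask=np.ones(grid.shape, bool))
    J = current_density(E, sigma)
    assert np.allclose(J.magnitude(), 2.0)  # sigma_CSF = 2 S/m


def test_current_density_zero_in_air():
    grid = GridSpec(shape=(4, 4, 4), spacing=1.0)
    sigma = ConductivityVolume(grid=grid, sigma=np.zeros(grid.shape))
    E = VectorField(grid=grid, components=(np.ones(grid.shape),) * 3,
                    mask=np.ones(grid.shape, bool))
    assert np.all(current_density(E, sigma).magnitude() == 0.0)


def test_heart_conversion_consistency():
    """sigma_heart * 3.6 V/m ~ 0.19 A/m^2."""
    assert 0.0537 * 3.6 == pytest.approx(0.19, abs=0.005)


def test_current_density_grid_mismatch():
    grid = GridSpec(shape=(4, 4, 4), spacing=1.0)
    other = ConductivityVolume(grid=GridSpec(shape=(5, 5, 5), spacing=1.0),
                               sigma=np.ones((5, 5, 5)))
    E = VectorField(grid=grid, components=(np.ones(grid.shape),) * 3,
                    mask=np.ones(grid.shape, bool))
    with pytest.raises(AnalysisError):
        current_density(E, other)


# --- ICNIRP averaging ------------------------------------------------------


def _label_field(labels, comps, spacing=1.0):
    labels = np.asarray(labels, dtype=np.int16)
    grid = GridSpec(shape=labels.shape, spacing=spacing)
    vol = LabelVolume(grid=grid, labels=labels)
    comps = tuple(np.asarray(c, dtype=float) for c in comps)
    return vol, VectorField(grid=grid, components=comps,
                            mask=np.ones(labels.shape, bool))


def test_averaging_identity_on_uniform_field():
    shape = (6, 6, 6)
    vol, E = _label_field(np.full(shape, GRAY), [np.full(shape, v) for v in (1, 2, 3)])
    out = icnirp_average(E, vol, window_mm=2.0)
    for c, v in zip(out.components, (1, 2, 3)):
        assert np.allclose(c, v)


def test_averaging_cancels_opposite_vectors():
    """Vector (not magnitude) averaging: +v and -v cancel to zero."""
    labels = np.full((2, 1, 1), GRAY)
    ex = np.array([[[1.0]], [[-1.0]]])
    vol, E = _label_field(labels, (ex, np.zeros_like(ex), np.zeros_like(ex)))
    out = icnirp_average(E, vol, window_mm=2.0)
    assert np.allclose(out.components[0], 0.0)


def test_averaging_restricted_to_same_tissue():
    """A window straddling two tissues only averages the center's tissue."""
    labels = np.array([[[GRAY, GRAY, 45]]]).reshape(3, 1, 1)  # 2 gray + 1 CSF
    ex = np.array([2.0, 4.0, 100.0]).reshape(3, 1, 1)
    vol, E = _label_field(labels, (ex, np.zeros_like(ex), np.zeros_like(ex)))
    out = icnirp_average(E, vol, window_mm=2.0)
    # brute force: voxel 0 averages {2,4}; voxel 1's window {1,2} includes
    # the CSF voxel, which is excluded, leaving {4}; voxel 2 averages {100}
    assert out.components[0][0, 0, 0] == pytest.approx(3.0)
    assert out.components[0][1, 0, 0] == pytest.approx(4.0)
    assert out.components[0][2, 0, 0] == pytest.approx(100.0)


def test_averaging_window_below_spacing_rejected():
    vol, E = _label_field(np.full((3, 3, 3), GRAY), [np.ones((3, 3, 3))] * 3,
                          spacing=4.0)
    with pytest.raises(AnalysisError, match="window"):
        icnirp_average(E, vol, window_mm=2.0)


@pytest.mark.parametrize("seed", range(5))
def test_averaging_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    vol, E = random_field_fixture(rng, shape=(5, 5, 5), n_tissues=3)
    out = icnirp_average(E, vol, window_mm=2.0)
    s = 2

    def start(i, n):  # window shifted inward at lattice edges
        return min(max(i - (s - 1) // 2, 0), n - s)

    for i in range(5):
        for j in range(5):
            for k in range(5):
                acc = np.zeros(3)
                n = 0
                for ii in range(start(i, 5), start(i, 5) + s):
                    for jj in range(start(j, 5), start(j, 5) + s):
                        for kk in range(start(k, 5), start(k, 5) + s):
                            if vol.labels[ii, jj, kk] != vol.labels[i, j, k]:
                                continue
                            acc += [c[ii, jj, kk] for c in E.components]
                            n += 1
                for c, a in zip(out.components, acc / n):
                    assert c[i, j, k] == pytest.approx(a)


def test_averaging_never_increases_tissue_max():
    rng = np.random.default_rng(0)
    for _ in range(10):
        vol, E = random_field_fixture(rng, shape=(7, 7, 7), n_tissues=2)
        out = icnirp_average(E, vol, window_mm=3.0)
        for tid in np.unique(vol.labels):
            m = vol.labels == tid
            assert out.magnitude()[m].max() <= E.magnitude()[m].max() + 1e-12


# --- descriptive statistics ------------------------------------------------


def _brute_percentile(values, q):
    """Independent linear-interpolation percentile (sorted-sample rule)."""
    v = sorted(values)
    pos = (len(v) - 1) * q / 100.0
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    return v[lo] + (v[hi] - v[lo]) * (pos - lo)


def test_stats_on_ramp():
    shape = (100, 1, 1)
    labels = np.full(shape, GRAY)
    ex = np.arange(1.0, 101.0).reshape(shape)
    vol, E = _label_field(labels, (ex, np.zeros(shape), np.zeros(shape)))
    st_ = tissue_stats(E, vol, "Brain gray matter")
    assert st_.median == pytest.approx(50.5)
    assert st_.p99 == pytest.approx(99.01)
    assert st_.p99 == pytest.approx(_brute_percentile(range(1, 101), 99))
    assert st_.min == 1.0
    assert st_.voxel_count == 100


def test_stats_constant_field():
    shape = (4, 4, 4)
    vol, E = _label_field(np.full(shape, GRAY), (np.full(shape, 2.5),
                                               np.zeros(shape), np.zeros(shape)))
    st_ = tissue_stats(E, vol, "Brain gray matter")
    assert st_.min == st_.q25 == st_.median == st_.q75 == st_.p99 == 2.5


def test_stats_absent_tissue_rejected():
    shape = (3, 3, 3)
    vol, E = _label_field(np.full(shape, GRAY), [np.ones(shape)] * 3)
    with pytest.raises(AnalysisError, match="absent"):
        tissue_stats(E, vol, "Liver")


@pytest.mark.parametrize("seed", range(20))
def test_stats_match_brute_force(seed):
    rng = np.random.default_rng(100 + seed)
    vol, E = random_field_fixture(rng, shape=(8, 8, 8), n_tissues=3)
    mag = E.magnitude()
    for tid in np.unique(vol.labels):
        name = vol.catalogue.tissue_name(int(tid))
        vals = mag[vol.labels == tid]
        st_ = tissue_stats(E, vol, name)
        assert st_.min == pytest.approx(min(vals))
        for q, got in ((25, st_.q25), (50, st_.median), (75, st_.q75),
                       (99, st_.p99)):
            assert got == pytest.approx(_brute_percentile(vals, q))


# --- spread metrics --------------------------------------------------------


def test_spread_constant_field_is_100pct():
    shape = (5, 5, 5)
    vol, E = _label_field(np.full(shape, GRAY), (np.full(shape, 1.0),
                                               np.zeros(shape), np.zeros(shape)))
    v50, v70 = spread_within(E, vol, "Brain gray matter")
    assert v50 == 100.0 and v70 == 100.0


def test_spread_two_level_fixture_matches_count():
    shape = (100, 1, 1)
    ex = np.full(shape, 0.1)
    ex[:10] = 1.0
    vol, E = _label_field(np.full(shape, GRAY), (ex, np.zeros(shape),
                                               np.zeros(shape)))
    v50, v70 = spread_within(E, vol, "Brain gray matter")
    peak = _brute_percentile(ex.ravel(), 99)
    expected_v70 = 100.0 * sum(1 for v in ex.ravel() if v >= 0.7 * peak) / 100
    assert v70 == pytest.approx(expected_v70)
    assert v50 >= v70


@pytest.mark.parametrize("seed", range(20))
def test_spread_matches_brute_force(seed):
    rng = np.random.default_rng(200 + seed)
    vol, E = random_field_fixture(rng, shape=(8, 8, 8), n_tissues=2)
    mag = np.abs(E.magnitude())
    for tid in np.unique(vol.labels):
        name = vol.catalogue.tissue_name(int(tid))
        vals = mag[vol.labels == tid]
        peak = _brute_percentile(vals, 99)
        v50, v70 = spread_within(E, vol, name)
        assert v50 == pytest.approx(
            100.0 * sum(1 for v in vals if v >= 0.5 * peak) / len(vals)
        )
        assert v70 == pytest.approx(
            100.0 * sum(1 for v in vals if v >= 0.7 * peak) / len(vals)
        )
        assert 0.0 <= v70 <= v50 <= 100.0


def test_spread_to_structure_extremes_and_brute_force():
    shape = (10, 1, 1)
    labels = np.full(shape, GRAY)
    labels[5:] = 44  # cerebellum
    ex = np.linspace(0.1, 1.0, 10).reshape(shape)
    vol, E = _label_field(labels, (ex, np.zeros(shape), np.zeros(shape)))
    assert spread_to_structure(E, vol, "Brain gray matter", 10.0) == 0.0
    assert spread_to_structure(E, vol, "Brain gray matter", 0.01) == 100.0
    ref = 0.5
    got = spread_to_structure(E, vol, "Brain gray matter", ref)
    vals = ex.ravel()[:5]
    assert got == pytest.approx(100.0 * sum(1 for v in vals if v > 0.7 * ref) / 5)
    with pytest.raises(AnalysisError):
        spread_to_structure(E, vol, "Brain gray matter", 0.0)


# --- slice profiles --------------------------------------------------------


def _profile_fixture(slice_values, tissue_id=NERVE):
    """Column of z-slices; each slice holds the given |E| values as E_x."""
    nz = len(slice_values)
    width = max(len(v) for v in slice_values)
    labels = np.zeros((width, 1, nz), dtype=np.int16)
    ex = np.zeros((width, 1, nz))
    for z, vals in enumerate(slice_values):
        labels[: len(vals), 0, z] = tissue_id
        ex[: len(vals), 0, z] = vals
    grid = GridSpec(shape=labels.shape, spacing=1.0)
    vol = LabelVolume(grid=grid, labels=labels)
    E = VectorField(grid=grid, components=(ex, np.zeros_like(ex),
                                           np.zeros_like(ex)),
                    mask=np.ones(labels.shape, bool))
    return vol, E


def test_cv_zero_for_constant_slices():
    vol, E = _profile_fixture([[2.0, 2.0], [3.0, 3.0]])
    prof = slice_cv(E, vol, "Nerve", {"seg": (0, 1)})
    assert prof.values == [0.0, 0.0]
    assert prof.segment_means["seg"] == 0.0


def test_cv_hand_computed_population_sd():
    vol, E = _profile_fixture([[1.0, 3.0], [2.0, 2.0]])
    prof = slice_cv(E, vol, "Nerve", {"seg": (0, 1)})
    assert prof.values[0] == pytest.approx(50.0)  # sd=1 (population), mean=2
    assert prof.segment_means["seg"] == pytest.approx(25.0)


def test_cv_excludes_single_voxel_slices():
    vol, E = _profile_fixture([[1.0, 3.0], [5.0]])
    prof = slice_cv(E, vol, "Nerve", {"seg": (0, 1)})
    assert prof.slices == [0]


def test_cv_missing_segment_rejected():
    vol, E = _profile_fixture([[1.0, 3.0], []])
    with pytest.raises(AnalysisError, match="empty"):
        slice_cv(E, vol, "Nerve", {"seg": (0, 0), "empty": (1, 1)})


def test_ratio_345_identity():
    """Uniform (3,4,5) field: transverse = 5, so R = 1 in every slice."""
    shape = (2, 2, 3)
    labels = np.full(shape, NERVE)
    comps = (np.full(shape, 3.0), np.full(shape, 4.0), np.full(shape, 5.0))
    grid = GridSpec(shape=shape, spacing=1.0)
    vol = LabelVolume(grid=grid, labels=labels)
    E = VectorField(grid=grid, components=comps, mask=np.ones(shape, bool))
    prof = longitudinal_ratio(E, vol, "Nerve", {"seg": (0, 2)})
    assert prof.values == pytest.approx([1.0, 1.0, 1.0])
    assert prof.segment_means["seg"] == pytest.approx(1.0)


def test_ratio_zero_longitudinal():
    shape = (2, 2, 2)
    grid = GridSpec(shape=shape, spacing=1.0)
    vol = LabelVolume(grid=grid, labels=np.full(shape, NERVE, dtype=np.int16))
    E = VectorField(grid=grid,
                    components=(np.ones(shape), np.ones(shape), np.zeros(shape)),
                    mask=np.ones(shape, bool))
    prof = longitudinal_ratio(E, vol, "Nerve", {"seg": (0, 1)})
    assert prof.segment_means["seg"] == 0.0


def test_ratio_purely_longitudinal_slice_undefined():
    shape = (2, 2, 2)
    grid = GridSpec(shape=shape, spacing=1.0)
    vol = LabelVolume(grid=grid, labels=np.full(shape, NERVE, dtype=np.int16))
    E = VectorField(grid=grid,
                    components=(np.zeros(shape), np.zeros(shape), np.ones(shape)),
                    mask=np.ones(shape, bool))
    prof = longitudinal_ratio(E, vol, "Nerve", {"seg": (0, 1)})
    assert prof.slices == []
    assert np.isnan(prof.segment_means["seg"])
    assert prof.excluded_voxels == 8


@pytest.mark.parametrize("seed", range(10))
def test_profiles_match_brute_force(seed):
    rng = np.random.default_rng(300 + seed)
    vol, E = random_field_fixture(rng, shape=(6, 6, 6), n_tissues=2)
    name = vol.catalogue.tissue_name(1)
    segments = {"lower": (0, 2), "upper": (3, 5)}
    try:
        cv = slice_cv(E, vol, name, segments)
        rr = longitudinal_ratio(E, vol, name, segments)
    except AnalysisError:
        return  # a segment without the tissue: contract, not a failure
    mag = E.magnitude()
    ex, ey, ez = E.components
    cv_expect, r_expect = {}, {}
    for z in range(6):
        m = vol.labels[:, :, z] == 1
        vals = mag[:, :, z][m]
        if len(vals) >= 2 and vals.mean() > 0:
            mu = sum(vals) / len(vals)
            sd = np.sqrt(sum((v - mu) ** 2 for v in vals) / len(vals))
            cv_expect[z] = 100.0 * sd / mu
        t = np.sqrt(ex[:, :, z][m] ** 2 + ey[:, :, z][m] ** 2)
        l = np.abs(ez[:, :, z][m])
        ok = t > 0
        if ok.any():
            r_expect[z] = float(np.mean(l[ok] / t[ok]))
    assert cv.slices == sorted(cv_expect)
    for z, v in zip(cv.slices, cv.values):
        assert v == pytest.approx(cv_expect[z])
    for z, v in zip(rr.slices, rr.values):
        assert v == pytest.approx(r_expect[z])
    for seg, (z0, z1) in segments.items():
        vs = [cv_expect[z] for z in cv_expect if z0 <= z <= z1]
        if vs:
            assert cv.segment_means[seg] == pytest.approx(np.mean(vs))


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=120, deadline=None, derandomize=True)
def test_metric_suite_property_random_fixtures(seed):
    """Percentiles and spreads agree with brute force on random lattices."""
    rng = np.random.default_rng(seed)
    shape = tuple(rng.integers(3, 9, size=3))
    vol, E = random_field_fixture(rng, shape=shape, n_tissues=2)
    mag = E.magnitude()
    name = vol.catalogue.tissue_name(1)
    vals = mag[vol.labels == 1]
    if vals.size == 0:
        return
    st_ = tissue_stats(E, vol, name)
    assert st_.p99 == pytest.approx(_brute_percentile(vals, 99))
    assert st_.min <= st_.q25 <= st_.median <= st_.q75 <= st_.p99
    v50, v70 = spread_within(E, vol, name)
    peak = _brute_percentile(vals, 99)
    assert v50 == pytest.approx(
        100.0 * sum(1 for v in vals if v >= 0.5 * peak) / len(vals)
    )
    assert 0.0 <= v70 <= v50 <= 100.0


# --- dose equivalence ------------------------------------------------------


def test_match_peak_dose():
    assert match_peak_dose(1.0, 1.0, 2e-3) == 2e-3
    # child peak 67% above the adult reference at 2 mA -> about 1.2 mA
    assert match_peak_dose(1.0, 1.667, 2e-3) == pytest.approx(1.2e-3, rel=0.01)
    assert match_peak_dose(1.0, 1.4, 2e-3) == pytest.approx(1.43e-3, rel=0.01)
    assert match_peak_dose(1.0, 2.0, 2e-3) == pytest.approx(1e-3)
    with pytest.raises(AnalysisError):
        match_peak_dose(0.0, 1.0, 2e-3)
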