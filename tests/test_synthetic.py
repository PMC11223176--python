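"""Generator contracts: determinism, design conservation, noise models, and
noiseless round trips against the matching estimators."""

import numpy as np
import pytest
from dataclasses import replace
from scipy import ndimage

from renalperf import (ASLParams, KidneyMask, ParametricMap, StudyConfig,
                       generate_cohort, generate_kidney_mask, quantify_asl_rbf,
                       simulate_asl_pair, simulate_ceus_tic, simulate_dce,
                       simulate_multiecho, tic_parameters)
from renalperf.dce import AIFCurve, GammaVariateAIF, PKParams, pk_forward
from renalperf.synthetic import CEUSBolusTruth, MaskGeometry
from renalperf.types import InvalidGeometryError, InvalidInputError

ECHO_TIMES = np.arange(1, 13) * 4.2e-3


def test_ellipse_mask_area(ellipse_mask):
    assert abs(ellipse_mask.n_pixels - np.pi * 30 * 15) <= 20


def test_mask_determinism():
    geom = MaskGeometry(concavity=0.3, jitter=1.0)
    m1 = generate_kidney_mask(geom, seed=42)
    m2 = generate_kidney_mask(geom, seed=42)
    assert np.array_equal(m1.grid, m2.grid)
    assert m1.pole_axis_hint == m2.pole_axis_hint


def test_mask_geometry_errors():
    with pytest.raises(InvalidGeometryError):
        generate_kidney_mask(MaskGeometry(grid_shape=(40, 40), semi_major=25,
                                          semi_minor=12, jitter=0), seed=0)
    with pytest.raises(InvalidGeometryError):
        generate_kidney_mask(MaskGeometry(semi_major=2, semi_minor=1, jitter=0),
                             seed=0)


def test_random_geometries_connected():
    """Masks are single connected components (flood-fill oracle)."""
    rng = np.random.default_rng(0)
    for _ in range(500):
        geom = MaskGeometry(semi_major=float(rng.uniform(18, 32)),
                            semi_minor=float(rng.uniform(10, 16)),
                            exponent=float(rng.uniform(1.8, 3.0)),
                            concavity=float(rng.uniform(0, 0.4)),
                            jitter=1.0)
        mask = generate_kidney_mask(geom, seed=int(rng.integers(2**31)))
        _, n = ndimage.label(mask.grid)
        assert n == 1
        assert mask.n_pixels >= 200


# --- multi-echo -------------------------------------------------------------

def test_multiecho_closed_form(small_mask, make_map):
    series = simulate_multiecho(make_map(small_mask, 25.0, "R2*"),
                                make_map(small_mask, 1000.0, "S0"),
                                ECHO_TIMES, noise_sd=0.0, seed=0)
    assert series.echoes[-1][small_mask.grid] == pytest.approx(
        1000 * np.exp(-25 * 0.0504), abs=1e-9)
    series0 = simulate_multiecho(make_map(small_mask, 0.0, "R2*"),
                                 make_map(small_mask, 800.0, "S0"),
                                 ECHO_TIMES, noise_sd=0.0, seed=0)
    assert np.allclose(series0.echoes[:, small_mask.grid], 800.0)


def test_multiecho_rejects_nonpositive_s0(small_mask, make_map):
    with pytest.raises(InvalidInputError):
        simulate_multiecho(make_map(small_mask, 25.0, "R2*"),
                           make_map(small_mask, 0.0, "S0"),
                           ECHO_TIMES, noise_sd=0.0, seed=0)


def test_rician_noise_floor_and_mean():
    """Magnitude means exceed the noiseless signal; the excess matches a
    Monte-Carlo oracle of the Rician mean."""
    grid = np.ones((100, 100), dtype=bool)
    grid[[0, -1], :] = grid[:, [0, -1]] = False
    mask = KidneyMask(grid=grid)
    s0v, r2sv, sd = 1000.0, 30.0, 20.0
    s0 = ParametricMap(np.where(grid, s0v, 0.0), mask, "S0")
    r2s = ParametricMap(np.where(grid, r2sv, 0.0), mask, "R2*")
    series = simulate_multiecho(r2s, s0, ECHO_TIMES, noise_sd=sd, seed=123)
    noiseless = s0v * np.exp(-r2sv * ECHO_TIMES)
    means = series.echoes[:, grid].mean(axis=1)
    assert (means >= noiseless - 0.05 * sd).all()  # Rician bias is >= 0

    rng = np.random.default_rng(999)  # independent Monte-Carlo oracle
    n = series.echoes[:, grid].shape[1]
    oracle = np.hypot(noiseless[:, None] + rng.normal(0, sd, (12, n)),
                      rng.normal(0, sd, (12, n))).mean(axis=1)
    assert means == pytest.approx(oracle, abs=4 * sd / np.sqrt(n) * 2)


# --- ASL --------------------------------------------------------------------

def test_asl_zero_rbf_means_equal_images(small_mask, make_map):
    control, label, _ = simulate_asl_pair(make_map(small_mask, 0.0),
                                          make_map(small_mask, 1000.0, "M0"),
                                          ASLParams(), 0.0, seed=0)
    assert np.array_equal(control, label)


def test_asl_noiseless_round_trip(small_mask, make_map):
    params = ASLParams()
    control, label, m0 = simulate_asl_pair(make_map(small_mask, 300.0),
                                           make_map(small_mask, 1000.0, "M0"),
                                           params, 0.0, seed=0)
    res = quantify_asl_rbf(control, label, m0, params, small_mask)
    assert np.abs(res.rbf_map.masked() - 300.0).max() < 1e-9 * 300


def test_asl_between_run_noise_sd():
    """Same-image differences between two runs have SD ~ sqrt(2)*noise_sd."""
    grid = np.ones((100, 100), dtype=bool)
    grid[[0, -1], :] = grid[:, [0, -1]] = False
    mask = KidneyMask(grid=grid)
    rbf = ParametricMap(np.where(grid, 250.0, 0), mask, "RBF")
    m0 = ParametricMap(np.where(grid, 1000.0, 0), mask, "M0")
    sd = 8.0
    control, _, _ = simulate_asl_pair(rbf, m0, ASLParams(), sd, seed=5)
    diff = (control[0] - control[1])[grid]
    assert diff.std() == pytest.approx(np.sqrt(2) * sd, rel=0.05)


# --- DCE --------------------------------------------------------------------

def test_dce_uptake_ft0_equals_one_compartment_convolution():
    """With F_t = 0 the uptake model collapses to F_p*exp(-t F_p/v_p) (x) AIF;
    oracle: explicit numerical convolution loop."""
    t = np.arange(80) * 1.5
    sim = simulate_dce(PKParams(fp=120, vp=30, ft=0), GammaVariateAIF(), t,
                       "Cr25", 0.0, seed=0, model="C2UM")
    fp, vp = 120 / 6000, 30 / 100
    irf = fp * np.exp(-t * fp / vp)
    ca = sim.aif.concentration
    oracle = np.array([1.5 * sum(ca[j] * irf[i - j] for j in range(i + 1))
                       for i in range(t.size)])
    assert sim.tissue.data == pytest.approx(oracle, abs=1e-12)


def test_dce_linearity_in_aif():
    t = np.arange(80) * 1.5
    truth = PKParams(fp=120, vp=30, ft=30)
    a1 = GammaVariateAIF(amplitude=5.0)
    a2 = GammaVariateAIF(amplitude=10.0)
    s1 = simulate_dce(truth, a1, t, "Cr25", 0.0, 0)
    s2 = simulate_dce(truth, a2, t, "Cr25", 0.0, 0)
    assert s2.tissue.data == pytest.approx(2 * s1.tissue.data, rel=1e-12)


def test_dce_placement_delay_shifts_aif_peak():
    t = np.arange(240) * 0.5
    sim = simulate_dce(PKParams(fp=120, vp=30, ft=30), GammaVariateAIF(), t,
                       "Ca", 0.0, 0, placements_map={"Cr25": (0, 0), "Ca": (1.0, 0.0)})
    assert sim.aif.peak_time - sim.aif_reference.peak_time == pytest.approx(1.0)


def test_dce_unknown_placement_errors():
    t = np.arange(80) * 1.5
    with pytest.raises(InvalidInputError):
        simulate_dce(PKParams(), GammaVariateAIF(), t, "nowhere", 0.0, 0)


# --- CEUS -------------------------------------------------------------------

def test_ceus_noiseless_peak_and_baseline():
    t = np.arange(0, 90.001, 0.5)
    truth = CEUSBolusTruth(baseline=5.0, amplitude=20.0, t0=8.0, tp=10.0)
    tic = simulate_ceus_tic(truth, t, 0.0, seed=0)
    assert tic.intensity.max() == pytest.approx(25.0)  # baseline + amplitude
    assert tic.intensity[0] == pytest.approx(5.0)


def test_ceus_ttp_round_trip():
    """Noiseless bolus: recovered TTP within one grid step of a dense-grid
    argmax oracle."""
    t = np.arange(0, 90.001, 0.5)
    truth = CEUSBolusTruth(baseline=5.0, amplitude=20.0, t0=8.3, tp=9.7)
    tic = simulate_ceus_tic(truth, t, 0.0, seed=0)
    params = tic_parameters(tic)
    dense = np.arange(0, 90, 0.001)
    ttp_oracle = dense[int(np.argmax(truth(dense)))]
    assert abs(params.ttp - ttp_oracle) <= 0.5


def test_ceus_peak_outside_window_errors():
    with pytest.raises(InvalidInputError):
        simulate_ceus_tic(CEUSBolusTruth(t0=85.0, tp=10.0),
                          np.arange(0, 90.001, 0.5), 0.0, 0)


# --- cohort -----------------------------------------------------------------

def test_cohort_design_conservation():
    cfg = StudyConfig(modalities=())
    cohort = generate_cohort(cfg)
    assert len(cohort) == 8 * 2 * 2
    keys = {(d.subject, d.treatment, d.side) for d in cohort}
    assert len(keys) == 32


def test_cohort_determinism():
    cfg = StudyConfig(n_subjects=1)
    c1 = generate_cohort(cfg)
    c2 = generate_cohort(cfg)
    for d1, d2 in zip(c1, c2):
        assert np.array_equal(d1.mask.grid, d2.mask.grid)
        assert np.array_equal(d1.bold.echoes, d2.bold.echoes)
        assert np.array_equal(d1.asl[0], d2.asl[0])
        assert np.array_equal(d1.dce.tissue.data, d2.dce.tissue.data)
        assert np.array_equal(d1.ceus["cortex"][0].intensity,
                              d2.ceus["cortex"][0].intensity)


def test_cohort_truth_matches_config_without_variability():
    """With biological variability off, ground-truth regional values equal
    the configured means exactly, and dopamine raises RBF / lowers R2*."""
    cfg = StudyConfig(n_subjects=2, subject_cv_rbf=0, subject_sd_r2s=0,
                      side_cv_rbf=0, side_sd_r2s=0, visit_cv_rbf=0,
                      visit_sd_r2s=0, modalities=())
    cohort = generate_cohort(cfg)
    for ds in cohort:
        expect = cfg.regional_truth[ds.treatment]
        assert ds.truth.region_values["cortex"]["RBF"] == pytest.approx(
            expect["cortex"]["RBF"])
        assert ds.truth.region_values["medulla"]["R2*"] == pytest.approx(
            expect["medulla"]["R2*"])
        # map values on the cortical layers equal the cortical truth
        sel = np.isin(ds.truth.labels_tlco.labels, [1, 2, 3])
        assert np.allclose(ds.truth.rbf_map.values[sel], expect["cortex"]["RBF"])
        # cortical RBF truth exceeds medullary truth
        assert (ds.truth.region_values["cortex"]["RBF"]
                > ds.truth.region_values["medulla"]["RBF"])
    dop = [d for d in cohort if d.treatment == "dopamine"][0]
    ctl = [d for d in cohort if d.treatment == "control"][0]
    assert dop.truth.region_values["cortex"]["RBF"] > ctl.truth.region_values["cortex"]["RBF"]
    assert dop.truth.region_values["medulla"]["R2*"] < ctl.truth.region_values["medulla"]["R2*"]
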