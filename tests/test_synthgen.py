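"""Cohort, latent-truth and waveform generators: marginals, oracles, determinism."""

import dataclasses

import numpy as np
import pytest

from carostiff.errors import ConfigurationError, PressureError, SimulationError
from carostiff.stiffness import PressurePair, compute_panel
from carostiff.synthgen import (
    SimConfig,
    echo_from_waveform,
    latent_beta,
    noise_sd_for_r2,
    replicate_trial,
    sample_covariates,
    waveform_from_truth,
    LatentTruth,
)
from conftest import make_subject


def test_invalid_marginals_rejected():
    with pytest.raises(ConfigurationError):
        SimConfig(age_decade_weights={"30-39": 0.5, "40-49": 0.6})
    with pytest.raises(ConfigurationError):
        SimConfig(sbp_sd=-1.0)


def test_empty_cohort():
    assert sample_covariates(SimConfig(n_subjects=0, seed=1)) == []


def test_seed_determinism_field_by_field():
    a = sample_covariates(SimConfig(n_subjects=40, seed=99))
    b = sample_covariates(SimConfig(n_subjects=40, seed=99))
    for sa, sb in zip(a, b):
        assert dataclasses.asdict(sa) == dataclasses.asdict(sb)


def test_cohort_marginals_match_study_targets():
    subs = sample_covariates(SimConfig(n_subjects=983, seed=11))
    ages = np.array([s.age for s in subs])
    frac_40_59 = np.mean((ages >= 40) & (ages <= 59))
    assert frac_40_59 == pytest.approx(0.61, abs=0.04)
    frac_male = np.mean([s.sex == "male" for s in subs])
    assert frac_male == pytest.approx(409 / 983, abs=0.05)
    males = [s for s in subs if s.sex == "male"]
    ever_smoker = np.mean([s.smoking_status != "never" for s in males])
    assert ever_smoker == pytest.approx(0.44, abs=0.06)
    # no female smokers under the default configuration
    assert all(s.smoking_status == "never" for s in subs if s.sex == "female")
    assert all(s.age >= 30 for s in subs)
    assert all(s1 > d1 and s2 > d2 for (s1, s2), (d1, d2) in
               ((s.sbp, s.dbp) for s in subs))


@pytest.mark.parametrize(
    "age,sex,expected",
    [
        # hand evaluation of the generative β equation:
        # 0.087·age + 1.361·sex + 0.046·120 − 0.076·80 + 2.099
        (45, "male", 6.815),
        (50, "female", 8.611),
    ],
)
def test_latent_beta_linear_predictor_hand_values(age, sex, expected):
    subject = make_subject(age=age, sex=sex)
    truth = latent_beta(subject, 0, 0.0, np.random.default_rng(0))
    assert truth.beta_true == pytest.approx(expected, abs=1e-9)


def test_latent_beta_deterministic_without_noise():
    s = make_subject()
    t1 = latent_beta(s, 2, 0.0, np.random.default_rng(1))
    t2 = latent_beta(s, 2, 0.0, np.random.default_rng(2))
    assert t1.beta_true == t2.beta_true


def test_latent_beta_rejects_bad_risk_count():
    with pytest.raises(ConfigurationError):
        latent_beta(make_subject(), 6, 0.0, np.random.default_rng(0))


def test_noise_sd_for_r2_analytic():
    lp = np.random.default_rng(3).normal(8.0, 1.3, 5000)
    sd = noise_sd_for_r2(lp, 0.65)
    assert sd == pytest.approx(np.std(lp) * np.sqrt(0.35 / 0.65), rel=1e-12)
    with pytest.raises(ConfigurationError):
        noise_sd_for_r2(lp, 1.5)


def test_waveform_peak_diameter_from_inverted_beta(clean_config):
    # strain = ln(1.5)/5.8567 = 0.069231 -> Ds = 5.20 · (1 + strain) = 5.56
    truth = LatentTruth(beta_true=5.8567, dd_true=5.20, noise_sd=0.0)
    wf = waveform_from_truth(truth, PressurePair(120, 80), clean_config,
                             np.random.default_rng(4))
    assert wf.diameter.max() == pytest.approx(5.56, abs=2e-4)
    assert wf.diameter.min() == pytest.approx(5.20, abs=1e-12)
    assert wf.beat_ds[0] == pytest.approx(5.20 * (1 + np.log(1.5) / 5.8567), rel=1e-12)


def test_waveform_round_trip_beta_exact(clean_config, rng):
    """Noise-free: compute_panel on the generated waveform returns beta_true."""
    for beta_true in (4.0, 6.5, 9.0, 12.0):
        truth = LatentTruth(beta_true=beta_true, dd_true=5.4, noise_sd=0.0)
        p = PressurePair(125, 82)
        wf = waveform_from_truth(truth, p, clean_config, rng)
        panel = compute_panel(wf, p)
        assert panel.beta == pytest.approx(beta_true, rel=1e-9)


def test_degenerate_pressures_and_strain():
    with pytest.raises(PressureError):
        PressurePair(120, 120)  # zero-distension request dies at the pressures
    cfg = SimConfig()
    truth = LatentTruth(beta_true=0.5, dd_true=5.2, noise_sd=0.0)
    with pytest.raises(SimulationError):
        # ln(1.5)/0.5 = 0.81 strain: unphysiologic
        waveform_from_truth(truth, PressurePair(120, 80), cfg, np.random.default_rng(0))


def test_typical_cohort_distension_in_published_band(small_config):
    """Mean distension of a default cohort sits within 0.36 ± 0.14 mm."""
    cfg = SimConfig(n_subjects=300, seed=21)
    rng = np.random.default_rng(21)
    subs = sample_covariates(cfg, rng)
    dist = []
    for s in subs:
        truth = latent_beta(s, 1, 0.0, rng)
        p = PressurePair(s.sbp[0], s.dbp[0])
        try:
            wf = waveform_from_truth(truth, p, cfg, rng)
        except SimulationError:
            continue
        dist.append(wf.beat_ds[0] - wf.beat_dd[0])
    assert 0.22 <= float(np.mean(dist)) <= 0.50


def test_replicate_identical_when_error_zero(clean_config):
    truth = LatentTruth(beta_true=6.0, dd_true=5.2, noise_sd=0.0)
    p = PressurePair(120, 80)
    rng = np.random.default_rng(5)
    wf1 = waveform_from_truth(truth, p, clean_config, rng)
    wf2 = replicate_trial(wf1, p, clean_config, rng,
                          inter_trial_dd_rel_sd=0.0, inter_trial_strain_rel_sd=0.0)
    assert wf2.beat_dd[0] == pytest.approx(wf1.beat_dd[0], rel=1e-12)
    assert wf2.beat_ds[0] == pytest.approx(wf1.beat_ds[0], rel=1e-12)


def test_replicate_seed_determinism(small_config):
    truth = LatentTruth(beta_true=6.0, dd_true=5.2, noise_sd=0.0)
    p = PressurePair(120, 80)
    wf1 = waveform_from_truth(truth, p, small_config, np.random.default_rng(6))
    r1 = replicate_trial(wf1, p, small_config, np.random.default_rng(77))
    r2 = replicate_trial(wf1, p, small_config, np.random.default_rng(77))
    assert np.array_equal(r1.diameter, r2.diameter)


def test_replicate_calibration_diameter_rd(small_config):
    """≈80% of two-trial end-diastolic diameter pairs have RD ≤ 15%."""
    cfg = SimConfig(n_subjects=1, seed=0)
    rng = np.random.default_rng(31)
    p = PressurePair(120, 80)
    rds = []
    for _ in range(1000):
        truth = LatentTruth(beta_true=7.0, dd_true=5.35, noise_sd=0.0)
        wf1 = waveform_from_truth(truth, p, cfg, rng)
        wf2 = replicate_trial(wf1, p, cfg, rng)
        d1, d2 = wf1.beat_dd[0], wf2.beat_dd[0]
        rds.append(100.0 * abs(d1 - d2) / ((d1 + d2) / 2.0))
    assert np.mean(np.array(rds) <= 15.0) == pytest.approx(0.80, abs=0.03)


def test_echo_frames_peaks_at_wall_depths(clean_config):
    d = np.full(40, 5.2)
    from carostiff.echotrack import DistensionWaveform

    wf = DistensionWaveform(times=np.arange(40) / 100.0, diameter=d)
    seq = echo_from_waveform(wf, clean_config, np.random.default_rng(0))
    dz = seq.depth_step_mm
    f0 = seq.frame(0)
    grid = f0.depth_axis_mm
    half = np.searchsorted(grid, 17.6)
    depths = np.array([
        grid[int(np.argmax(f0.samples[:half]))],
        grid[half + int(np.argmax(f0.samples[half:]))],
    ])
    # lumen centre 17.6 mm, diameter 5.2 -> walls at 15.0 / 20.2 mm
    assert depths[0] == pytest.approx(15.0, abs=dz)
    assert depths[1] == pytest.approx(20.2, abs=dz)
    assert depths[1] - depths[0] == pytest.approx(5.2, abs=2 * dz)
    # zero distension: every frame identical
    assert np.array_equal(seq.samples[0], seq.samples[-1])


def test_echo_walls_outside_window_rejected(clean_config):
    from carostiff.echotrack import DistensionWaveform

    wf = DistensionWaveform(times=np.arange(10) / 100.0, diameter=np.full(10, 28.0))
    with pytest.raises(SimulationError):
        echo_from_waveform(wf, clean_config, np.random.default_rng(0))


def test_echo_speckle_determinism(small_config):
    from carostiff.echotrack import DistensionWaveform

    wf = DistensionWaveform(times=np.arange(20) / 100.0, diameter=np.full(20, 5.2))
    a = echo_from_waveform(wf, small_config, np.random.default_rng(8))
    b = echo_from_waveform(wf, small_config, np.random.default_rng(8))
    assert np.array_equal(a.samples, b.samples)


def test_generated_geometry_physiologic():
    cfg = SimConfig(n_subjects=200, seed=13)
    rng = np.random.default_rng(13)
    subs = sample_covariates(cfg, rng)
    for s in subs[:50]:
        truth = latent_beta(s, 0, 0.0, rng)
        assert 4.0 <= truth.dd_true <= 8.0
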