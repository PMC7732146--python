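"""Synthetic cohorts, latent stiffness truths, and simulated A-mode measurements.

This generator emulates a community carotid-stiffness screening study so that
every downstream stage (echo tracking, stiffness indices, repeatability and
population statistics) is testable without any field data:

* covariates are drawn to match the published study marginals (sex ratio
  409:574, 61% of subjects aged 40-59, 44% of males ever-smokers, no female
  smokers, Asian-Indian anthropometry and blood chemistry);
* the latent stiffness truth ``beta_true`` for each subject is the published
  β regression on (age, sex, SBP, DBP, smoking-years, risk count) plus
  Gaussian noise whose SD is derived analytically from the realized
  linear-predictor spread to hit a configured R²;
* beat-resolved diameter waveforms invert the β formula — systolic strain is
  set to ``ln(Ps/Pd)/beta_true`` — so the stiffness module recovers the truth
  exactly in the noise-free case;
* two-trial replication applies inter-trial diameter and strain perturbations
  calibrated analytically to the study's printed repeatability (≈80% of
  diameter pairs within a 15% relative difference, BP RD well under 5%);
* optional raw A-mode envelope frames place two Gaussian echo lobes moving
  out of phase about a fixed lumen centre, with multiplicative speckle.

All randomness flows through :func:`numpy.random.default_rng`; a fixed seed
reproduces every artifact bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .echotrack import DistensionWaveform, EchoSequence
from .errors import ConfigurationError, SimulationError
from .reference_values import SEX_CODE, published_linear_predictor
from .stiffness import PressurePair

__all__ = [
    "SubjectCovariates",
    "LatentTruth",
    "SimConfig",
    "sample_covariates",
    "latent_beta",
    "noise_sd_for_r2",
    "waveform_from_truth",
    "replicate_trial",
    "echo_from_waveform",
]

# Analytic repeatability calibrations (see docs/methods.md):
#   P(|N(0,s)| <= 0.15) = 0.80  =>  s = 0.15 / Phi^-1(0.90) = 0.117046
_INTER_TRIAL_DD_REL_SD = 0.117046
#   strain perturbation sized so the implied two-trial beta RD ~= 20%
_INTER_TRIAL_STRAIN_REL_SD = 0.22
#   mean BP RD = 100 * sqrt(2) * s * sqrt(2/pi) ~= 2.8% < 5% at s = 0.025
_BP_REPLICATE_REL_SD = 0.025


@dataclass(frozen=True)
class SubjectCovariates:
    """One participant's demographic, anthropometric and biochemical record.

    ``sbp``/``dbp`` hold the two replicate readings (one per measurement
    trial); risk rules operate on their mean.
    """

    subject_id: str
    age: int  # years, >= 30
    sex: Literal["male", "female"]
    waist: float  # cm
    sbp: tuple[float, float]  # mmHg, replicate readings
    dbp: tuple[float, float]
    fpg: float  # mg/dL
    tgl: float  # mg/dL
    hdl: float | None  # mg/dL; None = assay unavailable
    on_bp_meds: bool
    on_glucose_meds: bool
    on_lipid_meds: bool
    smoking_status: Literal["never", "former", "current"]
    smoking_years: float
    alcohol_status: Literal["never", "former", "current", "regular"]

    def __post_init__(self) -> None:
        if self.age < 30:
            raise ConfigurationError("cohort is adults aged >= 30")
        for s, d in zip(self.sbp, self.dbp):
            if not s > d > 0:
                raise ConfigurationError("each replicate must have SBP > DBP > 0")
        if (self.smoking_years == 0) != (self.smoking_status == "never"):
            raise ConfigurationError("smoking_years must be 0 iff never-smoker")

    @property
    def sbp_mean(self) -> float:
        return float(np.mean(self.sbp))

    @property
    def dbp_mean(self) -> float:
        return float(np.mean(self.dbp))

    @property
    def sex_code(self) -> int:
        return SEX_CODE[self.sex]


@dataclass(frozen=True)
class LatentTruth:
    """A subject's generative stiffness truth."""

    beta_true: float
    dd_true: float  # mm, end-diastolic diameter
    noise_sd: float

    def __post_init__(self) -> None:
        if self.beta_true <= 0.0:
            raise SimulationError("beta_true must be > 0")


class SimConfig(BaseModel):
    """Cohort and waveform simulation parameters (defaults = study conditions)."""

    n_subjects: int = 983
    seed: int = 0

    # covariate marginals
    sex_male_frac: float = 409 / 983
    age_decade_weights: dict[str, float] = Field(
        default_factory=lambda: {"30-39": 0.24, "40-49": 0.34, "50-59": 0.27, "60+": 0.15}
    )
    age_max: int = 75
    male_smoking_probs: dict[str, float] = Field(  # current/former sum to 44%
        default_factory=lambda: {"never": 0.56, "former": 0.14, "current": 0.30}
    )
    female_smoking_probs: dict[str, float] = Field(
        default_factory=lambda: {"never": 1.0, "former": 0.0, "current": 0.0}
    )
    male_alcohol_probs: dict[str, float] = Field(  # current+regular = 55%
        default_factory=lambda: {"never": 0.40, "former": 0.05, "current": 0.30, "regular": 0.25}
    )
    female_alcohol_probs: dict[str, float] = Field(
        default_factory=lambda: {"never": 0.92, "former": 0.02, "current": 0.04, "regular": 0.02}
    )
    waist_male: tuple[float, float] = (88.0, 10.0)  # mean, SD (cm)
    waist_female: tuple[float, float] = (79.0, 9.0)
    sbp_mean: float = 131.0
    sbp_sd: float = 17.0
    dbp_mean: float = 80.0
    dbp_sd: float = 10.0
    bp_corr: float = 0.6
    bp_replicate_rel_sd: float = _BP_REPLICATE_REL_SD
    fpg_mean: float = 105.0
    fpg_sd: float = 30.0
    tgl_mean: float = 140.0
    tgl_sd: float = 60.0
    hdl_male: tuple[float, float] = (42.0, 10.0)
    hdl_female: tuple[float, float] = (48.0, 11.0)
    p_bp_meds: float = 0.12
    p_glucose_meds: float = 0.08
    p_lipid_meds: float = 0.0  # statin users were excluded at enrollment

    # latent truth
    target_r2: float = 0.65
    beta_floor: float = 1.0
    dd_mean: float = 5.35
    dd_sd: float = 0.5
    dd_range: tuple[float, float] = (4.0, 8.0)

    # waveform
    hr_range: tuple[float, float] = (60.0, 90.0)  # bpm
    beats_per_trial: int = 10
    frame_rate: float = 100.0  # Hz, diameter samples
    systole_frac: float = 0.3
    decay_tau_frac: float = 0.08  # fast early-diastolic decay, flat late diastole
    diameter_noise_sd: float = 0.005  # mm, additive per sample
    inter_trial_dd_rel_sd: float = _INTER_TRIAL_DD_REL_SD
    inter_trial_strain_rel_sd: float = _INTER_TRIAL_STRAIN_REL_SD

    # echo frames
    speed_of_sound: float = 1540.0  # m/s
    env_sampling_rate: float = 40e6  # Hz  (depth step ~19 µm)
    depth_window: tuple[float, float] = (5.0, 35.0)  # mm
    lumen_center: float = 17.6  # mm
    echo_pulse_sigma: float = 0.3  # mm, Gaussian lobe width
    echo_amp_proximal: float = 1.0
    echo_amp_distal: float = 0.85
    speckle_sigma: float = 0.05  # lognormal sigma; 0 = clean

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        for name in ("age_decade_weights", "male_smoking_probs", "female_smoking_probs",
                     "male_alcohol_probs", "female_alcohol_probs"):
            w = getattr(self, name)
            if any(v < 0 for v in w.values()) or abs(sum(w.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must be non-negative and sum to 1")
        for sd in (self.sbp_sd, self.dbp_sd, self.fpg_sd, self.tgl_sd,
                   self.diameter_noise_sd, self.speckle_sigma,
                   self.inter_trial_dd_rel_sd, self.inter_trial_strain_rel_sd,
                   self.bp_replicate_rel_sd, self.dd_sd):
            if sd < 0:
                raise ConfigurationError("all SDs must be >= 0")
        if not 0.0 <= self.sex_male_frac <= 1.0:
            raise ConfigurationError("sex_male_frac must be in [0, 1]")
        if self.env_sampling_rate <= 0 or self.frame_rate <= 0:
            raise ConfigurationError("sampling rates must be > 0")
        if not self.depth_window[1] > self.depth_window[0] > 0:
            raise ConfigurationError("depth window must be increasing and positive")
        return self


_DECADES = {"30-39": (30, 39), "40-49": (40, 49), "50-59": (50, 59)}


def sample_covariates(
    config: SimConfig, rng: np.random.Generator | None = None
) -> list[SubjectCovariates]:
    """Draw a cohort whose marginals converge to the configured targets.

    SBP/DBP are drawn jointly (correlation ``bp_corr``); all other marginals
    are independent apart from the smoking-by-sex restriction.  Deterministic
    given ``config.seed`` (or an explicit ``rng``).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_subjects
    subjects: list[SubjectCovariates] = []
    decade_names = list(config.age_decade_weights)
    decade_w = np.array([config.age_decade_weights[k] for k in decade_names])

    for i in range(n):
        sex = "male" if rng.random() < config.sex_male_frac else "female"
        decade = decade_names[rng.choice(len(decade_names), p=decade_w)]
        if decade in _DECADES:
            lo, hi = _DECADES[decade]
        else:
            lo, hi = 60, config.age_max
        age = int(rng.integers(lo, hi + 1))

        smk_probs = config.male_smoking_probs if sex == "male" else config.female_smoking_probs
        smoking_status = rng.choice(list(smk_probs), p=list(smk_probs.values()))
        if smoking_status == "never":
            smoking_years = 0.0
        else:
            cap = max(age - 18, 1)
            smoking_years = float(np.clip(round(rng.normal(12.0, 8.0)), 1, min(cap, 40)))

        alc_probs = config.male_alcohol_probs if sex == "male" else config.female_alcohol_probs
        alcohol_status = rng.choice(list(alc_probs), p=list(alc_probs.values()))

        wm, ws = config.waist_male if sex == "male" else config.waist_female
        waist = float(max(rng.normal(wm, ws), 50.0))

        # true BP, jointly normal, then two replicate readings per pressure
        z = rng.multivariate_normal(
            [config.sbp_mean, config.dbp_mean],
            [
                [config.sbp_sd**2, config.bp_corr * config.sbp_sd * config.dbp_sd],
                [config.bp_corr * config.sbp_sd * config.dbp_sd, config.dbp_sd**2],
            ],
        )
        sbp_true = max(float(z[0]), 85.0)
        dbp_true = float(np.clip(z[1], 45.0, sbp_true - 15.0))
        reps_s, reps_d = [], []
        for _ in range(2):
            s = sbp_true * (1.0 + rng.normal(0.0, config.bp_replicate_rel_sd))
            d = dbp_true * (1.0 + rng.normal(0.0, config.bp_replicate_rel_sd))
            d = min(d, s - 5.0)
            reps_s.append(s)
            reps_d.append(d)

        fpg = float(max(rng.normal(config.fpg_mean, config.fpg_sd), 60.0))
        tgl = float(max(rng.normal(config.tgl_mean, config.tgl_sd), 40.0))
        hm, hs = config.hdl_male if sex == "male" else config.hdl_female
        hdl = float(max(rng.normal(hm, hs), 15.0))

        subjects.append(
            SubjectCovariates(
                subject_id=f"S{i:04d}",
                age=age,
                sex=sex,
                waist=waist,
                sbp=(reps_s[0], reps_s[1]),
                dbp=(reps_d[0], reps_d[1]),
                fpg=fpg,
                tgl=tgl,
                hdl=hdl,
                on_bp_meds=bool(rng.random() < config.p_bp_meds),
                on_glucose_meds=bool(rng.random() < config.p_glucose_meds),
                on_lipid_meds=bool(rng.random() < config.p_lipid_meds),
                smoking_status=str(smoking_status),
                smoking_years=smoking_years,
                alcohol_status=str(alcohol_status),
            )
        )
    return subjects


def noise_sd_for_r2(linear_predictors: Sequence[float], r2: float) -> float:
    """Latent-noise SD giving the requested R² against a realized predictor set.

    If the outcome is ``lp + N(0, σ²)`` then the population R² of the true
    model is ``Var(lp)/(Var(lp)+σ²)``; solving for σ gives
    ``σ = sd(lp)·sqrt((1−R²)/R²)``.
    """
    if not 0.0 < r2 < 1.0:
        raise ConfigurationError("r2 must be in (0, 1)")
    sd_lp = float(np.std(np.asarray(linear_predictors, dtype=float)))
    return sd_lp * math.sqrt((1.0 - r2) / r2)


def latent_beta(
    subject: SubjectCovariates,
    n_cmr: int,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    *,
    dd_mean: float = 5.35,
    dd_sd: float = 0.5,
    dd_range: tuple[float, float] = (4.0, 8.0),
    beta_floor: float = 1.0,
) -> LatentTruth:
    """Draw a subject's latent stiffness from the published β regression.

    ``beta_true`` is the exact published linear predictor on (age, sex code,
    replicate-mean SBP/DBP, smoking-years, risk count) plus one Gaussian draw,
    floored at ``beta_floor`` to stay physiologic.  ``dd_true`` is drawn from
    a truncated normal within ``dd_range``.
    """
    if not 0 <= n_cmr <= 5:
        raise ConfigurationError("n_cmr must be in 0..5")
    rng = np.random.default_rng(0) if rng is None else rng
    lp = published_linear_predictor(
        "beta",
        age=subject.age,
        sex_code=subject.sex_code,
        sbp=subject.sbp_mean,
        dbp=subject.dbp_mean,
        smoking_years=subject.smoking_years,
        n_cmr=n_cmr,
    )
    beta = lp + (rng.normal(0.0, noise_sd) if noise_sd > 0.0 else 0.0)
    beta = max(beta, beta_floor)
    dd = float(np.clip(rng.normal(dd_mean, dd_sd), *dd_range))
    return LatentTruth(beta_true=beta, dd_true=dd, noise_sd=noise_sd)


def _beat_template(
    dd: float, ds: float, period: float, systole_frac: float, tau_frac: float, fs: float
) -> np.ndarray:
    """One cardiac cycle on the frame grid: raised-cosine upstroke, exponential
    relaxation back towards Dd.  Period and rise time are quantized to whole
    samples so the diastolic minimum and systolic peak fall on the grid."""
    n = max(int(round(period * fs)), 4)
    n_up = min(max(int(round(systole_frac * period * fs)), 2), n - 2)
    tau = max(tau_frac * period, 1.0 / fs)
    t = np.arange(n) / fs
    t_up = n_up / fs
    amp = ds - dd
    beat = np.empty(n)
    up = t[: n_up + 1]
    beat[: n_up + 1] = dd + amp * 0.5 * (1.0 - np.cos(np.pi * up / t_up))
    # relaxation (1 + x)e^{-x} starts with zero slope, so the systolic peak is
    # a smooth extremum rather than a corner
    down = (t[n_up + 1 :] - t_up) / tau
    beat[n_up + 1 :] = dd + amp * (1.0 + down) * np.exp(-down)
    return beat


def waveform_from_truth(
    truth: LatentTruth,
    pressures: PressurePair,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    *,
    n_beats: int | None = None,
) -> DistensionWaveform:
    """Beat-resolved diameter waveform whose β equals ``truth.beta_true``.

    Systolic strain is set to ``ln(Ps/Pd)/beta_true``; per-beat Ds/Dd
    annotations carry the exact truth so a noise-free round trip through the
    stiffness formulas is exact.  Additive Gaussian diameter noise
    (``config.diameter_noise_sd``) is applied per sample.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    strain = math.log(pressures.ps / pressures.pd) / truth.beta_true
    if not 0.0 < strain < 0.5:
        raise SimulationError(f"unphysiologic systolic strain {strain:.4f}")
    dd = truth.dd_true
    ds = dd * (1.0 + strain)
    n_beats = config.beats_per_trial if n_beats is None else n_beats
    fs = config.frame_rate
    hr = rng.uniform(*config.hr_range)
    period = 60.0 / hr
    beat = _beat_template(dd, ds, period, config.systole_frac, config.decay_tau_frac, fs)
    nb = beat.size
    diameter = np.tile(beat, n_beats)
    if config.diameter_noise_sd > 0.0:
        diameter = diameter + rng.normal(0.0, config.diameter_noise_sd, diameter.size)
        diameter = np.maximum(diameter, 1e-3)
    times = np.arange(diameter.size) / fs
    boundaries = np.arange(n_beats + 1) * nb
    boundaries[-1] = diameter.size - 1
    return DistensionWaveform(
        times=times,
        diameter=diameter,
        beat_boundaries=boundaries,
        beat_ds=np.full(n_beats, ds),
        beat_dd=np.full(n_beats, dd),
        accepted=np.ones(n_beats, dtype=bool),
    )


def replicate_trial(
    waveform: DistensionWaveform,
    pressures: PressurePair,
    config: SimConfig,
    rng: np.random.Generator,
    *,
    inter_trial_dd_rel_sd: float | None = None,
    inter_trial_strain_rel_sd: float | None = None,
) -> DistensionWaveform:
    """Simulate the repeat measurement taken 10–15 minutes after the first.

    Probe repositioning perturbs the measured end-diastolic diameter
    (relative SD calibrated so ≈80% of two-trial diameter pairs fall within a
    15% relative difference) and the measured strain (calibrated to the
    printed two-trial index repeatability); the second waveform is rebuilt
    from the perturbed geometry with fresh sample noise.
    """
    dd_sd = config.inter_trial_dd_rel_sd if inter_trial_dd_rel_sd is None else inter_trial_dd_rel_sd
    st_sd = (
        config.inter_trial_strain_rel_sd
        if inter_trial_strain_rel_sd is None
        else inter_trial_strain_rel_sd
    )
    dd1 = float(waveform.beat_dd.mean())
    ds1 = float(waveform.beat_ds.mean())
    strain1 = (ds1 - dd1) / dd1
    dd2 = dd1 * (1.0 + rng.normal(0.0, dd_sd)) if dd_sd > 0 else dd1
    dd2 = float(np.clip(dd2, 1.0, 12.0))
    strain2 = strain1 * (1.0 + rng.normal(0.0, st_sd)) if st_sd > 0 else strain1
    strain2 = float(np.clip(strain2, 1e-4, 0.49))
    beta2 = math.log(pressures.ps / pressures.pd) / strain2
    truth2 = LatentTruth(beta_true=beta2, dd_true=dd2, noise_sd=0.0)
    return waveform_from_truth(truth2, pressures, config, rng, n_beats=waveform.n_beats)


def echo_from_waveform(
    waveform: DistensionWaveform,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> EchoSequence:
    """Render a diameter waveform as A-mode envelope frames.

    Each frame holds two Gaussian lobes centred at the proximal and distal
    wall depths; the walls move out of phase about the fixed lumen centre
    (proximal at centre − D/2, distal at centre + D/2).  Depth follows
    ``depth = c·t/2``; multiplicative lognormal speckle is applied when
    ``config.speckle_sigma > 0``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    d = waveform.diameter
    z_prox = config.lumen_center - d / 2.0
    z_dist = config.lumen_center + d / 2.0
    lo, hi = config.depth_window
    margin = 3.0 * config.echo_pulse_sigma
    if z_prox.min() < lo + margin or z_dist.max() > hi - margin:
        raise SimulationError("wall depths exceed the frame depth window")
    dz = config.speed_of_sound / (2.0 * config.env_sampling_rate) * 1e3
    grid = np.arange(lo, hi, dz)
    s2 = 2.0 * config.echo_pulse_sigma**2
    env = config.echo_amp_proximal * np.exp(
        -((grid[None, :] - z_prox[:, None]) ** 2) / s2
    ) + config.echo_amp_distal * np.exp(-((grid[None, :] - z_dist[:, None]) ** 2) / s2)
    if config.speckle_sigma > 0.0:
        env = env * np.exp(rng.normal(0.0, config.speckle_sigma, env.shape))
    return EchoSequence(
        samples=env,
        times=waveform.times.copy(),
        sampling_rate=config.env_sampling_rate,
        speed_of_sound=config.speed_of_sound,
        depth_origin=float(lo),
    )
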