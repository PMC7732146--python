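import numpy as np
import pytest

from carostiff.synthgen import SimConfig, SubjectCovariates


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A small default-noise study configuration."""
    return SimConfig(n_subjects=25, seed=7)


@pytest.fixture
def clean_config():
    """Noise-free study configuration (clean envelopes, exact diameters)."""
    return SimConfig(n_subjects=25, seed=7, diameter_noise_sd=0.0, speckle_sigma=0.0)


def make_subject(
    *,
    subject_id="S0000",
    age=45,
    sex="male",
    waist=85.0,
    sbp=(120.0, 120.0),
    dbp=(80.0, 80.0),
    fpg=90.0,
    tgl=100.0,
    hdl=55.0,
    on_bp_meds=False,
    on_glucose_meds=False,
    on_lipid_meds=False,
    smoking_status="never",
    smoking_years=0.0,
    alcohol_status="never",
):
    return SubjectCovariates(
        subject_id=subject_id, age=age, sex=sex, waist=waist,
        sbp=sbp, dbp=dbp, fpg=fpg, tgl=tgl, hdl=hdl,
        on_bp_meds=on_bp_meds, on_glucose_meds=on_glucose_meds,
        on_lipid_meds=on_lipid_meds, smoking_status=smoking_status,
        smoking_years=smoking_years, alcohol_status=alcohol_status,
    )
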