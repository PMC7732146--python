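"""Pipeline orchestration: simulate → track → indices → qc → analyze.

The in-memory entry point is :func:`simulate_study`, which produces a tidy
per-subject analysis table (covariates + risk flags + trial-averaged stiffness
panel) plus the per-trial panels needed for repeatability statistics.  The
file-based entry point is :func:`run_pipeline`, which executes the staged
pipeline into an output directory, writes a checksum manifest, and
short-circuits stages whose outputs already match the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import io as cio
from .echotrack import (
    DistensionWaveform,
    detect_walls,
    diameter_series,
    segment_beats,
    track_walls,
)
from .errors import CarostiffError, ConfigurationError, QualityError
from .popstats import (
    bp_category_contrasts,
    fit_predictive_models,
    quintile_assign,
    quintile_or,
    stratified_summary,
)
from .quality import rd_summary
from .reference_values import published_linear_predictor
from .riskprofile import classify_risks
from .stiffness import (
    DEFAULT_BLOOD_DENSITY,
    PressurePair,
    compute_panel,
    panel_from_diameters,
)
from .synthgen import (
    SimConfig,
    echo_from_waveform,
    latent_beta,
    noise_sd_for_r2,
    replicate_trial,
    sample_covariates,
    waveform_from_truth,
)

logger = logging.getLogger("carostiff")

STAGES = ("simulate", "track", "indices", "qc", "analyze")

PANEL_COLS = ("beta", "ep", "ac", "pwv_beta", "dc", "ds", "dd")


class RunConfig(BaseModel):
    """Persisted pipeline configuration; same config + seed ⇒ identical artifacts."""

    seed: int = 0
    stages: list[str] = Field(default_factory=lambda: list(STAGES))
    sim: SimConfig = Field(default_factory=SimConfig)
    with_echo: bool = False
    echo_subjects: int = 3  # raw frames are bulky; persist only the first few
    rho: float = DEFAULT_BLOOD_DENSITY
    exclude_htn_dm: bool = False
    log_level: str = "INFO"

    def model_post_init(self, __context) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages: {sorted(unknown)}")
        order = [s for s in STAGES if s in self.stages]
        if order != self.stages:
            raise ConfigurationError("stages must follow simulate→track→indices→qc→analyze order")


def measure_waveform(
    wf,
    pressures: PressurePair,
    config: SimConfig,
    rng: np.random.Generator,
    *,
    via_echo: bool = False,
    rho: float = DEFAULT_BLOOD_DENSITY,
):
    """Re-measure a simulated waveform as the device would.

    ``via_echo`` renders A-mode frames, detects and tracks the walls, and
    rebuilds the diameter series before beat segmentation; otherwise the
    diameter samples are segmented directly.  Either way the generator's beat
    annotations are discarded — Ds/Dd are re-estimated from the signal.
    """
    if via_echo:
        seq = echo_from_waveform(wf, config, rng)
        prox, dist, _ = detect_walls(seq.frame(0), min_separation=2.0)
        track = track_walls(seq, (prox, dist))
        dwf = diameter_series(track)
    else:
        dwf = wf.unsegmented()
    seg = segment_beats(dwf)
    return compute_panel(seg, pressures, rho)


def simulate_study(
    config: SimConfig,
    *,
    rho: float = DEFAULT_BLOOD_DENSITY,
    via_echo: bool = False,
    remeasure: bool = True,
) -> dict:
    """Generate a full two-trial study and return its analysis tables.

    Returns a dict with ``subjects`` (covariate dataclasses), ``truths``,
    ``analysis`` (per-subject DataFrame with covariates, risk flags and
    trial-averaged indices) and ``trial_panels`` (per-trial values for
    repeatability work).  ``remeasure=False`` keeps the generator's exact beat
    annotations (used by noise-free contract checks); the default re-measures
    every trial from the simulated signal.
    """
    rng = np.random.default_rng(config.seed)
    subjects = sample_covariates(config, rng)
    profiles = [classify_risks(s) for s in subjects]
    lps = [
        published_linear_predictor(
            "beta",
            age=s.age, sex_code=s.sex_code, sbp=s.sbp_mean, dbp=s.dbp_mean,
            smoking_years=s.smoking_years, n_cmr=p.n_risks,
        )
        for s, p in zip(subjects, profiles)
    ]
    noise_sd = noise_sd_for_r2(lps, config.target_r2)

    truths, rows, trial_rows = [], [], []
    for s, prof in zip(subjects, profiles):
        truth = latent_beta(
            s, prof.n_risks, noise_sd, rng,
            dd_mean=config.dd_mean, dd_sd=config.dd_sd,
            dd_range=config.dd_range, beta_floor=config.beta_floor,
        )
        truths.append(truth)
        p1 = PressurePair(s.sbp[0], s.dbp[0])
        p2 = PressurePair(s.sbp[1], s.dbp[1])
        wf1 = waveform_from_truth(truth, p1, config, rng)
        wf2 = replicate_trial(wf1, p2, config, rng)
        panels = []
        for trial, (wf, p) in enumerate(((wf1, p1), (wf2, p2)), start=1):
            if remeasure:
                try:
                    panel = measure_waveform(wf, p, config, rng, via_echo=via_echo, rho=rho)
                except QualityError:
                    logger.warning("subject %s trial %d failed QC", s.subject_id, trial)
                    continue
            else:
                panel = compute_panel(wf, p, rho)
            panels.append(panel)
            trial_rows.append(
                {"subject_id": s.subject_id, "trial": trial,
                 **{c: getattr(panel, c) for c in PANEL_COLS},
                 "ps": p.ps, "pd": p.pd}
            )
        if not panels:
            continue
        row = {
            "subject_id": s.subject_id, "age": s.age, "sex": s.sex,
            "sex_code": s.sex_code, "waist": s.waist,
            "sbp": s.sbp_mean, "dbp": s.dbp_mean,
            "fpg": s.fpg, "tgl": s.tgl, "hdl": s.hdl,
            "smoking_years": s.smoking_years,
            "smoking_status": s.smoking_status,
            "alcohol_status": s.alcohol_status,
            "n_cmr": prof.n_risks, "high_risk": prof.high_risk,
            "high_bp": prof.high_bp, "elevated_fpg": prof.elevated_fpg,
            "bp_category": prof.bp_category,
            "beta_true": truth.beta_true, "dd_true": truth.dd_true,
        }
        for c in PANEL_COLS:
            row[c] = float(np.mean([getattr(q, c) for q in panels]))
        rows.append(row)
    return {
        "subjects": subjects,
        "profiles": profiles,
        "truths": truths,
        "noise_sd": noise_sd,
        "analysis": pd.DataFrame(rows),
        "trial_panels": pd.DataFrame(trial_rows),
    }


def roundtrip_beta_errors(
    config: SimConfig,
    n_subjects: int,
    seed: int,
    *,
    via_echo: bool = True,
    rho: float = DEFAULT_BLOOD_DENSITY,
) -> np.ndarray:
    """Signed relative β errors of the full measurement chain against truth.

    For each simulated subject the latent β is rendered as a waveform
    (optionally through A-mode frames and the echo tracker), re-measured, and
    compared with ``beta_true``.  A validation utility used by the test and
    acceptance suites.
    """
    cfg = config.model_copy(update={"n_subjects": n_subjects, "seed": seed})
    rng = np.random.default_rng(seed)
    subjects = sample_covariates(cfg, rng)
    errs = []
    for s in subjects:
        prof = classify_risks(s)
        truth = latent_beta(
            s, prof.n_risks, 0.0, rng,
            dd_mean=cfg.dd_mean, dd_sd=cfg.dd_sd,
            dd_range=cfg.dd_range, beta_floor=cfg.beta_floor,
        )
        p = PressurePair(s.sbp[0], s.dbp[0])
        wf = waveform_from_truth(truth, p, cfg, rng)
        panel = measure_waveform(wf, p, cfg, rng, via_echo=via_echo, rho=rho)
        errs.append((panel.beta - truth.beta_true) / truth.beta_true)
    return np.array(errs)


# ---------------------------------------------------------------------------
# staged, file-based pipeline
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(config.model_dump_json().encode()).hexdigest()


def _build_analysis_table(cohort_df: pd.DataFrame, panels: pd.DataFrame) -> pd.DataFrame:
    """Merge cohort covariates, risk flags and trial-averaged panels."""
    subjects = cio.frame_to_cohort(cohort_df)
    cov_rows = []
    for s in subjects:
        try:
            prof = classify_risks(s)
        except CarostiffError:
            continue  # e.g. missing HDL: excluded from risk analyses
        cov_rows.append(
            {
                "subject_id": s.subject_id, "age": s.age, "sex": s.sex,
                "sex_code": s.sex_code, "waist": s.waist,
                "sbp": s.sbp_mean, "dbp": s.dbp_mean,
                "fpg": s.fpg, "tgl": s.tgl, "hdl": s.hdl,
                "smoking_years": s.smoking_years,
                "smoking_status": s.smoking_status,
                "alcohol_status": s.alcohol_status,
                "n_cmr": prof.n_risks, "high_risk": prof.high_risk,
                "high_bp": prof.high_bp, "elevated_fpg": prof.elevated_fpg,
                "bp_category": prof.bp_category,
            }
        )
    cov = pd.DataFrame(cov_rows)
    avg = panels.groupby("subject_id")[list(PANEL_COLS)].mean().reset_index()
    return cov.merge(avg, on="subject_id", how="inner")


def smoking_duration_contrasts(analysis: pd.DataFrame) -> pd.DataFrame:
    """Stiffness by years of smoking (<5 / 5–10 / >10) among male smokers."""
    smokers = analysis[
        (analysis["sex"] == "male") & (analysis["smoking_status"] != "never")
    ].copy()
    bins = [
        ("<5", smokers["smoking_years"] < 5),
        ("5-10", (smokers["smoking_years"] >= 5) & (smokers["smoking_years"] <= 10)),
        (">10", smokers["smoking_years"] > 10),
    ]
    base = smokers[bins[0][1]]
    rows = []
    for label, mask in bins:
        sub = smokers[mask]
        row: dict[str, object] = {"smoking_years_band": label, "n": len(sub)}
        for c in ("beta", "ep", "pwv_beta", "ac"):
            m = float(sub[c].mean()) if len(sub) else np.nan
            b = float(base[c].mean()) if len(base) else np.nan
            row[f"{c}_mean"] = m
            row[f"{c}_delta"] = m - b if len(sub) and len(base) else np.nan
            row[f"{c}_pct"] = (
                round(100.0 * (m - b) / b, 1) if len(sub) and len(base) and b else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _quintile_or_table(analysis: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for sex in ("male", "female"):
        sub = analysis[analysis["sex"] == sex]
        if len(sub) < 25 or sub["high_risk"].nunique() < 2:
            continue
        for index_name in ("beta", "ep", "pwv_beta", "ac"):
            values = sub[index_name].to_numpy()
            labels, _ = quintile_assign(values)
            try:
                or_rows = quintile_or(
                    sub["high_risk"].to_numpy().astype(int), labels,
                    sub["age"].to_numpy(), index_name=index_name, values=values,
                )
            except CarostiffError:
                continue
            for r in or_rows:
                rows.append({"sex": sex, **r.__dict__})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, outdir: Path) -> dict:
    """Execute the configured stages into ``outdir`` and return the manifest.

    Re-running with an unchanged config against intact outputs performs no
    recomputation (checksum short-circuit).  Stage order is enforced; asking
    for a downstream stage without its upstream artifacts is a dependency
    error.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    cfg_hash = _config_hash(config)
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") == cfg_hash and all(
            (outdir / f).exists() and _sha256(outdir / f) == h
            for f, h in old.get("files", {}).items()
        ):
            logger.info("outputs up to date; skipping recomputation")
            return old

    produced: dict[str, str] = {}

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        produced[name] = _sha256(path)

    def require(name: str, stage: str) -> Path:
        path = outdir / name
        if name not in produced and not path.exists():
            raise ConfigurationError(
                f"stage '{stage}' requires artifact '{name}'; run its upstream stage"
            )
        return path

    sim = config.sim.model_copy(update={"seed": config.seed})

    if "simulate" in config.stages:
        logger.info("simulate: n=%d seed=%d", sim.n_subjects, config.seed)
        rng = np.random.default_rng(config.seed)
        subjects = sample_covariates(sim, rng)
        profiles = [classify_risks(s) for s in subjects]
        lps = [
            published_linear_predictor(
                "beta",
                age=s.age, sex_code=s.sex_code, sbp=s.sbp_mean, dbp=s.dbp_mean,
                smoking_years=s.smoking_years, n_cmr=p.n_risks,
            )
            for s, p in zip(subjects, profiles)
        ]
        noise_sd = noise_sd_for_r2(lps, sim.target_r2)
        truths = []
        wf_frames = []
        for s, prof in zip(subjects, profiles):
            truth = latent_beta(
                s, prof.n_risks, noise_sd, rng,
                dd_mean=sim.dd_mean, dd_sd=sim.dd_sd,
                dd_range=sim.dd_range, beta_floor=sim.beta_floor,
            )
            truths.append(truth)
            p1 = PressurePair(s.sbp[0], s.dbp[0])
            p2 = PressurePair(s.sbp[1], s.dbp[1])
            wf1 = waveform_from_truth(truth, p1, sim, rng)
            wf2 = replicate_trial(wf1, p2, sim, rng)
            wf_frames.append(cio.waveform_to_frame(wf1, s.subject_id, 1))
            wf_frames.append(cio.waveform_to_frame(wf2, s.subject_id, 2))
        emit("cohort.csv", lambda p: cio.write_cohort_csv(subjects, p))
        emit("truths.csv", lambda p: pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in subjects],
                "beta_true": [t.beta_true for t in truths],
                "dd_true": [t.dd_true for t in truths],
            }
        ).to_csv(p, index=False))
        emit("waveforms.csv", lambda p: pd.concat(wf_frames, ignore_index=True).to_csv(p, index=False))
        if config.with_echo:
            rng_echo = np.random.default_rng(config.seed + 1)
            for s, t in list(zip(subjects, truths))[: config.echo_subjects]:
                p1 = PressurePair(s.sbp[0], s.dbp[0])
                wf = waveform_from_truth(t, p1, sim, rng_echo)
                seq = echo_from_waveform(wf, sim, rng_echo)
                cio.write_echo(seq, outdir / f"echo_{s.subject_id}")
                produced[f"echo_{s.subject_id}.npy"] = _sha256(outdir / f"echo_{s.subject_id}.npy")
                produced[f"echo_{s.subject_id}.json"] = _sha256(outdir / f"echo_{s.subject_id}.json")

    if "track" in config.stages:
        path = require("waveforms.csv", "track")
        wf_long = pd.read_csv(path)
        beat_rows = []
        for (sid, trial), grp in wf_long.groupby(["subject_id", "trial"], sort=True):
            dwf = DistensionWaveform(
                times=grp["time"].to_numpy(), diameter=grp["diameter"].to_numpy()
            )
            try:
                seg = segment_beats(dwf)
            except QualityError:
                logger.warning("subject %s trial %s failed beat QC", sid, trial)
                continue
            for k in range(seg.n_beats):
                beat_rows.append(
                    {"subject_id": sid, "trial": trial, "beat": k,
                     "ds": seg.beat_ds[k], "dd": seg.beat_dd[k],
                     "accepted": bool(seg.accepted[k])}
                )
        emit("beats.csv", lambda p: pd.DataFrame(beat_rows).to_csv(p, index=False))

    if "indices" in config.stages:
        beats_path = require("beats.csv", "indices")
        cohort_path = require("cohort.csv", "indices")
        beats = pd.read_csv(beats_path)
        cohort_df = pd.read_csv(cohort_path)
        bp = cohort_df.set_index("subject_id")
        panel_rows = []
        for (sid, trial), grp in beats.groupby(["subject_id", "trial"], sort=True):
            acc = grp[grp["accepted"]]
            if acc.empty:
                continue
            ps = float(bp.loc[sid, "sbp1" if trial == 1 else "sbp2"])
            pdn = float(bp.loc[sid, "dbp1" if trial == 1 else "dbp2"])
            panel = panel_from_diameters(
                float(acc["ds"].mean()), float(acc["dd"].mean()),
                PressurePair(ps, pdn), config.rho,
            )
            panel_rows.append(
                {"subject_id": sid, "trial": trial,
                 **{c: getattr(panel, c) for c in PANEL_COLS},
                 "ps": ps, "pd": pdn}
            )
        emit("trial_panels.csv", lambda p: pd.DataFrame(panel_rows).to_csv(p, index=False))

    if "qc" in config.stages:
        path = require("trial_panels.csv", "qc")
        panels = pd.read_csv(path)
        wide = panels.pivot(index="subject_id", columns="trial")
        rows = []
        for name in ("dd", "beta", "ep", "ac", "pwv_beta"):
            pair = (wide[(name, 1)].to_numpy(), wide[(name, 2)].to_numpy())
            ok = np.isfinite(pair[0]) & np.isfinite(pair[1])
            summ = rd_summary((pair[0][ok], pair[1][ok]))
            rows.append({"quantity": name, **summ.__dict__})
        emit("repeatability.csv", lambda p: pd.DataFrame(rows).to_csv(p, index=False))

    if "analyze" in config.stages:
        panels_path = require("trial_panels.csv", "analyze")
        cohort_path = require("cohort.csv", "analyze")
        analysis = _build_analysis_table(
            pd.read_csv(cohort_path), pd.read_csv(panels_path)
        )
        emit("analysis.csv", lambda p: analysis.to_csv(p, index=False))
        emit("strata_by_age_sex.csv", lambda p: stratified_summary(
            analysis, exclude_htn_dm=config.exclude_htn_dm
        ).to_csv(p, index=False))
        emit("bp_category_contrasts.csv", lambda p: bp_category_contrasts(analysis).to_csv(p, index=False))
        emit("smoking_duration_contrasts.csv", lambda p: smoking_duration_contrasts(analysis).to_csv(p, index=False))
        emit("quintile_or.csv", lambda p: _quintile_or_table(analysis).to_csv(p, index=False))
        models = fit_predictive_models(analysis)
        emit("regression_models.csv", lambda p: pd.DataFrame(
            [
                {"index_name": m.index_name, **m.coefficients,
                 "intercept": m.intercept, "r_squared": m.r_squared, "n": m.n}
                for m in models.values()
            ]
        ).to_csv(p, index=False))
        emit("report.txt", lambda p: p.write_text(_text_report(analysis, models)))

    manifest = {"config_hash": cfg_hash, "files": produced}
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _text_report(analysis: pd.DataFrame, models: dict) -> str:
    lines = ["Carotid stiffness study report", "=" * 32, ""]
    lines.append(f"subjects analysed: {len(analysis)}")
    for c in ("beta", "ep", "pwv_beta", "ac"):
        lines.append(
            f"  {c:>8}: {analysis[c].mean():8.3f} ± {analysis[c].std(ddof=1):.3f}"
        )
    lines.append("")
    lines.append("Predictive models (OLS):")
    for m in models.values():
        terms = " + ".join(f"{v:+.3f}·{k}" for k, v in m.coefficients.items())
        lines.append(f"  {m.index_name} = {terms} {m.intercept:+.3f}   (R²={m.r_squared:.3f})")
    return "\n".join(lines) + "\n"
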