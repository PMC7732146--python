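"""CSV / matrix file formats binding the pipeline stages together.

Tabular artifacts are plain CSV with documented headers; echo-frame stacks are
saved as a NumPy matrix (frames × samples) with a JSON sidecar carrying the
acquisition metadata (sampling rate, frame times, speed of sound, depth
origin).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .echotrack import DistensionWaveform, EchoSequence
from .synthgen import SubjectCovariates

#: Column order of a cohort CSV (one row per subject).
COHORT_COLUMNS = [
    "subject_id", "age", "sex", "waist",
    "sbp1", "sbp2", "dbp1", "dbp2",
    "fpg", "tgl", "hdl",
    "on_bp_meds", "on_glucose_meds", "on_lipid_meds",
    "smoking_status", "smoking_years", "alcohol_status",
]


def cohort_to_frame(subjects: Sequence[SubjectCovariates]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        rows.append(
            {
                "subject_id": s.subject_id, "age": s.age, "sex": s.sex,
                "waist": s.waist,
                "sbp1": s.sbp[0], "sbp2": s.sbp[1],
                "dbp1": s.dbp[0], "dbp2": s.dbp[1],
                "fpg": s.fpg, "tgl": s.tgl, "hdl": s.hdl,
                "on_bp_meds": s.on_bp_meds,
                "on_glucose_meds": s.on_glucose_meds,
                "on_lipid_meds": s.on_lipid_meds,
                "smoking_status": s.smoking_status,
                "smoking_years": s.smoking_years,
                "alcohol_status": s.alcohol_status,
            }
        )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def frame_to_cohort(df: pd.DataFrame) -> list[SubjectCovariates]:
    subjects = []
    for row in df.itertuples(index=False):
        hdl = float(row.hdl) if pd.notna(row.hdl) else None
        subjects.append(
            SubjectCovariates(
                subject_id=str(row.subject_id),
                age=int(row.age),
                sex=str(row.sex),
                waist=float(row.waist),
                sbp=(float(row.sbp1), float(row.sbp2)),
                dbp=(float(row.dbp1), float(row.dbp2)),
                fpg=float(row.fpg),
                tgl=float(row.tgl),
                hdl=hdl,
                on_bp_meds=bool(row.on_bp_meds),
                on_glucose_meds=bool(row.on_glucose_meds),
                on_lipid_meds=bool(row.on_lipid_meds),
                smoking_status=str(row.smoking_status),
                smoking_years=float(row.smoking_years),
                alcohol_status=str(row.alcohol_status),
            )
        )
    return subjects


def write_cohort_csv(subjects: Sequence[SubjectCovariates], path: Path) -> None:
    cohort_to_frame(subjects).to_csv(path, index=False)


def read_cohort_csv(path: Path) -> list[SubjectCovariates]:
    return frame_to_cohort(pd.read_csv(path))


def waveform_to_frame(
    wf: DistensionWaveform, subject_id: str, trial: int
) -> pd.DataFrame:
    """Long-format rows (subject_id, trial, time, diameter)."""
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "trial": trial,
            "time": wf.times,
            "diameter": wf.diameter,
        }
    )


def write_waveform_csv(wf: DistensionWaveform, path: Path) -> None:
    """Single-waveform CSV: time, diameter [, beat_id, accepted]."""
    df = pd.DataFrame({"time": wf.times, "diameter": wf.diameter})
    if wf.n_beats:
        beat_id = np.full(wf.times.size, -1, dtype=int)
        acc = np.zeros(wf.times.size, dtype=bool)
        b = wf.beat_boundaries
        for k in range(wf.n_beats):
            beat_id[b[k] : b[k + 1]] = k
            acc[b[k] : b[k + 1]] = wf.accepted[k]
        df["beat_id"] = beat_id
        df["accepted"] = acc
    df.to_csv(path, index=False)


def read_waveform_csv(path: Path) -> DistensionWaveform:
    df = pd.read_csv(path)
    return DistensionWaveform(
        times=df["time"].to_numpy(), diameter=df["diameter"].to_numpy()
    )


def write_echo(seq: EchoSequence, path: Path) -> None:
    """Frame matrix as ``<path>.npy`` plus a ``<path>.json`` sidecar."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), seq.samples)
    sidecar = {
        "sampling_rate": seq.sampling_rate,
        "speed_of_sound": seq.speed_of_sound,
        "depth_origin": seq.depth_origin,
        "times": seq.times.tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_echo(path: Path) -> EchoSequence:
    path = Path(path)
    samples = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return EchoSequence(
        samples=samples,
        times=np.asarray(meta["times"], dtype=float),
        sampling_rate=float(meta["sampling_rate"]),
        speed_of_sound=float(meta["speed_of_sound"]),
        depth_origin=float(meta["depth_origin"]),
    )
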