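"""A-mode wall-echo detection, tracking, and beat-segmented distension waveforms.

A single-element A-mode probe held over the common carotid artery returns, per
transmit event, one envelope trace along the scan axis.  The artery shows up as
two strong echo lobes — the proximal (near) and distal (far) wall — moving out
of phase about the lumen centre as the vessel distends with each heart beat.
This module finds those lobes, follows them frame to frame, converts the wall
separation into a lumen-diameter waveform, and segments that waveform into
quality-controlled cardiac cycles ready for the stiffness formulas.

Conventions: depth is measured from the transducer face in millimetres with
``depth = c·t/2``; the proximal wall is the shallower echo.  Wall position is
taken at the envelope-lobe *peak* (not its leading edge).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .errors import DetectionError, GeometryError, QualityError, TrackLossError

__all__ = [
    "EchoFrame",
    "EchoSequence",
    "WallTrack",
    "DistensionWaveform",
    "detect_walls",
    "track_walls",
    "diameter_series",
    "segment_beats",
]


@dataclass(frozen=True)
class EchoFrame:
    """One A-mode envelope trace.

    ``samples`` are non-negative envelope amplitudes on a uniform time grid of
    rate ``sampling_rate`` (Hz); ``speed_of_sound`` (m/s) and ``depth_origin``
    (mm) define the depth axis ``depth_origin + c·t/2``.
    """

    samples: np.ndarray
    sampling_rate: float
    t0: float
    speed_of_sound: float = 1540.0
    depth_origin: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size == 0:
            raise DetectionError("frame must be a non-empty 1-D envelope")
        if not np.all(np.isfinite(samples)) or np.any(samples < 0.0):
            raise DetectionError("envelope samples must be finite and >= 0")
        if self.sampling_rate <= 0.0:
            raise DetectionError("sampling_rate must be > 0")

    @property
    def depth_step_mm(self) -> float:
        return self.speed_of_sound / (2.0 * self.sampling_rate) * 1e3

    @property
    def depth_axis_mm(self) -> np.ndarray:
        return self.depth_origin + self.depth_step_mm * np.arange(self.samples.size)


@dataclass(frozen=True)
class EchoSequence:
    """A stack of frames sharing one depth axis (rows = frames)."""

    samples: np.ndarray  # (n_frames, n_samples)
    times: np.ndarray  # seconds, per frame
    sampling_rate: float
    speed_of_sound: float = 1540.0
    depth_origin: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if self.samples.ndim != 2 or self.samples.shape[0] != self.times.size:
            raise DetectionError("samples must be (n_frames, n_samples)")

    @property
    def depth_step_mm(self) -> float:
        return self.speed_of_sound / (2.0 * self.sampling_rate) * 1e3

    def frame(self, i: int) -> EchoFrame:
        return EchoFrame(
            samples=self.samples[i],
            sampling_rate=self.sampling_rate,
            t0=float(self.times[i]),
            speed_of_sound=self.speed_of_sound,
            depth_origin=self.depth_origin,
        )

    def __len__(self) -> int:
        return self.samples.shape[0]

    def __iter__(self) -> Iterator[EchoFrame]:
        return (self.frame(i) for i in range(len(self)))


@dataclass
class WallTrack:
    """Per-frame proximal/distal wall depths (mm) with confidence in [0, 1]."""

    times: np.ndarray
    proximal_depth: np.ndarray
    distal_depth: np.ndarray
    confidence: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.proximal_depth) == len(self.distal_depth) == len(self.confidence) == n):
            raise GeometryError("track arrays must have equal length")


@dataclass
class DistensionWaveform:
    """Time-resolved lumen diameter, optionally segmented into beats.

    ``beat_boundaries`` are the sample indices of diastolic minima (beat
    starts); beat *k* spans ``[beat_boundaries[k], beat_boundaries[k+1])`` and
    carries its end-systolic/diastolic diameters ``beat_ds[k]``/``beat_dd[k]``
    plus an ``accepted`` quality flag.
    """

    times: np.ndarray
    diameter: np.ndarray  # mm
    beat_boundaries: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    beat_ds: np.ndarray = field(default_factory=lambda: np.empty(0))
    beat_dd: np.ndarray = field(default_factory=lambda: np.empty(0))
    accepted: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.diameter = np.asarray(self.diameter, dtype=float)
        self.beat_boundaries = np.asarray(self.beat_boundaries, dtype=int)
        self.beat_ds = np.asarray(self.beat_ds, dtype=float)
        self.beat_dd = np.asarray(self.beat_dd, dtype=float)
        self.accepted = np.asarray(self.accepted, dtype=bool)
        if np.any(self.diameter <= 0.0):
            raise GeometryError("diameter must be strictly positive")
        if self.beat_boundaries.size > 1 and np.any(np.diff(self.beat_boundaries) <= 0):
            raise GeometryError("beat boundaries must be strictly increasing")

    @property
    def n_beats(self) -> int:
        return int(self.beat_ds.size)

    def unsegmented(self) -> "DistensionWaveform":
        return DistensionWaveform(times=self.times, diameter=self.diameter)


# ---------------------------------------------------------------------------
# peak refinement helpers
# ---------------------------------------------------------------------------


def _log_parabolic_peak(env: np.ndarray, idx: int, halfwidth: int) -> float:
    """Sub-sample peak location by a least-squares parabola on log-amplitude.

    Exact for a Gaussian lobe (whose log is a parabola); falls back to the
    3-point parabola on raw amplitude when the window clips the trace or
    contains non-positive samples.  Returns a fractional sample index.
    """
    lo = max(idx - halfwidth, 0)
    hi = min(idx + halfwidth + 1, env.size)
    window = env[lo:hi]
    x = np.arange(lo, hi, dtype=float)
    if window.size >= 3 and np.all(window > 0.0):
        coeffs = np.polyfit(x - idx, np.log(window), 2)
        if coeffs[0] < 0.0:
            vertex = -coeffs[1] / (2.0 * coeffs[0])
            if abs(vertex) <= halfwidth:
                return idx + float(vertex)
    # 3-point fallback on raw amplitude
    if 0 < idx < env.size - 1:
        y0, y1, y2 = env[idx - 1], env[idx], env[idx + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0.0:
            return idx + float(0.5 * (y0 - y2) / denom)
    return float(idx)


def _parabolic_vertex(y: np.ndarray, i: int) -> float:
    """3-point parabolic sub-sample refinement of an extremum at index ``i``."""
    if i <= 0 or i >= y.size - 1:
        return float(i)
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    if denom == 0.0:
        return float(i)
    delta = 0.5 * (y[i - 1] - y[i + 1]) / denom
    if abs(delta) > 1.0:
        return float(i)
    return i + float(delta)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def detect_walls(
    frame: EchoFrame,
    min_separation: float = 2.0,
    *,
    prominence_frac: float = 0.1,
    refine_halfwidth_mm: float = 0.6,
) -> tuple[float, float, float]:
    """Locate the proximal and distal wall echoes in one frame.

    Returns ``(proximal_mm, distal_mm, confidence)`` where the walls are the
    two highest-prominence envelope peaks separated by at least
    ``min_separation`` mm, each refined to sub-sample precision, and the
    confidence is the weaker peak's prominence normalized by the stronger's.

    Raises :class:`DetectionError` when fewer than two qualifying peaks exist
    (the "reposition probe" condition).
    """
    if min_separation <= 0.0:
        raise DetectionError("min_separation must be > 0")
    env = frame.samples
    dz = frame.depth_step_mm
    peak_max = float(env.max())
    if peak_max <= 0.0:
        raise DetectionError("flat envelope; no echoes")
    idx, props = find_peaks(env, prominence=prominence_frac * peak_max)
    if idx.size < 2:
        raise DetectionError("fewer than two qualifying wall echoes")
    prom = props["prominences"]
    order = np.argsort(prom)[::-1]
    first = idx[order[0]]
    second = None
    second_prom = 0.0
    for j in order[1:]:
        if abs(idx[j] - first) * dz >= min_separation:
            second = idx[j]
            second_prom = prom[j]
            break
    if second is None:
        raise DetectionError("no second echo beyond the minimum separation")
    halfwidth = max(int(round(refine_halfwidth_mm / dz)), 1)
    pos = sorted(
        frame.depth_origin + dz * _log_parabolic_peak(env, int(i), halfwidth)
        for i in (first, second)
    )
    confidence = float(second_prom / prom[order[0]])
    return pos[0], pos[1], confidence


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------


def _ncc_lag(prev: np.ndarray, cur_ext: np.ndarray, max_lag: int) -> tuple[float, float]:
    """Best lag of ``prev`` within the extended current segment by NCC.

    ``cur_ext`` must be ``prev.size + 2*max_lag`` long.  Returns the
    sub-sample lag (samples, positive = deeper) and the NCC peak value.
    """
    p = prev - prev.mean()
    pn = np.linalg.norm(p)
    n = prev.size
    if pn == 0.0:
        return 0.0, 0.0
    # sliding windows of cur_ext, length n
    ncc = np.empty(2 * max_lag + 1)
    num = np.correlate(cur_ext, p, mode="valid")  # length 2*max_lag+1
    # window means/norms via cumulative sums
    c1 = np.concatenate(([0.0], np.cumsum(cur_ext)))
    c2 = np.concatenate(([0.0], np.cumsum(cur_ext * cur_ext)))
    sums = c1[n:] - c1[:-n]
    sqs = c2[n:] - c2[:-n]
    var = sqs - sums * sums / n
    var[var < 0.0] = 0.0
    denom = pn * np.sqrt(var)
    with np.errstate(invalid="ignore", divide="ignore"):
        ncc = np.where(denom > 0.0, num / denom, 0.0)
    k = int(np.argmax(ncc))
    lag = _parabolic_vertex(ncc, k) - max_lag
    return float(lag), float(ncc[k])


def track_walls(
    frames: EchoSequence | Sequence[EchoFrame],
    seed_gates: tuple[float, float],
    gate_halfwidth: float = 1.5,
    *,
    corr_threshold: float = 0.5,
    max_lost_frames: int = 10,
    refine_peak: bool = True,
    refine_halfwidth_mm: float = 0.6,
) -> WallTrack:
    """Track both wall echoes through a frame sequence.

    Each wall keeps a depth gate of half-width ``gate_halfwidth`` mm.  Frame to
    frame, the gated segment is matched against the previous frame's segment by
    normalized cross-correlation searched within ±``gate_halfwidth``, with
    sub-sample lag by parabolic interpolation; the NCC peak value is the
    per-frame confidence.  With ``refine_peak`` (default) the reported depth is
    then re-anchored to the sub-sample envelope-lobe peak inside the updated
    gate, which removes the slow random walk that integrating frame-to-frame
    lags would otherwise accumulate.  The tracker is causal.

    Raises :class:`TrackLossError` when the NCC peak stays below
    ``corr_threshold`` for more than ``max_lost_frames`` consecutive frames.
    """
    if isinstance(frames, EchoSequence):
        seq = frames
    else:
        frames = list(frames)
        seq = EchoSequence(
            samples=np.vstack([f.samples for f in frames]),
            times=np.array([f.t0 for f in frames]),
            sampling_rate=frames[0].sampling_rate,
            speed_of_sound=frames[0].speed_of_sound,
            depth_origin=frames[0].depth_origin,
        )
    env = seq.samples
    dz = seq.depth_step_mm
    n_frames, n_samples = env.shape
    gate_hw = max(int(round(gate_halfwidth / dz)), 2)
    max_lag = gate_hw
    refine_hw = max(int(round(refine_halfwidth_mm / dz)), 1)

    pos = [
        float((seed_gates[0] - seq.depth_origin) / dz),
        float((seed_gates[1] - seq.depth_origin) / dz),
    ]
    out = np.empty((n_frames, 2))
    conf = np.ones(n_frames)
    lost_streak = 0

    def gate(center: float) -> tuple[int, int]:
        c = int(round(center))
        lo = max(c - gate_hw, 0)
        hi = min(c + gate_hw + 1, n_samples)
        return lo, hi

    for w in (0, 1):
        if refine_peak:
            lo, hi = gate(pos[w])
            k = lo + int(np.argmax(env[0, lo:hi]))
            pos[w] = _log_parabolic_peak(env[0], k, refine_hw)
    out[0] = pos
    for i in range(1, n_frames):
        frame_conf = 1.0
        for w in (0, 1):
            lo, hi = gate(pos[w])
            prev_seg = env[i - 1, lo:hi]
            elo = max(lo - max_lag, 0)
            ehi = min(hi + max_lag, n_samples)
            cur_ext = env[i, elo:ehi]
            pad_l = max_lag - (lo - elo)
            pad_r = max_lag - (ehi - hi)
            if pad_l > 0 or pad_r > 0:
                cur_ext = np.pad(cur_ext, (max(pad_l, 0), max(pad_r, 0)))
            lag, peak = _ncc_lag(prev_seg, cur_ext, max_lag)
            frame_conf = min(frame_conf, peak)
            pos[w] = pos[w] + lag
            if refine_peak and peak >= corr_threshold:
                lo2, hi2 = gate(pos[w])
                seg = env[i, lo2:hi2]
                if seg.size and seg.max() > 0.0:
                    k = lo2 + int(np.argmax(seg))
                    pos[w] = _log_parabolic_peak(env[i], k, refine_hw)
        conf[i] = frame_conf
        if frame_conf < corr_threshold:
            lost_streak += 1
            if lost_streak > max_lost_frames:
                raise TrackLossError(
                    f"correlation below {corr_threshold} for {lost_streak} "
                    f"consecutive frames at t={seq.times[i]:.3f}s"
                )
        else:
            lost_streak = 0
        out[i] = pos
    proximal = seq.depth_origin + dz * out[:, 0]
    distal = seq.depth_origin + dz * out[:, 1]
    return WallTrack(
        times=seq.times.copy(),
        proximal_depth=proximal,
        distal_depth=distal,
        confidence=conf,
    )


def diameter_series(track: WallTrack) -> DistensionWaveform:
    """Lumen diameter = distal − proximal wall depth, per frame."""
    d = np.asarray(track.distal_depth, float) - np.asarray(track.proximal_depth, float)
    if np.any(d <= 0.0):
        raise GeometryError("non-positive lumen diameter in track")
    return DistensionWaveform(times=np.asarray(track.times, float), diameter=d)


# ---------------------------------------------------------------------------
# beat segmentation
# ---------------------------------------------------------------------------


def _resample(y: np.ndarray, n: int) -> np.ndarray:
    x_old = np.linspace(0.0, 1.0, y.size)
    return np.interp(np.linspace(0.0, 1.0, n), x_old, y)


def segment_beats(
    waveform: DistensionWaveform,
    hr_bounds: tuple[float, float] = (40.0, 180.0),
    *,
    distension_band: tuple[float, float] = (0.05, 1.5),
    min_beat_correlation: float = 0.8,
    smooth: bool = True,
) -> DistensionWaveform:
    """Segment a diameter waveform into cardiac cycles at diastolic minima.

    Diastolic minima are detected on a lightly smoothed copy subject to the
    inter-beat spacing implied by ``hr_bounds`` (bpm).  Per beat, Dd is the
    diameter at the starting minimum and Ds the maximum within the beat.  A
    beat is accepted iff its distension lies in ``distension_band`` (mm), its
    duration is consistent with ``hr_bounds``, and its shape correlates with
    the median beat at ``min_beat_correlation`` or better.

    Raises :class:`QualityError` when no beat passes the gates.
    """
    d = waveform.diameter
    t = waveform.times
    if d.size < 8:
        raise QualityError("waveform too short to segment")
    fs = 1.0 / float(np.median(np.diff(t)))
    hr_min, hr_max = hr_bounds
    if smooth and d.size >= 9:
        # quartic Savitzky-Golay: near-unbiased at smooth extrema with ~0.75x
        # noise gain at the window centre
        win = int(round(fs * 0.07))
        win = max(win | 1, 7)  # odd, >= 7
        if win < d.size:
            ds_smooth = savgol_filter(d, win, 4)
        else:
            ds_smooth = d.copy()
    else:
        ds_smooth = d.copy()
    min_dist = max(int(fs * 60.0 / hr_max), 1)
    span = float(np.percentile(ds_smooth, 98) - np.percentile(ds_smooth, 2))
    minima, _ = find_peaks(-ds_smooth, distance=min_dist, prominence=0.3 * span)
    if minima.size < 2:
        raise QualityError("fewer than two diastolic minima found")

    # Ds/Dd are read from the smoothed series: a LS-quadratic (Savitzky-Golay)
    # value is unbiased at a smooth extremum, whereas min/max of the raw noisy
    # series would bias the distension upward by order one noise SD.
    beat_dd, beat_ds, accepted, boundaries = [], [], [], []
    shapes = []
    for a, b in zip(minima[:-1], minima[1:]):
        seg = ds_smooth[a:b]
        dd = float(seg[0])
        ds_val = float(seg.max())
        duration = (b - a) / fs
        boundaries.append(int(a))
        beat_dd.append(dd)
        beat_ds.append(ds_val)
        ok_dist = distension_band[0] <= ds_val - dd <= distension_band[1]
        ok_dur = 60.0 / hr_max * 0.8 <= duration <= 60.0 / hr_min * 1.2
        accepted.append(bool(ok_dist and ok_dur))
        shapes.append(_resample(seg, 50))
    boundaries.append(int(minima[-1]))

    accepted = np.array(accepted, dtype=bool)
    if accepted.any():
        ref = np.median(np.vstack([s for s, a in zip(shapes, accepted) if a]), axis=0)
        for k, s in enumerate(shapes):
            if not accepted[k]:
                continue
            sr = s - s.mean()
            rr = ref - ref.mean()
            denom = np.linalg.norm(sr) * np.linalg.norm(rr)
            corr = float(sr @ rr / denom) if denom > 0.0 else 1.0
            if corr < min_beat_correlation:
                accepted[k] = False
    if not accepted.any():
        raise QualityError("no beat passed the quality gates")

    return DistensionWaveform(
        times=t,
        diameter=d,
        beat_boundaries=np.array(boundaries, dtype=int),
        beat_ds=np.array(beat_ds),
        beat_dd=np.array(beat_dd),
        accepted=accepted,
    )
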