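"""Continuous-signal conditioning and movement segmentation.

The processing chain mirrors standard elbow-movement EMG studies: kinematics
are low-pass filtered at 6 Hz, angular velocity is obtained by central
differences, movement onset/offset are found with a 0.01 deg/s velocity
threshold, EMG is power-line band-stop filtered (49-51 Hz) then band-pass
filtered to 3-100 Hz, and each movement is cut out with 3 s pads on both
sides so that downstream wavelet transforms can absorb edge effects.  All
filters are fourth-order zero-lag (forward-backward) Butterworth filters and
the EMG is never rectified.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal

from .core import MovementBounds, MovementTrial, Recording, TimeSeries

logger = logging.getLogger(__name__)

#: velocity threshold (deg/s) defining movement onset/offset
VELOCITY_THRESHOLD = 0.01
#: minimum absolute peak velocity (deg/s) for an excursion to count as a movement
MIN_PEAK_VELOCITY = 5.0


def zero_lag_butterworth(
    series: TimeSeries,
    kind: str,
    cutoffs: float | tuple[float, float],
    order: int = 4,
) -> TimeSeries:
    """Forward-backward Butterworth filter (zero phase, effective order doubled).

    ``kind`` is one of ``"low"``, ``"band"``, ``"stop"``; ``cutoffs`` is a
    scalar for low-pass and a ``(low, high)`` pair otherwise, in Hz, strictly
    inside (0, fs/2).
    """
    btype = {"low": "lowpass", "band": "bandpass", "stop": "bandstop"}.get(kind)
    if btype is None:
        raise ValueError(f"unknown filter kind {kind!r}")
    nyq = series.fs / 2
    edges = np.atleast_1d(np.asarray(cutoffs, dtype=float))
    if np.any(edges <= 0) or np.any(edges >= nyq):
        raise ValueError(f"cutoffs {cutoffs} outside (0, {nyq}) Hz")
    wn = float(edges[0]) if edges.size == 1 else edges
    sos = signal.butter(order, wn, btype=btype, fs=series.fs, output="sos")
    return series.with_samples(signal.sosfiltfilt(sos, series.samples))


def preprocess_kinematics(angle: TimeSeries, lowpass_hz: float = 6.0) -> TimeSeries:
    """6 Hz zero-lag low-pass for the continuous elbow angle."""
    return zero_lag_butterworth(angle, "low", lowpass_hz)


def angular_velocity(angle: TimeSeries) -> TimeSeries:
    """Instantaneous angular velocity by central differences (deg/s).

    Same length as the input; one-sided differences at the two endpoints.
    """
    if angle.n < 3:
        raise ValueError("need at least 3 samples to differentiate")
    v = np.gradient(angle.samples, 1.0 / angle.fs)
    return TimeSeries(v, angle.fs, label=f"{angle.label}_velocity", t0=angle.t0)


def preprocess_emg(series: TimeSeries) -> TimeSeries:
    """Power-line band-stop (49-51 Hz) followed by 3-100 Hz band-pass.

    The EMG is deliberately not rectified: coherence is computed on the raw
    interference signal.
    """
    if series.fs <= 200:
        raise ValueError("EMG sampling rate too low for the 3-100 Hz band-pass")
    notched = zero_lag_butterworth(series, "stop", (49.0, 51.0))
    return zero_lag_butterworth(notched, "band", (3.0, 100.0))


def detect_movement_bounds(
    velocity: TimeSeries,
    threshold: float = VELOCITY_THRESHOLD,
    min_peak_velocity: float = MIN_PEAK_VELOCITY,
) -> list[MovementBounds]:
    """Detect movements from an already low-pass-filtered velocity trace.

    Each contiguous excursion of ``|v|`` above ``threshold`` whose absolute
    peak exceeds ``min_peak_velocity`` yields one movement.  The peak-velocity
    time is the argmax of ``|v|`` within the excursion; onset is the last
    sample before the peak with ``|v| < threshold`` and offset the first such
    sample after it (searching outward from the peak keeps the rule robust to
    a noise floor near the threshold).  Excursions never dropping below the
    peak gate are ignored (tremor/noise); an empty list is returned when no
    movement is found.
    """
    v = velocity.samples
    if np.any(~np.isfinite(v)):
        raise ValueError("velocity contains non-finite values")
    above = np.abs(v) >= threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, v.size]

    out: list[MovementBounds] = []
    for s, e in zip(starts, ends):
        seg = np.abs(v[s:e])
        peak = s + int(np.argmax(seg))
        if np.abs(v[peak]) < min_peak_velocity:
            continue
        i = peak
        while i > 0 and np.abs(v[i]) >= threshold:
            i -= 1
        onset = i
        j = peak
        while j < v.size - 1 and np.abs(v[j]) >= threshold:
            j += 1
        offset = j
        if not (onset < peak < offset):
            continue  # peak at a recording edge: not a usable movement

        # refine onset/offset to the sub-sample threshold crossing: at
        # kinematic rates (125 Hz) the nearest-sample rule alone can be off
        # by more than one sample relative to the analytic crossing
        def crossing(i_below: int, i_above: int) -> float:
            lo, hi = np.abs(v[i_below]), np.abs(v[i_above])
            frac = 0.0 if hi == lo else (threshold - lo) / (hi - lo)
            return i_below + np.clip(frac, 0.0, 1.0) * (i_above - i_below)

        t = velocity.t0
        out.append(
            MovementBounds(
                onset=t + crossing(onset, onset + 1) / velocity.fs,
                offset=t + crossing(offset, offset - 1) / velocity.fs,
                peak_velocity_time=t + peak / velocity.fs,
                peak_velocity=float(v[peak]),
            )
        )
    return out


def extract_trials(
    recording: Recording,
    bounds: list[MovementBounds],
    pad: float = 3.0,
    velocity: TimeSeries | None = None,
) -> list[MovementTrial]:
    """Cut one padded trial per movement from preprocessed continuous data.

    Each trial covers ``[onset - pad, offset + pad]``.  EMG, angle and
    velocity keep their native rates; event times live on the shared session
    clock, so kinematic events are mapped onto the EMG clock by
    nearest-sample conversion when indexing.  Movements whose pads would
    extend past either end of the recording are dropped with a warning.
    """
    if velocity is None:
        velocity = angular_velocity(recording.angle)
    ref = recording.emg["TB"]
    trials: list[MovementTrial] = []
    for k, b in enumerate(bounds):
        lo, hi = b.onset - pad, b.offset + pad
        if lo < ref.t0 or hi > ref.t_end or lo < recording.angle.t0 or hi > recording.angle.t_end:
            logger.warning(
                "dropping movement %d of subject %s: pad [%0.2f, %0.2f] s exceeds recording",
                k, recording.subject, lo, hi,
            )
            continue
        trials.append(
            MovementTrial(
                emg={ch: ts.slice(lo, hi) for ch, ts in recording.emg.items()},
                angle=recording.angle.slice(lo, hi),
                velocity=velocity.slice(lo, hi),
                bounds=b,
                pad=pad,
            )
        )
    return trials
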