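"""Antagonist co-contraction: flexor RMS during extension, in percent of MVC.

The index is the average over the two elbow flexors (BB, BR) of the ratio of
movement RMS (over [onset, offset]) to the muscle's maximal-voluntary-
contraction reference RMS, averaged over movements and expressed in percent.
Averaging per-muscle ratios before combining makes the index invariant to
per-channel amplifier gains; RMS itself makes it invariant to rectification.

The MVC reference comes from a series of (typically three) 5 s maximal
isometric flexion contractions: the trial with the highest plateau torque is
selected and the reference RMS is computed per muscle on its central 3 s
plateau, excluding ramp-up/down.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import FLEXORS, MovementTrial, MVCTrial, TimeSeries


def rms(series: TimeSeries | np.ndarray, window: tuple[float, float] | None = None) -> float:
    """Root-mean-square value, optionally over a time window [start, end] (s)."""
    if isinstance(series, TimeSeries):
        if window is not None:
            series = series.slice(*window)
        x = series.samples
    else:
        x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    return float(np.sqrt(np.mean(x**2)))


@dataclass
class MVCReference:
    """Per-muscle MVC reference RMS (volts), with the selection metadata."""

    reference_rms: dict[str, float]
    selected_trial: int
    max_torque: float

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.reference_rms.values()):
            raise ValueError("MVC reference RMS must be positive")


def mvc_reference(
    mvc_trials: list[MVCTrial],
    muscles: tuple[str, ...] = FLEXORS,
    plateau: float = 3.0,
) -> MVCReference:
    """Select the maximal-torque MVC trial and compute per-muscle plateau RMS.

    The torque scalar of each trial is its mean torque over the central
    ``plateau`` seconds; the trial with the largest value is selected and the
    reference RMS is computed on the same window.
    """
    if not mvc_trials:
        raise ValueError("no MVC trials")

    def plateau_window(ts: TimeSeries) -> tuple[float, float]:
        mid = ts.t0 + ts.duration / 2
        half = min(plateau, ts.duration) / 2
        return (mid - half, mid + half)

    torques = [
        float(np.mean(t.torque.slice(*plateau_window(t.torque)).samples)) for t in mvc_trials
    ]
    if max(torques) <= 0:
        raise ValueError("no valid MVC: all plateau torques are zero")
    best = int(np.argmax(torques))
    trial = mvc_trials[best]
    refs = {}
    for m in muscles:
        if m not in trial.emg:
            raise ValueError(f"MVC trial missing channel {m}")
        refs[m] = rms(trial.emg[m], plateau_window(trial.emg[m]))
    return MVCReference(reference_rms=refs, selected_trial=trial.trial_id, max_torque=torques[best])


@dataclass
class CocontractionIndex:
    """Antagonist co-contraction in percent of MVC, with its components."""

    value: float  # percent
    per_muscle: dict[str, float] = field(default_factory=dict)  # percent, per flexor
    per_movement: np.ndarray = field(default_factory=lambda: np.empty(0))  # percent

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("co-contraction index cannot be negative")


def antagonist_cocontraction(
    trials: list[MovementTrial],
    ref: MVCReference,
    muscles: tuple[str, ...] = FLEXORS,
) -> CocontractionIndex:
    """Flexor activation during extension as percent of the MVC reference.

    Per movement, each flexor's RMS over [onset, offset] is divided by its
    MVC reference and the per-muscle ratios are averaged; the index is the
    mean across movements, in percent.
    """
    if not trials:
        raise ValueError("no movements")
    missing = [m for m in muscles if m not in ref.reference_rms]
    if missing:
        raise ValueError(f"MVC reference missing muscles: {missing}")
    per_movement = []
    per_muscle_acc = {m: [] for m in muscles}
    for t in trials:
        ratios = []
        for m in muscles:
            if m not in t.emg:
                raise ValueError(f"movement trial missing flexor channel {m}")
            r = rms(t.emg_movement(m)) / ref.reference_rms[m]
            ratios.append(r)
            per_muscle_acc[m].append(r)
        per_movement.append(np.mean(ratios))
    return CocontractionIndex(
        value=float(100.0 * np.mean(per_movement)),
        per_muscle={m: float(100.0 * np.mean(v)) for m, v in per_muscle_acc.items()},
        per_movement=100.0 * np.asarray(per_movement),
    )
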