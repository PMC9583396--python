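"""Synthetic elbow-extension sessions with a planted common drive.

The generator emulates the statistical structure the coherence analysis
assumes, so that every downstream stage can be verified against known ground
truth without clinical recordings:

* minimum-jerk elbow extensions (bell-shaped velocity profiles) separated by
  randomized 8-15 s rests, with a slower return flexion after each extension;
* per-muscle EMG built as ``x_i = a_i * s + n_i`` where ``s`` is a
  band-limited (13-31 Hz by default) Gaussian common drive shared by all
  muscles and ``n_i`` is independent noise band-limited to the 3-100 Hz
  analysis band;
* flexor amplitude during each extension scaled so the planted RMS ratio to
  the MVC reference equals ``cocontraction_ratio`` exactly, by construction;
* three 5 s MVC trials with trapezoidal torque, exactly one of which (the
  designated reference) carries a 10 % higher plateau.

Powers are band-referenced: ``source_power`` is the variance of the drive
(which lies entirely inside ``drive_band``) and ``noise_power`` is the noise
variance falling inside that same band.  With this convention the in-band
magnitude-squared coherence between two channels has the closed form
``(a1*a2*Ps)**2 / ((a1**2*Ps + P1) * (a2**2*Ps + P2))`` at every in-band
frequency, which :func:`theoretical_msc` evaluates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal

from .core import EMG_CHANNELS, FLEXORS, MovementBounds, MVCTrial, Recording, TimeSeries

EMG_BAND = (3.0, 100.0)  # noise support matches the preprocessing band-pass


# ---------------------------------------------------------------------------
# configuration & ground truth


@dataclass
class SynthConfig:
    """Study-condition defaults for one simulated limb session.

    Defaults reproduce the recording protocol the analysis targets: 20
    extension movements per limb, EMG at 1000 Hz, kinematics at 125 Hz,
    randomized rests of 8-15 s, a 13-31 Hz (beta) common drive, and a planted
    antagonist co-contraction of 30 % of MVC.
    """

    n_trials: int = 20
    fs_emg: float = 1000.0
    fs_kin: float = 125.0
    movement_duration: float = 1.0
    angle_start: float = 90.0
    angle_end: float = 160.0
    rest_range: tuple[float, float] = (8.0, 15.0)
    coupling_gains: dict[str, float] = field(
        default_factory=lambda: {"TB": 1.0, "BB": 1.0, "BR": 1.0}
    )
    drive_band: tuple[float, float] = (13.0, 31.0)
    source_power: float = 1.0
    noise_power: dict[str, float] = field(
        default_factory=lambda: {"TB": 1.0, "BB": 1.0, "BR": 1.0}
    )
    cocontraction_ratio: float = 0.30
    amplitude_jitter: float = 0.0  # movement-to-movement gain variability (fractional SD)
    mvc_rms: dict[str, float] = field(default_factory=lambda: {"BB": 0.5, "BR": 0.4})
    tb_movement_rms: float = 0.6
    baseline_rms: float = 0.02
    mvc_torque: float = 40.0
    hold_duration: float = 2.0
    lead: float = 4.0  # quiet time at both ends, > segmentation pad
    seed: int = 0
    event_seed: int = 12345  # separate stream: movement schedule is seed-invariant

    def validate(self) -> None:
        if self.n_trials < 2:
            raise ValueError("n_trials must be >= 2")
        if self.fs_emg <= 0 or self.fs_kin <= 0 or self.movement_duration <= 0:
            raise ValueError("rates and durations must be positive")
        lo, hi = self.drive_band
        if not (0 < lo < hi < self.fs_emg / 2):
            raise ValueError(f"drive band {self.drive_band} outside (0, Nyquist)")
        if self.source_power < 0 or any(v < 0 for v in self.noise_power.values()):
            raise ValueError("powers must be >= 0")
        if any(g < 0 for g in self.coupling_gains.values()):
            raise ValueError("coupling gains must be >= 0")
        if not (0 <= self.cocontraction_ratio):
            raise ValueError("cocontraction_ratio must be >= 0")


@dataclass
class GroundTruth:
    """Planted parameters recorded alongside a simulated session."""

    events: list[MovementBounds]
    theoretical_msc: dict[str, float]
    cocontraction_ratio: float
    coupling_gains: dict[str, float]
    mvc_rms: dict[str, float]
    selected_mvc: int
    seed: int


# ---------------------------------------------------------------------------
# primitives


def minimum_jerk_trajectory(
    theta0: float, theta1: float, duration: float, fs: float
) -> TimeSeries:
    """Minimum-jerk angle profile theta(t) = theta0 + dtheta*(10 tau^3 - 15 tau^4 + 6 tau^5).

    Velocity and acceleration vanish at both endpoints; the peak angular
    velocity is ``15*dtheta/(8*duration)`` at mid-movement.
    """
    if duration <= 0 or fs <= 0:
        raise ValueError("duration and fs must be positive")
    t = np.arange(int(np.ceil(duration * fs)) + 1) / fs  # grid reaches `duration`
    tau = np.clip(t / duration, 0.0, 1.0)
    shape = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    return TimeSeries(theta0 + (theta1 - theta0) * shape, fs, label="elbow_angle")


def _minimum_jerk_shape(tau: np.ndarray) -> np.ndarray:
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def minimum_jerk_threshold_crossings(
    dtheta: float, duration: float, threshold: float
) -> tuple[float, float]:
    """Times (relative to movement start) where |velocity| crosses ``threshold``.

    The minimum-jerk speed is ``|dtheta| * 30 tau^2 (1-tau)^2 / duration``;
    the two crossings bracket the bell and are found by bisection.
    """
    a = 30.0 * abs(dtheta) / duration

    def speed(tau: float) -> float:
        return a * tau**2 * (1 - tau) ** 2

    if speed(0.5) <= threshold:
        raise ValueError("movement never exceeds the velocity threshold")
    t_on = optimize.brentq(lambda u: speed(u) - threshold, 0.0, 0.5)
    t_off = optimize.brentq(lambda u: speed(u) - threshold, 0.5, 1.0)
    return t_on * duration, t_off * duration


def theoretical_msc(
    gains: tuple[float, float],
    source_power: float,
    noise_powers: tuple[float, float],
) -> float:
    """Closed-form in-band MSC of ``x_i = a_i*s + n_i`` (band-referenced powers)."""
    a1, a2 = gains
    p1, p2 = noise_powers
    d1 = a1**2 * source_power + p1
    d2 = a2**2 * source_power + p2
    if d1 <= 0 or d2 <= 0:
        raise ValueError("zero total in-band power in a channel: MSC undefined")
    value = (a1 * a2 * source_power) ** 2 / (d1 * d2)
    return float(min(value, 1.0))


def _bandpass(x: np.ndarray, band: tuple[float, float], fs: float) -> np.ndarray:
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def band_limited_source(
    n: int, fs: float, band: tuple[float, float], power: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise filtered into ``band`` and rescaled to variance ``power``."""
    s = _bandpass(rng.standard_normal(n), band, fs)
    v = s.var()
    if power == 0 or v == 0:
        return np.zeros(n)
    return s * np.sqrt(power / v)


def emg_noise(
    n: int,
    fs: float,
    in_band_power: float,
    rng: np.random.Generator,
    drive_band: tuple[float, float],
) -> np.ndarray:
    """Broadband (3-100 Hz) noise whose variance inside ``drive_band`` is
    ``in_band_power`` (empirically rescaled, so the closed-form MSC is exact)."""
    nz = _bandpass(rng.standard_normal(n), EMG_BAND, fs)
    if in_band_power == 0:
        return np.zeros(n)
    v_band = _bandpass(nz, drive_band, fs).var()
    return nz * np.sqrt(in_band_power / v_band)


def generate_common_drive_emg(
    n_samples: int,
    fs: float,
    gains: tuple[float, float],
    band: tuple[float, float] = (13.0, 31.0),
    source_power: float = 1.0,
    noise_powers: tuple[float, float] = (1.0, 1.0),
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Paired EMG-like series sharing a band-limited common drive.

    Returns ``(x1, x2, msc)`` where ``msc`` is the theoretical in-band
    magnitude-squared coherence of the pair.  Deterministic given ``seed``.
    """
    lo, hi = band
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"band {band} outside (0, Nyquist={fs / 2})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    s = band_limited_source(n_samples, fs, band, source_power, rng)
    x1 = gains[0] * s + emg_noise(n_samples, fs, noise_powers[0], rng, band)
    x2 = gains[1] * s + emg_noise(n_samples, fs, noise_powers[1], rng, band)
    return x1, x2, theoretical_msc(gains, source_power, noise_powers)


# ---------------------------------------------------------------------------
# full session


def _smooth_envelope(
    t: np.ndarray, start: float, end: float, ramp: float
) -> np.ndarray:
    """0->1->0 envelope with cosine ramps of width ``ramp`` outside [start, end]."""
    e = np.zeros_like(t)
    up = (t >= start - ramp) & (t < start)
    e[up] = 0.5 * (1 - np.cos(np.pi * (t[up] - (start - ramp)) / ramp))
    e[(t >= start) & (t <= end)] = 1.0
    down = (t > end) & (t <= end + ramp)
    e[down] = 0.5 * (1 + np.cos(np.pi * (t[down] - end) / ramp))
    return e


@dataclass
class SimulatedSession:
    recording: Recording
    mvc_trials: list[MVCTrial]
    truth: GroundTruth


def simulate_session(
    config: SynthConfig,
    subject: str = "sim",
    group: str = "control",
    limb: str = "dominant",
    age: float = 55.0,
) -> SimulatedSession:
    """Generate one limb session: recording, MVC series and ground truth.

    Movement schedule (rest draws, MVC reference choice) comes from
    ``config.event_seed``, the noise from ``config.seed``: changing the noise
    seed leaves every event time identical.
    """
    cfg = config
    cfg.validate()
    event_rng = np.random.default_rng(cfg.event_seed)
    rng = np.random.default_rng(cfg.seed)

    D = cfg.movement_duration
    dtheta = cfg.angle_end - cfg.angle_start
    return_D = 1.5 * D

    # --- schedule
    starts = []
    cursor = cfg.lead
    rests = event_rng.uniform(*cfg.rest_range, size=cfg.n_trials)
    for r in rests:
        cursor += r
        starts.append(cursor)
        cursor += D + cfg.hold_duration + return_D
    total = cursor + cfg.lead

    t_on, t_off = minimum_jerk_threshold_crossings(dtheta, D, 0.01)
    events = [
        MovementBounds(
            onset=s + t_on,
            offset=s + t_off,
            peak_velocity_time=s + D / 2,
            peak_velocity=15 * dtheta / (8 * D),
        )
        for s in starts
    ]

    # --- kinematics (fs_kin clock)
    tk = np.arange(int(round(total * cfg.fs_kin))) / cfg.fs_kin
    angle = np.full(tk.size, cfg.angle_start)
    for s in starts:
        angle += dtheta * _minimum_jerk_shape((tk - s) / D)
        angle -= dtheta * _minimum_jerk_shape((tk - (s + D + cfg.hold_duration)) / return_D)
    angle_ts = TimeSeries(angle, cfg.fs_kin, label="elbow_angle")

    # --- EMG (fs_emg clock)
    n = int(round(total * cfg.fs_emg))
    te = np.arange(n) / cfg.fs_emg
    drive = band_limited_source(n, cfg.fs_emg, cfg.drive_band, cfg.source_power, rng)
    ramp = 0.1
    # The activity plateau extends past the analytic onset/offset because the
    # 6 Hz zero-phase kinematic filter stretches the detected window by up to
    # ~0.2 s at the 0.01 deg/s threshold; RMS is stationary inside the
    # plateau, so the planted ratio is preserved over the detected window.
    margin = 0.25

    emg: dict[str, TimeSeries] = {}
    for ch in EMG_CHANNELS:
        noise = emg_noise(n, cfg.fs_emg, cfg.noise_power[ch], rng, cfg.drive_band)
        active = cfg.coupling_gains[ch] * drive + noise
        base = emg_noise(n, cfg.fs_emg, cfg.noise_power[ch], rng, cfg.drive_band)
        base_scale = cfg.baseline_rms / max(base.std(), 1e-12)
        if ch in FLEXORS:
            target = cfg.cocontraction_ratio * cfg.mvc_rms[ch]
        else:
            target = cfg.tb_movement_rms
        x = np.zeros(n)
        env_total = np.zeros(n)
        for ev, s in zip(events, starts):
            e = _smooth_envelope(te, ev.onset - margin, ev.offset + margin, ramp)
            i0 = int(round(ev.onset * cfg.fs_emg))
            i1 = int(round(ev.offset * cfg.fs_emg))
            seg_rms = np.sqrt(np.mean(active[i0 : i1 + 1] ** 2))
            c = target / max(seg_rms, 1e-12)
            if cfg.amplitude_jitter > 0:
                c *= max(1.0 + cfg.amplitude_jitter * rng.standard_normal(), 0.1)
            x += c * active * e
            env_total = np.maximum(env_total, e)
        x += base_scale * base * (1.0 - env_total)
        emg[ch] = TimeSeries(x, cfg.fs_emg, label=ch)

    recording = Recording(
        subject=subject, group=group, limb=limb, emg=emg, angle=angle_ts, age=age
    )

    # --- MVC series: 3 x 5 s, one designated max-torque trial
    selected = int(event_rng.integers(0, 3))
    mvc_trials: list[MVCTrial] = []
    n_mvc = int(round(5.0 * cfg.fs_emg))
    t_mvc = np.arange(n_mvc) / cfg.fs_emg
    trap = _smooth_envelope(t_mvc, 1.0, 4.0, 1.0)
    for k in range(3):
        plateau = cfg.mvc_torque * (1.10 if k == selected else 1.0)
        torque = plateau * trap + 0.002 * cfg.mvc_torque * rng.standard_normal(n_mvc)
        ch_emg = {}
        for m in FLEXORS:
            nz = emg_noise(n_mvc, cfg.fs_emg, 1.0, rng, cfg.drive_band)
            mid = slice(int(1.0 * cfg.fs_emg), int(4.0 * cfg.fs_emg))
            scale = cfg.mvc_rms[m] / np.sqrt(np.mean((nz * trap)[mid] ** 2))
            ch_emg[m] = TimeSeries(scale * nz * trap, cfg.fs_emg, label=m)
        mvc_trials.append(
            MVCTrial(emg=ch_emg, torque=TimeSeries(torque, cfg.fs_emg, "torque"), trial_id=k)
        )

    pairs = {"TB-BR": ("TB", "BR"), "BB-BR": ("BB", "BR")}
    truth = GroundTruth(
        events=events,
        theoretical_msc={
            name: theoretical_msc(
                (cfg.coupling_gains[a], cfg.coupling_gains[b]),
                cfg.source_power,
                (cfg.noise_power[a], cfg.noise_power[b]),
            )
            for name, (a, b) in pairs.items()
        },
        cocontraction_ratio=cfg.cocontraction_ratio,
        coupling_gains=dict(cfg.coupling_gains),
        mvc_rms=dict(cfg.mvc_rms),
        selected_mvc=selected,
        seed=cfg.seed,
    )
    return SimulatedSession(recording=recording, mvc_trials=mvc_trials, truth=truth)


# ---------------------------------------------------------------------------
# two-group cohorts


@dataclass
class CohortConfig:
    """A two-group cohort with group-specific coupling and a planted negative
    volume/co-contraction association in the paretic group.

    Paretic subjects draw a common-drive gain from N(paretic_gain_mean, sd)
    and receive ``cocontraction = base - slope*(gain - mean) + noise``, so
    stronger common drive comes with weaker antagonist co-contraction; control
    subjects get an uncorrelated, lower co-contraction.
    """

    n_per_group: int = 16
    n_trials: int = 20
    control_gain_mean: float = 0.55
    paretic_gain_mean: float = 0.85
    gain_sd: float = 0.10
    control_cocontraction: float = 0.20
    paretic_cocontraction: float = 0.35
    cocontraction_slope: float = 0.8
    cocontraction_noise: float = 0.02
    seed: int = 0

    def subject_params(self) -> list[dict]:
        """Per-subject draws (deterministic given ``seed``)."""
        rng = np.random.default_rng(self.seed)
        rows = []
        for grp, gain_mean, base in (
            ("control", self.control_gain_mean, self.control_cocontraction),
            ("stroke", self.paretic_gain_mean, self.paretic_cocontraction),
        ):
            for i in range(self.n_per_group):
                gain = float(np.clip(rng.normal(gain_mean, self.gain_sd), 0.1, 1.5))
                if grp == "stroke":
                    ratio = base - self.cocontraction_slope * (gain - gain_mean)
                else:
                    ratio = base
                ratio = float(np.clip(ratio + rng.normal(0, self.cocontraction_noise), 0.02, 0.95))
                rows.append(
                    dict(
                        subject=f"{grp[:3]}{i + 1:02d}",
                        group=grp,
                        limb="paretic" if grp == "stroke" else "dominant",
                        age=float(rng.uniform(35, 75)),
                        gain=gain,
                        cocontraction_ratio=ratio,
                        seed=int(rng.integers(0, 2**31 - 1)),
                        event_seed=int(rng.integers(0, 2**31 - 1)),
                    )
                )
        return rows


def simulate_cohort(cohort: CohortConfig) -> list[SimulatedSession]:
    """One session per subject (paretic limb for stroke, dominant for control)."""
    sessions = []
    for p in cohort.subject_params():
        cfg = SynthConfig(
            n_trials=cohort.n_trials,
            coupling_gains={ch: p["gain"] for ch in EMG_CHANNELS},
            cocontraction_ratio=p["cocontraction_ratio"],
            seed=p["seed"],
            event_seed=p["event_seed"],
        )
        sessions.append(
            simulate_session(cfg, subject=p["subject"], group=p["group"], limb=p["limb"], age=p["age"])
        )
    return sessions
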