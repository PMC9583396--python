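"""End-to-end orchestration: simulate/load -> preprocess -> coherence ->
metrics -> group statistics, reproducibly from a single configuration.

The pipeline consumes either a cohort manifest of delimited-table sessions or
a simulation request, and produces the per-subject long-format metrics table
(one row per limb x muscle pair, carrying the beta-band coherence volume, the
antagonist co-contraction and the ANCOVA covariates) plus the group-level
results: the co-contraction t-test, the limb x muscle-pair ANCOVA for each
requested limb contrast, and the partial Spearman correlation between volume
and co-contraction within the paretic limb.  Every output carries the
configuration hash; per-stage counts are logged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as iomod
from .cocontraction import antagonist_cocontraction, mvc_reference
from .coherence import (
    BETA_BAND,
    QUANT_WINDOW,
    WaveletParams,
    aligned_movement_segments,
    build_frequency_grid,
    imc_volume,
    movement_pair_coherence,
)
from .core import MVCTrial, Recording
from .preprocess import (
    angular_velocity,
    detect_movement_bounds,
    extract_trials,
    preprocess_emg,
    preprocess_kinematics,
)
from .simulate import CohortConfig, simulate_cohort
from .stats import ancova_limb_by_pair, partial_spearman, two_sample_t

logger = logging.getLogger(__name__)

PAIRS = {"TB-BR": ("TB", "BR"), "BB-BR": ("BB", "BR")}


@dataclass
class PipelineConfig:
    """Every tunable constant of the analysis chain, validated on load."""

    wavelet: WaveletParams = field(default_factory=WaveletParams)
    beta_band: tuple[float, float] = BETA_BAND
    window: tuple[float, float] = QUANT_WINDOW
    pad: float = 3.0
    velocity_threshold: float = 0.01
    min_peak_velocity: float = 5.0
    kinematic_lowpass: float = 6.0
    significance: str = "analytic"
    ancova_alpha: float = 0.017
    simulate: CohortConfig | None = None
    manifest: str | None = None
    outdir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.beta_band
        if not lo < hi:
            raise ValueError(f"beta band {self.beta_band} must be (low, high)")
        if not self.window[0] < self.window[1]:
            raise ValueError(f"window {self.window} must be (start, end)")
        if self.pad <= 0:
            raise ValueError("pad must be positive")
        if self.simulate is None and self.manifest is None:
            raise ValueError("config needs either a simulation request or a manifest")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "wavelet" in raw and isinstance(raw["wavelet"], dict):
            raw["wavelet"] = WaveletParams(**raw["wavelet"])
        if "simulate" in raw and isinstance(raw["simulate"], dict):
            raw["simulate"] = CohortConfig(**raw["simulate"])
        for key in ("beta_band", "window"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# per-session analysis


def analyze_session(
    recording: Recording,
    mvc_trials: list[MVCTrial],
    config: PipelineConfig,
) -> tuple[list[dict], dict]:
    """Run preprocessing, coherence and co-contraction for one limb session.

    Returns (metrics rows, stage counts).  Only extension movements (angle
    increasing) are analyzed.
    """
    angle = preprocess_kinematics(recording.angle, config.kinematic_lowpass)
    velocity = angular_velocity(angle)
    bounds = detect_movement_bounds(
        velocity, config.velocity_threshold, config.min_peak_velocity
    )
    extensions = [b for b in bounds if b.direction == "extension"]
    rec_filtered = Recording(
        subject=recording.subject,
        group=recording.group,
        limb=recording.limb,
        age=recording.age,
        emg={ch: preprocess_emg(ts) for ch, ts in recording.emg.items()},
        angle=angle,
    )
    trials = extract_trials(rec_filtered, extensions, pad=config.pad, velocity=velocity)
    counts = dict(
        movements_detected=len(bounds),
        extensions=len(extensions),
        trials_kept=len(trials),
    )
    if len(trials) < 2:
        raise RuntimeError(
            f"subject {recording.subject} ({recording.limb}): "
            f"only {len(trials)} usable movements"
        )

    # MVC EMG gets the same conditioning as movement EMG so the RMS ratio is
    # unbiased by the filters
    mvc_filtered = [
        MVCTrial(
            emg={ch: preprocess_emg(ts) for ch, ts in t.emg.items()},
            torque=t.torque,
            trial_id=t.trial_id,
        )
        for t in mvc_trials
    ]
    ref = mvc_reference(mvc_filtered)
    cci = antagonist_cocontraction(trials, ref)

    grid = build_frequency_grid(config.wavelet, fs=recording.fs_emg)
    stacks, times, _ = aligned_movement_segments(
        trials, ("TB", "BB", "BR"), grid, config.wavelet.wavenumber
    )
    rows = []
    for pair_name, pair in PAIRS.items():
        result = movement_pair_coherence(
            trials, pair, config.wavelet, grid,
            significance=config.significance, stacks=stacks, times=times,
        )
        metrics = imc_volume(result, trials, band=config.beta_band, window=config.window)
        counts[f"significant_cells_{pair_name}"] = int(result.mask.values.sum())
        rows.append(
            dict(
                subject=recording.subject,
                group=recording.group,
                limb=recording.limb,
                muscle_pair=pair_name,
                imc_volume=metrics.volume,
                cocontraction=cci.value,
                mean_angle=metrics.mean_angle,
                mean_velocity=metrics.mean_velocity,
                age=recording.age,
                n_trials=len(trials),
            )
        )
    logger.info("subject %s %s: %s", recording.subject, recording.limb, counts)
    return rows, counts


# ---------------------------------------------------------------------------
# full run


@dataclass
class PipelineResult:
    metrics: pd.DataFrame
    ttest: object
    ancova: dict
    correlation: dict
    counts: list[dict]
    config_hash: str


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full chain; deterministic given the config (and its seeds)."""
    config.validate()
    sessions: list[tuple[Recording, list[MVCTrial]]] = []
    if config.simulate is not None:
        for sess in simulate_cohort(config.simulate):
            sessions.append((sess.recording, sess.mvc_trials))
    else:
        for row in iomod.read_manifest(config.manifest):
            sessions.append((iomod.read_recording(row), iomod.read_mvc(row["mvc"])))

    rows: list[dict] = []
    counts: list[dict] = []
    for rec, mvc in sessions:
        try:
            r, c = analyze_session(rec, mvc, config)
        except Exception as exc:  # noqa: BLE001 - abort with stage context
            raise RuntimeError(
                f"stage 'analyze_session' failed for subject {rec.subject} "
                f"({rec.limb}): {exc}"
            ) from exc
        rows.extend(r)
        counts.append({"subject": rec.subject, "limb": rec.limb, **c})
    metrics = pd.DataFrame(rows)

    limbs = sorted(metrics["limb"].unique())
    ancova: dict[str, dict] = {}
    if {"paretic", "dominant"} <= set(limbs):
        ancova["paretic_vs_dominant"] = ancova_limb_by_pair(
            metrics, ("paretic", "dominant"), alpha=config.ancova_alpha
        )
    if {"paretic", "non-paretic"} <= set(limbs):
        ancova["paretic_vs_non_paretic"] = ancova_limb_by_pair(
            metrics, ("paretic", "non-paretic"), alpha=config.ancova_alpha
        )
    if {"non-paretic", "dominant"} <= set(limbs):
        ancova["non_paretic_vs_dominant"] = ancova_limb_by_pair(
            metrics, ("non-paretic", "dominant"), alpha=config.ancova_alpha
        )

    ttest = None
    correlation: dict = {}
    per_limb = metrics.drop_duplicates(["subject", "limb"])
    if {"paretic", "dominant"} <= set(limbs):
        ttest = two_sample_t(
            per_limb.loc[per_limb.limb == "paretic", "cocontraction"],
            per_limb.loc[per_limb.limb == "dominant", "cocontraction"],
        )
    paretic_bb = metrics[(metrics.limb == "paretic") & (metrics.muscle_pair == "BB-BR")]
    if len(paretic_bb) > 6:
        cov = paretic_bb[["mean_velocity", "mean_angle", "age"]].to_numpy()
        for label, drop in (("with_outliers", False), ("without_outliers", True)):
            correlation[label] = partial_spearman(
                paretic_bb["imc_volume"].to_numpy(),
                paretic_bb["cocontraction"].to_numpy(),
                cov,
                drop_outliers=drop,
            )

    result = PipelineResult(
        metrics=metrics, ttest=ttest, ancova=ancova,
        correlation=correlation, counts=counts, config_hash=config.hash(),
    )
    if config.outdir:
        _write_outputs(Path(config.outdir), result, config)
    return result


def _stat_row(contrast: str, term: str, s) -> dict:
    return dict(
        contrast=contrast, term=term, F=s.statistic, df1=s.df, df2=s.df2,
        p=s.p, partial_eta2=s.effect, significant=s.extra.get("significant"),
    )


def _write_outputs(outdir: Path, result: PipelineResult, config: PipelineConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    meta = f"# config_hash={result.config_hash}\n"
    for name, df in (
        ("metrics.csv", result.metrics),
        ("stage_counts.csv", pd.DataFrame(result.counts)),
    ):
        path = outdir / name
        with open(path, "w") as fh:
            fh.write(meta)
            df.to_csv(fh, index=False)
    anc_rows = [
        _stat_row(contrast, term, s)
        for contrast, terms in result.ancova.items()
        for term, s in terms.items()
    ]
    if anc_rows:
        with open(outdir / "ancova.csv", "w") as fh:
            fh.write(meta)
            pd.DataFrame(anc_rows).to_csv(fh, index=False)
    summary = {
        "config_hash": result.config_hash,
        "config": config.to_dict(),
        "n_rows": len(result.metrics),
        "ttest": None
        if result.ttest is None
        else {"t": result.ttest.statistic, "df": result.ttest.df,
              "p": result.ttest.p, "cohen_d": result.ttest.effect},
        "correlation": {
            k: {"rho": v.statistic, "p": v.p, "ci": v.ci,
                "outliers": v.extra.get("outliers", [])}
            for k, v in result.correlation.items()
        },
    }
    (outdir / "run_summary.json").write_text(json.dumps(summary, indent=1, default=str))
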