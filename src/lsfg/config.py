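"""Configuration objects for the simulation → waveform → statistics pipeline.

Every tunable that corresponds to an underspecified vendor choice (half-level
rule for blowout time, blowout-score formula, skew scaling, rising/falling-rate
definition, intraclass-correlation form, continuity correction) is exposed here
with a documented default; the defaults reproduce the study-fidelity behaviour
described in ``docs/methods.md``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "WaveformConfig",
    "GeneratorConfig",
    "StatsConfig",
    "PipelineConfig",
]


@dataclass
class WaveformConfig:
    """Settings of the cardiac-cycle / pulse-waveform analysis.

    Attributes
    ----------
    n_phase_bins:
        Number of equally spaced phase points of the composite cycle
        (default 30 ≈ one bin per frame at 30 fps and 60 bpm).
    smooth_window:
        Moving-average width (samples) applied before trough detection.
    hr_window:
        Admissible heart-rate range in beats/min; detected cycles whose
        implied rate falls outside are discarded.
    bot_level:
        Half-level rule for blowout time: ``"half"`` = (min+max)/2 (standard
        half-width level), ``"quarter"`` = (min+max)/4.
    skew_scale:
        Multiplier applied to the raw third-moment skewness; the vendor
        scaling is unpublished, so the constant is configurable.
    """

    n_phase_bins: int = 30
    smooth_window: int = 3
    hr_window: tuple[float, float] = (40.0, 120.0)
    bot_level: str = "half"
    skew_scale: float = 10.0

    def __post_init__(self) -> None:
        if self.n_phase_bins < 8:
            raise ValueError("n_phase_bins must be >= 8")
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")
        lo, hi = self.hr_window
        if not 0 < lo < hi:
            raise ValueError("hr_window must satisfy 0 < low < high")
        if self.bot_level not in ("half", "quarter"):
            raise ValueError("bot_level must be 'half' or 'quarter'")


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Age maps are linear in age with Gaussian subject scatter; slopes are
    calibrated once so that the cohort-level correlations with age have the
    direction (and roughly the magnitude) seen in healthy-eye optic-nerve-head
    flowgraphy cohorts.  Units: MBR levels in AU, time constants in seconds,
    pressures in mmHg.
    """

    # acquisition geometry
    n_frames: int = 118
    frame_rate: float = 30.0
    exposure: float = 1.0 / 500.0

    # diastolic MBR floor of the tissue waveform (AU), linear in age
    baseline_at_18: float = 7.5
    baseline_slope_per_year: float = -0.030
    baseline_sd: float = 1.2

    # systolic rise above the floor (AU)
    amplitude_mean: float = 10.0
    amplitude_sd: float = 1.5

    # Windkessel-style diastolic decay constant (s), decreases with age
    tau_at_18: float = 0.75
    tau_slope_per_year: float = -0.006
    tau_sd: float = 0.10

    # fraction of the cycle occupied by the systolic upstroke
    rise_fraction_at_18: float = 0.30
    rise_fraction_slope_per_year: float = -0.0004
    rise_fraction_sd: float = 0.03

    # heart rate (bpm), mild decline with age
    hr_at_18: float = 75.0
    hr_slope_per_year: float = -0.10
    hr_sd: float = 9.0

    # systemic covariates
    sbp_at_18: float = 119.0
    sbp_slope_per_year: float = 0.19
    sbp_sex_shift: float = 4.3  # + for male, − for female
    sbp_sd: float = 10.0
    dbp_at_18: float = 78.0
    dbp_slope_per_year: float = 0.08
    dbp_sex_shift: float = 2.0
    dbp_sd: float = 7.0
    min_pulse_pressure: float = 20.0
    iop_mean: float = 12.8
    iop_sd: float = 2.4

    # noise model
    measurement_noise_sd: float = 0.4  # per-frame additive noise (AU)
    between_scan_sd: float = 0.35  # per-scan baseline offset (AU)
    phase_jitter: bool = True  # random cardiac phase at scan start

    # vessel/tissue structure
    vessel_ratio_mean: float = 3.35  # vessel MBR scale relative to tissue
    vessel_ratio_sd: float = 0.35
    vessel_fraction_mean: float = 0.39  # vessel share of the ONH area
    vessel_fraction_sd: float = 0.03

    # scan-failure model (Bernoulli per scan)
    failure_prob_undilated: float = 15.0 / 240.0
    failure_prob_dilated: float = 3.0 / 240.0

    # additive index shifts applied to dilated-condition rows
    dilation_offsets: dict[str, float] = field(
        default_factory=lambda: {
            "MA": -0.2,
            "MV": -0.4,
            "MT": 0.0,
            "BOT": -0.9,
            "BOS": -1.6,
            "Skew": 0.6,
            "ATI": -0.7,
            "RR": 0.2,
            "FR": 0.2,
            "FAI": 0.07,
            "RI": 0.02,
        }
    )

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        for name in ("baseline_sd", "amplitude_sd", "tau_sd", "rise_fraction_sd",
                     "hr_sd", "sbp_sd", "dbp_sd", "iop_sd",
                     "measurement_noise_sd", "between_scan_sd",
                     "vessel_ratio_sd", "vessel_fraction_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("failure_prob_undilated", "failure_prob_dilated"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def noise_free(self) -> "GeneratorConfig":
        """Return a copy with every stochastic element switched off.

        All noise SDs and failure probabilities are zeroed and the random
        cardiac phase is fixed, so every generator collapses to its analytic
        core and repeated scans of a subject are identical.
        """
        return dataclasses.replace(
            self,
            baseline_sd=0.0,
            amplitude_sd=0.0,
            tau_sd=0.0,
            rise_fraction_sd=0.0,
            hr_sd=0.0,
            sbp_sd=0.0,
            dbp_sd=0.0,
            iop_sd=0.0,
            measurement_noise_sd=0.0,
            between_scan_sd=0.0,
            vessel_ratio_sd=0.0,
            vessel_fraction_sd=0.0,
            failure_prob_undilated=0.0,
            failure_prob_dilated=0.0,
            phase_jitter=False,
        )


@dataclass
class StatsConfig:
    """Settings of the study statistics."""

    icc_form: str = "icc3"  # icc3 | icc2 | oneway
    yates: bool = False  # continuity correction for the 2x2 chi-square
    welch: bool = False  # Welch instead of pooled-variance independent t
    alpha: float = 0.05
    map_formula: str = "standard"  # standard: DBP + (SBP-DBP)/3

    def __post_init__(self) -> None:
        if self.icc_form not in ("icc3", "icc2", "oneway"):
            raise ValueError("icc_form must be one of icc3, icc2, oneway")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.map_formula not in ("standard", "printed"):
            raise ValueError("map_formula must be 'standard' or 'printed'")


@dataclass
class PipelineConfig:
    """Top-level configuration: one seed, one generator, one analysis chain."""

    seed: int = 0
    n_per_cell: int = 10  # subjects per age-group × sex cell
    repeats: int = 3  # scans per condition
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    waveform: WaveformConfig = field(default_factory=WaveformConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def __post_init__(self) -> None:
        if self.n_per_cell < 1:
            raise ValueError("n_per_cell must be >= 1")
        if self.repeats < 2:
            raise ValueError("repeats must be >= 2 (repeatability undefined)")

    # -- serialisation ---------------------------------------------------

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data)
        kwargs: dict[str, Any] = {}
        for section, section_cls in (
            ("generator", GeneratorConfig),
            ("waveform", WaveformConfig),
            ("stats", StatsConfig),
        ):
            if section in data:
                sub = data.pop(section)
                _check_keys(sub, section_cls, section)
                if section == "waveform" and "hr_window" in sub:
                    sub["hr_window"] = tuple(sub["hr_window"])
                kwargs[section] = section_cls(**sub)
        _check_keys(data, cls, "pipeline")
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["waveform"]["hr_window"] = list(d["waveform"]["hr_window"])
        return d

    def config_hash(self) -> str:
        """Stable hash of the full configuration, recorded in run logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _check_keys(data: dict[str, Any], cls: type, where: str) -> None:
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown {where} config keys: {sorted(unknown)}")
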