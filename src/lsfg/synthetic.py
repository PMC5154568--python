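"""Synthetic flowgraphy data with the statistical structure of a healthy cohort.

The generator emulates, at the mean-blur-rate (MBR) level, what an optic
nerve head (ONH) flowgraphy study records: per-scan MBR time series sampled
at the camera frame rate, 2-D flow-map stacks with a vessel/tissue structure,
and a full cohort table (4 age groups × 2 sexes × n subjects, 3 repeated
scans before and after pupil dilation) with systemic covariates.

The analytic pulse model is piecewise: a raised-cosine systolic upstroke over
a fraction ``systolic_rise_fraction`` of the cardiac period, followed by an
exponential diastolic decay with time constant ``diastolic_decay_tau`` — a
Windkessel-style curve.  Arterial stiffening with age is modelled as a linear
decrease of the decay constant (faster diastolic run-off) plus a mild decline
of the diastolic MBR floor, which is what drives the cohort-level
correlations of the waveform indices with age.

Every generator is a pure function of its inputs and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import GeneratorConfig, WaveformConfig
from .waveform import INDEX_NAMES, MbrSeries, NoCycleError, waveform_profile

__all__ = [
    "SubjectProfile",
    "FlowMapStack",
    "GroundTruthScene",
    "COHORT_COLUMNS",
    "AGE_GROUPS",
    "simulate_subject",
    "mbr_waveform",
    "generate_mbr_series",
    "make_scene",
    "generate_flowmap_stack",
    "simulate_cohort",
]

AGE_GROUPS = ((18, 34), (35, 49), (50, 64), (65, 80))

COHORT_COLUMNS = [
    "subject_id", "age", "sex", "sbp", "dbp", "hr", "iop",
    "condition", "repeat", "scan_success",
    "MA", "MV", "MT",
    "BOT", "BOS", "Skew", "ATI", "RR", "FR", "FAI", "RI",
]


@dataclass
class SubjectProfile:
    """Physiological parameters of one synthetic subject."""

    subject_id: str
    age: float  # years
    sex: str  # male | female
    heart_rate: float  # beats/min
    mbr_baseline: float  # AU, diastolic floor of tissue MBR
    pulse_amplitude: float  # AU, systolic rise above the floor
    systolic_rise_fraction: float  # fraction of the cycle before the peak
    diastolic_decay_tau: float  # s, Windkessel-style decay constant
    sbp: float  # mmHg
    dbp: float  # mmHg
    iop: float  # mmHg
    measurement_noise_sd: float = 0.0  # AU, per-frame
    between_scan_sd: float = 0.0  # AU, per-scan baseline offset

    def __post_init__(self) -> None:
        if not 18 <= self.age <= 80:
            raise ValueError(f"age must lie in [18, 80], got {self.age}")
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if not 40 <= self.heart_rate <= 120:
            raise ValueError("heart_rate must lie in [40, 120] bpm")
        if self.pulse_amplitude < 0:
            raise ValueError("pulse_amplitude must be >= 0")
        if self.pulse_amplitude > 0 and not 0 < self.systolic_rise_fraction < 0.5:
            raise ValueError("systolic_rise_fraction must lie in (0, 0.5)")
        if self.diastolic_decay_tau <= 0:
            raise ValueError("diastolic_decay_tau must be positive")
        if not self.sbp > self.dbp > 0:
            raise ValueError("need sbp > dbp > 0")
        if self.measurement_noise_sd < 0 or self.between_scan_sd < 0:
            raise ValueError("noise SDs must be >= 0")

    @property
    def period(self) -> float:
        """Cardiac period in seconds."""
        return 60.0 / self.heart_rate


@dataclass
class GroundTruthScene:
    """Ground truth for segmentation tests: ONH ellipse + surface-vessel mask."""

    center: tuple[float, float]  # (x, y) pixels
    semi_axes: tuple[float, float]  # (a, b) pixels
    rotation: float  # degrees
    vessel_mask: np.ndarray  # bool, True = surface vessel
    tissue_flow_scale: float  # AU
    vessel_flow_scale: float  # AU

    def __post_init__(self) -> None:
        self.vessel_mask = np.asarray(self.vessel_mask, dtype=bool)
        if not self.vessel_flow_scale > self.tissue_flow_scale > 0:
            raise ValueError("need vessel_flow_scale > tissue_flow_scale > 0")
        h, w = self.vessel_mask.shape
        cx, cy = self.center
        r = max(self.semi_axes)
        if not (r <= cx <= w - 1 - r and r <= cy <= h - 1 - r):
            raise ValueError("ellipse must lie fully inside the frame")

    @property
    def shape(self) -> tuple[int, int]:
        return self.vessel_mask.shape


@dataclass
class FlowMapStack:
    """An ordered stack of 2-D MBR maps (one per frame)."""

    frames: np.ndarray  # (n_frames, height, width), AU
    frame_rate: float = 30.0
    exposure: float = 1.0 / 500.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, height, width)")
        if np.any(self.frames < 0):
            raise ValueError("MBR values must be non-negative")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


# ---------------------------------------------------------------------------
# subject + waveform
# ---------------------------------------------------------------------------


def simulate_subject(
    age: float,
    sex: str,
    rng_seed: int | np.random.Generator,
    config: Optional[GeneratorConfig] = None,
    subject_id: str = "S000",
) -> SubjectProfile:
    """Draw one subject's physiological parameters.

    The age maps are linear with Gaussian scatter: the diastolic decay
    constant strictly decreases in expectation with age (arterial stiffening),
    the systolic rise fraction weakly decreases, and male subjects have a
    higher mean systolic pressure than female subjects.
    """
    if not 18 <= age <= 80:
        raise ValueError(f"age must lie in [18, 80], got {age}")
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(rng_seed)
    years = age - 18.0

    def draw(mean: float, sd: float) -> float:
        return float(mean + sd * rng.standard_normal()) if sd > 0 else float(mean)

    baseline = max(draw(cfg.baseline_at_18 + cfg.baseline_slope_per_year * years,
                        cfg.baseline_sd), 2.0)
    amplitude = max(draw(cfg.amplitude_mean, cfg.amplitude_sd), 2.0)
    tau = max(draw(cfg.tau_at_18 + cfg.tau_slope_per_year * years, cfg.tau_sd), 0.05)
    rise = float(np.clip(
        draw(cfg.rise_fraction_at_18 + cfg.rise_fraction_slope_per_year * years,
             cfg.rise_fraction_sd), 0.08, 0.45))
    hr = float(np.clip(draw(cfg.hr_at_18 + cfg.hr_slope_per_year * years, cfg.hr_sd),
                       45.0, 115.0))
    sex_sign = 1.0 if sex == "male" else -1.0
    sbp = draw(cfg.sbp_at_18 + cfg.sbp_slope_per_year * years
               + sex_sign * cfg.sbp_sex_shift, cfg.sbp_sd)
    dbp = draw(cfg.dbp_at_18 + cfg.dbp_slope_per_year * years
               + sex_sign * cfg.dbp_sex_shift, cfg.dbp_sd)
    dbp = float(np.clip(dbp, 45.0, sbp - cfg.min_pulse_pressure))
    iop = float(np.clip(draw(cfg.iop_mean, cfg.iop_sd), 7.0, 21.0))

    return SubjectProfile(
        subject_id=subject_id,
        age=float(age),
        sex=sex,
        heart_rate=hr,
        mbr_baseline=baseline,
        pulse_amplitude=amplitude,
        systolic_rise_fraction=rise,
        diastolic_decay_tau=tau,
        sbp=sbp,
        dbp=dbp,
        iop=iop,
        measurement_noise_sd=cfg.measurement_noise_sd,
        between_scan_sd=cfg.between_scan_sd,
    )


def mbr_waveform(profile: SubjectProfile, t: np.ndarray | float) -> np.ndarray:
    """Noise-free analytic MBR pulse at times ``t`` (seconds).

    Periodic with the cardiac period; within each period the curve rises from
    the diastolic minimum to ``baseline + amplitude`` along a raised cosine
    over ``systolic_rise_fraction`` of the period, then decays exponentially
    toward the baseline with time constant ``diastolic_decay_tau``.  The curve
    is continuous across the cycle boundary: the upstroke starts at the level
    the decay reached at the end of the previous cycle.
    """
    t = np.asarray(t, dtype=float)
    b, A = profile.mbr_baseline, profile.pulse_amplitude
    if A == 0:
        return np.full_like(t, b)
    T = profile.period
    f = profile.systolic_rise_fraction
    tau = profile.diastolic_decay_tau
    e_end = np.exp(-(1.0 - f) * T / tau)  # residual elevation at cycle end
    p = np.mod(t, T) / T
    out = np.empty_like(p)
    rising = p < f
    out[rising] = b + A * (e_end + (1.0 - e_end)
                           * 0.5 * (1.0 - np.cos(np.pi * p[rising] / f)))
    out[~rising] = b + A * np.exp(-(p[~rising] - f) * T / tau)
    return out


def generate_mbr_series(
    profile: SubjectProfile,
    n_frames: int = 118,
    frame_rate: float = 30.0,
    rng_seed: int | np.random.Generator = 0,
    phase_offset: Optional[float] = None,
    scan_id: str = "",
    region_label: str = "tissue",
) -> MbrSeries:
    """Sample the analytic pulse at frame times with noise and a random phase.

    ``phase_offset`` (seconds) overrides the random phase; when ``None`` a
    uniform offset over one cardiac period is drawn (scans start at an
    arbitrary cardiac phase).  Additive Gaussian frame noise with SD
    ``profile.measurement_noise_sd`` is truncated at zero (MBR ≥ 0).
    """
    if n_frames / frame_rate < 2.0 * profile.period:
        raise ValueError(
            "series must span at least 2 cardiac cycles "
            f"({n_frames} frames at {frame_rate} fps < 2×{profile.period:.2f} s)"
        )
    rng = np.random.default_rng(rng_seed)
    if phase_offset is None:
        phase_offset = float(rng.uniform(0.0, profile.period))
    t = np.arange(n_frames) / frame_rate + phase_offset
    values = mbr_waveform(profile, t)
    if profile.measurement_noise_sd > 0:
        values = values + profile.measurement_noise_sd * rng.standard_normal(n_frames)
    values = np.maximum(values, 0.0)
    return MbrSeries(values=values, frame_rate=frame_rate,
                     scan_id=scan_id, region_label=region_label)


# ---------------------------------------------------------------------------
# flow-map stacks
# ---------------------------------------------------------------------------


def make_scene(
    rng_seed: int | np.random.Generator = 0,
    shape: tuple[int, int] = (360, 750),
    tissue_flow_scale: float = 12.0,
    vessel_flow_scale: float = 40.0,
    n_vessels: int = 5,
) -> GroundTruthScene:
    """Build a ground-truth scene: centred ONH ellipse with radial vessels.

    Vessels are drawn as thick line segments radiating from near the ellipse
    centre, mimicking the branching pattern of retinal surface vessels.
    """
    from skimage.draw import line as draw_line
    from skimage.morphology import dilation, disk

    rng = np.random.default_rng(rng_seed)
    h, w = shape
    cx, cy = w / 2.0, h / 2.0
    a = 0.22 * w
    b = 0.30 * h
    mask = np.zeros(shape, dtype=bool)
    thickness = max(2, int(0.012 * min(h, w)))
    for _ in range(n_vessels):
        ang = rng.uniform(0, 2 * np.pi)
        x0 = int(cx + rng.uniform(-0.1, 0.1) * a)
        y0 = int(cy + rng.uniform(-0.1, 0.1) * b)
        x1 = int(np.clip(cx + 1.2 * a * np.cos(ang), 0, w - 1))
        y1 = int(np.clip(cy + 1.2 * b * np.sin(ang), 0, h - 1))
        rr, cc = draw_line(y0, x0, y1, x1)
        mask[rr, cc] = True
    mask = dilation(mask, disk(thickness))
    return GroundTruthScene(
        center=(cx, cy),
        semi_axes=(a, b),
        rotation=0.0,
        vessel_mask=mask,
        tissue_flow_scale=tissue_flow_scale,
        vessel_flow_scale=vessel_flow_scale,
    )


def generate_flowmap_stack(
    profile: SubjectProfile,
    scene: GroundTruthScene,
    n_frames: int = 118,
    frame_rate: float = 30.0,
    rng_seed: int | np.random.Generator = 0,
    pixel_noise_sd: float = 0.0,
    phase_offset: float = 0.0,
) -> FlowMapStack:
    """Render a stack of flow maps from the scene and the subject's pulse.

    Per-pixel value = (vessel or tissue flow scale) × the unit-mean pulse at
    the frame time, plus optional additive Gaussian pixel noise truncated at
    zero.  Vessel pixels therefore exceed tissue pixels in time-averaged
    value by exactly the ratio of the two scales (at zero noise).
    """
    rng = np.random.default_rng(rng_seed)
    t = np.arange(n_frames) / frame_rate + phase_offset
    pulse = mbr_waveform(profile, t)
    pulse = pulse / pulse.mean()  # unit time-mean over the sampled frames
    base = np.where(scene.vessel_mask, scene.vessel_flow_scale,
                    scene.tissue_flow_scale)
    frames = pulse[:, None, None] * base[None, :, :]
    if pixel_noise_sd > 0:
        frames = frames + pixel_noise_sd * rng.standard_normal(frames.shape)
    frames = np.maximum(frames, 0.0)
    return FlowMapStack(frames=frames, frame_rate=frame_rate)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def simulate_cohort(
    n_per_cell: int = 10,
    repeats: int = 3,
    rng_seed: int | np.random.Generator = 0,
    config: Optional[GeneratorConfig] = None,
    waveform_config: Optional[WaveformConfig] = None,
) -> pd.DataFrame:
    """Simulate the full study table: 4 age groups × 2 sexes × ``n_per_cell``.

    Each subject contributes ``repeats`` scans per condition (undilated,
    dilated).  Every successful scan is pushed through the actual waveform
    pipeline (:func:`lsfg.waveform.waveform_profile`) on a simulated tissue
    MBR series — the cohort table is produced by the analysis under test,
    not copied from formulas.  MV comes from a scaled vessel series; MA is
    the area-weighted mixture of MV and MT.

    Scans fail (``scan_success = False``, indices missing) with the
    configured per-condition Bernoulli probabilities; undilated scans fail
    more often, emulating small natural pupils.
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    if repeats < 2:
        raise ValueError("repeats must be >= 2 (repeatability undefined)")
    cfg = config or GeneratorConfig()
    wcfg = waveform_config or WaveformConfig()
    rng = np.random.default_rng(rng_seed)

    rows: list[dict] = []
    sid = 0
    for lo, hi in AGE_GROUPS:
        for sex in ("male", "female"):
            for _ in range(n_per_cell):
                sid += 1
                age = float(rng.uniform(lo, hi))
                subject_id = f"S{sid:03d}"
                profile = simulate_subject(age, sex, rng, cfg, subject_id)
                ratio = max(float(cfg.vessel_ratio_mean
                                  + cfg.vessel_ratio_sd * rng.standard_normal()), 1.2)
                vfrac = float(np.clip(
                    cfg.vessel_fraction_mean
                    + cfg.vessel_fraction_sd * rng.standard_normal(), 0.2, 0.6))
                for condition, p_fail in (
                    ("undilated", cfg.failure_prob_undilated),
                    ("dilated", cfg.failure_prob_dilated),
                ):
                    for rep in range(1, repeats + 1):
                        row = {
                            "subject_id": subject_id,
                            "age": age,
                            "sex": sex,
                            "sbp": profile.sbp,
                            "dbp": profile.dbp,
                            "hr": profile.heart_rate,
                            "iop": profile.iop,
                            "condition": condition,
                            "repeat": rep,
                            "scan_success": True,
                        }
                        failed = rng.uniform() < p_fail
                        indices = None
                        if not failed:
                            indices = _scan_indices(
                                profile, ratio, vfrac, cfg, wcfg, rng)
                            failed = indices is None
                        if failed:
                            row["scan_success"] = False
                            row.update({c: np.nan for c in COHORT_COLUMNS[10:]})
                        else:
                            if condition == "dilated":
                                for k, off in cfg.dilation_offsets.items():
                                    indices[k] = indices.get(k, np.nan) + off
                            row.update(indices)
                        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def _scan_indices(
    profile: SubjectProfile,
    vessel_ratio: float,
    vessel_fraction: float,
    cfg: GeneratorConfig,
    wcfg: WaveformConfig,
    rng: np.random.Generator,
) -> Optional[dict[str, float]]:
    """One scan: simulate tissue + vessel series, run the waveform pipeline."""
    offset = (cfg.between_scan_sd * rng.standard_normal()
              if cfg.between_scan_sd > 0 else 0.0)
    scan_profile = SubjectProfile(
        subject_id=profile.subject_id,
        age=profile.age,
        sex=profile.sex,
        heart_rate=profile.heart_rate,
        mbr_baseline=max(profile.mbr_baseline + offset, 1.0),
        pulse_amplitude=profile.pulse_amplitude,
        systolic_rise_fraction=profile.systolic_rise_fraction,
        diastolic_decay_tau=profile.diastolic_decay_tau,
        sbp=profile.sbp,
        dbp=profile.dbp,
        iop=profile.iop,
        measurement_noise_sd=profile.measurement_noise_sd,
        between_scan_sd=profile.between_scan_sd,
    )
    phase = None if cfg.phase_jitter else 0.0
    try:
        tissue = generate_mbr_series(
            scan_profile, cfg.n_frames, cfg.frame_rate, rng,
            phase_offset=phase, region_label="tissue")
        wp = waveform_profile(tissue, wcfg)
        # vessel waveform: same shape scaled up, with its own frame noise
        vessel_profile = SubjectProfile(
            subject_id=profile.subject_id,
            age=profile.age,
            sex=profile.sex,
            heart_rate=profile.heart_rate,
            mbr_baseline=scan_profile.mbr_baseline * vessel_ratio,
            pulse_amplitude=scan_profile.pulse_amplitude * vessel_ratio,
            systolic_rise_fraction=profile.systolic_rise_fraction,
            diastolic_decay_tau=profile.diastolic_decay_tau,
            sbp=profile.sbp,
            dbp=profile.dbp,
            iop=profile.iop,
            measurement_noise_sd=profile.measurement_noise_sd * vessel_ratio,
        )
        vessel = generate_mbr_series(
            vessel_profile, cfg.n_frames, cfg.frame_rate, rng,
            phase_offset=phase, region_label="vessel")
        mv = waveform_profile(vessel, wcfg).mean_mbr
    except NoCycleError:
        return None
    mt = wp.mean_mbr
    ma = vessel_fraction * mv + (1.0 - vessel_fraction) * mt
    out = {"MA": ma, "MV": mv, "MT": mt}
    d = wp.as_dict()
    for name in INDEX_NAMES:
        out[name] = d[name]
    return out
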