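"""Cardiac-cycle detection, phase normalisation, and pulse-waveform indices.

The primary flowgraphy output is a mean-blur-rate (MBR) time series sampled at
the camera frame rate over ~4 s.  The analysis chain is:

1. :func:`detect_cycles` — locate diastolic troughs in a lightly smoothed
   series; consecutive troughs bound one cardiac cycle.
2. :func:`composite_cycle` — resample each cycle onto a common normalised
   phase axis and average, yielding one composite cycle.
3. The eight pulse-waveform indices of the composite cycle:

   ========  =====================================================
   BOT       % of the cycle above the half-level between min and max
   BOS       100·(1 − (max−min)/(2·mean)): constancy of flow
   Skew      scaled third-moment asymmetry of the value distribution
   ATI       % of the cycle elapsed before the peak
   RR / FR   mean per-bin rise / fall over the monotone limbs, / mean, ×100
   FAI       largest increment between adjacent phase bins (AU/frame)
   RI        (max − min)/max: pulsatility proxy
   ========  =====================================================

:func:`waveform_profile` runs the whole chain and is the single entry point
used by the cohort simulator and the CLI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .config import WaveformConfig

__all__ = [
    "MbrSeries",
    "CycleSegmentation",
    "PulseCycle",
    "WaveformIndices",
    "detect_cycles",
    "composite_cycle",
    "blowout_time",
    "blowout_score",
    "skew",
    "acceleration_time_index",
    "rising_rate",
    "falling_rate",
    "flow_acceleration_index",
    "resistivity_index",
    "waveform_profile",
    "NoCycleError",
]

INDEX_NAMES = ("BOT", "BOS", "Skew", "ATI", "RR", "FR", "FAI", "RI")


class NoCycleError(ValueError):
    """No admissible cardiac cycle could be detected in a series."""


@dataclass
class MbrSeries:
    """A per-scan MBR time series.

    Parameters
    ----------
    values : array of MBR samples (AU), one per frame, all ≥ 0.
    frame_rate : acquisition rate in frames/s.
    scan_id : opaque scan identifier.
    region_label : which ONH region the series was averaged over.
    """

    values: np.ndarray
    frame_rate: float
    scan_id: str = ""
    region_label: str = "all"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("MbrSeries needs a 1-D array of >= 2 samples")
        if np.any(self.values < 0):
            raise ValueError("MBR values must be non-negative")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.region_label not in ("all", "vessel", "tissue"):
            raise ValueError("region_label must be all|vessel|tissue")

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        return self.n_samples / self.frame_rate


@dataclass
class CycleSegmentation:
    """Cycle boundaries: trough sample indices, cycles half-open [b[i], b[i+1])."""

    boundaries: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=int)
        if self.boundaries.size < 2:
            raise NoCycleError("no cardiac cycle detected")
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly increasing")

    @property
    def n_cycles(self) -> int:
        return int(self.boundaries.size - 1)

    @property
    def cycle_lengths(self) -> np.ndarray:
        return np.diff(self.boundaries)


@dataclass
class PulseCycle:
    """One phase-normalised composite cardiac cycle."""

    phase_values: np.ndarray
    cycle_duration: float  # seconds, mean over detected cycles
    n_phase_bins: int = field(init=False)

    def __post_init__(self) -> None:
        self.phase_values = np.asarray(self.phase_values, dtype=float)
        self.n_phase_bins = int(self.phase_values.size)
        if self.n_phase_bins < 8:
            raise ValueError("a pulse cycle needs >= 8 phase bins")
        if np.any(self.phase_values < 0):
            raise ValueError("phase values must be non-negative")
        if self.cycle_duration <= 0:
            raise ValueError("cycle_duration must be positive")


@dataclass
class WaveformIndices:
    """The eight pulse-waveform parameters plus mean MBR for one scan/region."""

    mean_mbr: float
    bot: float
    bos: float
    skew: float
    ati: float
    rr: float
    fr: float
    fai: float
    ri: float

    def __post_init__(self) -> None:
        if not 0 <= self.bot <= 100:
            raise ValueError("BOT out of [0, 100]")
        if not 0 <= self.bos <= 100:
            raise ValueError("BOS out of [0, 100]")
        if not 0 <= self.ati <= 100:
            raise ValueError("ATI out of [0, 100]")
        if not 0 <= self.ri <= 1:
            raise ValueError("RI out of [0, 1]")
        if self.fai < 0:
            raise ValueError("FAI must be >= 0")
        if self.mean_mbr <= 0:
            raise ValueError("mean MBR must be positive")

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_mbr": self.mean_mbr,
            "BOT": self.bot,
            "BOS": self.bos,
            "Skew": self.skew,
            "ATI": self.ati,
            "RR": self.rr,
            "FR": self.fr,
            "FAI": self.fai,
            "RI": self.ri,
        }


# ---------------------------------------------------------------------------
# cycle detection and phase normalisation
# ---------------------------------------------------------------------------


def detect_cycles(
    series: MbrSeries, config: Optional[WaveformConfig] = None
) -> CycleSegmentation:
    """Detect cardiac cycles as stretches between successive diastolic troughs.

    The series is smoothed with a short moving average, local minima are
    located, and consecutive minima whose spacing implies a heart rate inside
    the physiological window are kept (the longest admissible run).

    Raises
    ------
    NoCycleError
        If no pair of troughs with an admissible spacing exists — this maps
        to the study's scan-quality exclusion.
    """
    config = config or WaveformConfig()
    v = series.values
    fr = series.frame_rate
    if config.smooth_window > 1:
        v = uniform_filter1d(v, size=config.smooth_window, mode="nearest")

    hr_lo, hr_hi = config.hr_window
    min_len = fr * 60.0 / hr_hi  # shortest admissible cycle, samples
    max_len = fr * 60.0 / hr_lo
    if np.ptp(v) == 0:
        raise NoCycleError("no cardiac cycle detected: series has no pulsatility")

    troughs, _ = signal.find_peaks(
        -v, distance=max(1, int(np.floor(min_len))), prominence=0.05 * np.ptp(v)
    )
    if troughs.size < 2:
        raise NoCycleError("no cardiac cycle detected: fewer than two troughs")

    gaps = np.diff(troughs)
    ok = (gaps >= min_len) & (gaps <= max_len)
    if not ok.any():
        raise NoCycleError("no cardiac cycle detected: no admissible cycle length")

    # longest consecutive run of admissible gaps
    best_start, best_len, start, run = 0, 0, 0, 0
    for i, good in enumerate(ok):
        if good:
            run += 1
            if run > best_len:
                best_len, best_start = run, start
        else:
            start, run = i + 1, 0
    boundaries = troughs[best_start : best_start + best_len + 1]
    return CycleSegmentation(boundaries=boundaries, frame_rate=fr)


def composite_cycle(
    series: MbrSeries,
    seg: CycleSegmentation,
    n_phase_bins: int = 30,
) -> PulseCycle:
    """Average all detected cycles on a common normalised phase axis.

    Each cycle ``[s, e)`` is resampled to ``n_phase_bins`` points by linear
    interpolation at phases k/n_phase_bins, then cycles are averaged
    pointwise.  With a single cycle and ``n_phase_bins`` equal to its length
    this is the identity.
    """
    if n_phase_bins < 8:
        raise ValueError("n_phase_bins must be >= 8")
    idx = np.arange(series.n_samples, dtype=float)
    phases = np.arange(n_phase_bins, dtype=float) / n_phase_bins
    resampled = np.empty((seg.n_cycles, n_phase_bins))
    for k in range(seg.n_cycles):
        s, e = seg.boundaries[k], seg.boundaries[k + 1]
        positions = s + phases * (e - s)
        resampled[k] = np.interp(positions, idx, series.values)
    duration = float(np.mean(seg.cycle_lengths)) / series.frame_rate
    return PulseCycle(phase_values=resampled.mean(axis=0), cycle_duration=duration)


# ---------------------------------------------------------------------------
# pulse-waveform indices
# ---------------------------------------------------------------------------


def _level(cycle: PulseCycle, rule: str) -> float:
    mn, mx = cycle.phase_values.min(), cycle.phase_values.max()
    return (mn + mx) / 2.0 if rule == "half" else (mn + mx) / 4.0


def blowout_time(cycle: PulseCycle, level_rule: str = "half") -> float:
    """BOT: percent of the cycle spent above the half-level between min and max.

    High BOT indicates well-maintained perfusion between heartbeats.  A flat
    cycle sits at the level everywhere and is defined as 100 (with a warning).
    """
    v = cycle.phase_values
    if v.max() == v.min():
        warnings.warn("flat cycle: blowout time defined as 100", stacklevel=2)
        return 100.0
    level = _level(cycle, level_rule)
    return 100.0 * float(np.mean(v > level))


def blowout_score(cycle: PulseCycle) -> float:
    """BOS = 100·(1 − (max − min)/(2·mean)): constancy of flow over the cycle."""
    v = cycle.phase_values
    m = v.mean()
    if m <= 0:
        raise ValueError("blowout score undefined for zero-mean cycle")
    bos = 100.0 * (1.0 - (v.max() - v.min()) / (2.0 * m))
    if not 0.0 <= bos <= 100.0:
        warnings.warn(f"blowout score {bos:.2f} clipped to [0, 100]", stacklevel=2)
        bos = float(np.clip(bos, 0.0, 100.0))
    return float(bos)


def skew(cycle: PulseCycle, scale: float = 10.0) -> float:
    """Scaled third-moment asymmetry of the waveform shape.

    The waveform is treated as a distribution of flow over the cycle: phase
    bins are weighted by their MBR value and the standardised third moment
    of that phase distribution is returned, times a configurable scale
    constant (the vendor scaling is unpublished; all sign and symmetry
    properties are scale-free).

    Exactly 0 for a waveform symmetric in time about its peak; positive for
    a leftward (early-peaked) waveform with a long diastolic tail; negated
    by time-mirroring the cycle.
    """
    v = cycle.phase_values
    if np.unique(v).size < 3:
        raise ValueError("skew needs >= 3 distinct values")
    if v.std() == 0:
        raise ValueError("skew undefined for zero-variance cycle")
    w = v / v.sum()
    p = np.arange(v.size, dtype=float)
    mu = float((w * p).sum())
    m2 = float((w * (p - mu) ** 2).sum())
    m3 = float((w * (p - mu) ** 3).sum())
    return float(scale * m3 / m2**1.5)


def acceleration_time_index(cycle: PulseCycle) -> float:
    """ATI: percent of the cycle elapsed before the peak (first occurrence)."""
    return 100.0 * float(np.argmax(cycle.phase_values)) / cycle.n_phase_bins


def _monotone_segment(v: np.ndarray, start: int, stop: int) -> np.ndarray:
    """Values from bin ``start`` to ``stop`` walking forward cyclically."""
    n = v.size
    if stop >= start:
        return v[start : stop + 1]
    return np.concatenate([v[start:], v[: stop + 1]])


def rising_rate(cycle: PulseCycle) -> float:
    """RR: mean per-bin increment over the ascending limb, / mean MBR, ×100."""
    return _limb_rate(cycle, rising=True)


def falling_rate(cycle: PulseCycle) -> float:
    """FR: mean per-bin decrement over the descending limb, / mean MBR, ×100.

    FR grows as the diastolic decay steepens, making it a marker of a more
    pulsatile, less buffered flow pattern.
    """
    return _limb_rate(cycle, rising=False)


def _limb_rate(cycle: PulseCycle, rising: bool) -> float:
    v = cycle.phase_values
    imin, imax = int(np.argmin(v)), int(np.argmax(v))
    if imin == imax or v.max() == v.min():
        raise ValueError("rising/falling rate undefined for a flat cycle")
    seg = (
        _monotone_segment(v, imin, imax) if rising else _monotone_segment(v, imax, imin)
    )
    d = np.diff(seg)
    steps = d[d > 0] if rising else -d[d < 0]
    if steps.size == 0:
        raise ValueError("no monotone limb found")
    return 100.0 * float(steps.mean()) / float(v.mean())


def flow_acceleration_index(cycle: PulseCycle) -> float:
    """FAI: the largest MBR increment between adjacent phase bins (cyclic)."""
    v = cycle.phase_values
    inc = np.roll(v, -1) - v
    return float(max(inc.max(), 0.0))


def resistivity_index(cycle: PulseCycle) -> float:
    """RI = (max − min)/max ∈ [0, 1]; zero iff the cycle is flat."""
    v = cycle.phase_values
    if v.max() <= 0:
        raise ValueError("resistivity index undefined for non-positive cycle")
    return float((v.max() - v.min()) / v.max())


# ---------------------------------------------------------------------------
# single entry point
# ---------------------------------------------------------------------------


def indices_from_cycle(
    cycle: PulseCycle, config: Optional[WaveformConfig] = None
) -> WaveformIndices:
    """Compute all eight indices plus mean MBR on an existing composite cycle."""
    config = config or WaveformConfig()
    return WaveformIndices(
        mean_mbr=float(cycle.phase_values.mean()),
        bot=blowout_time(cycle, config.bot_level),
        bos=blowout_score(cycle),
        skew=skew(cycle, config.skew_scale),
        ati=acceleration_time_index(cycle),
        rr=rising_rate(cycle),
        fr=falling_rate(cycle),
        fai=flow_acceleration_index(cycle),
        ri=resistivity_index(cycle),
    )


def waveform_profile(
    series: MbrSeries, config: Optional[WaveformConfig] = None
) -> WaveformIndices:
    """Full chain: detect cycles → composite cycle → all indices.

    Raises :class:`NoCycleError` when the series shows no admissible
    pulsatility (the scan would be excluded in a real study).
    """
    config = config or WaveformConfig()
    seg = detect_cycles(series, config)
    cycle = composite_cycle(series, seg, config.n_phase_bins)
    return indices_from_cycle(cycle, config)
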