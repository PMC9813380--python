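"""Synthetic high-density sEMG generator.

Emulates the acquisition that the analysis pipeline expects: a 64-channel
monopolar grid recording of a submaximal isometric contraction following a
trapezoidal excitation target (linear up-ramp, hold, linear down-ramp),
sampled at 2,048 Hz.

The generative model is deliberately simple but physiologically shaped:

* a pool of motor units whose territories scatter around an active region
  of the grid, with recruitment thresholds increasing with unit size
  (Henneman's size principle: small, low-threshold units fire first);
* each recruited unit fires as a Gamma-renewal point process (shape 5,
  giving an ISI coefficient of variation of ~0.45) whose rate follows the
  excitation drive above its threshold;
* each discharge contributes a biphasic action-potential waveform (first
  derivative of a Gaussian, ~10 ms) to every channel, attenuated by an
  isotropic exponential decay of the electrode-to-territory distance;
* additive white measurement noise.

Muscle-fiber conduction-velocity propagation, pinnation and a realistic
volume conductor are intentionally out of scope; the generator's job is to
provide recordings with a *known* active region, contraction profile,
noise level and bad channels so every downstream stage is testable.

All randomness is driven by explicit integer seeds; identical seeds and
parameters give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ValidationError
from .grid import ElectrodeGrid

DEFAULT_FS_HZ = 2048.0
#: plateau length used throughout the analysis (5 s at 2,048 Hz)
PLATEAU_SAMPLES = 10_240


@dataclass(frozen=True)
class MotorUnit:
    territory_center: tuple[float, float]  # continuous (row, col) grid coords
    territory_radius_mm: float
    peak_amp: float
    waveform_ms: float
    recruitment_threshold: float  # fraction of maximum excitation, [0, 1)
    base_rate_hz: float
    rate_gain_hz: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.recruitment_threshold < 1.0:
            raise ValidationError("recruitment threshold must lie in [0, 1)")
        if self.territory_radius_mm <= 0 or self.peak_amp <= 0:
            raise ValidationError("territory radius and amplitude must be positive")


@dataclass(frozen=True)
class MotorUnitPool:
    units: tuple[MotorUnit, ...]

    def __len__(self) -> int:
        return len(self.units)


@dataclass(frozen=True)
class ExcitationProfile:
    """Piecewise-linear trapezoidal drive, sampled at ``fs_hz``."""

    times: np.ndarray  # seconds
    level: np.ndarray  # fraction of maximum, [0, 1]
    fs_hz: float
    hold_slice: slice  # samples belonging to the hold phase

    @property
    def plateau_level(self) -> float:
        return float(self.level.max(initial=0.0))


@dataclass(frozen=True)
class Recording:
    """samples x channels voltage matrix plus acquisition geometry."""

    data: np.ndarray
    fs_hz: float
    grid: ElectrodeGrid
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2:
            raise ValidationError("recording data must be 2-D (samples x channels)")
        if data.shape[1] != self.grid.n_channels:
            raise ValidationError(
                f"recording has {data.shape[1]} channels, grid expects "
                f"{self.grid.n_channels}"
            )
        if self.fs_hz <= 0:
            raise ValidationError("sampling rate must be positive")
        if not np.all(np.isfinite(data)):
            raise ValidationError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray, **meta_updates) -> "Recording":
        meta = {**self.meta, **meta_updates}
        return Recording(data=data, fs_hz=self.fs_hz, grid=self.grid, meta=meta)


def make_trapezoid_profile(
    up_s: float,
    hold_s: float,
    down_s: float,
    level: float,
    fs_hz: float = DEFAULT_FS_HZ,
) -> ExcitationProfile:
    """Trapezoidal excitation: 0 -> ``level`` over ``up_s``, hold, back to 0.

    The profile is sampled on the closed interval [0, up+hold+down] at
    ``fs_hz``; ramps are exactly linear.
    """
    if up_s <= 0 or hold_s <= 0 or down_s <= 0:
        raise ValidationError("all trapezoid durations must be positive")
    if not 0.0 < level <= 1.0:
        raise ValidationError("plateau level must lie in (0, 1]")
    if fs_hz <= 0:
        raise ValidationError("sampling rate must be positive")
    total = up_s + hold_s + down_s
    n = int(round(total * fs_hz)) + 1
    times = np.arange(n) / fs_hz
    knots_t = [0.0, up_s, up_s + hold_s, total]
    knots_v = [0.0, level, level, 0.0]
    values = np.interp(times, knots_t, knots_v)
    hold_start = int(np.ceil(up_s * fs_hz - 1e-9))
    hold_stop = int(np.floor((up_s + hold_s) * fs_hz + 1e-9)) + 1
    return ExcitationProfile(
        times=times, level=values, fs_hz=fs_hz, hold_slice=slice(hold_start, hold_stop)
    )


def generate_pool(
    n_units: int,
    active_center: tuple[float, float],
    spread_mm: float,
    seed: int,
    grid: ElectrodeGrid | None = None,
    mean_radius_mm: float = 6.0,
    max_threshold: float = 0.8,
    base_rate_hz: float = 8.0,
    rate_gain_hz: float = 30.0,
) -> MotorUnitPool:
    """Draw a motor-unit pool clustered around ``active_center``.

    Thresholds and peak amplitudes are jointly ordered so that larger units
    have strictly higher recruitment thresholds (size principle). Territory
    centers scatter with standard deviation ``spread_mm`` around the active
    center; radii are log-normal around ``mean_radius_mm``.
    """
    if n_units < 1:
        raise ValidationError("n_units must be >= 1")
    if spread_mm < 0:
        raise ValidationError("spread_mm must be non-negative")
    grid = grid or ElectrodeGrid()
    r0, c0 = active_center
    if not (-0.5 <= r0 <= grid.n_rows - 0.5 and -0.5 <= c0 <= grid.n_cols - 0.5):
        raise ValidationError("active_center must lie within the grid extent")
    rng = np.random.default_rng(seed)
    spread_px = spread_mm / grid.ied_mm
    centers = np.column_stack(
        [
            rng.normal(r0, spread_px, n_units),
            rng.normal(c0, spread_px, n_units),
        ]
    )
    radii = mean_radius_mm * rng.lognormal(0.0, 0.3, n_units)
    # size principle: sort both so threshold increases with amplitude
    amps = np.sort(rng.lognormal(0.0, 0.5, n_units))
    thresholds = np.sort(rng.uniform(0.0, max_threshold, n_units))
    # strictness for reproducible ordering even under ties
    thresholds = thresholds + np.arange(n_units) * 1e-9
    thresholds = np.clip(thresholds, 0.0, np.nextafter(1.0, 0.0))
    units = tuple(
        MotorUnit(
            territory_center=(float(centers[i, 0]), float(centers[i, 1])),
            territory_radius_mm=float(radii[i]),
            peak_amp=float(amps[i]),
            waveform_ms=10.0,
            recruitment_threshold=float(thresholds[i]),
            base_rate_hz=base_rate_hz,
            rate_gain_hz=rate_gain_hz,
        )
        for i in range(n_units)
    )
    return MotorUnitPool(units=units)


def _muap_waveform(waveform_ms: float, fs_hz: float) -> np.ndarray:
    """Biphasic kernel: first derivative of a Gaussian, peak amplitude 1."""
    half = waveform_ms / 2000.0  # seconds
    sigma = half / 3.0
    t = np.arange(-half, half + 0.5 / fs_hz, 1.0 / fs_hz)
    w = -t * np.exp(-(t**2) / (2 * sigma**2))
    peak = np.abs(w).max()
    return w / peak if peak > 0 else w


def _gamma_renewal_spikes(
    rate_hz: np.ndarray, fs_hz: float, rng: np.random.Generator, shape: float = 5.0
) -> np.ndarray:
    """Sample spike indices of an inhomogeneous Gamma-renewal process.

    Implemented by time-warping: a stationary unit-rate Gamma renewal
    process is generated in operational time and mapped back through the
    cumulative intensity of ``rate_hz``.
    """
    total = float(rate_hz.sum()) / fs_hz  # integral of the rate
    if total <= 0:
        return np.empty(0, dtype=int)
    # draw enough unit-mean ISIs to cover the warped duration
    n_draw = max(16, int(total * 1.5) + 8 * int(np.sqrt(total) + 1))
    isis = rng.gamma(shape, 1.0 / shape, n_draw)
    arrival = np.cumsum(isis)
    while arrival[-1] < total:
        isis = rng.gamma(shape, 1.0 / shape, n_draw)
        arrival = np.append(arrival, arrival[-1] + np.cumsum(isis))
    arrival = arrival[arrival < total]
    cum = np.cumsum(rate_hz) / fs_hz
    return np.searchsorted(cum, arrival)


def render_recording(
    pool: MotorUnitPool,
    profile: ExcitationProfile,
    grid: ElectrodeGrid | None = None,
    noise_rms: float = 0.0,
    seed: int = 0,
) -> Recording:
    """Mix MUAP trains of all recruited units onto the grid.

    A unit is recruited wherever the excitation exceeds its threshold; its
    instantaneous rate is ``base_rate + gain * (excitation - threshold)``.
    Every discharge adds the unit's biphasic waveform to each channel,
    scaled by ``peak_amp * exp(-distance_mm / territory_radius_mm)``.
    """
    if noise_rms < 0:
        raise ValidationError("noise_rms must be non-negative")
    grid = grid or ElectrodeGrid()
    rng = np.random.default_rng(seed)
    n = len(profile.level)
    data = np.zeros((n, grid.n_channels))
    positions = grid.positions_mm()  # (ch, 2) in (x, y) mm
    exc = profile.level
    for unit in pool.units:
        drive = exc - unit.recruitment_threshold
        rate = np.where(drive > 0, unit.base_rate_hz + unit.rate_gain_hz * drive, 0.0)
        spikes = _gamma_renewal_spikes(rate, profile.fs_hz, rng)
        if spikes.size == 0:
            continue
        train = np.zeros(n)
        np.add.at(train, spikes, 1.0)
        kernel = _muap_waveform(unit.waveform_ms, profile.fs_hz)
        source = np.convolve(train, kernel, mode="same")
        row, col = unit.territory_center
        ux, uy = col * grid.ied_mm, row * grid.ied_mm
        dist = np.hypot(positions[:, 0] - ux, positions[:, 1] - uy)
        gains = unit.peak_amp * np.exp(-dist / unit.territory_radius_mm)
        data += np.outer(source, gains)
    if noise_rms > 0:
        data += rng.normal(0.0, noise_rms, size=data.shape)
    meta = {
        "seed": seed,
        "noise_rms": noise_rms,
        "n_units": len(pool),
        "plateau_slice": [profile.hold_slice.start, profile.hold_slice.stop],
        "plateau_level": profile.plateau_level,
    }
    return Recording(data=data, fs_hz=profile.fs_hz, grid=grid, meta=meta)


def inject_bad_channels(
    rec: Recording, channels: list[int], gain: float, seed: int = 0
) -> Recording:
    """Replace ``channels`` with gain-scaled white noise (fault injection).

    The noise standard deviation is ``gain`` times the median channel RMS of
    the recording, mimicking a saturated or detached electrode.
    """
    channels = list(channels)
    if len(set(channels)) != len(channels):
        raise ValidationError("duplicate channel indices")
    if any(not 0 <= ch < rec.n_channels for ch in channels):
        raise ValidationError("channel index out of range")
    if len(channels) >= rec.n_channels:
        raise ValidationError("cannot corrupt every channel: nothing left to repair from")
    if not channels:
        return rec
    rng = np.random.default_rng(seed)
    scale = gain * float(np.median(np.sqrt(np.mean(rec.data**2, axis=0))))
    data = rec.data.copy()
    for ch in channels:
        data[:, ch] = rng.normal(0.0, scale, rec.n_samples)
    return rec.with_data(data, injected_channels=sorted(channels))


def simulate_recording(
    n_units: int = 60,
    active_center: tuple[float, float] = (3.5, 3.5),
    spread_mm: float = 10.0,
    level: float = 0.6,
    up_s: float = 6.0,
    hold_s: float = 6.0,
    down_s: float = 8.0,
    noise_rms: float = 0.05,
    seed: int = 0,
    grid: ElectrodeGrid | None = None,
    fs_hz: float = DEFAULT_FS_HZ,
    plateau_samples: int = PLATEAU_SAMPLES,
) -> Recording:
    """One-call convenience: pool + trapezoid + mixing.

    The hold phase is trimmed (centered) so the metadata ``plateau_slice``
    spans exactly ``plateau_samples`` samples, matching the segment length
    the analysis operates on.
    """
    grid = grid or ElectrodeGrid()
    pool = generate_pool(n_units, active_center, spread_mm, seed=seed, grid=grid)
    profile = make_trapezoid_profile(up_s, hold_s, down_s, level, fs_hz)
    rec = render_recording(pool, profile, grid, noise_rms=noise_rms, seed=seed + 1)
    start, stop = rec.meta["plateau_slice"]
    if stop - start > plateau_samples:
        mid = (start + stop) // 2
        start = mid - plateau_samples // 2
        stop = start + plateau_samples
    meta = {
        **rec.meta,
        "plateau_slice": [int(start), int(stop)],
        "active_center": list(active_center),
        "spread_mm": spread_mm,
        "level": level,
    }
    return Recording(data=rec.data, fs_hz=rec.fs_hz, grid=grid, meta=meta)
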