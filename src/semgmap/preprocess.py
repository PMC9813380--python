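"""Signal conditioning ahead of map generation.

Steps, in the order the pipeline applies them: per-channel mean removal,
plateau segmentation, zero-lag (forward-backward) second-order Butterworth
band-pass at 20-400 Hz, and outlier-channel detection via Z-scores of the
log channel RMS. Outlier repair replaces a bad channel by the mean of its
unflagged grid neighbors within Chebyshev radius 1; by default the pipeline
applies the repair at the map-pixel level, but :func:`repair_channels` also
accepts a raw recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .exceptions import (
    EmptySegmentError,
    UnrecoverableChannelError,
    ValidationError,
)
from .grid import ElectrodeGrid
from .simulate import Recording


@dataclass(frozen=True)
class PreprocessConfig:
    band_low_hz: float = 20.0
    band_high_hz: float = 400.0
    filter_order: int = 2
    z_threshold: float = 3.0
    repair_radius_px: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValidationError("band edges must satisfy 0 < low < high")
        if self.filter_order < 1:
            raise ValidationError("filter order must be >= 1")
        if self.z_threshold <= 0:
            raise ValidationError("z_threshold must be positive")
        if self.repair_radius_px < 1:
            raise ValidationError("repair radius must be >= 1")


@dataclass(frozen=True)
class OutlierReport:
    channel_z: np.ndarray  # Z-score of log channel RMS, per channel
    flagged: tuple[int, ...]
    replaced_fraction: float = 0.0


def mean_center(rec: Recording) -> Recording:
    """Remove each channel's sample mean."""
    if rec.n_samples == 0:
        raise ValidationError("empty recording")
    return rec.with_data(rec.data - rec.data.mean(axis=0, keepdims=True))


def bandpass_zero_lag(rec: Recording, cfg: PreprocessConfig | None = None) -> Recording:
    """Forward-backward Butterworth band-pass (zero phase, order doubled).

    Edge transients are controlled with odd-reflection padding of three
    filter lengths, scipy's default for ``filtfilt``.
    """
    cfg = cfg or PreprocessConfig()
    nyq = rec.fs_hz / 2.0
    if cfg.band_high_hz >= nyq:
        raise ValidationError(
            f"band edge {cfg.band_high_hz} Hz >= Nyquist ({nyq} Hz)"
        )
    sos = signal.butter(
        cfg.filter_order,
        [cfg.band_low_hz, cfg.band_high_hz],
        btype="bandpass",
        fs=rec.fs_hz,
        output="sos",
    )
    out = signal.sosfiltfilt(sos, rec.data, axis=0)
    return rec.with_data(out)


def segment_plateau(
    rec: Recording,
    force: np.ndarray | None = None,
    criterion: float = 0.95,
) -> Recording:
    """Extract the hold-phase sub-recording.

    If the recording metadata carries a generator ``plateau_slice`` it is
    used verbatim. Otherwise ``force`` (or excitation) is thresholded at
    ``criterion`` times its maximum and the longest contiguous run above
    threshold is returned; note this includes the top ``1 - criterion``
    fraction of both ramps.
    """
    if not 0 < criterion <= 1:
        raise ValidationError("criterion must lie in (0, 1]")
    if force is None:
        sl = rec.meta.get("plateau_slice")
        if sl is None:
            raise ValidationError("need either a force trace or plateau_slice metadata")
        start, stop = int(sl[0]), int(sl[1])
        data = rec.data[start:stop]
        if data.shape[0] == 0:
            raise EmptySegmentError("metadata plateau slice is empty")
        return rec.with_data(data, plateau_slice=[0, data.shape[0]], segment_origin=[start, stop])
    force = np.asarray(force, dtype=float)
    if force.shape[0] != rec.n_samples:
        raise ValidationError("force trace length must match the recording")
    level = force.max(initial=-np.inf)
    mask = force >= criterion * level
    # guard: a strictly increasing ramp never *holds* the criterion level
    if criterion >= 1.0 and np.count_nonzero(force == level) <= 1:
        raise EmptySegmentError("no plateau: criterion met at a single sample only")
    if not mask.any():
        raise EmptySegmentError("no samples satisfy the plateau criterion")
    # longest contiguous run above threshold
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, stops = edges[::2], edges[1::2]
    best = int(np.argmax(stops - starts))
    start, stop = int(starts[best]), int(stops[best])
    data = rec.data[start:stop]
    return rec.with_data(data, plateau_slice=[0, data.shape[0]], segment_origin=[start, stop])


def detect_outliers(rec: Recording, cfg: PreprocessConfig | None = None) -> OutlierReport:
    """Flag channels whose log-RMS Z-score exceeds the threshold.

    Log-RMS makes multiplicative gain faults additive, so a x100 electrode
    fault stands far outside the cross-channel distribution.
    """
    cfg = cfg or PreprocessConfig()
    if rec.n_channels < 2:
        raise ValidationError("need at least 2 channels to score outliers")
    rms = np.sqrt(np.mean(rec.data**2, axis=0))
    log_rms = np.log(np.maximum(rms, np.finfo(float).tiny))
    sd = log_rms.std()
    if sd == 0:
        z = np.zeros_like(log_rms)
    else:
        z = (log_rms - log_rms.mean()) / sd
    flagged = tuple(int(i) for i in np.flatnonzero(np.abs(z) > cfg.z_threshold))
    return OutlierReport(channel_z=z, flagged=flagged)


def _repair_matrix(
    values: np.ndarray, flagged: list[int], grid: ElectrodeGrid, radius: int
) -> np.ndarray:
    """Replace flagged channels (columns of ``values``) by unflagged-neighbor means."""
    flagged_set = set(flagged)
    out = values.copy()
    for ch in flagged:
        good = [nb for nb in grid.neighbors(ch, radius) if nb not in flagged_set]
        if not good:
            raise UnrecoverableChannelError(
                f"channel {ch} has no unflagged neighbor within radius {radius}"
            )
        out[..., ch] = values[..., good].mean(axis=-1)
    return out


def repair_channels(
    obj,
    flagged: list[int],
    grid: ElectrodeGrid | None = None,
    radius: int = 1,
):
    """Neighborhood-mean repair of flagged channels.

    Accepts a :class:`Recording` (repairs the time series) or any array
    whose last axis is channels (e.g. a map stack flattened to 64 pixels).
    Unflagged channels are left bit-identical.
    """
    flagged = sorted(set(int(f) for f in flagged))
    if isinstance(obj, Recording):
        grid = grid or obj.grid
        if any(not 0 <= ch < obj.n_channels for ch in flagged):
            raise ValidationError("flagged channel index out of range")
        if not flagged:
            return obj
        data = _repair_matrix(obj.data, flagged, grid, radius)
        return obj.with_data(data, repaired_channels=flagged)
    values = np.asarray(obj, dtype=float)
    grid = grid or ElectrodeGrid()
    if values.shape[-1] != grid.n_channels:
        raise ValidationError("last axis must index grid channels")
    if any(not 0 <= ch < grid.n_channels for ch in flagged):
        raise ValidationError("flagged channel index out of range")
    if not flagged:
        return values.copy()
    return _repair_matrix(values, flagged, grid, radius)
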