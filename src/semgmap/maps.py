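"""Instantaneous activation-map generation.

A recording is cut into windows of ``N`` samples every ``R`` samples
(rectangular window, trailing partial window discarded); each window and
channel yields one pixel intensity

    I = sqrt( (1/(N-1)) * sum x^2 )        (rms mode, default)

or the un-rooted mean square, arranged on the 8 x 8 grid. One stack of
maps per (window length, overlap) condition; the whole factorial grid of
conditions is the study's intervention.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import DegenerateInputError, ValidationError
from .grid import ElectrodeGrid
from .simulate import Recording

#: factorial design of the segmentation study
DEFAULT_WINDOWS_MS = (50.0, 100.0, 150.0, 250.0, 500.0, 1000.0)
DEFAULT_OVERLAPS_PCT = (0.0, 25.0, 50.0, 75.0, 90.0)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class SegmentationScheme:
    """Window length / overlap pair with derived sample counts."""

    window_ms: float
    overlap_pct: float
    N: int  # window length in samples
    R: int  # hop in samples

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValidationError("window must span at least 2 samples")
        if not 1 <= self.R <= self.N:
            raise ValidationError("hop must satisfy 1 <= R <= N")
        if not 0 <= self.overlap_pct < 100:
            raise ValidationError("overlap must lie in [0, 100)")


@dataclass(frozen=True)
class ActivationMapStack:
    """t consecutive (rows x cols) intensity maps for one recording x scheme."""

    maps: np.ndarray  # (t, n_rows, n_cols)
    scheme: SegmentationScheme
    window_starts: np.ndarray  # sample index of each window
    norm_constant: float = 1.0  # divisor already applied (voltage units)
    intensity: str = "rms"

    @property
    def n_maps(self) -> int:
        return self.maps.shape[0]

    def as_vectors(self, grid: ElectrodeGrid) -> np.ndarray:
        """(t, n_channels) pixel matrix in channel order."""
        return grid.to_channels(self.maps)


def scheme_from(
    window_ms: float, overlap_pct: float, fs_hz: float
) -> SegmentationScheme:
    """Derive sample counts: N = round(window*fs/1000), R = round(N*(1-ov)).

    Rounding is half-away-from-zero; the hop is floored at one sample.
    """
    if window_ms <= 0:
        raise ValidationError("window_ms must be positive")
    if not 0 <= overlap_pct < 100:
        raise ValidationError("overlap_pct must lie in [0, 100)")
    if fs_hz <= 0:
        raise ValidationError("fs_hz must be positive")
    N = _round_half_away(window_ms * fs_hz / 1000.0)
    if N < 2:
        raise ValidationError(
            f"window of {window_ms} ms at {fs_hz} Hz spans fewer than 2 samples"
        )
    R = max(1, _round_half_away(N * (1.0 - overlap_pct / 100.0)))
    return SegmentationScheme(window_ms=window_ms, overlap_pct=overlap_pct, N=N, R=R)


def count_windows(L: int, scheme: SegmentationScheme) -> int:
    """Number of full windows: floor((L - N)/R) + 1; zero when L < N."""
    if L < scheme.N:
        return 0
    return (L - scheme.N) // scheme.R + 1


def compute_stack(
    rec: Recording,
    scheme: SegmentationScheme,
    grid: ElectrodeGrid | None = None,
    intensity: str = "rms",
) -> ActivationMapStack:
    """Windowed per-channel intensity arranged as a stack of grid images."""
    if intensity not in ("rms", "mean_square"):
        raise ValidationError(f"unknown intensity mode {intensity!r}")
    grid = grid or rec.grid
    L = rec.n_samples
    t = count_windows(L, scheme)
    if t < 1:
        raise ValidationError(
            f"recording of {L} samples shorter than one window ({scheme.N})"
        )
    starts = np.arange(t) * scheme.R
    # strided view: (t, N, channels) without copying
    windows = np.lib.stride_tricks.sliding_window_view(rec.data, scheme.N, axis=0)
    windows = windows[starts]  # (t, channels, N)
    ms = (windows**2).sum(axis=-1) / (scheme.N - 1)
    vals = np.sqrt(ms) if intensity == "rms" else ms
    return ActivationMapStack(
        maps=grid.to_image(vals),
        scheme=scheme,
        window_starts=starts,
        norm_constant=1.0,
        intensity=intensity,
    )


def normalize_stack(stack: ActivationMapStack) -> ActivationMapStack:
    """Divide the whole stack by its single global maximum (plateau max)."""
    peak = float(stack.maps.max(initial=0.0))
    if peak <= 0:
        raise DegenerateInputError("all-zero stack cannot be normalized")
    return replace(
        stack,
        maps=stack.maps / peak,
        norm_constant=stack.norm_constant * peak,
    )


def grid_search(
    rec: Recording,
    windows_ms=DEFAULT_WINDOWS_MS,
    overlaps_pct=DEFAULT_OVERLAPS_PCT,
    grid: ElectrodeGrid | None = None,
    intensity: str = "rms",
    normalize: bool = True,
) -> list[ActivationMapStack]:
    """One stack per (window, overlap) pair, window-major order."""
    windows_ms = list(windows_ms)
    overlaps_pct = list(overlaps_pct)
    if not windows_ms or not overlaps_pct:
        raise ValidationError("factor lists must be non-empty")
    stacks = []
    for w, ov in itertools.product(windows_ms, overlaps_pct):
        try:
            scheme = scheme_from(w, ov, rec.fs_hz)
            stack = compute_stack(rec, scheme, grid=grid, intensity=intensity)
        except ValidationError as exc:
            raise ValidationError(
                f"condition (window={w} ms, overlap={ov}%): {exc}"
            ) from exc
        stacks.append(normalize_stack(stack) if normalize else stack)
    return stacks


def stack_smoothness(stack: ActivationMapStack) -> float:
    """Mean absolute difference between consecutive maps.

    Short hops re-use most of the previous window, so this drops as overlap
    grows; it quantifies the truncation discontinuities introduced by
    non-overlapped rectangular windows.
    """
    if stack.n_maps < 2:
        raise ValidationError("need at least two maps")
    return float(np.abs(np.diff(stack.maps, axis=0)).mean())


def plot_map(map_2d: np.ndarray, ax=None, ied_mm: float = 10.0):
    """Heat-map rendering of a single activation map (mm axes)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    n_rows, n_cols = map_2d.shape
    im = ax.imshow(
        map_2d,
        origin="upper",
        extent=(-ied_mm / 2, (n_cols - 0.5) * ied_mm, (n_rows - 0.5) * ied_mm, -ied_mm / 2),
        cmap="viridis",
    )
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    return im
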