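"""Electrode grid geometry.

The acquisition montage is an 8 x 8 monopolar grid with 10 mm
inter-electrode distance (IED). Channel *k* sits at grid position
``channel_order[k] = (row, col)``; by default channels are row-major, with
row 0 / col 0 at the corner electrode that serves as the mm origin.
Columns map to the x axis and rows to the y axis, so channel positions in
mm are ``(col * ied_mm, row * ied_mm)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError


def _default_order(n_rows: int, n_cols: int) -> tuple[tuple[int, int], ...]:
    return tuple((r, c) for r in range(n_rows) for c in range(n_cols))


@dataclass(frozen=True)
class ElectrodeGrid:
    """Rectangular electrode grid with a channel -> (row, col) mapping."""

    n_rows: int = 8
    n_cols: int = 8
    ied_mm: float = 10.0
    channel_order: tuple[tuple[int, int], ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValidationError("grid dimensions must be positive")
        if self.ied_mm <= 0:
            raise ValidationError("inter-electrode distance must be positive")
        if self.channel_order is None:
            object.__setattr__(
                self, "channel_order", _default_order(self.n_rows, self.n_cols)
            )
        order = tuple((int(r), int(c)) for r, c in self.channel_order)
        object.__setattr__(self, "channel_order", order)
        if len(order) != self.n_channels:
            raise ValidationError(
                f"channel_order has {len(order)} entries, expected {self.n_channels}"
            )
        if len(set(order)) != self.n_channels or any(
            not (0 <= r < self.n_rows and 0 <= c < self.n_cols) for r, c in order
        ):
            raise ValidationError("channel_order must be a bijection onto grid cells")

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols

    def positions_mm(self) -> np.ndarray:
        """(n_channels, 2) array of (x, y) electrode positions in mm."""
        rc = np.asarray(self.channel_order, dtype=float)
        return np.column_stack([rc[:, 1], rc[:, 0]]) * self.ied_mm

    def to_image(self, channel_values: np.ndarray) -> np.ndarray:
        """Arrange per-channel values (last axis) onto the (rows, cols) grid."""
        vals = np.asarray(channel_values)
        if vals.shape[-1] != self.n_channels:
            raise ValidationError(
                f"expected {self.n_channels} channels, got {vals.shape[-1]}"
            )
        img = np.empty(vals.shape[:-1] + (self.n_rows, self.n_cols), dtype=vals.dtype)
        rows, cols = zip(*self.channel_order)
        img[..., list(rows), list(cols)] = vals
        return img

    def to_channels(self, image: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`to_image`."""
        img = np.asarray(image)
        rows, cols = zip(*self.channel_order)
        return img[..., list(rows), list(cols)]

    def neighbors(self, channel: int, radius: int = 1) -> list[int]:
        """Channels within Chebyshev ``radius`` on the grid (excluding ``channel``)."""
        r0, c0 = self.channel_order[channel]
        rc_to_ch = {rc: ch for ch, rc in enumerate(self.channel_order)}
        out = []
        for r in range(max(0, r0 - radius), min(self.n_rows, r0 + radius + 1)):
            for c in range(max(0, c0 - radius), min(self.n_cols, c0 + radius + 1)):
                if (r, c) != (r0, c0):
                    out.append(rc_to_ch[(r, c)])
        return out

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "ied_mm": self.ied_mm,
            "channel_order": [list(rc) for rc in self.channel_order],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ElectrodeGrid":
        return cls(
            n_rows=d["n_rows"],
            n_cols=d["n_cols"],
            ied_mm=d["ied_mm"],
            channel_order=tuple(tuple(rc) for rc in d["channel_order"]),
        )
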