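"""Shared containers and exception types.

Activity matrices hold deconvolved, nonnegative "temporal neural activity"
(cells x frames) as produced by upstream source extraction + deconvolution.
Each cell's trace is scaled by an unknown constant, so all downstream
statistics are designed to be invariant to per-cell rescaling.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class PlacecellError(Exception):
    """Base class for errors raised by this package."""


class AlignmentError(PlacecellError):
    """Streams that must share a frame count or grid do not."""


class OutOfBoundsError(PlacecellError):
    """Positions fall outside the binning grid."""

    def __init__(self, message: str, frames: np.ndarray | None = None):
        super().__init__(message)
        self.frames = frames


class ConfigurationError(PlacecellError):
    """Required calibration/geometry/configuration is missing or invalid."""


class UntrackableSessionError(PlacecellError):
    """No frame in a behavior video passed the LED contrast check."""


class DegenerateMapError(PlacecellError):
    """A map operation received an all-invalid mask."""


@dataclass
class ActivityMatrix:
    """Deconvolved nonnegative activity, shape (n_cells, n_frames).

    Values are in arbitrary activity units per frame; dividing a binned sum
    by binned occupancy time yields activity units per second.
    """

    values: np.ndarray
    frame_rate_hz: float
    cell_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("activity must be 2-D (cells x frames)")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if np.any(self.values < 0):
            raise ValueError("deconvolved activity must be nonnegative")
        if self.cell_ids is None:
            self.cell_ids = np.arange(self.values.shape[0])
        else:
            self.cell_ids = np.asarray(self.cell_ids)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]
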