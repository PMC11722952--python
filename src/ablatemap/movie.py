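"""In-memory container for two-channel fluorescence movies."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Movie:
    """A two-channel time-lapse movie.

    ``green`` carries the calcium indicator (GCaMP6f), ``red`` the
    astrocytic dye (SR-101). Both are ``(T, H, W)`` arrays on a common
    clock. Geometry is stored in pixels; ``pixel_size`` (um/px) converts
    to micrometres at analysis boundaries only.
    """

    green: np.ndarray
    red: np.ndarray | None
    frame_rate: float  # Hz
    pixel_size: float  # um / pixel
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.green = np.asarray(self.green)
        if self.green.ndim != 3:
            raise ValueError("green must be a (T, H, W) stack")
        if self.red is not None:
            self.red = np.asarray(self.red)
            if self.red.shape != self.green.shape:
                raise ValueError(
                    f"channel shape mismatch: green {self.green.shape} "
                    f"vs red {self.red.shape}"
                )
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def n_frames(self) -> int:
        return self.green.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.green.shape[1:]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_frames / self.frame_rate

    def channel(self, name: str) -> np.ndarray:
        if name == "green":
            return self.green
        if name == "red":
            if self.red is None:
                raise ValueError("movie has no red channel")
            return self.red
        raise ValueError(f"unknown channel {name!r}; expected 'green' or 'red'")
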