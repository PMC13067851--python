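"""The VoltageMovie container: T x H x W frames plus acquisition metadata."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class VoltageMovie:
    """A stack of voltage (or fluorescence) frames.

    frames
        float32 array of shape (T, H, W). For simulator output the values are
        membrane potential in mV; for camera output they are arbitrary
        fluorescence units.
    frame_interval_ms
        Time between consecutive frames.
    spacing_um
        Physical size of one pixel/node (square pixels assumed).
    seed
        Seed of the generating process, for provenance.
    """

    frames: np.ndarray
    frame_interval_ms: float
    spacing_um: float
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape

    @property
    def duration_ms(self) -> float:
        return self.n_frames * self.frame_interval_ms

    def __getitem__(self, idx):
        return self.frames[idx]
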