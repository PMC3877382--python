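"""Particle tracks: time-stamped positions along an axon path."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ParticleTrack:
    """A sequence of positions (μm along the axon path) over time.

    Ground-truth tracks produced by the simulator carry ``truth_mobile`` and
    ``truth_speed``; tracks recovered by detection + linking leave them None.
    """

    particle_id: int
    positions: np.ndarray          # μm along the path, one per frame present
    times: np.ndarray              # s, strictly increasing
    frames: np.ndarray | None = None
    y_px: np.ndarray | None = None
    cargo_kind: str = "mitochondrion"
    truth_mobile: bool | None = None
    truth_speed: float | None = None   # μm/s run speed (0 for stationary)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.positions.shape != self.times.shape:
            raise ValueError("positions and times must have equal length")
        if self.positions.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.frames is not None:
            self.frames = np.asarray(self.frames, dtype=int)

    def __len__(self) -> int:
        return int(self.positions.size)

    @property
    def elapsed(self) -> float:
        """Elapsed time (s) between first and last observation."""
        return float(self.times[-1] - self.times[0])

    @property
    def net_displacement(self) -> float:
        """Signed net displacement (μm), positive = away from the soma end at 0."""
        return float(self.positions[-1] - self.positions[0])

    @property
    def mean_position(self) -> float:
        return float(self.positions.mean())
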