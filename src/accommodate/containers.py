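"""Lightweight in-memory containers shared by the simulation and analysis layers.

Times are in reduced units (tau_ru, ~1 ns); coordinates and distances in
Angstrom; angles in degrees; areas in Angstrom^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import IntegrityError


@dataclass
class Trajectory:
    """Ordered coordinate frames with times in reduced units.

    frames : (n_frames, n_atoms, 3) float array, Angstrom.
    times  : (n_frames,) strictly increasing, tau_ru.
    """

    frames: np.ndarray
    times: np.ndarray
    topology_hash: str | None = None
    seed: int | None = None
    #: step at which an early-stop condition fired, if any
    stop_step: int | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise IntegrityError(
                f"frames must have shape (n_frames, n_atoms, 3), got {self.frames.shape}"
            )
        if len(self.times) != len(self.frames):
            raise IntegrityError("frames and times length mismatch")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise IntegrityError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


@dataclass
class ObservableSeries:
    """A named scalar time series (distance, angle, area, ...)."""

    name: str
    values: np.ndarray
    times: np.ndarray
    units: str = "A"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape != self.times.shape:
            raise IntegrityError("values and times length mismatch")

    def __len__(self) -> int:
        return len(self.values)
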