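"""Core data containers shared across the package."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np


@dataclass
class RawTrial:
    """One EEG trial: channel-major samples plus rating metadata.

    ``samples`` is an ``(n_channels, n_samples)`` array of amplitudes in
    microvolts.  Ratings follow the 1-9 self-assessment scale used for
    valence and arousal.
    """

    samples: np.ndarray
    sampling_rate: float
    valence_rating: float
    arousal_rating: float
    trial_id: int = 0
    subject_id: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError(
                f"samples must be 2-D (channels x time), got shape {self.samples.shape}"
            )
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be positive, got {self.sampling_rate}")
        for name, rating in (
            ("valence_rating", self.valence_rating),
            ("arousal_rating", self.arousal_rating),
        ):
            if not 1.0 <= rating <= 9.0:
                raise ValueError(f"{name} must lie in [1, 9], got {rating}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_seconds(self) -> float:
        return self.n_samples / self.sampling_rate

    def with_samples(self, samples: np.ndarray) -> "RawTrial":
        return replace(self, samples=samples)


@dataclass
class FrameMap:
    """A 2-D scalp map on the electrode grid.

    Before interpolation, cells without an electrode are NaN and flagged
    off in ``occupancy``; after interpolation every cell holds a value.
    """

    values: np.ndarray
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.occupancy = np.asarray(self.occupancy, dtype=bool)
        if self.values.shape != self.occupancy.shape:
            raise ValueError("values and occupancy shapes differ")

    @property
    def is_complete(self) -> bool:
        return bool(np.isfinite(self.values).all())


@dataclass
class WindowTensor:
    """One 1-s window rendered as a depth x height x width stack."""

    data: np.ndarray
    label_valence: int
    label_arousal: int
    window_index: int = 0
    trial_id: int = 0
    subject_id: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"window data must be 3-D, got shape {self.data.shape}")
        if not np.isfinite(self.data).all():
            raise ValueError("window tensor contains non-finite entries")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]
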