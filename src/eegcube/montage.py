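"""EEG trials to 3D spatiotemporal tensors.

Each 1-s window of a multichannel trial is rendered, sample by sample, as a
topographic scalp map: channel amplitudes are placed on a 9x9 electrode grid,
empty cells are filled by thin-plate-spline RBF interpolation, and the map is
upsampled to ``target_side`` x ``target_side`` with Keys bicubic interpolation.
Stacking the maps of all samples in a window yields the model input tensor
(default 128 x 64 x 64).

Every stage is linear in the channel amplitudes, so the whole
channels-to-map transform collapses to a single precomputed matrix; the
staged operations (:func:`project_to_grid`, :func:`rbf_fill`,
:func:`upsample_bicubic`) remain available as the reference path.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RBFInterpolator

from .datatypes import FrameMap, RawTrial, WindowTensor

logger = logging.getLogger(__name__)

DEFAULT_TARGET_SIDE = 64
DEFAULT_WINDOW_SECONDS = 1.0
DEFAULT_PRE_STIMULUS_SECONDS = 3.0


# ---------------------------------------------------------------------------
# montage grid
# ---------------------------------------------------------------------------

@dataclass
class MontageGrid:
    """Electrode-to-cell assignment on a rectangular scalp grid.

    Rows run anterior to posterior and columns left to right (0-based,
    midline in the centre column).  ``channel_order`` fixes the meaning of
    positions in a channel-value vector; ``coordinates`` are the planar
    positions (cell centres) used for interpolation distances.
    """

    grid_shape: tuple[int, int]
    assignments: dict[str, tuple[int, int]]
    channel_order: list[str]

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        cells = list(self.assignments.values())
        if len(set(cells)) != len(cells):
            raise ValueError("montage assigns two channels to the same cell")
        for name, (r, c) in self.assignments.items():
            if not (0 <= r < rows and 0 <= c < cols):
                raise ValueError(f"channel {name} assigned outside the {rows}x{cols} grid")
        missing = set(self.channel_order) - set(self.assignments)
        if missing:
            raise ValueError(f"channels without a grid cell: {sorted(missing)}")

    @property
    def n_channels(self) -> int:
        return len(self.channel_order)

    @property
    def cells(self) -> np.ndarray:
        """(n_channels, 2) integer (row, col) per channel, in channel order."""
        return np.array([self.assignments[ch] for ch in self.channel_order], dtype=int)

    @property
    def coordinates(self) -> np.ndarray:
        """Planar electrode positions used for RBF distances (cell centres)."""
        return self.cells.astype(float)

    def cache_key(self) -> tuple:
        return (
            self.grid_shape,
            tuple(self.channel_order),
            tuple(self.assignments[ch] for ch in self.channel_order),
        )

    @classmethod
    def from_json(cls, path) -> "MontageGrid":
        with open(path) as fh:
            payload = json.load(fh)
        return cls._from_payload(payload)

    @classmethod
    def _from_payload(cls, payload: dict) -> "MontageGrid":
        return cls(
            grid_shape=tuple(payload["grid_shape"]),
            assignments={k: tuple(v) for k, v in payload["assignments"].items()},
            channel_order=list(payload["channel_order"]),
        )

    @classmethod
    def deap(cls) -> "MontageGrid":
        """The shipped 9x9 layout for the 32 DEAP EEG channels."""
        text = resources.files("eegcube.resources").joinpath("deap_montage_9x9.json").read_text()
        return cls._from_payload(json.loads(text))


# ---------------------------------------------------------------------------
# trial-level operations
# ---------------------------------------------------------------------------

def trim_trial(trial: RawTrial, pre_stimulus_seconds: float = DEFAULT_PRE_STIMULUS_SECONDS) -> RawTrial:
    """Drop the leading pre-stimulus portion of a trial.

    For DEAP-style trials this removes the first 3 s baseline, keeping the
    60 s of stimulus-locked signal.
    """
    n_drop_f = pre_stimulus_seconds * trial.sampling_rate
    n_drop = int(round(n_drop_f))
    if abs(n_drop_f - n_drop) > 1e-9 or n_drop < 0:
        raise ValueError(
            f"pre_stimulus_seconds x sampling_rate must be a nonnegative integer, got {n_drop_f}"
        )
    if n_drop > trial.n_samples:
        raise ValueError(
            f"cannot trim {n_drop} samples ({pre_stimulus_seconds} s) from a trial "
            f"of {trial.n_samples} samples"
        )
    return trial.with_samples(trial.samples[:, n_drop:])


def segment_windows(trial: RawTrial, window_seconds: float = DEFAULT_WINDOW_SECONDS) -> list[np.ndarray]:
    """Cut a trial into contiguous non-overlapping channel x time segments.

    Trailing samples that do not fill a whole window are discarded.
    """
    w_f = window_seconds * trial.sampling_rate
    w = int(round(w_f))
    if abs(w_f - w) > 1e-9 or w <= 0:
        raise ValueError(
            f"window_seconds x sampling_rate must be a positive integer, got {w_f}"
        )
    n_windows = trial.n_samples // w
    if n_windows == 0:
        logger.info(
            "window of %d samples longer than trial of %d samples; no segments",
            w, trial.n_samples,
        )
    dropped = trial.n_samples - n_windows * w
    if dropped:
        logger.debug("discarding %d trailing samples", dropped)
    return [trial.samples[:, i * w:(i + 1) * w] for i in range(n_windows)]


# ---------------------------------------------------------------------------
# per-frame stages
# ---------------------------------------------------------------------------

def project_to_grid(channel_values: Sequence[float], montage: MontageGrid) -> FrameMap:
    """Place one sample of channel amplitudes on the montage grid.

    Cells without an electrode are NaN and marked unoccupied.
    """
    values = np.asarray(channel_values, dtype=np.float64).ravel()
    if values.size != montage.n_channels:
        raise ValueError(
            f"expected {montage.n_channels} channel values, got {values.size}"
        )
    grid = np.full(montage.grid_shape, np.nan)
    occ = np.zeros(montage.grid_shape, dtype=bool)
    cells = montage.cells
    grid[cells[:, 0], cells[:, 1]] = values
    occ[cells[:, 0], cells[:, 1]] = True
    return FrameMap(values=grid, occupancy=occ)


def _check_not_collinear(points: np.ndarray) -> None:
    if len(points) < 3:
        raise ValueError(f"need at least 3 electrode-backed cells, got {len(points)}")
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise ValueError("electrode cells are collinear; interpolation is degenerate")


def rbf_fill(frame: FrameMap, montage: MontageGrid | None = None) -> FrameMap:
    """Fill empty grid cells by thin-plate-spline interpolation.

    The interpolant uses a degree-1 polynomial tail, so constant and planar
    fields sampled at the electrodes are reproduced exactly; values at
    electrode-backed cells are left untouched (interpolation, not smoothing).
    """
    occ = frame.occupancy
    nodes = np.argwhere(occ).astype(float)
    _check_not_collinear(nodes)
    node_values = frame.values[occ]
    if not np.isfinite(node_values).all():
        raise ValueError("occupied cells contain non-finite values")
    filled = frame.values.copy()
    empty = np.argwhere(~occ).astype(float)
    if len(empty):
        interp = RBFInterpolator(nodes, node_values, kernel="thin_plate_spline", degree=1)
        filled[~occ] = interp(empty)
    return FrameMap(values=filled, occupancy=occ)


def _keys_kernel(x: np.ndarray, a: float = -0.5) -> np.ndarray:
    """Keys cubic-convolution kernel (the classic a = -0.5 dialect)."""
    x = np.abs(x)
    out = np.zeros_like(x)
    near = x <= 1
    far = (x > 1) & (x < 2)
    out[near] = (a + 2) * x[near] ** 3 - (a + 3) * x[near] ** 2 + 1
    out[far] = a * x[far] ** 3 - 5 * a * x[far] ** 2 + 8 * a * x[far] - 4 * a
    return out


def _reflect_index(i: np.ndarray, n: int) -> np.ndarray:
    # mirror about the edge samples (period 2n-2)
    if n == 1:
        return np.zeros_like(i)
    period = 2 * n - 2
    i = np.mod(i, period)
    return np.where(i >= n, period - i, i)


def bicubic_weight_matrix(n_src: int, n_dst: int, a: float = -0.5) -> np.ndarray:
    """(n_dst, n_src) resampling matrix for 1-D Keys cubic interpolation.

    Align-corners coordinate mapping: source endpoints map to target
    endpoints.  Out-of-range taps are reflected at the borders.
    """
    W = np.zeros((n_dst, n_src))
    for t in range(n_dst):
        s = t * (n_src - 1) / (n_dst - 1) if n_dst > 1 else 0.0
        base = math.floor(s)
        taps = np.arange(base - 1, base + 3)
        w = _keys_kernel(s - taps, a=a)
        idx = _reflect_index(taps, n_src)
        np.add.at(W[t], idx, w)
    return W


def upsample_bicubic(frame: FrameMap | np.ndarray, target_side: int = DEFAULT_TARGET_SIDE) -> np.ndarray:
    """Upsample a fully populated map to ``target_side`` squared."""
    values = frame.values if isinstance(frame, FrameMap) else np.asarray(frame, dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("frame must be fully populated before upsampling")
    rows, cols = values.shape
    if target_side < max(rows, cols):
        raise ValueError(
            f"target side {target_side} smaller than source {rows}x{cols}; downsampling unsupported"
        )
    Wr = bicubic_weight_matrix(rows, target_side)
    Wc = bicubic_weight_matrix(cols, target_side)
    return Wr @ values @ Wc.T


# ---------------------------------------------------------------------------
# fused renderer and window/dataset assembly
# ---------------------------------------------------------------------------

class GridRenderer:
    """Precomputed linear map from channel amplitudes to an upsampled scalp map.

    Placement, RBF fill and bicubic upsampling are all linear, so for a fixed
    montage the 9x9 fill is ``G = place(v); G[empty] = M v`` with ``M`` built
    once from the interpolation of unit vectors, and the upsampled map is
    ``A_r G A_c^T``.
    """

    def __init__(self, montage: MontageGrid, target_side: int = DEFAULT_TARGET_SIDE):
        self.montage = montage
        self.target_side = int(target_side)
        rows, cols = montage.grid_shape
        if self.target_side < max(rows, cols):
            raise ValueError(
                f"target side {target_side} smaller than source {rows}x{cols}"
            )
        cells = montage.cells
        occ = np.zeros(montage.grid_shape, dtype=bool)
        occ[cells[:, 0], cells[:, 1]] = True
        self._occ = occ
        self._cells = cells
        nodes = cells.astype(float)
        _check_not_collinear(nodes)
        empty = np.argwhere(~occ).astype(float)
        interp = RBFInterpolator(nodes, np.eye(montage.n_channels),
                                 kernel="thin_plate_spline", degree=1)
        self._fill_matrix = interp(empty)  # (n_empty, n_channels)
        self._empty_idx = np.argwhere(~occ)
        self._Wr = bicubic_weight_matrix(rows, self.target_side)
        self._Wc = bicubic_weight_matrix(cols, self.target_side)

    def render_grids(self, segment: np.ndarray) -> np.ndarray:
        """(C, T) channel samples -> (T, rows, cols) filled 9x9 maps."""
        segment = np.asarray(segment, dtype=np.float64)
        if segment.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"expected {self.montage.n_channels} channels, got {segment.shape[0]}"
            )
        T = segment.shape[1]
        grids = np.empty((T,) + self.montage.grid_shape)
        grids[:, self._cells[:, 0], self._cells[:, 1]] = segment.T
        filled = segment.T @ self._fill_matrix.T  # (T, n_empty)
        grids[:, self._empty_idx[:, 0], self._empty_idx[:, 1]] = filled
        return grids

    def render(self, segment: np.ndarray) -> np.ndarray:
        """(C, T) channel samples -> (T, side, side) upsampled maps."""
        grids = self.render_grids(segment)
        return np.einsum("ij,tjk,lk->til", self._Wr, grids, self._Wc, optimize=True)


_RENDERER_CACHE: dict[tuple, GridRenderer] = {}


def get_renderer(montage: MontageGrid, target_side: int = DEFAULT_TARGET_SIDE) -> GridRenderer:
    key = (montage.cache_key(), int(target_side))
    if key not in _RENDERER_CACHE:
        _RENDERER_CACHE[key] = GridRenderer(montage, target_side)
    return _RENDERER_CACHE[key]


def build_window_tensor(
    segment: np.ndarray,
    montage: MontageGrid,
    target_side: int = DEFAULT_TARGET_SIDE,
    *,
    label_valence: int = 0,
    label_arousal: int = 0,
    window_index: int = 0,
    trial_id: int = 0,
    subject_id: int = 0,
) -> WindowTensor:
    """Render one channel x time segment into a depth x side x side tensor.

    Depth slice ``t`` is the upsampled scalp map of time sample ``t``.
    """
    segment = np.asarray(segment, dtype=np.float64)
    data = get_renderer(montage, target_side).render(segment)
    return WindowTensor(
        data=data,
        label_valence=label_valence,
        label_arousal=label_arousal,
        window_index=window_index,
        trial_id=trial_id,
        subject_id=subject_id,
    )


class WindowDataset:
    """A stack of window tensors with labels and provenance.

    ``tensors`` has shape (n_windows, depth, side, side); provenance is a
    DataFrame with subject_id, trial_id and window_index per row.
    """

    def __init__(self, tensors: np.ndarray, labels_valence: np.ndarray,
                 labels_arousal: np.ndarray, provenance: pd.DataFrame):
        self.tensors = np.asarray(tensors)
        self.labels_valence = np.asarray(labels_valence, dtype=int)
        self.labels_arousal = np.asarray(labels_arousal, dtype=int)
        self.provenance = provenance.reset_index(drop=True)
        n = len(self.tensors)
        if not (len(self.labels_valence) == len(self.labels_arousal) == len(self.provenance) == n):
            raise ValueError("tensor/label/provenance lengths differ")

    def __len__(self) -> int:
        return len(self.tensors)

    def labels(self, task: str) -> np.ndarray:
        if task == "valence":
            return self.labels_valence
        if task == "arousal":
            return self.labels_arousal
        raise ValueError(f"unknown task {task!r}; expected 'valence' or 'arousal'")

    def subset(self, indices: np.ndarray) -> "WindowDataset":
        indices = np.asarray(indices)
        return WindowDataset(
            self.tensors[indices],
            self.labels_valence[indices],
            self.labels_arousal[indices],
            self.provenance.iloc[indices],
        )

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("tensors", data=self.tensors.astype(np.float32))
            fh.create_dataset("labels_valence", data=self.labels_valence)
            fh.create_dataset("labels_arousal", data=self.labels_arousal)
            for col in ("subject_id", "trial_id", "window_index"):
                fh.create_dataset(f"provenance/{col}", data=self.provenance[col].to_numpy())

    @classmethod
    def from_hdf5(cls, path) -> "WindowDataset":
        import h5py

        with h5py.File(path, "r") as fh:
            tensors = fh["tensors"][...]
            lv = fh["labels_valence"][...]
            la = fh["labels_arousal"][...]
            prov = pd.DataFrame({
                col: fh[f"provenance/{col}"][...]
                for col in ("subject_id", "trial_id", "window_index")
            })
        return cls(tensors, lv, la, prov)


def build_dataset(
    trials: Iterable[RawTrial],
    montage: MontageGrid,
    *,
    window_seconds: float = DEFAULT_WINDOW_SECONDS,
    target_side: int = DEFAULT_TARGET_SIDE,
    pre_stimulus_seconds: float = DEFAULT_PRE_STIMULUS_SECONDS,
    rating_threshold: float = 5.0,
    zscore_channels: bool = False,
) -> WindowDataset:
    """Full pipeline: trim, window, render, and label a batch of trials.

    Optional per-channel z-scoring (off by default: the pipeline applies no
    normalization unless asked).
    """
    from .training import binarize_rating

    trials = list(trials)
    tensors: list[np.ndarray] = []
    lv: list[int] = []
    la: list[int] = []
    prov: list[dict] = []
    n_channels = None
    sampling_rate = None
    for trial in trials:
        if n_channels is None:
            n_channels, sampling_rate = trial.n_channels, trial.sampling_rate
        elif trial.n_channels != n_channels:
            raise ValueError(
                f"inconsistent channel counts across trials: {n_channels} vs {trial.n_channels}"
            )
        elif trial.sampling_rate != sampling_rate:
            raise ValueError("inconsistent sampling rates across trials")
        trimmed = trim_trial(trial, pre_stimulus_seconds)
        if zscore_channels:
            mu = trimmed.samples.mean(axis=1, keepdims=True)
            sd = trimmed.samples.std(axis=1, keepdims=True)
            sd[sd == 0] = 1.0
            trimmed = trimmed.with_samples((trimmed.samples - mu) / sd)
        v_label = binarize_rating(trial.valence_rating, rating_threshold)
        a_label = binarize_rating(trial.arousal_rating, rating_threshold)
        for idx, segment in enumerate(segment_windows(trimmed, window_seconds)):
            wt = build_window_tensor(
                segment, montage, target_side,
                label_valence=v_label, label_arousal=a_label,
                window_index=idx, trial_id=trial.trial_id, subject_id=trial.subject_id,
            )
            tensors.append(wt.data.astype(np.float32))
            lv.append(v_label)
            la.append(a_label)
            prov.append({
                "subject_id": trial.subject_id,
                "trial_id": trial.trial_id,
                "window_index": idx,
            })
    depth = int(round(window_seconds * (sampling_rate or 128)))
    shape = (len(tensors), depth, target_side, target_side)
    stacked = np.stack(tensors) if tensors else np.empty(shape, dtype=np.float32)
    return WindowDataset(
        stacked, np.array(lv, dtype=int), np.array(la, dtype=int),
        pd.DataFrame(prov, columns=["subject_id", "trial_id", "window_index"]),
    )
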