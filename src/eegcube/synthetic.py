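"""DEAP-structured synthetic EEG with a controllable class effect.

Each channel is a 1/f-shaped Gaussian background plus band-limited
sinusoids (theta/alpha/beta) with per-trial random frequency and phase.
The class-conditional structure follows two well-worn electrophysiological
conventions, chosen so that both the spatial and the temporal pathway of a
model carry signal:

* high valence — frontal alpha asymmetry: the alpha amplitude is scaled by
  ``1 + delta`` on left-frontal channels and by ``max(0, 1 - delta/2)`` on
  right-frontal channels;
* high arousal — beta gain: the beta amplitude is scaled by ``1 + delta``
  on frontal-central channels.

This emulates the DEAP per-subject layout (data ``trials x channels x
samples``, labels ``trials x 4`` with columns valence, arousal, dominance,
liking) and makes no claim about the real dataset's generative process.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.fft import irfft, rfft, rfftfreq

from .datatypes import RawTrial
from .montage import MontageGrid

logger = logging.getLogger(__name__)

BANDS_HZ = {"theta": (4.0, 8.0), "alpha": (8.0, 13.0), "beta": (14.0, 30.0)}

LEFT_FRONTAL = ("Fp1", "AF3", "F3", "F7")
RIGHT_FRONTAL = ("Fp2", "AF4", "F4", "F8")
FRONTAL_CENTRAL = ("FC5", "FC1", "FC2", "FC6", "Fz", "Cz")

DEAP_CHANNELS: tuple[str, ...] = tuple(MontageGrid.deap().channel_order)


@dataclass
class SynthConfig:
    """Generator settings; the defaults mirror one DEAP subject file."""

    n_subjects: int = 1
    n_trials_per_subject: int = 40
    n_channels: int = 32
    sampling_rate: float = 128.0
    trial_seconds: float = 63.0  # 3 s pre-stimulus + 60 s stimulus
    effect_size: float = 1.0
    noise_exponent: float = 1.0
    background_std: float = 5.0  # microvolts
    band_amplitudes: dict = field(
        default_factory=lambda: {"theta": 4.0, "alpha": 8.0, "beta": 3.0}
    )
    seed: int = 0

    def __post_init__(self):
        for name in ("n_subjects", "n_trials_per_subject", "n_channels",
                     "sampling_rate", "trial_seconds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.effect_size < 0:
            raise ValueError(f"effect_size must be >= 0, got {self.effect_size}")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_seconds * self.sampling_rate))

    @property
    def channel_names(self) -> tuple[str, ...]:
        return DEAP_CHANNELS[: self.n_channels]


def _pink_background(rng: np.random.Generator, n: int, fs: float,
                     exponent: float, std: float) -> np.ndarray:
    white = rng.standard_normal(n)
    spectrum = rfft(white)
    freqs = rfftfreq(n, 1.0 / fs)
    shaping = np.zeros_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    sig = irfft(spectrum * shaping, n)
    s = sig.std()
    return sig * (std / s) if s > 0 else sig


def _draw_rating(rng: np.random.Generator, high: bool) -> float:
    # high class in (5, 9], low in [1, 5]; the boundary 5 belongs to low
    if high:
        return float(rng.uniform(np.nextafter(5.0, 9.0), 9.0))
    return float(rng.uniform(1.0, 5.0))


def generate_trial(
    labels: tuple[int, int],
    config: SynthConfig,
    rng: np.random.Generator,
    *,
    trial_id: int = 0,
    subject_id: int = 0,
    ratings: tuple[float, float] | None = None,
) -> RawTrial:
    """One synthetic trial for a (valence, arousal) binary class pair."""
    v_bin, a_bin = labels
    n = config.n_samples
    fs = config.sampling_rate
    t = np.arange(n) / fs
    delta = config.effect_size
    names = config.channel_names
    samples = np.empty((config.n_channels, n))
    for ci, name in enumerate(names):
        sig = _pink_background(rng, n, fs, config.noise_exponent, config.background_std)
        for band, (lo, hi) in BANDS_HZ.items():
            amp = config.band_amplitudes.get(band, 0.0)
            if band == "alpha" and v_bin == 1:
                if name in LEFT_FRONTAL:
                    amp *= 1.0 + delta
                elif name in RIGHT_FRONTAL:
                    amp *= max(0.0, 1.0 - delta / 2.0)
            if band == "beta" and a_bin == 1 and name in FRONTAL_CENTRAL:
                amp *= 1.0 + delta
            f0 = rng.uniform(lo, hi)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            sig += amp * np.sin(2.0 * np.pi * f0 * t + phase)
        samples[ci] = sig
    if ratings is None:
        ratings = (_draw_rating(rng, bool(v_bin)), _draw_rating(rng, bool(a_bin)))
    return RawTrial(
        samples=samples,
        sampling_rate=fs,
        valence_rating=ratings[0],
        arousal_rating=ratings[1],
        trial_id=trial_id,
        subject_id=subject_id,
    )


@dataclass
class SyntheticArchive:
    """Per-subject arrays mirroring the DEAP preprocessed layout."""

    data: dict[int, np.ndarray]    # subject -> (trials, channels, samples)
    labels: dict[int, np.ndarray]  # subject -> (trials, 4): val, aro, dom, lik
    config: SynthConfig

    def trials(self) -> list[RawTrial]:
        out = []
        for subject_id in sorted(self.data):
            for ti in range(self.data[subject_id].shape[0]):
                v, a = self.labels[subject_id][ti, 0], self.labels[subject_id][ti, 1]
                out.append(RawTrial(
                    samples=self.data[subject_id][ti],
                    sampling_rate=self.config.sampling_rate,
                    valence_rating=float(v),
                    arousal_rating=float(a),
                    trial_id=ti,
                    subject_id=subject_id,
                ))
        return out

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            for key, value in asdict(self.config).items():
                if key == "band_amplitudes":
                    for band, amp in value.items():
                        fh.attrs[f"band_amplitude_{band}"] = amp
                else:
                    fh.attrs[key] = value
            for subject_id in sorted(self.data):
                grp = fh.create_group(f"s{subject_id:02d}")
                grp.create_dataset("data", data=self.data[subject_id])
                grp.create_dataset("labels", data=self.labels[subject_id])

    @classmethod
    def from_hdf5(cls, path) -> "SyntheticArchive":
        import h5py

        with h5py.File(path, "r") as fh:
            attrs = dict(fh.attrs)
            band_amplitudes = {
                band: float(attrs.pop(f"band_amplitude_{band}"))
                for band in list(BANDS_HZ)
                if f"band_amplitude_{band}" in attrs
            }
            config = SynthConfig(band_amplitudes=band_amplitudes, **{
                k: (int(v) if isinstance(v, (np.integer,)) else float(v) if isinstance(v, np.floating) else v)
                for k, v in attrs.items()
            })
            data, labels = {}, {}
            for name in fh:
                subject_id = int(name.lstrip("s"))
                data[subject_id] = fh[name]["data"][...]
                labels[subject_id] = fh[name]["labels"][...]
        return cls(data=data, labels=labels, config=config)

    def to_npz(self, path) -> None:
        arrays = {}
        for subject_id in sorted(self.data):
            arrays[f"data_s{subject_id:02d}"] = self.data[subject_id]
            arrays[f"labels_s{subject_id:02d}"] = self.labels[subject_id]
        np.savez(path, **arrays)


def _balanced_classes(n_trials: int, rng: np.random.Generator) -> np.ndarray:
    """(n_trials, 2) binary (valence, arousal) classes, balanced 2x2, shuffled."""
    grid = np.array([(0, 0), (0, 1), (1, 0), (1, 1)], dtype=int)
    reps = -(-n_trials // 4)  # ceil
    classes = np.tile(grid, (reps, 1))[:n_trials]
    return classes[rng.permutation(n_trials)]


def generate_dataset(config: SynthConfig | None = None) -> SyntheticArchive:
    """A full archive: balanced classes, DEAP-shaped arrays, seeded."""
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    data, labels = {}, {}
    for subject_id in range(1, config.n_subjects + 1):
        classes = _balanced_classes(config.n_trials_per_subject, rng)
        subject_data = np.empty(
            (config.n_trials_per_subject, config.n_channels, config.n_samples)
        )
        subject_labels = np.empty((config.n_trials_per_subject, 4))
        for ti, (v_bin, a_bin) in enumerate(classes):
            trial = generate_trial(
                (int(v_bin), int(a_bin)), config, rng,
                trial_id=ti, subject_id=subject_id,
            )
            subject_data[ti] = trial.samples
            subject_labels[ti] = (
                trial.valence_rating,
                trial.arousal_rating,
                rng.uniform(1.0, 9.0),  # dominance: filler for the 40x4 layout
                rng.uniform(1.0, 9.0),  # liking: filler
            )
        data[subject_id] = subject_data
        labels[subject_id] = subject_labels
    return SyntheticArchive(data=data, labels=labels, config=config)


def load_deap_preprocessed(path, sampling_rate: float = 128.0) -> list[RawTrial]:
    """Read one DEAP "preprocessed Python" per-subject pickled file.

    Expects a dict with ``data`` (trials x 40 x 8064; first 32 channels are
    EEG, the rest peripheral and discarded) and ``labels`` (trials x 4,
    columns valence, arousal, dominance, liking).  Purely synthetic files
    with exactly 32 channels are accepted too.
    """
    with open(path, "rb") as fh:
        payload = pickle.load(fh, encoding="latin1")
    if not isinstance(payload, dict) or "data" not in payload or "labels" not in payload:
        raise ValueError("expected a pickled dict with 'data' and 'labels' arrays")
    data = np.asarray(payload["data"])
    labels = np.asarray(payload["labels"])
    if data.ndim != 3 or data.shape[1] not in (32, 40):
        raise ValueError(
            f"expected data of shape (trials, 40 or 32, samples), got {data.shape}"
        )
    if labels.ndim != 2 or labels.shape[1] != 4 or labels.shape[0] != data.shape[0]:
        raise ValueError(
            f"expected labels of shape ({data.shape[0]}, 4), got {labels.shape}"
        )
    if ((labels[:, :2] < 1) | (labels[:, :2] > 9)).any():
        raise ValueError("valence/arousal ratings outside [1, 9]")
    trials = []
    for ti in range(data.shape[0]):
        trials.append(RawTrial(
            samples=data[ti, :32],
            sampling_rate=sampling_rate,
            valence_rating=float(labels[ti, 0]),
            arousal_rating=float(labels[ti, 1]),
            trial_id=ti,
        ))
    return trials


# ---------------------------------------------------------------------------
# generator validation probe
# ---------------------------------------------------------------------------

def _band_power_features(trial: RawTrial, channel_names: tuple[str, ...]) -> np.ndarray:
    """Log band powers over the effect-carrying channel groups (Welch PSD)."""
    from scipy.signal import welch

    fs = trial.sampling_rate
    nperseg = int(fs)  # 1-s Hann segments, 50% overlap
    freqs, psd = welch(trial.samples, fs=fs, window="hann",
                       nperseg=nperseg, noverlap=nperseg // 2)

    def band_power(channels: tuple[str, ...], band: str) -> float:
        idx = [channel_names.index(c) for c in channels if c in channel_names]
        lo, hi = BANDS_HZ[band]
        sel = (freqs >= lo) & (freqs <= hi)
        return float(np.trapezoid(psd[np.ix_(idx, np.flatnonzero(sel))],
                                  freqs[sel], axis=1).mean())

    lf_alpha = band_power(LEFT_FRONTAL, "alpha")
    rf_alpha = band_power(RIGHT_FRONTAL, "alpha")
    fc_beta = band_power(FRONTAL_CENTRAL, "beta")
    all_alpha = band_power(channel_names, "alpha")
    all_beta = band_power(channel_names, "beta")
    eps = 1e-12
    return np.log(np.array([lf_alpha, rf_alpha, fc_beta, all_alpha, all_beta]) + eps)


def band_power_probe(
    archive: SyntheticArchive | list[RawTrial],
    task: str,
    seed: int = 0,
    n_folds: int = 5,
) -> float:
    """Cross-validated AUC of a linear probe on band-power features.

    Verifies the generator's effect-size dial: near 0.5 at delta = 0,
    approaching 1 for large delta.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import roc_auc_score
    from sklearn.model_selection import StratifiedKFold
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    from .training import binarize_rating

    trials = archive.trials() if isinstance(archive, SyntheticArchive) else list(archive)
    if not trials:
        raise ValueError("archive is empty")
    names = DEAP_CHANNELS[: trials[0].n_channels]
    X = np.stack([_band_power_features(t, names) for t in trials])
    if task == "valence":
        y = np.array([binarize_rating(t.valence_rating) for t in trials])
    elif task == "arousal":
        y = np.array([binarize_rating(t.arousal_rating) for t in trials])
    else:
        raise ValueError(f"unknown task {task!r}")
    if len(np.unique(y)) < 2:
        raise ValueError("probe needs both classes present in the archive")
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    aucs = []
    for train_idx, test_idx in splitter.split(X, y):
        clf = make_pipeline(StandardScaler(), LogisticRegression(max_iter=1000))
        clf.fit(X[train_idx], y[train_idx])
        scores = clf.predict_proba(X[test_idx])[:, 1]
        aucs.append(roc_auc_score(y[test_idx], scores))
    return float(np.mean(aucs))
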