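"""ERP epoch containers and the stop-minus-slow-go N2 derivation.

Stop-signal-locked ERPs overlap with activity evoked by the preceding go
stimulus.  The standard remedy is a difference wave: go trials are median-
split on RT, the slow-go average (the go trials most comparable to
successful stops under the race model) is subtracted from the
successful-stop average, and the N2 is quantified as the mean amplitude of
that difference wave over a right anterior-frontal channel region of
interest in a window around the N2 peak (180-250 ms by default).

Containers are plain numpy-backed dataclasses; ``save_epochs`` /
``load_epochs`` persist one subject per ``.npz`` payload plus a JSON
sidecar (shape, channel labels, sampling rate, condition table).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "EpochSet",
    "ERPWave",
    "RoiSpec",
    "SplitHalfResult",
    "baseline_correct",
    "median_split_go",
    "condition_erp",
    "difference_wave",
    "roi_mean_amplitude",
    "derive_n2",
    "split_half_reliability",
    "save_epochs",
    "load_epochs",
]

CONDITIONS = ("successful_stop", "unsuccessful_stop", "go")


@dataclass
class EpochSet:
    """Per-subject epoched data: trials x channels x samples, in microvolts.

    ``epoch_window`` is (tmin, tmax) in ms relative to the time-locking
    event, endpoints inclusive on the sample grid, so the sample count must
    equal window-length-in-seconds * sampling_rate + 1.  ``conditions``
    labels each trial as successful_stop, unsuccessful_stop or go; ``go_rt``
    holds the response time for go trials (NaN otherwise).
    """

    data: np.ndarray
    sampling_rate: float
    epoch_window: tuple[float, float]
    channels: tuple[str, ...]
    conditions: np.ndarray
    go_rt: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.conditions = np.asarray(self.conditions, dtype=object)
        self.go_rt = np.asarray(self.go_rt, dtype=float)
        self.channels = tuple(self.channels)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        n_trials, n_channels, n_samples = self.data.shape
        if n_channels != len(self.channels):
            raise ValueError("channel axis does not match channel labels")
        tmin, tmax = self.epoch_window
        expected = round((tmax - tmin) / 1000.0 * self.sampling_rate) + 1
        if n_samples != expected:
            raise ValueError(
                f"expected {expected} samples for window {self.epoch_window} "
                f"at {self.sampling_rate} Hz, got {n_samples}"
            )
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown condition labels: {sorted(unknown)}")
        if len(self.conditions) != n_trials or len(self.go_rt) != n_trials:
            raise ValueError("per-trial metadata length mismatch")

    @property
    def times(self) -> np.ndarray:
        """Sample timestamps in ms, exact multiples of 1/rate from onset."""
        step = 1000.0 / self.sampling_rate
        return self.epoch_window[0] + step * np.arange(self.data.shape[2])

    def subset(self, index: np.ndarray) -> "EpochSet":
        index = np.asarray(index)
        return EpochSet(
            data=self.data[index],
            sampling_rate=self.sampling_rate,
            epoch_window=self.epoch_window,
            channels=self.channels,
            conditions=self.conditions[index],
            go_rt=self.go_rt[index],
        )


@dataclass
class ERPWave:
    """Trial-averaged waveform: channels x samples, in microvolts."""

    data: np.ndarray
    sampling_rate: float
    epoch_window: tuple[float, float]
    channels: tuple[str, ...]
    n_trials: int

    @property
    def times(self) -> np.ndarray:
        step = 1000.0 / self.sampling_rate
        return self.epoch_window[0] + step * np.arange(self.data.shape[1])


@dataclass(frozen=True)
class RoiSpec:
    """Channel subset and time window (ms) over which to average."""

    channels: tuple[str, ...]
    window: tuple[float, float] = (180.0, 250.0)


def baseline_correct(epochs: EpochSet, baseline: tuple[float, float] = (-200.0, 0.0)) -> EpochSet:
    """Subtract each trial/channel's mean over the baseline window."""
    tmin, tmax = epochs.epoch_window
    if baseline[0] < tmin or baseline[1] > tmax or baseline[0] > baseline[1]:
        raise ValueError(f"baseline {baseline} outside epoch window {epochs.epoch_window}")
    times = epochs.times
    mask = (times >= baseline[0]) & (times <= baseline[1])
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    corrected = epochs.data - epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return replace(epochs, data=corrected)


def median_split_go(epochs: EpochSet) -> np.ndarray:
    """Tag go trials 'slow' (RT >= median) or 'fast' (RT < median).

    Ties at the median count as slow, making the split deterministic.
    Non-go trials receive an empty tag.  Requires >= 2 go trials with RTs.
    """
    is_go = epochs.conditions == "go"
    rts = epochs.go_rt[is_go]
    if is_go.sum() < 2 or np.isnan(rts).any():
        raise ValueError("median split needs >= 2 go trials with RTs")
    median = float(np.median(rts))
    tags = np.full(len(epochs.conditions), "", dtype=object)
    tags[is_go] = np.where(rts >= median, "slow", "fast")
    return tags


def condition_erp(epochs: EpochSet, which: str | np.ndarray) -> ERPWave:
    """Average trials matching a condition label (or boolean mask)."""
    mask = (epochs.conditions == which) if isinstance(which, str) else np.asarray(which, bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"no trials match {which!r}")
    return ERPWave(
        data=epochs.data[mask].mean(axis=0),
        sampling_rate=epochs.sampling_rate,
        epoch_window=epochs.epoch_window,
        channels=epochs.channels,
        n_trials=n,
    )


def difference_wave(stop_erp: ERPWave, slow_go_erp: ERPWave) -> ERPWave:
    """Pointwise stop minus slow-go wave; inputs must share geometry."""
    if (
        stop_erp.channels != slow_go_erp.channels
        or stop_erp.sampling_rate != slow_go_erp.sampling_rate
        or stop_erp.epoch_window != slow_go_erp.epoch_window
        or stop_erp.data.shape != slow_go_erp.data.shape
    ):
        raise ValueError("waves differ in channels, sampling or window")
    return ERPWave(
        data=stop_erp.data - slow_go_erp.data,
        sampling_rate=stop_erp.sampling_rate,
        epoch_window=stop_erp.epoch_window,
        channels=stop_erp.channels,
        n_trials=min(stop_erp.n_trials, slow_go_erp.n_trials),
    )


def roi_mean_amplitude(wave: ERPWave, roi: RoiSpec) -> float:
    """Mean amplitude over ROI channels, then over in-window samples.

    Window endpoints are inclusive on the sample grid (e.g. at 250 Hz the
    180-250 ms window covers samples 180, 184, ..., 248 ms).
    """
    missing = [ch for ch in roi.channels if ch not in wave.channels]
    if missing:
        raise ValueError(f"ROI channels not in wave: {missing}")
    idx = [wave.channels.index(ch) for ch in roi.channels]
    times = wave.times
    mask = (times >= roi.window[0]) & (times <= roi.window[1])
    if not mask.any():
        raise ValueError("ROI window contains no samples")
    return float(wave.data[idx].mean(axis=0)[mask].mean())


def derive_n2(
    epochs: EpochSet,
    roi: RoiSpec,
    baseline: tuple[float, float] = (-200.0, 0.0),
) -> float:
    """Full N2 pipeline: baseline -> median split -> difference wave -> ROI mean."""
    corrected = baseline_correct(epochs, baseline)
    tags = median_split_go(corrected)
    stop = condition_erp(corrected, "successful_stop")
    slow_go = condition_erp(corrected, tags == "slow")
    return roi_mean_amplitude(difference_wave(stop, slow_go), roi)


@dataclass(frozen=True)
class SplitHalfResult:
    half_correlation: float
    reliability: float  # Spearman-Brown corrected
    n_subjects: int


def spearman_brown(r: float) -> float:
    """Step-up correction for a half-length measure: 2r / (1 + r)."""
    return 2.0 * r / (1.0 + r)


def split_half_reliability(
    subject_epochs: Sequence[EpochSet],
    roi: RoiSpec,
    derivation: Callable[[EpochSet, RoiSpec], float] = derive_n2,
) -> SplitHalfResult:
    """Odd/even split-half reliability of the per-subject N2 measure.

    For each subject, trials are split by order (odd vs even) within each
    condition, the derivation runs on each half, and the two half-measures
    are correlated across subjects; the Spearman-Brown formula steps the
    half-length correlation up to full length.
    """
    if len(subject_epochs) < 3:
        raise ValueError("split-half reliability needs >= 3 subjects")
    halves = ([], [])
    for epochs in subject_epochs:
        n_stop = int((epochs.conditions == "successful_stop").sum())
        n_go = int((epochs.conditions == "go").sum())
        if n_stop < 4 or n_go < 4:
            raise ValueError("each subject needs >= 4 successful-stop and >= 4 go trials")
        order = np.zeros(len(epochs.conditions), dtype=int)
        for label in CONDITIONS:
            mask = epochs.conditions == label
            order[mask] = np.arange(int(mask.sum()))
        for parity in (0, 1):
            half = epochs.subset(np.where(order % 2 == parity)[0])
            halves[parity].append(derivation(half, roi))
    a, b = np.asarray(halves[0]), np.asarray(halves[1])
    r = float(np.corrcoef(a, b)[0, 1])
    return SplitHalfResult(half_correlation=r, reliability=spearman_brown(r), n_subjects=len(a))


def save_epochs(epochs: EpochSet, path) -> None:
    """Write one subject's epochs as <path>.npz + <path>.json sidecar."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), data=epochs.data)
    sidecar = {
        "shape": list(epochs.data.shape),
        "sampling_rate": epochs.sampling_rate,
        "epoch_window": list(epochs.epoch_window),
        "channels": list(epochs.channels),
        "conditions": [str(c) for c in epochs.conditions],
        "go_rt": [None if np.isnan(v) else float(v) for v in epochs.go_rt],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_epochs(path) -> EpochSet:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as payload:
        data = payload["data"]
    return EpochSet(
        data=data,
        sampling_rate=meta["sampling_rate"],
        epoch_window=tuple(meta["epoch_window"]),
        channels=tuple(meta["channels"]),
        conditions=np.array(meta["conditions"], dtype=object),
        go_rt=np.array([np.nan if v is None else v for v in meta["go_rt"]]),
    )
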