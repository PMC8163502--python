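"""EEG ingestion, preprocessing, and state-epoch extraction.

The preprocessing chain mirrors a standard anesthesia-EEG workflow:
down-sampling to 250 Hz, re-referencing to the linked mastoids, reduction to
a 21-channel 10-20 scalp montage, and zero-phase band-pass filtering at
0.5-30 Hz with a 4th-order Butterworth filter (applied forward-backward).
From the continuous recording, labelled 2-minute state epochs are cut around
behavioural events: eyes-closed resting sessions (EC1-EC7), loss of
consciousness (LOC), the end of anesthetic maintenance, and the 2 minutes
preceding recovery of consciousness (PreROC). Maintenance epochs containing
burst suppression are replaced by the nearest suppression-free 2-minute
segment, searching the last 10 minutes of anesthetic administration first
and the 7 minutes after discontinuation second.

Artifact handling is explicit rather than automatic: a boolean sample mask
(or a CSV sidecar of masked spans) marks samples that epochs must avoid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .errors import (
    EpochUnavailableError,
    FormatError,
    MontageError,
    ParameterError,
    ReferenceError_,
    SamplingError,
)

#: The reduced scalp montage: the 19 standard 10-20 positions plus Fpz and Oz.
STANDARD_21 = (
    "Fp1", "Fpz", "Fp2",
    "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "Oz", "O2",
)

FRONTAL_CHANNELS = ("Fp1", "Fp2", "Fpz", "F3", "F4", "Fz")
POSTERIOR_CHANNELS = ("P3", "P4", "Pz", "O1", "O2", "Oz")

LEFT_MASTOID_ALIASES = ("M1", "A1", "TP9")
RIGHT_MASTOID_ALIASES = ("M2", "A2", "TP10")

ANESTHESIA_STATES = (
    "EC1", "LOC", "Maintenance", "PreROC", "EC2", "EC3", "EC4", "EC5", "EC6", "EC7",
)
CONTROL_STATES = ("EC1", "EC2", "EC3", "EC4", "EC5", "EC6", "EC7")

_CANONICAL = {
    lab.upper(): lab
    for lab in STANDARD_21 + LEFT_MASTOID_ALIASES + RIGHT_MASTOID_ALIASES
}


def normalize_channel_label(label: str) -> str:
    """Map vendor spellings ('EEG FP1-REF', 'fpz') onto canonical 10-20 names."""
    lab = label.strip()
    for prefix in ("EEG ", "eeg "):
        if lab.startswith(prefix):
            lab = lab[len(prefix):]
    lab = lab.split("-")[0].strip()
    return _CANONICAL.get(lab.upper(), lab)


@dataclass
class EEGRecording:
    """A multichannel scalp EEG recording in microvolts.

    ``data`` is ``n_channels x n_samples``; ``artifact_mask`` flags samples
    (True = excluded) that state epochs must not overlap.
    """

    subject_id: str
    data: np.ndarray
    fs: float
    channel_labels: list[str]
    artifact_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise FormatError("EEG data must be a 2-D channels x samples matrix")
        if self.fs <= 0:
            raise SamplingError(f"non-positive sampling rate {self.fs}")
        if len(self.channel_labels) != self.data.shape[0]:
            raise MontageError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise MontageError("channel labels are not unique")
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.data.shape[1], dtype=bool)
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if self.artifact_mask.shape != (self.data.shape[1],):
            raise FormatError("artifact mask length must equal n_samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class StateEpoch:
    """A contiguous, artifact-free 2-minute segment with a state label."""

    subject_id: str
    state: str
    data: np.ndarray
    fs: float
    channel_labels: list[str]
    start_s: float = 0.0

    def __post_init__(self) -> None:
        if self.state not in ANESTHESIA_STATES:
            raise ParameterError(f"unknown state label {self.state!r}")
        self.data = np.asarray(self.data, dtype=np.float64)

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs


@dataclass
class EpochSelectionEvents:
    """Event times (seconds from recording start) used to place state epochs.

    ``loc_time``/``iso_off_time``/``roc_time`` are None for control subjects,
    who only contribute the seven resting eyes-closed sessions.
    """

    resting_session_starts: Sequence[float]
    loc_time: float | None = None
    iso_off_time: float | None = None
    roc_time: float | None = None

    def __post_init__(self) -> None:
        starts = list(self.resting_session_starts)
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ParameterError("resting session starts must be strictly increasing")
        anes = (self.loc_time, self.iso_off_time, self.roc_time)
        if any(t is not None for t in anes):
            if any(t is None for t in anes):
                raise ParameterError("loc/iso-off/roc times must be given together")
            if not (self.loc_time < self.iso_off_time < self.roc_time):
                raise ParameterError("require loc_time < iso_off_time < roc_time")


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_eeg(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording as plain text: ``<path>`` CSV (samples x channels,
    header = labels) plus a ``.json`` sidecar with fs and subject id."""
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=rec.channel_labels)
    df.to_csv(path, index=False, float_format="%.6f")
    meta = {"fs": rec.fs, "subject_id": rec.subject_id}
    path.with_suffix(".json").write_text(json.dumps(meta))
    return path


def read_artifact_mask(path: str | Path, fs: float, n_samples: int) -> np.ndarray:
    """Read a (start_s, end_s) span CSV into a boolean per-sample mask."""
    spans = pd.read_csv(path)
    mask = np.zeros(n_samples, dtype=bool)
    for _, row in spans.iterrows():
        i0 = max(0, int(np.floor(row["start_s"] * fs)))
        i1 = min(n_samples, int(np.ceil(row["end_s"] * fs)))
        mask[i0:i1] = True
    return mask


def read_events(path: str | Path) -> EpochSelectionEvents:
    """Read an (event, time_s) CSV into epoch-selection events.

    Recognized event names: ``loc``, ``iso_off``, ``roc``, ``ec1``..``ec7``.
    """
    df = pd.read_csv(path)
    times = {str(e).strip().lower(): float(t) for e, t in zip(df["event"], df["time_s"])}
    starts = [times[f"ec{i}"] for i in range(1, 8) if f"ec{i}" in times]
    return EpochSelectionEvents(
        resting_session_starts=starts,
        loc_time=times.get("loc"),
        iso_off_time=times.get("iso_off"),
        roc_time=times.get("roc"),
    )


def read_eeg(
    path: str | Path,
    format: str = "auto",
    mask_path: str | Path | None = None,
    subject_id: str | None = None,
) -> EEGRecording:
    """Read an EEG recording from CSV (this package's text format), EDF, or
    BrainVision, returning data in microvolts with normalized 10-20 labels."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "auto":
        suffix = path.suffix.lower()
        format = {".csv": "csv", ".edf": "edf", ".vhdr": "brainvision"}.get(suffix, "")
        if not format:
            raise FormatError(f"cannot infer format from suffix {suffix!r}")

    if format == "csv":
        try:
            df = pd.read_csv(path)
            meta = json.loads(path.with_suffix(".json").read_text())
        except Exception as exc:  # noqa: BLE001 - surfaced as a format error
            raise FormatError(f"unreadable recording {path}: {exc}") from exc
        labels = [normalize_channel_label(c) for c in df.columns]
        data = df.to_numpy(dtype=np.float64).T
        fs = float(meta["fs"])
        sid = subject_id or str(meta.get("subject_id", path.stem))
    elif format in ("edf", "brainvision"):
        import mne

        reader = mne.io.read_raw_edf if format == "edf" else mne.io.read_raw_brainvision
        try:
            raw = reader(path, preload=True, verbose="error")
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"unreadable recording {path}: {exc}") from exc
        labels = [normalize_channel_label(c) for c in raw.ch_names]
        data = raw.get_data() * 1e6  # volts -> microvolts
        fs = float(raw.info["sfreq"])
        sid = subject_id or path.stem
    else:
        raise FormatError(f"unknown format {format!r}")

    if data.shape[0] < 21:
        raise MontageError(
            f"{data.shape[0]} channels; at least the 21 scalp channels are required"
        )
    mask = None
    if mask_path is not None:
        mask = read_artifact_mask(mask_path, fs, data.shape[1])
    return EEGRecording(sid, data, fs, labels, mask)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def _find_mastoids(
    labels: Sequence[str], substitute: tuple[str, str] | None
) -> tuple[str, str]:
    if substitute is not None:
        left, right = substitute
        if left in labels and right in labels:
            return left, right
        raise ReferenceError_(f"substitute reference pair {substitute} not in montage")
    left = next((m for m in LEFT_MASTOID_ALIASES if m in labels), None)
    right = next((m for m in RIGHT_MASTOID_ALIASES if m in labels), None)
    if left is None or right is None:
        raise ReferenceError_(
            "no mastoid channels found and no substitute reference pair declared"
        )
    return left, right


def _resample_mask(mask: np.ndarray, n_new: int, fs_in: float, fs_out: float) -> np.ndarray:
    """Propagate a boolean mask through resampling, dilating conservatively."""
    if not mask.any():
        return np.zeros(n_new, dtype=bool)
    t_new = np.arange(n_new) / fs_out
    t_old = np.arange(mask.size) / fs_in
    interp = np.interp(t_new, t_old, mask.astype(float))
    new = interp > 1e-3
    # one-sample dilation guards the filter edges of masked spans
    return new | np.roll(new, 1) | np.roll(new, -1)


def preprocess_eeg(
    rec: EEGRecording,
    target_fs: float = 250.0,
    band: tuple[float, float] = (0.5, 30.0),
    order: int = 4,
    reference_pair: tuple[str, str] | None = None,
    montage: Sequence[str] = STANDARD_21,
) -> EEGRecording:
    """Linked-mastoid reference, montage reduction, polyphase resampling to
    250 Hz, and zero-phase order-4 Butterworth band-pass (0.5-30 Hz)."""
    if rec.fs < 2 * band[1]:
        raise SamplingError(
            f"fs={rec.fs} Hz cannot represent the {band[1]} Hz band edge"
        )
    left, right = _find_mastoids(rec.channel_labels, reference_pair)
    idx = {lab: i for i, lab in enumerate(rec.channel_labels)}
    ref = 0.5 * (rec.data[idx[left]] + rec.data[idx[right]])

    missing = [ch for ch in montage if ch not in idx]
    if missing:
        raise MontageError(f"montage channels missing from recording: {missing}")
    data = np.stack([rec.data[idx[ch]] - ref for ch in montage])

    mask = rec.artifact_mask
    if rec.fs != target_fs:
        frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
        data = signal.resample_poly(data, frac.numerator, frac.denominator, axis=1)
        mask = _resample_mask(mask, data.shape[1], rec.fs, target_fs)
    else:
        mask = mask.copy()

    sos = signal.butter(order, band, btype="bandpass", fs=target_fs, output="sos")
    data = signal.sosfiltfilt(sos, data, axis=1)
    return EEGRecording(rec.subject_id, data, target_fs, list(montage), mask)


# ---------------------------------------------------------------------------
# Burst suppression
# ---------------------------------------------------------------------------

def suppression_fraction(
    data: np.ndarray | StateEpoch,
    fs: float | None = None,
    amp_threshold: float = 5.0,
    min_span_s: float = 0.5,
) -> float:
    """Fraction of time all channels stay below ``amp_threshold`` microvolts
    for at least ``min_span_s`` seconds (an amplitude-envelope stand-in for
    visual burst-suppression identification)."""
    if isinstance(data, StateEpoch):
        fs = data.fs
        data = data.data
    if fs is None:
        raise ParameterError("fs required when passing a raw matrix")
    if amp_threshold <= 0:
        raise ParameterError("amp_threshold must be positive")
    below = np.all(np.abs(np.atleast_2d(data)) < amp_threshold, axis=0)
    n = below.size
    min_len = max(1, int(round(min_span_s * fs)))
    # run-length encode `below`
    edges = np.flatnonzero(np.diff(below.astype(np.int8)))
    starts = np.concatenate(([0], edges + 1))
    ends = np.concatenate((edges + 1, [n]))
    suppressed = 0
    for s, e in zip(starts, ends):
        if below[s] and (e - s) >= min_len:
            suppressed += e - s
    return suppressed / n


# ---------------------------------------------------------------------------
# State-epoch extraction
# ---------------------------------------------------------------------------

def _clean_start(
    rec: EEGRecording,
    candidates: np.ndarray,
    n_epoch: int,
    accept: Callable[[int], bool] | None = None,
) -> int | None:
    """First candidate start sample yielding an unmasked (and accepted) epoch."""
    for c in candidates:
        c = int(c)
        if c < 0 or c + n_epoch > rec.n_samples:
            continue
        if rec.artifact_mask[c : c + n_epoch].any():
            continue
        if accept is not None and not accept(c):
            continue
        return c
    return None


def extract_state_epochs(
    rec: EEGRecording,
    events: EpochSelectionEvents,
    group: str,
    duration_s: float = 120.0,
    bs_amp_threshold: float = 5.0,
    bs_min_span_s: float = 0.5,
    search_step_s: float = 1.0,
) -> tuple[list[StateEpoch], list[EpochUnavailableError]]:
    """Cut the labelled 2-minute epochs for one subject.

    Anesthesia subjects yield up to ten epochs (EC1, LOC, Maintenance,
    PreROC, EC2-EC7); controls up to seven (EC1-EC7). Epochs that cannot be
    placed without touching the artifact mask are reported in the second
    return value, never fabricated.
    """
    if group not in ("anesthesia", "control"):
        raise ParameterError(f"unknown group {group!r}")
    fs = rec.fs
    n_ep = int(round(duration_s * fs))
    step = max(1, int(round(search_step_s * fs)))

    def fwd(t0: float, span: float) -> np.ndarray:
        s0 = int(round(t0 * fs))
        return np.arange(s0, s0 + int(span * fs) + 1, step)

    def bwd(t_end: float, span: float) -> np.ndarray:
        # latest-first candidates for windows anchored at their right edge
        s_last = int(round(t_end * fs)) - n_ep
        return np.arange(s_last, s_last - int(span * fs) - 1, -step)

    plans: list[tuple[str, np.ndarray, Callable[[int], bool] | None]] = []
    starts = list(events.resting_session_starts)
    ec_states = CONTROL_STATES if group == "control" else CONTROL_STATES
    for state, t0 in zip(ec_states, starts):
        plans.append((state, fwd(t0, 480.0), None))

    if group == "anesthesia":
        if events.loc_time is None:
            raise ParameterError("anesthesia subject requires loc/iso_off/roc events")
        no_bs = lambda c: suppression_fraction(  # noqa: E731
            rec.data[:, c : c + n_ep], fs, bs_amp_threshold, bs_min_span_s
        ) == 0.0
        plans.append(("LOC", fwd(events.loc_time, 300.0), None))
        # Maintenance: nominal last 2 min of anesthetic administration; on
        # burst suppression fall back to earlier segments of the last 10 min,
        # then to the 7 min after discontinuation.
        maint = np.concatenate(
            [bwd(events.iso_off_time, 480.0), fwd(events.iso_off_time, 300.0)]
        )
        plans.append(("Maintenance", maint, no_bs))
        plans.append(("PreROC", bwd(events.roc_time, 300.0), None))

    order = ANESTHESIA_STATES if group == "anesthesia" else CONTROL_STATES
    found: dict[str, StateEpoch] = {}
    missing: list[EpochUnavailableError] = []
    for state, candidates, accept in plans:
        c = _clean_start(rec, candidates, n_ep, accept)
        if c is None:
            missing.append(EpochUnavailableError(state, "no admissible unmasked window"))
            continue
        found[state] = StateEpoch(
            rec.subject_id,
            state,
            rec.data[:, c : c + n_ep].copy(),
            fs,
            list(rec.channel_labels),
            start_s=c / fs,
        )
    epochs = [found[s] for s in order if s in found]
    return epochs, missing
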