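"""Windowing, labelling, derived channels, and subject-wise fold planning.

A recording is labelled from its KSS score (>= 4 means fatigue), cut into
fixed-length windows that inherit the label, and optionally converted to
derived physiological channels: an instantaneous heart-rate series (from
systolic peak detection) and a breathing series (the 0.1-0.5 Hz modulation
band).  Cross-validation plans are always subject-disjoint: either k groups
of subjects or leave-one-subject-out.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .synth import CONDITIONS, FATIGUE, NON_FATIGUE, PpgRecord, SubjectProfile

CHANNELS = ("ppg", "hr", "br", "hr_br")
SCHEMES = ("kfold_by_subject", "leave_one_subject_out")

KSS_FATIGUE_MIN = 4  # KSS >= 4 is labelled fatigue, <= 3 non-fatigue

DEFAULT_WINDOW_S = 10.56  # 1056 samples at 100 Hz, the models' canonical window
DEFAULT_RESAMPLE_HZ = 4.0  # uniform rate for derived HR / BR series


@dataclass(frozen=True)
class Window:
    """A fixed-length signal segment carrying its subject and inherited label."""

    subject_id: str
    window_index: int
    samples: np.ndarray  # (T,) for single channels, (2, T) for hr_br
    channel: str
    label: str

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        if self.label not in CONDITIONS:
            raise ValueError(f"label must be one of {CONDITIONS}, got {self.label!r}")


@dataclass(frozen=True)
class FoldPlan:
    scheme: str
    folds: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]  # (train_ids, test_ids)
    seed: int

    def __post_init__(self) -> None:
        for train, test in self.folds:
            if set(train) & set(test):
                raise ValueError("train and test subjects overlap within a fold")


def label_from_kss(kss: int) -> str:
    """Map a KSS score to the binary condition label (>= 4 means fatigue)."""
    if not float(kss).is_integer() or kss < 1:
        raise ValueError(f"kss must be an integer >= 1, got {kss!r}")
    return FATIGUE if kss >= KSS_FATIGUE_MIN else NON_FATIGUE


def _segment_array(
    samples: np.ndarray, n_window: int, overlap_fraction: float
) -> list[np.ndarray]:
    stride = max(int(round(n_window * (1.0 - overlap_fraction))), 1)
    starts = range(0, len(samples) - n_window + 1, stride)
    return [samples[s : s + n_window] for s in starts]


def segment(
    record: PpgRecord,
    window_s: float = DEFAULT_WINDOW_S,
    overlap_fraction: float = 0.0,
    channel: str = "ppg",
    max_windows: int | None = None,
) -> list[Window]:
    """Cut a record into equal-length windows; trailing partial window dropped.

    Each window inherits the record's subject id and condition label.
    """
    if not (0 <= overlap_fraction < 1):
        raise ValueError(f"overlap_fraction must be in [0, 1), got {overlap_fraction}")
    n_window = int(round(window_s * record.fs_hz))
    if n_window < 2:
        raise ValueError(f"window of {window_s} s at {record.fs_hz} Hz has < 2 samples")
    if n_window > len(record.samples):
        raise ValueError(
            f"window of {n_window} samples longer than record ({len(record.samples)})"
        )
    pieces = _segment_array(record.samples, n_window, overlap_fraction)
    if max_windows is not None:
        pieces = pieces[:max_windows]
    return [
        Window(record.subject_id, i, np.asarray(p, dtype=float), channel, record.condition)
        for i, p in enumerate(pieces)
    ]


def detect_peaks(
    samples: np.ndarray,
    fs_hz: float,
    threshold_frac: float = 0.6,
    refractory_s: float = 0.3,
    rolling_s: float = 2.0,
) -> np.ndarray:
    """Systolic peak indices: adaptive-threshold local maxima with a refractory period.

    Peak search runs on a 0.5-8 Hz band-passed copy (suppresses baseline
    wander and powerline buzz); a candidate peak is kept when it exceeds
    ``threshold_frac`` times the rolling ``rolling_s`` maximum.
    """
    from scipy.ndimage import maximum_filter1d

    sos = sps.butter(2, [0.5, 8.0], btype="bandpass", fs=fs_hz, output="sos")
    filt = sps.sosfiltfilt(sos, np.asarray(samples, dtype=float))
    roll = maximum_filter1d(filt, size=max(int(rolling_s * fs_hz), 1))
    cand, _ = sps.find_peaks(filt, distance=max(int(refractory_s * fs_hz), 1))
    return cand[filt[cand] >= threshold_frac * roll[cand]]


def hr_series(
    record: PpgRecord, resample_hz: float = DEFAULT_RESAMPLE_HZ
) -> PpgRecord:
    """Instantaneous heart rate (beats/min) resampled to a uniform rate.

    Peaks -> inter-beat intervals -> 60/IBI bpm at the interval midpoints,
    linearly interpolated onto a uniform grid.  Returned as a record with
    ``fs_hz = resample_hz`` so it can be segmented like any other channel.
    """
    peaks = detect_peaks(record.samples, record.fs_hz)
    if len(peaks) < 3:
        raise ValueError(
            f"need >= 3 detected systolic peaks to form an HR series, got {len(peaks)}"
        )
    peak_t = peaks / record.fs_hz
    ibis = np.diff(peak_t)
    hr_bpm = 60.0 / ibis
    mid_t = 0.5 * (peak_t[:-1] + peak_t[1:])
    grid = np.arange(0.0, record.duration_s, 1.0 / resample_hz)
    hr_uniform = np.interp(grid, mid_t, hr_bpm)
    return PpgRecord(
        subject_id=record.subject_id,
        condition=record.condition,
        fs_hz=resample_hz,
        samples=hr_uniform,
        meta=record.meta,
    )


def br_series(
    record: PpgRecord, resample_hz: float = DEFAULT_RESAMPLE_HZ
) -> PpgRecord:
    """Breathing waveform: the 0.1-0.5 Hz modulation band, uniformly resampled.

    The PPG baseline is modulated by respiration; a zero-phase Butterworth
    band-pass isolates that band and removes DC, so the output is zero-mean.
    """
    if record.duration_s < 30.0:
        raise ValueError(
            f"record of {record.duration_s:.1f} s too short for breathing "
            "extraction (need >= 30 s)"
        )
    sos = sps.butter(2, [0.1, 0.5], btype="bandpass", fs=record.fs_hz, output="sos")
    resp = sps.sosfiltfilt(sos, np.asarray(record.samples, dtype=float))
    grid = np.arange(0.0, record.duration_s, 1.0 / resample_hz)
    t = np.arange(len(resp)) / record.fs_hz
    resp_uniform = np.interp(grid, t, resp)
    resp_uniform = resp_uniform - resp_uniform.mean()
    return PpgRecord(
        subject_id=record.subject_id,
        condition=record.condition,
        fs_hz=resample_hz,
        samples=resp_uniform,
        meta=record.meta,
    )


def stack_hr_br(hr_windows: list[Window], br_windows: list[Window]) -> list[Window]:
    """Channel-wise stacking of aligned HR and BR windows into 2-channel windows."""
    if len(hr_windows) != len(br_windows):
        raise ValueError("hr and br window lists must be aligned")
    out = []
    for hw, bw in zip(hr_windows, br_windows):
        if (hw.subject_id, hw.window_index, hw.label) != (
            bw.subject_id,
            bw.window_index,
            bw.label,
        ):
            raise ValueError("hr/br windows are misaligned")
        out.append(
            Window(
                hw.subject_id,
                hw.window_index,
                np.stack([hw.samples, bw.samples]),
                "hr_br",
                hw.label,
            )
        )
    return out


def make_folds(
    subject_ids: list[str], scheme: str, k: int = 5, seed: int = 0
) -> FoldPlan:
    """Subject-disjoint cross-validation plan.

    ``kfold_by_subject`` shuffles the subjects with the seed and splits them
    into k near-equal groups; ``leave_one_subject_out`` yields one fold per
    subject.  Every subject appears in exactly one test set.
    """
    subject_ids = list(subject_ids)
    if len(set(subject_ids)) != len(subject_ids):
        raise ValueError("subject_ids must be unique")
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}, got {scheme!r}")
    if scheme == "leave_one_subject_out":
        folds = tuple(
            (tuple(s for s in subject_ids if s != sid), (sid,)) for sid in subject_ids
        )
        return FoldPlan(scheme, folds, seed)
    if k > len(subject_ids):
        raise ValueError(f"k={k} exceeds the number of subjects ({len(subject_ids)})")
    rng = np.random.default_rng(seed)
    shuffled = list(np.array(subject_ids)[rng.permutation(len(subject_ids))])
    groups = np.array_split(shuffled, k)
    folds = tuple(
        (
            tuple(s for s in subject_ids if s not in set(g)),
            tuple(str(s) for s in g),
        )
        for g in groups
    )
    return FoldPlan(scheme, folds, seed)


def split_counts(
    fold: tuple[tuple[str, ...], tuple[str, ...]], windows_per_subject: int
) -> tuple[int, int]:
    """(n_train, n_test) window counts for one fold at a fixed per-subject yield."""
    train, test = fold
    return len(train) * windows_per_subject, len(test) * windows_per_subject


def windows_to_arrays(
    windows: list[Window],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack windows into (X, y, subjects): X is (N, C, T), y is 1 for fatigue."""
    if not windows:
        raise ValueError("no windows given")
    mats = []
    for w in windows:
        arr = np.asarray(w.samples, dtype=float)
        mats.append(arr[None, :] if arr.ndim == 1 else arr)
    X = np.stack(mats)
    y = np.array([1 if w.label == FATIGUE else 0 for w in windows], dtype=int)
    subjects = np.array([w.subject_id for w in windows])
    return X, y, subjects


def load_cohort(manifest_path: str | Path) -> list[PpgRecord]:
    """Read a cohort written by ``synth.write_cohort``.

    Generative profile fields are unknown for data read from disk; the
    attached profile carries the manifest's KSS/PVT and nominal placeholders
    for the simulator-internal parameters.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    records = []
    for row in manifest.itertuples():
        sig = pd.read_csv(manifest_path.parent / row.path)
        profile = SubjectProfile(
            subject_id=row.subject_id,
            condition=row.condition,
            kss=int(row.kss),
            pvt_ms=float(row.pvt_ms),
            mean_ibi_s=0.8,
            ibi_sd_s=0.0,
            dicrotic_amp_rel=0.0,
        )
        records.append(
            PpgRecord(
                subject_id=row.subject_id,
                condition=row.condition,
                fs_hz=float(row.fs_hz),
                samples=sig.amplitude.to_numpy(dtype=float),
                meta=profile,
            )
        )
    return records
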