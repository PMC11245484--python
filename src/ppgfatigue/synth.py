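"""Synthetic two-class PPG cohort generator.

Produces seeded, reproducible photoplethysmogram recordings for a cohort of
subjects measured in two conditions (``fatigue`` / ``non_fatigue``).  Each
beat is a two-kernel template — a systolic bump plus a delayed, attenuated
dicrotic bump — strung along a sequence of inter-beat intervals (IBIs) drawn
from a positive-truncated normal.  The two classes differ in beat-interval
variability and dicrotic-wave amplitude, the two morphological axes the
fatigue-detection pipeline is meant to pick up.  Recordings are contaminated
with the three noise kinds typical of wearable PPG: low-frequency baseline
wander, mains (powerline) interference, and additive white Gaussian noise.

Every generated object is a pure function of its parameters and the seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reference import reference_cohort

FATIGUE = "fatigue"
NON_FATIGUE = "non_fatigue"
CONDITIONS = (FATIGUE, NON_FATIGUE)

# Beat-template geometry (fractions of one beat period).
SYSTOLIC_CENTER = 0.18
SYSTOLIC_WIDTH = 0.07
DICROTIC_WIDTH = 0.10
DEFAULT_DICROTIC_DELAY = 0.35

# KSS / PVT sampling distributions, taken from the reference cohort table.
_ref = reference_cohort()
_f = _ref[_ref.condition == FATIGUE]
_n = _ref[_ref.condition == NON_FATIGUE]
KSS_SUPPORT = {
    FATIGUE: _f.kss.value_counts(normalize=True).sort_index(),
    NON_FATIGUE: _n.kss.value_counts(normalize=True).sort_index(),
}
PVT_MEAN = {FATIGUE: float(_f.pvt_ms.mean()), NON_FATIGUE: float(_n.pvt_ms.mean())}
PVT_SD = {
    FATIGUE: float(_f.pvt_ms.std(ddof=0)),
    NON_FATIGUE: float(_n.pvt_ms.std(ddof=0)),
}
del _ref, _f, _n


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters for one subject-session."""

    subject_id: str
    condition: str
    kss: int
    pvt_ms: float
    mean_ibi_s: float
    ibi_sd_s: float
    dicrotic_amp_rel: float
    n_windows: int = 40

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if not (1 <= int(self.kss)):
            raise ValueError(f"kss must be >= 1, got {self.kss}")
        if self.pvt_ms <= 0:
            raise ValueError(f"pvt_ms must be positive, got {self.pvt_ms}")
        if self.mean_ibi_s <= 0:
            raise ValueError(f"mean_ibi_s must be positive, got {self.mean_ibi_s}")
        if self.ibi_sd_s < 0:
            raise ValueError(f"ibi_sd_s must be nonnegative, got {self.ibi_sd_s}")
        if not (0 <= self.dicrotic_amp_rel < 1):
            raise ValueError(f"dicrotic_amp_rel must be in [0, 1), got {self.dicrotic_amp_rel}")
        if self.n_windows < 1:
            raise ValueError(f"n_windows must be >= 1, got {self.n_windows}")


@dataclass(frozen=True)
class SynthConfig:
    """Recording-level simulation settings.

    Amplitudes are relative to the unit systolic peak.  Baseline wander lives
    in the 0.05-0.5 Hz band; the default 0.1 Hz matches slow respiratory /
    motion drift.  Mains pickup is nominally 50/60 Hz, which is not
    representable at the default 100 Hz sampling rate (it sits exactly at
    Nyquist), so the default interference tone is placed just below Nyquist
    at 45 Hz; set ``powerline_hz`` to true mains and raise ``fs_hz``
    accordingly when emulating a faster sensor.
    """

    fs_hz: float = 100.0
    duration_s: float = 600.0
    baseline_amp: float = 0.3
    baseline_hz: float = 0.1
    powerline_amp: float = 0.05
    powerline_hz: float = 45.0
    white_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"duration_s must be positive, got {self.duration_s}")
        if self.fs_hz <= 0:
            raise ValueError(f"fs_hz must be positive, got {self.fs_hz}")
        for name in ("baseline_amp", "powerline_amp", "white_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (0.05 <= self.baseline_hz <= 0.5):
            raise ValueError(f"baseline_hz must lie in [0.05, 0.5], got {self.baseline_hz}")
        if self.powerline_amp > 0 and self.fs_hz <= 2 * self.powerline_hz:
            raise ValueError(
                f"fs_hz={self.fs_hz} must exceed twice the powerline frequency "
                f"{self.powerline_hz} when powerline_amp > 0"
            )


@dataclass(frozen=True)
class PpgRecord:
    """One subject-session PPG signal plus its generative ground truth.

    ``clean`` is the uncontaminated pulse train and ``beat_times`` the true
    systolic onsets; both exist so downstream stages (denoising, peak
    detection) can be scored against the generator rather than against
    themselves.
    """

    subject_id: str
    condition: str
    fs_hz: float
    samples: np.ndarray
    meta: SubjectProfile
    clean: np.ndarray = field(repr=False, default=None)
    beat_times: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("PPG samples must be finite")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs_hz


def make_pulse(
    phase,
    dicrotic_amp_rel: float,
    dicrotic_delay_rel: float = DEFAULT_DICROTIC_DELAY,
):
    """Evaluate the beat template at ``phase`` (fraction of a beat in [0, 1)).

    The template is the sum of a unit-amplitude Gaussian systolic bump and a
    Gaussian dicrotic bump delayed by ``dicrotic_delay_rel`` and scaled by
    ``dicrotic_amp_rel``.  With the default widths the two bumps are well
    separated, so the systolic peak stays normalised at 1.
    """
    phase = np.asarray(phase, dtype=float)
    if np.any((phase < 0) | (phase >= 1)):
        raise ValueError("phase must lie in [0, 1)")
    if not (0 <= dicrotic_amp_rel < 1):
        raise ValueError(f"dicrotic_amp_rel must be in [0, 1), got {dicrotic_amp_rel}")
    if not (0 < dicrotic_delay_rel < 1):
        raise ValueError(f"dicrotic_delay_rel must be in (0, 1), got {dicrotic_delay_rel}")
    sys_bump = np.exp(-0.5 * ((phase - SYSTOLIC_CENTER) / SYSTOLIC_WIDTH) ** 2)
    dic_center = SYSTOLIC_CENTER + dicrotic_delay_rel
    dic_bump = np.exp(-0.5 * ((phase - dic_center) / DICROTIC_WIDTH) ** 2)
    out = sys_bump + dicrotic_amp_rel * dic_bump
    return out if out.ndim else float(out)


def _record_rng(config: SynthConfig, profile: SubjectProfile) -> np.random.Generator:
    sid_hash = zlib.crc32(profile.subject_id.encode()) & 0x7FFFFFFF
    cond_code = CONDITIONS.index(profile.condition)
    return np.random.default_rng([config.seed, sid_hash, cond_code])


def _draw_ibis(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    total_s: float,
    max_batches: int = 1000,
) -> np.ndarray:
    """Positive-truncated normal IBIs by rejection, until they span total_s."""
    if sd == 0:
        n = int(np.ceil(total_s / mean)) + 2
        return np.full(n, mean)
    ibis: list[np.ndarray] = []
    accumulated = 0.0
    batch = max(int(np.ceil(total_s / mean)) + 8, 16)
    for _ in range(max_batches):
        draw = rng.normal(mean, sd, size=batch)
        draw = draw[draw > 0]
        if draw.size:
            ibis.append(draw)
            accumulated += float(draw.sum())
            if accumulated > total_s:
                return np.concatenate(ibis)
    raise RuntimeError(
        f"IBI sampling collapsed: mean_ibi_s={mean}, ibi_sd_s={sd} rejects "
        f"essentially every draw (needed {total_s} s, got {accumulated:.3f} s)"
    )


def simulate_record(profile: SubjectProfile, config: SynthConfig) -> PpgRecord:
    """Simulate one subject-session recording; deterministic given the seed."""
    rng = _record_rng(config, profile)
    n = int(round(config.fs_hz * config.duration_s))
    t = np.arange(n) / config.fs_hz

    ibis = _draw_ibis(rng, profile.mean_ibi_s, profile.ibi_sd_s, config.duration_s + 2 * profile.mean_ibi_s)
    onsets = np.concatenate([[0.0], np.cumsum(ibis)])
    idx = np.searchsorted(onsets, t, side="right") - 1
    phase = np.clip((t - onsets[idx]) / ibis[idx], 0.0, np.nextafter(1.0, 0.0))
    clean = make_pulse(phase, profile.dicrotic_amp_rel)

    # Noise streams are always drawn so the clean/noisy split never depends on
    # which amplitudes happen to be zero.
    ph_base, ph_line = rng.uniform(0, 2 * np.pi, size=2)
    white = rng.standard_normal(n)
    noisy = (
        clean
        + config.baseline_amp * np.sin(2 * np.pi * config.baseline_hz * t + ph_base)
        + config.powerline_amp * np.sin(2 * np.pi * config.powerline_hz * t + ph_line)
        + config.white_sd * white
    )
    beat_times = onsets[(onsets >= 0) & (onsets < config.duration_s)]
    return PpgRecord(
        subject_id=profile.subject_id,
        condition=profile.condition,
        fs_hz=config.fs_hz,
        samples=noisy,
        meta=profile,
        clean=clean,
        beat_times=beat_times,
    )


def sample_kss_pvt(condition: str, rng: np.random.Generator) -> tuple[int, float]:
    """Draw a (KSS, PVT latency) pair from the reference-cohort distributions.

    KSS is categorical on the observed per-condition support with observed
    frequencies; PVT is a positive-truncated normal centred on the observed
    per-condition mean.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    support = KSS_SUPPORT[condition]
    kss = int(rng.choice(support.index.to_numpy(), p=support.to_numpy()))
    pvt = -1.0
    while pvt <= 0:
        pvt = float(rng.normal(PVT_MEAN[condition], PVT_SD[condition]))
    return kss, pvt


# Class-separation geometry: at separation knob = 1 the fatigue class sits
# ~0.035 s below non-fatigue in IBI standard deviation and ~0.22 below it in
# relative dicrotic amplitude.  The direction (fatigue = steadier rhythm,
# flatter dicrotic wave) is a simulator convention.
_NF_IBI_SD = 0.055
_NF_IBI_SD_JITTER = 0.008
_IBI_SD_GAP = 0.035
_NF_DICROTIC = 0.35
_NF_DICROTIC_JITTER = 0.04
_DICROTIC_GAP = 0.22


def simulate_cohort(
    n_subjects: int,
    config: SynthConfig,
    separation: float = 1.0,
    n_windows: int = 40,
) -> list[PpgRecord]:
    """Simulate a cohort: one fatigue and one non-fatigue record per subject.

    ``separation`` scales the class gap in IBI variability and dicrotic
    amplitude; 0 makes the classes generatively identical.
    """
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be >= 1, got {n_subjects}")
    if separation < 0:
        raise ValueError(f"separation must be nonnegative, got {separation}")
    rng = np.random.default_rng([config.seed, 0x5EED])
    records: list[PpgRecord] = []
    for i in range(n_subjects):
        sid = f"S{i + 1:02d}"
        mean_ibi = float(rng.normal(0.8, 0.05))
        nf_sd = max(float(rng.normal(_NF_IBI_SD, _NF_IBI_SD_JITTER)), 0.01)
        f_sd = max(nf_sd - _IBI_SD_GAP * separation + float(rng.normal(0, 0.003)), 0.004)
        nf_dic = float(np.clip(rng.normal(_NF_DICROTIC, _NF_DICROTIC_JITTER), 0.05, 0.9))
        f_dic = float(np.clip(nf_dic - _DICROTIC_GAP * separation + rng.normal(0, 0.02), 0.0, 0.9))
        for condition, ibi_sd, dic in (
            (FATIGUE, f_sd, f_dic),
            (NON_FATIGUE, nf_sd, nf_dic),
        ):
            kss, pvt = sample_kss_pvt(condition, rng)
            profile = SubjectProfile(
                subject_id=sid,
                condition=condition,
                kss=kss,
                pvt_ms=pvt,
                mean_ibi_s=mean_ibi,
                ibi_sd_s=ibi_sd,
                dicrotic_amp_rel=dic,
                n_windows=n_windows,
            )
            records.append(simulate_record(profile, config))
    return records


def write_cohort(records: list[PpgRecord], outdir: str | Path) -> Path:
    """Write one CSV per record plus a cohort manifest; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        fname = f"{rec.subject_id}_{rec.condition}.csv"
        pd.DataFrame(
            {"sample_index": np.arange(len(rec.samples)), "amplitude": rec.samples}
        ).to_csv(outdir / fname, index=False)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "condition": rec.condition,
                "kss": rec.meta.kss,
                "pvt_ms": rec.meta.pvt_ms,
                "fs_hz": rec.fs_hz,
                "path": fname,
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
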