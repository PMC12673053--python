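"""Synthetic annotated cough recordings.

Real ambulatory cough corpora are private, so the pipeline is exercised on
synthetic cohorts that reproduce the statistical structure the method
assumes: 8 kHz mono 16-bit recordings containing short (<= 500 ms) cough
events — an explosive broadband burst followed by a decaying phonation
tail — interleaved with distractor sounds (tones, formant sweeps, thuds)
over stationary background noise, with ground-truth annotations and
per-subject metadata (diagnostic category, sex, age, recording length).

Cough counts follow a Poisson law with mean ``rate * duration / 3600`` so a
cohort's per-category cough density (events per recorded hour) can be
configured to span the clinically observed range (~9 to ~450 per hour).
The acoustic model is deliberately minimal: it needs to be separable from
the distractors by a learnable margin, not clinically realistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .audio import (
    TARGET_SAMPLE_RATE,
    CoughAnnotation,
    Recording,
    save_annotation,
    save_recording,
)

#: The nine diagnostic categories of the ambulatory cohort.
DEFAULT_CATEGORIES = (
    "Asthma",
    "Bronchiectasis",
    "Chronic_cough",
    "Cystic_fibrosis",
    "COPD",
    "Healthy_volunteer",
    "ILD",
    "Lung_cancer",
    "Paediatrics",
)

#: Default per-category cough densities (events per recorded hour), matching
#: the published per-category recording statistics of the ambulatory cohort.
DEFAULT_CATEGORY_RATES = {
    "Asthma": 53.6,
    "Bronchiectasis": 453.7,
    "Chronic_cough": 371.3,
    "Cystic_fibrosis": 218.7,
    "COPD": 291.0,
    "Healthy_volunteer": 9.0,
    "ILD": 262.8,
    "Lung_cancer": 327.4,
    "Paediatrics": 443.0,
}

#: Default per-category male:female subject ratios (cohort demographics).
DEFAULT_CATEGORY_SEX_RATIOS = {
    "Asthma": (14, 32),
    "Bronchiectasis": (5, 2),
    "Chronic_cough": (20, 47),
    "Cystic_fibrosis": (1, 4),
    "COPD": (13, 11),
    "Healthy_volunteer": (9, 6),
    "ILD": (27, 12),
    "Lung_cancer": (9, 16),
    "Paediatrics": (2, 1),
}

MAX_COUGH_DURATION_S = 0.5


@dataclass
class SubjectProfile:
    """Generation parameters for one synthetic subject."""

    subject_id: str
    diagnostic_category: str
    sex: str  # "M" or "F"
    target_cough_rate: float  # events per recorded hour
    recording_duration: float  # seconds
    age: float | None = None
    categories: tuple[str, ...] = DEFAULT_CATEGORIES

    def __post_init__(self) -> None:
        if self.recording_duration <= 0:
            raise ValueError("recording_duration must be positive")
        if self.target_cough_rate < 0:
            raise ValueError("target_cough_rate must be non-negative")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.diagnostic_category not in self.categories:
            raise ValueError(
                f"unknown diagnostic_category {self.diagnostic_category!r}"
            )


@dataclass
class SyntheticEventSpec:
    """One placed event (cough or distractor) in a synthetic recording."""

    event_kind: str  # "cough" | "distractor"
    onset: float  # seconds
    duration: float  # seconds
    amplitude: float  # linear gain in (0, 1]

    def __post_init__(self) -> None:
        if self.event_kind == "cough" and self.duration > MAX_COUGH_DURATION_S:
            raise ValueError("cough duration must be <= 0.5 s")
        if not (0 < self.amplitude <= 1):
            raise ValueError("amplitude must be in (0, 1]")


def _cough_waveform(
    n: int, rng: np.random.Generator, f0: float, tilt: float
) -> np.ndarray:
    """Two-phase cough: broadband burst with sharp attack, then a damped
    harmonic phonation tail. ``f0``/``tilt`` carry subject-specific voice
    character so different subjects do not sound identical."""
    sr = TARGET_SAMPLE_RATE
    t = np.arange(n) / sr
    burst_len = int(rng.uniform(0.030, 0.100) * sr)
    burst_len = min(burst_len, n)
    burst = rng.standard_normal(burst_len)
    # spectral tilt: one-pole lowpass mix keeps the burst broadband but lets
    # subjects differ in brightness
    if burst_len > 1:
        smooth = np.convolve(burst, np.ones(3) / 3.0, mode="same")
        burst = (1 - tilt) * burst + tilt * smooth
    attack = np.minimum(np.arange(burst_len) / max(1, int(0.002 * sr)), 1.0)
    burst *= attack * np.exp(-np.arange(burst_len) / (0.35 * burst_len + 1))
    x = np.zeros(n)
    x[:burst_len] = burst / (np.max(np.abs(burst)) + 1e-12)
    tail_len = n - burst_len
    if tail_len > 8:
        tt = t[:tail_len]
        tail = np.zeros(tail_len)
        for h in (1, 2, 3):
            tail += (1.0 / h) * np.sin(
                2 * np.pi * f0 * h * tt + rng.uniform(0, 2 * np.pi)
            )
        tail *= np.exp(-tt / rng.uniform(0.05, 0.15))
        x[burst_len:] += 0.6 * tail / (np.max(np.abs(tail)) + 1e-12)
    return x


def _distractor_waveform(n: int, rng: np.random.Generator) -> np.ndarray:
    """Non-cough sounds: a pure tone, a speech-like formant sweep, or a
    low-frequency thud."""
    sr = TARGET_SAMPLE_RATE
    t = np.arange(n) / sr
    kind = rng.integers(0, 3)
    if kind == 0:  # tone
        f = rng.uniform(200, 3000)
        x = np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    elif kind == 1:  # formant-like sweep
        f_start = rng.uniform(300, 1000)
        f_end = rng.uniform(800, 2500)
        phase = 2 * np.pi * (f_start * t + (f_end - f_start) * t**2 / (2 * t[-1] + 1e-12))
        x = np.sin(phase) + 0.5 * np.sin(2 * phase)
    else:  # thud
        f = rng.uniform(40, 120)
        x = np.sin(2 * np.pi * f * t) * np.exp(-t / 0.04)
    env = np.minimum(np.arange(n) / max(1, int(0.01 * sr)), 1.0)
    env *= np.minimum((n - 1 - np.arange(n)) / max(1, int(0.01 * sr)), 1.0)
    x *= np.clip(env, 0, 1)
    return x / (np.max(np.abs(x)) + 1e-12)


def _place_events(
    rng: np.random.Generator,
    duration: float,
    durations: list[float],
    max_tries: int = 1000,
) -> list[float]:
    """Rejection-sample non-overlapping onsets (whole milliseconds).

    Raises if an event cannot be placed, rather than silently dropping it.
    """
    placed: list[tuple[float, float]] = []
    onsets: list[float] = []
    for d in durations:
        if d >= duration:
            raise ValueError(
                f"recording of {duration}s too short to place a {d}s event"
            )
        for _ in range(max_tries):
            onset = np.floor(rng.uniform(0, duration - d) * 1000) / 1000
            if all(onset + d <= a or onset >= b for a, b in placed):
                placed.append((onset, onset + d))
                onsets.append(onset)
                break
        else:
            raise ValueError(
                f"could not place a {d}s event without overlap in a "
                f"{duration}s recording after {max_tries} tries"
            )
    return onsets


def generate_subject(
    profile: SubjectProfile,
    seed: int,
    *,
    distractor_rate: float = 120.0,
    background_rms: float = 0.005,
) -> tuple[Recording, CoughAnnotation]:
    """Synthesise one annotated recording.

    Parameters
    ----------
    profile : SubjectProfile
        Subject metadata and generation targets.
    seed : int
        Same (profile, seed) pairs produce bit-identical output.
    distractor_rate : float
        Non-cough events per recorded hour (default 120: silence-removed
        ambulatory audio is dense in non-cough sounds).
    background_rms : float
        RMS of the stationary Gaussian background, full-scale linear units.

    Returns
    -------
    (Recording, CoughAnnotation)
        The annotation lists cough events only, in onset order.
    """
    rng = np.random.default_rng(seed)
    sr = TARGET_SAMPLE_RATE
    dur = profile.recording_duration
    n = int(round(dur * sr))

    n_cough = rng.poisson(profile.target_cough_rate * dur / 3600.0)
    n_distract = rng.poisson(distractor_rate * dur / 3600.0)

    # subject-specific voice character
    f0 = rng.uniform(140, 420)
    tilt = rng.uniform(0.0, 0.7)

    cough_durs = [
        np.floor(rng.uniform(0.250, MAX_COUGH_DURATION_S) * 1000) / 1000
        for _ in range(n_cough)
    ]
    distract_durs = [
        np.floor(rng.uniform(0.100, 0.500) * 1000) / 1000 for _ in range(n_distract)
    ]
    # coughs reserve the full 500 ms reference extent during placement so
    # the labelling reference windows never overlap another event
    placement_durs = [MAX_COUGH_DURATION_S] * n_cough + distract_durs
    onsets = _place_events(rng, dur, placement_durs)

    x = background_rms * rng.standard_normal(n)
    events: list[SyntheticEventSpec] = []
    for i, (onset, d) in enumerate(zip(onsets, cough_durs + distract_durs)):
        kind = "cough" if i < n_cough else "distractor"
        amp = rng.uniform(0.15, 0.7)
        i0 = int(round(onset * sr))
        m = int(round(d * sr))
        if kind == "cough":
            w = _cough_waveform(m, rng, f0, tilt)
        else:
            w = _distractor_waveform(m, rng)
        x[i0 : i0 + m] += amp * w
        events.append(SyntheticEventSpec(kind, onset, d, amp))

    samples = np.clip(np.round(x * 32767), -32768, 32767).astype(np.int16)
    recording = Recording(profile.subject_id, samples, sr)
    cough_events = sorted(
        (e.onset, round(e.onset + e.duration, 3))
        for e in events
        if e.event_kind == "cough"
    )
    annotation = CoughAnnotation(profile.subject_id, cough_events)
    return recording, annotation


def default_cohort_profiles(
    subjects_per_category: int = 3,
    recording_duration: float = 600.0,
    categories: tuple[str, ...] = DEFAULT_CATEGORIES,
    seed: int = 0,
) -> list[SubjectProfile]:
    """Build a cohort with the default per-category rates and sex ratios.

    Per-subject rates are jittered (lognormal, sigma 0.3) around the category
    rate so subjects within a category differ, as in real cohorts. Sexes are
    drawn to match the category's configured M:F proportion.
    """
    rng = np.random.default_rng(seed)
    profiles = []
    for cat in categories:
        rate = DEFAULT_CATEGORY_RATES.get(cat, 200.0)
        m, f = DEFAULT_CATEGORY_SEX_RATIOS.get(cat, (1, 1))
        p_male = m / (m + f)
        for i in range(subjects_per_category):
            jitter = float(np.exp(rng.normal(0.0, 0.3)))
            profiles.append(
                SubjectProfile(
                    subject_id=f"{cat[:4].upper()}{i:03d}",
                    diagnostic_category=cat,
                    sex="M" if rng.random() < p_male else "F",
                    age=float(np.round(rng.uniform(18, 85), 1)),
                    target_cough_rate=rate * jitter,
                    recording_duration=recording_duration,
                    categories=categories,
                )
            )
    return profiles


def generate_cohort(
    profiles: list[SubjectProfile],
    seed: int,
    out_dir: str | Path,
    **subject_kwargs,
) -> pd.DataFrame:
    """Generate and write a cohort dataset; return its manifest.

    Layout under ``out_dir``: ``audio/<subject_id>.wav``,
    ``annotations/<subject_id>.csv`` and a cohort-level ``metadata.csv``
    (subject_id, category, sex, age, duration_s) plus ``manifest.csv``.
    Per-subject seeds are spawned deterministically from ``seed``.
    """
    out_dir = Path(out_dir)
    ids = [p.subject_id for p in profiles]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate subject_id(s): {dupes}")

    rows = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(profiles))
    for profile, child in zip(profiles, children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        recording, annotation = generate_subject(profile, sub_seed, **subject_kwargs)
        wav_path = out_dir / "audio" / f"{profile.subject_id}.wav"
        ann_path = out_dir / "annotations" / f"{profile.subject_id}.csv"
        save_recording(recording, wav_path)
        save_annotation(annotation, ann_path)
        rows.append(
            {
                "subject_id": profile.subject_id,
                "category": profile.diagnostic_category,
                "sex": profile.sex,
                "age": profile.age,
                "duration_s": recording.duration,
                "n_coughs": len(annotation),
                "audio_path": str(wav_path),
                "annotation_path": str(ann_path),
                "seed": sub_seed,
            }
        )
    manifest = pd.DataFrame(
        rows,
        columns=[
            "subject_id", "category", "sex", "age", "duration_s",
            "n_coughs", "audio_path", "annotation_path", "seed",
        ],
    )
    if len(manifest):
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest[["subject_id", "category", "sex", "age", "duration_s"]].to_csv(
            out_dir / "metadata.csv", index=False
        )
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
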