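"""Audio and annotation I/O for ambulatory cough recordings.

The recording contract mirrors contact-microphone cough monitors: RIFF/PCM
WAV, 16-bit, mono, 8 kHz. Annotations are per-recording cough event
intervals in seconds, stored as CSV. Intervals are half-open
``[onset, offset)``; all overlap arithmetic downstream is done in integer
samples at 8 kHz so that threshold comparisons are exact.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal import resample_poly

logger = logging.getLogger(__name__)

#: Sampling rate (Hz) every pipeline stage assumes.
TARGET_SAMPLE_RATE = 8000


@dataclass
class Recording:
    """A mono 16-bit audio recording for one subject.

    Parameters
    ----------
    subject_id : str
        Opaque subject identifier.
    samples : ndarray of int16
        Mono PCM samples.
    sample_rate : int
        Sampling rate in Hz (8000 unless a resample was explicitly requested).
    """

    subject_id: str
    samples: np.ndarray
    sample_rate: int = TARGET_SAMPLE_RATE

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 1:
            raise ValueError(
                f"Recording must be mono; got shape {self.samples.shape}"
            )
        if self.samples.dtype != np.int16:
            raise ValueError(
                f"Recording samples must be int16 PCM; got {self.samples.dtype}"
            )

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return len(self.samples) / self.sample_rate

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def as_float(self) -> np.ndarray:
        """Samples scaled to [-1, 1) float64."""
        return self.samples.astype(np.float64) / 32768.0


@dataclass
class CoughAnnotation:
    """Ground-truth cough events of one recording as half-open intervals.

    ``events`` is an ordered list of ``(onset_s, offset_s)`` pairs, sorted by
    onset, pairwise non-overlapping, with ``0 <= onset < offset``. Abutting
    events (offset of one equal to onset of the next) are legal: intervals
    are half-open.
    """

    subject_id: str
    events: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for onset, offset in self.events:
            if not (0 <= onset < offset):
                raise ValueError(f"Invalid event interval ({onset}, {offset})")
        for (_, off_a), (on_b, _) in zip(self.events, self.events[1:]):
            if on_b < off_a:
                raise ValueError("Annotation events must be sorted and non-overlapping")

    def __len__(self) -> int:
        return len(self.events)

    @classmethod
    def from_raw_events(
        cls, subject_id: str, events: list[tuple[float, float]]
    ) -> "CoughAnnotation":
        """Build an annotation from possibly unsorted/overlapping raw events.

        Overlapping raw events are merged (interval union) with a logged
        warning, since the overlap-threshold labelling rule requires
        non-overlapping references. Abutting events are kept separate.
        """
        srt = sorted(events)
        merged: list[tuple[float, float]] = []
        n_merged = 0
        for onset, offset in srt:
            if merged and onset < merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], offset))
                n_merged += 1
            else:
                merged.append((onset, offset))
        if n_merged:
            warnings.warn(
                f"{subject_id}: merged {n_merged} overlapping annotation "
                "event(s) into interval unions",
                stacklevel=2,
            )
        return cls(subject_id=subject_id, events=merged)


def load_recording(
    path: str | Path,
    subject_id: str | None = None,
    *,
    channel: int | None = None,
    resample: bool = False,
) -> Recording:
    """Read a WAV file and validate the 8 kHz / 16-bit / mono contract.

    Parameters
    ----------
    path : path-like
        RIFF/PCM WAV file.
    subject_id : str, optional
        Defaults to the file stem.
    channel : int, optional
        For stereo files, which channel to keep (monitor devices record the
        contact microphone on one channel). Stereo input without an explicit
        channel is rejected.
    resample : bool
        If True, resample to 8 kHz instead of rejecting off-contract rates.
    """
    path = Path(path)
    rate, data = wavfile.read(str(path))
    if data.dtype != np.int16:
        raise ValueError(
            f"{path.name}: expected 16-bit PCM, got dtype {data.dtype}"
        )
    if data.ndim == 2:
        if channel is None:
            raise ValueError(
                f"{path.name}: stereo input; pass channel= to select one "
                "(contact-microphone channel)"
            )
        data = np.ascontiguousarray(data[:, channel])
    if rate != TARGET_SAMPLE_RATE:
        if not resample:
            raise ValueError(
                f"{path.name}: sample rate {rate} Hz violates the "
                f"{TARGET_SAMPLE_RATE} Hz recording contract; pass "
                "resample=True to convert explicitly"
            )
        g = np.gcd(TARGET_SAMPLE_RATE, rate)
        x = resample_poly(data.astype(np.float64), TARGET_SAMPLE_RATE // g, rate // g)
        data = np.clip(np.round(x), -32768, 32767).astype(np.int16)
        rate = TARGET_SAMPLE_RATE
    return Recording(
        subject_id=subject_id or path.stem, samples=data, sample_rate=rate
    )


def save_recording(recording: Recording, path: str | Path) -> Path:
    """Write a recording as mono 16-bit PCM WAV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    wavfile.write(str(path), recording.sample_rate, recording.samples)
    return path


def load_annotation(
    path: str | Path, recording: Recording | None = None
) -> CoughAnnotation:
    """Read a cough annotation CSV (columns subject_id, onset_s, offset_s).

    An empty event list is valid — healthy volunteers may cough zero times
    over a full recording. When ``recording`` is given, events past its end
    raise. Unsorted rows are sorted; overlapping rows are merged with a
    warning.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if len(df) == 0:
        subject_id = recording.subject_id if recording is not None else path.stem
        return CoughAnnotation(subject_id=subject_id, events=[])
    subject_ids = df["subject_id"].unique()
    if len(subject_ids) > 1:
        raise ValueError(f"{path.name}: multiple subject_ids in one annotation file")
    subject_id = str(subject_ids[0])
    events = [
        (float(r.onset_s), float(r.offset_s)) for r in df.itertuples(index=False)
    ]
    if recording is not None:
        for onset, offset in events:
            if offset > recording.duration + 1e-9:
                raise ValueError(
                    f"{path.name}: event offset {offset:.3f}s beyond recording "
                    f"end {recording.duration:.3f}s"
                )
    return CoughAnnotation.from_raw_events(subject_id, events)


def save_annotation(annotation: CoughAnnotation, path: str | Path) -> Path:
    """Write an annotation CSV (subject_id, onset_s, offset_s, ms precision)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "subject_id": annotation.subject_id,
            "onset_s": [round(on, 3) for on, _ in annotation.events],
            "offset_s": [round(off, 3) for _, off in annotation.events],
        }
    )
    df.to_csv(path, index=False)
    return path
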