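"""STFT spectrogram images for segment classification.

Each labelled segment is turned into a 224x224 RGB image through a fixed
pipeline: Hann-windowed non-centred STFT magnitude -> decibel scale ->
clip to [-80, 0] dB -> normalise to [0, 1] -> quantise to 8 bits -> jet
colormap -> bicubic resize -> PNG. Eighteen parameter combinations are
supported, the cross product of segment duration {500, 750, 1000} ms,
frame size {64, 128, 256} samples and hop {50%, 25%} of the frame, each
with DFT length matched to the frame (no zero-padding, radix-2 FFT).

Framing is non-centred and padding-free, so the image geometry is exactly
``width = floor((segment_samples - frame) / hop) + 1`` frames and
``height = frame/2 + 1`` bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from PIL import Image
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import get_window
from sklearn.base import BaseEstimator, TransformerMixin

from .audio import TARGET_SAMPLE_RATE
from .segmentation import Segment

logger = logging.getLogger(__name__)

DB_FLOOR = -80.0
DB_CEILING = 0.0
OUTPUT_SIZE = (224, 224)


@dataclass(frozen=True)
class SpectrogramConfig:
    """One STFT parameterisation, identified as "duration_frame_hop".

    Attributes
    ----------
    segment_ms : int
        Segment duration in milliseconds.
    frame_size : int
        STFT frame length in samples (power of two; DFT length equals it).
    hop_size : int
        Stride between frames in samples (frame/2 or frame/4).
    """

    segment_ms: int
    frame_size: int
    hop_size: int
    sample_rate: int = TARGET_SAMPLE_RATE

    def __post_init__(self) -> None:
        if self.frame_size < 2 or (self.frame_size & (self.frame_size - 1)) != 0:
            raise ValueError(
                f"frame_size must be a power of two (radix-2 FFT), got {self.frame_size}"
            )
        if self.hop_size <= 0:
            raise ValueError("hop_size must be positive")

    @classmethod
    def from_id(cls, config_id: str) -> "SpectrogramConfig":
        """Parse an id like ``"750_128_32"``."""
        parts = config_id.split("_")
        if len(parts) != 3:
            raise ValueError(f"config id must be 'duration_frame_hop', got {config_id!r}")
        return cls(int(parts[0]), int(parts[1]), int(parts[2]))

    @property
    def config_id(self) -> str:
        return f"{self.segment_ms}_{self.frame_size}_{self.hop_size}"

    @property
    def segment_samples(self) -> int:
        return self.segment_ms * self.sample_rate // 1000

    @property
    def n_bins(self) -> int:
        return self.frame_size // 2 + 1

    @property
    def n_frames(self) -> int:
        return (self.segment_samples - self.frame_size) // self.hop_size + 1

    @property
    def bin_spacing_hz(self) -> float:
        return self.sample_rate / self.frame_size

    @property
    def frame_resolution_ms(self) -> float:
        return 1000.0 * self.frame_size / self.sample_rate


def all_configs() -> list[SpectrogramConfig]:
    """The 18 evaluated configurations: {500,750,1000} ms x frame
    {64,128,256} x hop {frame/2, frame/4}."""
    out = []
    for dur in (500, 750, 1000):
        for frame in (64, 128, 256):
            for hop_frac in (2, 4):
                out.append(SpectrogramConfig(dur, frame, frame // hop_frac))
    return out


class Geometry(NamedTuple):
    width: int  # frames
    height: int  # bins
    bin_spacing_hz: float
    frame_resolution_ms: float


def derive_geometry(config: SpectrogramConfig) -> Geometry:
    """Image geometry implied by a configuration.

    Width is the frame count of a non-centred, non-padded STFT over one
    segment; height is the one-sided bin count ``frame/2 + 1``.
    """
    return Geometry(
        width=config.n_frames,
        height=config.n_bins,
        bin_spacing_hz=config.bin_spacing_hz,
        frame_resolution_ms=config.frame_resolution_ms,
    )


def compute_stft_magnitude(
    samples: np.ndarray, config: SpectrogramConfig
) -> np.ndarray:
    """Magnitude STFT of one segment, shape (n_bins, n_frames).

    Frames lie fully inside the segment (non-centred, no padding) and are
    tapered by a periodic Hann window of the frame length.
    """
    samples = np.asarray(samples, dtype=np.float64)
    if samples.ndim != 1 or len(samples) != config.segment_samples:
        raise ValueError(
            f"expected {config.segment_samples} samples for a "
            f"{config.segment_ms} ms segment, got shape {samples.shape}"
        )
    frames = sliding_window_view(samples, config.frame_size)[:: config.hop_size]
    window = get_window("hann", config.frame_size, fftbins=True)
    spec = np.fft.rfft(frames * window, n=config.frame_size, axis=1)
    return np.abs(spec).T  # (n_bins, n_frames)


def jet_lut() -> np.ndarray:
    """The canonical 256-entry piecewise-linear jet colormap, uint8 RGB.

    Defined in closed form (each channel a clipped tent function over the
    normalised intensity) so image output never drifts with plotting-library
    versions.
    """
    x = np.arange(256) / 255.0
    r = np.clip(np.minimum(4 * x - 1.5, -4 * x + 4.5), 0, 1)
    g = np.clip(np.minimum(4 * x - 0.5, -4 * x + 3.5), 0, 1)
    b = np.clip(np.minimum(4 * x + 0.5, -4 * x + 2.5), 0, 1)
    return np.round(np.stack([r, g, b], axis=1) * 255).astype(np.uint8)


_JET = jet_lut()


def magnitude_to_intensity(
    magnitude: np.ndarray,
    db_floor: float = DB_FLOOR,
    db_ceiling: float = DB_CEILING,
    reference: float | None = None,
    log_factor: float = 20.0,
) -> np.ndarray:
    """dB-scale, clip and quantise a magnitude matrix to uint8 intensities.

    ``reference`` defaults to the per-spectrogram maximum magnitude, which
    maps the strongest cell to 0 dB (the ceiling of the clip range).
    ``log_factor`` 20 treats the matrix as amplitude; pass 10 for power.
    An all-zero matrix maps to the uniform floor intensity (no NaNs).
    """
    mag = np.asarray(magnitude, dtype=np.float64)
    if not np.all(np.isfinite(mag)) or np.any(mag < 0):
        raise ValueError("magnitude matrix must be finite and non-negative")
    if reference is None:
        reference = float(mag.max())
    if reference <= 0:  # silent segment: uniform floor colour
        return np.zeros(mag.shape, dtype=np.uint8)
    with np.errstate(divide="ignore"):
        db = log_factor * np.log10(mag / reference)
    db = np.clip(db, db_floor, db_ceiling)
    unit = (db - db_floor) / (db_ceiling - db_floor)
    return np.round(unit * 255).astype(np.uint8)


def to_image(
    magnitude: np.ndarray,
    config: SpectrogramConfig | None = None,
    *,
    output_size: tuple[int, int] = OUTPUT_SIZE,
    log_factor: float = 20.0,
) -> np.ndarray:
    """Full image pipeline: dB -> clip -> normalise -> 8-bit -> jet -> resize.

    Rows are flipped so low frequencies sit at the bottom of the image, the
    usual spectrogram orientation. Returns uint8 RGB of ``output_size``.
    """
    intensity = magnitude_to_intensity(magnitude, log_factor=log_factor)
    rgb = _JET[intensity[::-1, :]]  # colormap then resize, in that order
    img = Image.fromarray(rgb, mode="RGB")
    img = img.resize(output_size, Image.Resampling.BICUBIC)
    return np.asarray(img)


def export_dataset(
    recording_samples: np.ndarray,
    segments: list[Segment],
    config: SpectrogramConfig,
    root: str | Path,
    category: str,
    *,
    force: bool = False,
) -> pd.DataFrame:
    """Write per-segment spectrogram PNGs in the five-level hierarchy.

    ``Spectrograms/<Diagnostic_Category>/<Subject_ID>/{positives|negatives}/
    <segment_index>.png``; the filename's segment index times the hop
    reconstructs the audio offset, so every image is back-traceable to its
    source audio for audit. Refuses to overwrite an existing subject tree
    unless ``force`` is set.
    """
    root = Path(root)
    if not segments:
        return pd.DataFrame(
            columns=["subject_id", "category", "segment_index", "label",
                     "start_s", "config_id", "path"]
        )
    subject_id = segments[0].subject_id
    subject_dir = root / "Spectrograms" / category / subject_id
    if subject_dir.exists() and not force:
        raise FileExistsError(
            f"{subject_dir} exists; pass force=True to re-export"
        )
    seen: set[int] = set()
    rows = []
    for seg in segments:
        if seg.label is None:
            raise ValueError("segments must be labelled before export")
        if seg.segment_index in seen:
            raise ValueError(f"duplicate segment_index {seg.segment_index}")
        seen.add(seg.segment_index)
        sub = "positives" if seg.label == "cough" else "negatives"
        out = subject_dir / sub / f"{seg.segment_index}.png"
        out.parent.mkdir(parents=True, exist_ok=True)
        audio = recording_samples[seg.start : seg.end] / 32768.0
        mag = compute_stft_magnitude(audio, config)
        Image.fromarray(to_image(mag, config), mode="RGB").save(out)
        rows.append(
            {
                "subject_id": subject_id,
                "category": category,
                "segment_index": seg.segment_index,
                "label": seg.label,
                "start_s": seg.start_s,
                "config_id": config.config_id,
                "path": str(out),
            }
        )
    return pd.DataFrame(rows)


class SpectrogramImager(BaseEstimator, TransformerMixin):
    """Transform raw segment audio into 224x224 RGB spectrogram images.

    Parameters
    ----------
    config_id : str
        One of the 18 parameterisations, e.g. ``"750_128_32"``.
    log_factor : float
        20 (amplitude dB, default) or 10 (power dB).
    """

    def __init__(self, config_id: str = "750_128_32", log_factor: float = 20.0):
        self.config_id = config_id
        self.log_factor = log_factor

    @property
    def config_(self) -> SpectrogramConfig:
        return SpectrogramConfig.from_id(self.config_id)

    def fit(self, X=None, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        """X: (n_segments, segment_samples) float audio -> (n, 224, 224, 3) uint8."""
        config = self.config_
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        out = np.empty((len(X), *OUTPUT_SIZE, 3), dtype=np.uint8)
        for i, seg in enumerate(X):
            mag = compute_stft_magnitude(seg, config)
            out[i] = to_image(mag, config, log_factor=self.log_factor)
        return out
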