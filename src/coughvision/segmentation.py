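"""Sliding-window segmentation and overlap-threshold labelling.

Recordings are cut into fixed-duration segments (500, 750 or 1000 ms) by a
sliding window with 50% overlap, so that most of any cough event appears
intact in at least one segment. Each annotated cough event defines a 500 ms
*reference window*; a segment is labelled ``cough`` iff its overlap with
some reference window meets the duration-specific threshold:

====================  =================
segment duration       overlap required
====================  =================
500 ms                 >= 250 ms (50%)
750 ms                 >= 375 ms (75%)
1000 ms                 = 500 ms (the whole reference window)
====================  =================

All overlap arithmetic is in integer samples at 8 kHz (thresholds
2000/3000/4000 samples), so equality cases are exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from sklearn.base import BaseEstimator

from .audio import TARGET_SAMPLE_RATE, CoughAnnotation, Recording

VALID_SEGMENT_MS = (500, 750, 1000)
OVERLAP_THRESHOLD_MS = {500: 250, 750: 375, 1000: 500}
REFERENCE_MS = 500


@dataclass(frozen=True)
class SegmentationConfig:
    """Window size, hop and labelling threshold for one segmentation run.

    ``hop_ms`` is fixed at 50% of the segment duration and the overlap
    threshold is fixed by the duration; both are derived, not free.
    """

    segment_ms: int
    reference_anchor: str = "onset"  # "onset" | "center"

    def __post_init__(self) -> None:
        if self.segment_ms not in VALID_SEGMENT_MS:
            raise ValueError(
                f"segment_ms must be one of {VALID_SEGMENT_MS}, got {self.segment_ms}"
            )
        if self.reference_anchor not in ("onset", "center"):
            raise ValueError("reference_anchor must be 'onset' or 'center'")

    @property
    def hop_ms(self) -> int:
        return self.segment_ms // 2

    @property
    def overlap_threshold_ms(self) -> int:
        return OVERLAP_THRESHOLD_MS[self.segment_ms]

    @property
    def segment_samples(self) -> int:
        return self.segment_ms * TARGET_SAMPLE_RATE // 1000

    @property
    def hop_samples(self) -> int:
        return self.hop_ms * TARGET_SAMPLE_RATE // 1000

    @property
    def overlap_threshold_samples(self) -> int:
        return self.overlap_threshold_ms * TARGET_SAMPLE_RATE // 1000

    @property
    def reference_samples(self) -> int:
        return REFERENCE_MS * TARGET_SAMPLE_RATE // 1000


@dataclass
class Segment:
    """One fixed-length window of a recording, with provenance."""

    subject_id: str
    segment_index: int
    start: int  # sample index
    length: int  # samples
    label: str | None = None  # "cough" | "non_cough" | None (unlabelled)
    source_event: int | None = None  # index of the reference that triggered

    @property
    def start_s(self) -> float:
        return self.start / TARGET_SAMPLE_RATE

    @property
    def end(self) -> int:
        return self.start + self.length


def make_reference_windows(
    annotation: CoughAnnotation,
    recording_samples: int,
    reference_ms: int = REFERENCE_MS,
    anchor: str = "onset",
) -> list[tuple[int, int]]:
    """One fixed 500 ms reference interval per annotated cough event.

    The reference is anchored at the event onset (default) or centred on the
    event midpoint, and clipped at the recording end with a warning. Events
    shorter than the reference duration still get a full-length reference:
    the labelling rule is defined on the reference window, not the raw event.
    Returned intervals are half-open ``[start, stop)`` in samples.
    """
    ref_len = reference_ms * TARGET_SAMPLE_RATE // 1000
    windows: list[tuple[int, int]] = []
    for onset_s, offset_s in annotation.events:
        if anchor == "onset":
            start = int(round(onset_s * TARGET_SAMPLE_RATE))
        elif anchor == "center":
            mid = (onset_s + offset_s) / 2
            start = int(round(mid * TARGET_SAMPLE_RATE)) - ref_len // 2
            start = max(start, 0)
        else:
            raise ValueError(f"unknown anchor {anchor!r}")
        stop = start + ref_len
        if stop > recording_samples:
            warnings.warn(
                f"{annotation.subject_id}: reference window at "
                f"{onset_s:.3f}s clipped at recording end",
                stacklevel=2,
            )
            stop = recording_samples
        windows.append((start, stop))
    return windows


def segment_recording(
    recording: Recording, config: SegmentationConfig
) -> list[Segment]:
    """Cut a recording into unlabelled sliding-window segments.

    Segment starts are 0, hop, 2*hop, ...; a trailing window that would run
    past the recording end is dropped (segments are fixed-length, never
    zero-padded), so the count is ``floor((L - seg) / hop) + 1`` for
    ``L >= seg`` and zero otherwise.
    """
    L = recording.n_samples
    seg = config.segment_samples
    hop = config.hop_samples
    if L < seg:
        warnings.warn(
            f"{recording.subject_id}: recording ({L} samples) shorter than "
            f"one {seg}-sample segment; no segments produced",
            stacklevel=2,
        )
        return []
    n = (L - seg) // hop + 1
    return [
        Segment(
            subject_id=recording.subject_id,
            segment_index=i,
            start=i * hop,
            length=seg,
        )
        for i in range(n)
    ]


def label_segments(
    segments: list[Segment],
    references: list[tuple[int, int]],
    config: SegmentationConfig,
) -> list[Segment]:
    """Assign cough / non_cough labels by the overlap-threshold rule.

    A segment is ``cough`` iff its maximum overlap over all reference
    windows meets the configured threshold; the triggering reference index
    is recorded in ``source_event``. References must be non-overlapping.
    """
    for (_, b0), (a1, _) in zip(references, references[1:]):
        if a1 < b0:
            raise ValueError("reference windows must be non-overlapping")
    thr = config.overlap_threshold_samples
    out = []
    for seg in segments:
        best, best_ref = 0, None
        for ref_idx, (a, b) in enumerate(references):
            ov = min(seg.end, b) - max(seg.start, a)
            if ov > best:
                best, best_ref = ov, ref_idx
        is_cough = best >= thr
        out.append(
            Segment(
                subject_id=seg.subject_id,
                segment_index=seg.segment_index,
                start=seg.start,
                length=seg.length,
                label="cough" if is_cough else "non_cough",
                source_event=best_ref if is_cough else None,
            )
        )
    return out


class SlidingWindowSegmenter(BaseEstimator):
    """Segment and label recordings; transform-shaped, stateless.

    Parameters
    ----------
    segment_ms : int
        Window duration, one of 500 / 750 / 1000 ms (hop is always 50%).
    reference_anchor : str
        Where the 500 ms reference window sits relative to an annotated
        event: at its onset (default) or centred on it.
    """

    def __init__(self, segment_ms: int = 750, reference_anchor: str = "onset"):
        self.segment_ms = segment_ms
        self.reference_anchor = reference_anchor

    @property
    def config_(self) -> SegmentationConfig:
        return SegmentationConfig(self.segment_ms, self.reference_anchor)

    def transform(
        self, recording: Recording, annotation: CoughAnnotation | None = None
    ) -> list[Segment]:
        """Segment one recording; label if an annotation is supplied."""
        config = self.config_
        segments = segment_recording(recording, config)
        if annotation is None:
            return segments
        refs = make_reference_windows(
            annotation, recording.n_samples, anchor=self.reference_anchor
        )
        return label_segments(segments, refs, config)
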