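"""Horizontal (time-wise) and vertical (channel-wise) EEG segmentation.

Subject identification consumes short multichannel windows: a K x L recording
is cut into r = floor(L / l_tilde) consecutive non-overlapping k_tilde x
l_tilde blocks (trailing remainder dropped).  Task classification instead
consumes whole single-channel sequences: the recording is split along the
channel axis into K segments of shape 1 x L, since cutting time would destroy
the task structure the classifier needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .eeg_io import EEGRecording

__all__ = [
    "SegmentationSpec",
    "SegmentBatch",
    "horizontal_split",
    "vertical_split",
    "select_channels",
]


@dataclass(frozen=True)
class SegmentationSpec:
    """How to cut a recording.

    mode : 'horizontal' or 'vertical'
    l_tilde : window length in samples (horizontal mode)
    k_tilde : number of channels retained (None = all)
    """

    mode: str = "horizontal"
    l_tilde: int | None = None
    k_tilde: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("horizontal", "vertical"):
            raise ValueError(f"mode must be horizontal|vertical, got {self.mode!r}")
        if self.mode == "horizontal":
            if self.l_tilde is None or self.l_tilde < 1:
                raise ValueError("horizontal mode needs l_tilde >= 1")
        if self.k_tilde is not None and self.k_tilde < 1:
            raise ValueError("k_tilde must be >= 1")


@dataclass
class SegmentBatch:
    """Labelled segments of identical shape.

    labels holds one (subject_id, task_id, class_id) triple per segment;
    provenance one (recording_index, time_offset) pair.
    """

    segments: list[np.ndarray]
    labels: list[tuple[int, int, int]]
    provenance: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.segments):
            raise ValueError("labels and segments length mismatch")
        shapes = {s.shape for s in self.segments}
        if len(shapes) > 1:
            raise ValueError(f"segments must share one shape, got {sorted(shapes)}")
        if not self.provenance:
            self.provenance = [(0, 0)] * len(self.segments)

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def subject_ids(self) -> np.ndarray:
        return np.array([s for s, _, _ in self.labels], dtype=int)

    @property
    def task_ids(self) -> np.ndarray:
        return np.array([t for _, t, _ in self.labels], dtype=int)

    @property
    def class_ids(self) -> np.ndarray:
        return np.array([c for _, _, c in self.labels], dtype=int)

    def as_array(self) -> np.ndarray:
        """Stack into one (n_segments, channels, samples) array."""
        return np.stack(self.segments)

    @staticmethod
    def concat(batches: list["SegmentBatch"]) -> "SegmentBatch":
        return SegmentBatch(
            segments=[s for b in batches for s in b.segments],
            labels=[l for b in batches for l in b.labels],
            provenance=[p for b in batches for p in b.provenance],
        )


def evenly_spaced_indices(K: int, k_tilde: int) -> np.ndarray:
    """k_tilde channel indices spread evenly over [0, K-1].

    First and last channels are always included for k_tilde >= 2; interior
    positions are rounded half-up, mirroring an even spatial subsampling of
    the montage.
    """
    if not 1 <= k_tilde <= K:
        raise ValueError(f"k_tilde must be in [1, {K}], got {k_tilde}")
    if k_tilde == 1:
        return np.array([0])
    pos = np.linspace(0, K - 1, k_tilde)
    idx = np.floor(pos + 0.5).astype(int)  # round half-up
    return np.unique(idx)


def select_channels(rec: EEGRecording, k_tilde: int) -> EEGRecording:
    """Retain k_tilde evenly spaced channels of a recording."""
    idx = evenly_spaced_indices(rec.n_channels, k_tilde)
    return EEGRecording(
        data=rec.data[idx],
        fs=rec.fs,
        subject_id=rec.subject_id,
        task_id=rec.task_id,
        channel_names=[rec.channel_names[i] for i in idx],
    )


def horizontal_split(
    rec: EEGRecording,
    spec: SegmentationSpec,
    class_id: int = 0,
    recording_index: int = 0,
) -> SegmentBatch:
    """Cut a recording into r = floor(L / l_tilde) consecutive windows.

    Remainder samples at the tail are dropped rather than padded.  Each window
    inherits the recording's subject and task labels.
    """
    if spec.mode != "horizontal":
        raise ValueError("horizontal_split needs a horizontal spec")
    l_tilde = int(spec.l_tilde)
    if l_tilde > rec.n_samples:
        raise ValueError(
            f"l_tilde={l_tilde} exceeds recording length {rec.n_samples}: empty batch"
        )
    src = rec if spec.k_tilde is None else select_channels(rec, spec.k_tilde)
    r = rec.n_samples // l_tilde
    segs = [src.data[:, i * l_tilde:(i + 1) * l_tilde].copy() for i in range(r)]
    label = (rec.subject_id, rec.task_id, class_id)
    return SegmentBatch(
        segments=segs,
        labels=[label] * r,
        provenance=[(recording_index, i * l_tilde) for i in range(r)],
    )


def vertical_split(
    rec: EEGRecording,
    class_id: int = 0,
    recording_index: int = 0,
) -> SegmentBatch:
    """Split a recording into K single-channel segments of shape 1 x L."""
    segs = [rec.data[k:k + 1].copy() for k in range(rec.n_channels)]
    label = (rec.subject_id, rec.task_id, class_id)
    return SegmentBatch(
        segments=segs,
        labels=[label] * rec.n_channels,
        provenance=[(recording_index, 0)] * rec.n_channels,
    )
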