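"""Labelled segment datasets.

A *segment* at time t is the run of 21 motion images from t-10 to t+10,
labelled with the frame label at t alone.  Segments are the unit the
classifier sees; consecutive segments overlap in 20 of their 21 images.

Motion images exist for t = 1 .. n_frames-1 (the first frame of a video
has no difference image), so with the default half-window of 10 the
admissible centre times of a video with images 1..M are 11 .. M-10.
Centre times whose window would leave the video are skipped, never padded.

Storage is bit-packed: a motion image is binary, so a 300x300 image takes
11.25 kB instead of 90 kB, and segments are unpacked on demand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

HALF_WINDOW = 10  # frames on each side of the centre; 21 images per segment
SEGMENT_LEN = 2 * HALF_WINDOW + 1

__all__ = [
    "HALF_WINDOW",
    "SEGMENT_LEN",
    "FrameLabelTrack",
    "Segment",
    "SegmentSet",
    "build_segment",
    "label_segment",
    "build_dataset",
    "load_label_csv",
]


# ---------------------------------------------------------------------------
# Frame labels
# ---------------------------------------------------------------------------


@dataclass
class FrameLabelTrack:
    """Per-frame binary behaviour labels for one video.

    ``scratch[i]`` is 1 when the animal scratches in frame i (0-based frame
    numbering matching the raw video).  An optional grooming track of the
    same length may accompany it; it is used only in evaluation.
    """

    scratch: np.ndarray
    grooming: np.ndarray | None = None
    video_id: str = ""

    def __post_init__(self) -> None:
        self.scratch = np.asarray(self.scratch, dtype=np.uint8)
        if not np.isin(self.scratch, (0, 1)).all():
            raise ValueError(f"frame labels must be binary (video {self.video_id!r})")
        if self.grooming is not None:
            self.grooming = np.asarray(self.grooming, dtype=np.uint8)
            if len(self.grooming) != len(self.scratch):
                raise ValueError(
                    f"grooming track length {len(self.grooming)} != "
                    f"scratch track length {len(self.scratch)} (video {self.video_id!r})"
                )

    def __len__(self) -> int:
        return len(self.scratch)


def load_label_csv(path: str | Path, video_id: str = "") -> FrameLabelTrack:
    """Read frame labels from CSV.

    Two dialects are accepted:

    * per-frame: header ``frame_index,scratch[,grooming]``, one row per
      frame, 0-based indices;
    * intervals: header ``start_frame,end_frame,behaviour`` with inclusive
      bounds; rows are expanded onto a dense track (behaviour is
      ``scratch`` or ``grooming``).
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"frame_index", "scratch"} <= cols:
        n = int(df["frame_index"].max()) + 1
        scratch = np.zeros(n, dtype=np.uint8)
        scratch[df["frame_index"].to_numpy()] = df["scratch"].to_numpy().astype(np.uint8)
        grooming = None
        if "grooming" in cols:
            grooming = np.zeros(n, dtype=np.uint8)
            grooming[df["frame_index"].to_numpy()] = (
                df["grooming"].to_numpy().astype(np.uint8)
            )
        return FrameLabelTrack(scratch, grooming, video_id or str(path))
    if {"start_frame", "end_frame", "behaviour"} <= cols:
        n = int(df["end_frame"].max()) + 1
        tracks = {"scratch": np.zeros(n, dtype=np.uint8)}
        for _, row in df.iterrows():
            b = str(row["behaviour"])
            if b not in tracks:
                tracks[b] = np.zeros(n, dtype=np.uint8)
            tracks[b][int(row["start_frame"]) : int(row["end_frame"]) + 1] = 1
        return FrameLabelTrack(
            tracks["scratch"], tracks.get("grooming"), video_id or str(path)
        )
    raise ValueError(
        f"{path}: unrecognised label CSV header {sorted(cols)}; expected "
        "frame_index,scratch[,grooming] or start_frame,end_frame,behaviour"
    )


# ---------------------------------------------------------------------------
# Segments
# ---------------------------------------------------------------------------


@dataclass
class Segment:
    """21 consecutive motion images centred at time t, plus one label."""

    images: np.ndarray  # (21, H, W) uint8 in {0, 1}
    t: int
    label: int

    def __post_init__(self) -> None:
        if self.images.shape[0] != SEGMENT_LEN:
            raise ValueError(
                f"segment needs {SEGMENT_LEN} images, got {self.images.shape[0]}"
            )


def build_segment(
    images: np.ndarray, t: int, half_window: int = HALF_WINDOW, t0: int = 1
) -> np.ndarray:
    """Collect the images from t-half_window to t+half_window.

    ``images[i]`` holds the motion image at time ``t0 + i`` (motion images
    of a full video start at t0 = 1).  Raises when the window leaves the
    available range.
    """
    lo = t - half_window - t0
    hi = t + half_window - t0 + 1
    if lo < 0 or hi > len(images):
        raise IndexError(
            f"segment window t={t}±{half_window} outside images "
            f"[{t0}, {t0 + len(images) - 1}]"
        )
    return images[lo:hi]


def label_segment(frame_labels: FrameLabelTrack | np.ndarray, t: int) -> int:
    """A segment's label is the frame label at its centre time, exactly."""
    labels = frame_labels.scratch if isinstance(frame_labels, FrameLabelTrack) else frame_labels
    if not (0 <= t < len(labels)):
        raise IndexError(f"t={t} outside label track of length {len(labels)}")
    return int(labels[t])


# ---------------------------------------------------------------------------
# SegmentSet
# ---------------------------------------------------------------------------


@dataclass
class _VideoEntry:
    video_id: str
    packed: np.ndarray  # bit-packed motion images
    shape: tuple[int, int, int]  # (n_images, H, W)
    labels: FrameLabelTrack
    centre_times: np.ndarray  # admissible t values (ascending)

    def image_block(self, lo_t: int, hi_t: int) -> np.ndarray:
        """Unpack motion images for times lo_t..hi_t inclusive (t0 = 1)."""
        n, h, w = self.shape
        per = h * w
        lo, hi = lo_t - 1, hi_t  # image i holds time i+1
        if lo < 0 or hi > n:
            raise IndexError(f"times {lo_t}..{hi_t} outside 1..{n}")
        # packbits flattened the whole stack; slice on byte boundaries only
        # when per is a multiple of 8, otherwise unpack with an offset
        start_bit = lo * per
        stop_bit = hi * per
        first_byte = start_bit // 8
        bits = np.unpackbits(
            self.packed[first_byte : (stop_bit + 7) // 8],
            count=stop_bit - first_byte * 8,
        )
        return bits[start_bit - first_byte * 8 :].reshape(hi - lo, h, w)


class SegmentSet:
    """All admissible segments of a collection of videos.

    Segments are indexed globally; ``index`` maps a global id to
    ``(video_idx, t)``.  The scratch index lists the ids of positive
    segments for imbalance-aware sampling.
    """

    def __init__(self, videos: list[_VideoEntry], half_window: int = HALF_WINDOW):
        self.videos = videos
        self.half_window = half_window
        index = []
        labels = []
        for vi, v in enumerate(videos):
            index.extend((vi, int(t)) for t in v.centre_times)
            labels.extend(int(v.labels.scratch[t]) for t in v.centre_times)
        self.index: list[tuple[int, int]] = index
        self.labels = np.asarray(labels, dtype=np.uint8)
        self.scratch_ids = np.nonzero(self.labels == 1)[0]

    def __len__(self) -> int:
        return len(self.index)

    @property
    def n_scratch(self) -> int:
        return int(self.labels.sum())

    @property
    def class_counts(self) -> dict[int, int]:
        n1 = self.n_scratch
        return {0: len(self) - n1, 1: n1}

    def image_shape(self) -> tuple[int, int]:
        return self.videos[0].shape[1:]

    def segment_images(self, seg_id: int) -> np.ndarray:
        vi, t = self.index[seg_id]
        v = self.videos[vi]
        return v.image_block(t - self.half_window, t + self.half_window)

    def get_segment(self, seg_id: int) -> Segment:
        vi, t = self.index[seg_id]
        return Segment(self.segment_images(seg_id), t, int(self.labels[seg_id]))

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Persist as an array archive plus a JSON manifest."""
        path = Path(path)
        arrays: dict[str, np.ndarray] = {}
        manifest = {"half_window": self.half_window, "videos": []}
        for vi, v in enumerate(self.videos):
            arrays[f"packed_{vi}"] = v.packed
            arrays[f"scratch_{vi}"] = v.labels.scratch
            if v.labels.grooming is not None:
                arrays[f"grooming_{vi}"] = v.labels.grooming
            manifest["videos"].append(
                {
                    "video_id": v.video_id,
                    "shape": list(v.shape),
                    "centre_times": [int(v.centre_times[0]), int(v.centre_times[-1])]
                    if len(v.centre_times)
                    else [],
                }
            )
        np.savez_compressed(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SegmentSet":
        path = Path(path)
        manifest = json.loads(path.with_suffix(".json").read_text())
        videos = []
        with np.load(path.with_suffix(".npz")) as z:
            for vi, m in enumerate(manifest["videos"]):
                shape = tuple(m["shape"])
                labels = FrameLabelTrack(
                    z[f"scratch_{vi}"],
                    z[f"grooming_{vi}"] if f"grooming_{vi}" in z.files else None,
                    m["video_id"],
                )
                ct = m["centre_times"]
                centre_times = (
                    np.arange(ct[0], ct[1] + 1) if ct else np.empty(0, dtype=int)
                )
                videos.append(
                    _VideoEntry(m["video_id"], z[f"packed_{vi}"], shape, labels, centre_times)
                )
        return cls(videos, manifest["half_window"])


def build_dataset(
    videos: list[tuple[np.ndarray, FrameLabelTrack]],
    half_window: int = HALF_WINDOW,
) -> SegmentSet:
    """Assemble a SegmentSet from (motion images, frame labels) per video.

    Each video contributes one segment per admissible centre time
    t = 1 + half_window .. n_images - half_window.  A video whose label
    track does not cover its frames (n_images must be n_frames - 1) raises
    an error naming the video.
    """
    entries = []
    for motion, labels in videos:
        motion = np.asarray(motion)
        if motion.ndim != 3:
            raise ValueError(f"video {labels.video_id!r}: motion images must be 3-D")
        n_images = motion.shape[0]
        if len(labels) != n_images + 1:
            raise ValueError(
                f"video {labels.video_id!r}: {n_images} motion images need "
                f"{n_images + 1} frame labels, got {len(labels)}"
            )
        lo = 1 + half_window
        hi = n_images - half_window  # last admissible centre time
        centre_times = np.arange(lo, hi + 1) if hi >= lo else np.empty(0, dtype=int)
        entries.append(
            _VideoEntry(
                labels.video_id,
                np.packbits(motion.astype(bool), axis=None),
                tuple(motion.shape),
                labels,
                centre_times,
            )
        )
    return SegmentSet(entries, half_window)
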