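"""Synthetic labelled arena videos.

Real recordings of this kind are a bright mouse on a dark arena filmed from
above at 60 Hz.  The generator emulates the statistical structure the
detector relies on, not the animal's appearance: a bright ellipse (the
body) alternates between rest, locomotion, grooming and scratching
episodes; grooming and scratching are rendered as a small appendage
ellipse that rhythmically extends beyond the body outline and retracts
under it, slowly (default 3 Hz) near the front for grooming and fast
(default 12 Hz) at the rear flank for scratching — matching the rapid,
repetitive back-and-forth hindlimb motion that defines a scratch bout.
While the appendage is retracted it is invisible (same intensity as the
body), so the per-frame motion energy oscillates at the configured
behaviour frequency.

Behaviour episodes follow a semi-Markov script: exponentially distributed
dwell times (truncated to >= 5 frames) and self-transition-free switching
weights.  Every frame carries ground-truth scratch and grooming labels,
which downstream modules treat exactly like human annotation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator

import numpy as np

from .dataset import FrameLabelTrack

__all__ = [
    "SynthConfig",
    "BehaviourScript",
    "script_behaviours",
    "render_frames",
    "iter_rendered_frames",
    "generate_dataset",
]

BEHAVIOURS = ("rest", "locomote", "groom", "scratch")

MIN_DWELL_FRAMES = 5


@dataclass(frozen=True)
class SynthConfig:
    """Arena, blob and behaviour-statistics parameters.

    Dwell means are seconds; the default mix yields roughly 2-3% scratch
    frames, mirroring the strong class imbalance of real recordings where
    scratching is rare among resting, locomotion and grooming.
    """

    frame_px: tuple[int, int] = (480, 480)  # (width, height)
    fps: int = 60
    n_frames: int = 1800
    blob_axes: tuple[float, float] = (55.0, 38.0)  # ellipse semi-axes, px
    blob_intensity: int = 200
    background: int = 20
    appendage_radius: float = 12.0
    dwell_mean_s: dict = field(
        default_factory=lambda: {
            "rest": 1.2,
            "locomote": 1.0,
            "groom": 0.9,
            "scratch": 0.55,
        }
    )
    transition_weights: dict = field(
        default_factory=lambda: {
            "rest": {"locomote": 3.0, "groom": 1.5, "scratch": 0.22},
            "locomote": {"rest": 3.0, "groom": 1.5, "scratch": 0.22},
            "groom": {"rest": 2.0, "locomote": 2.0, "scratch": 0.18},
            "scratch": {"rest": 2.0, "locomote": 1.0, "groom": 1.0},
        }
    )
    scratch_freq_hz: float = 12.0
    scratch_amp_px: float = 26.0
    groom_freq_hz: float = 3.0
    groom_amp_px: float = 18.0
    locomote_speed_px: float = 3.0  # RMS per-frame step of the random walk
    noise_std: float = 3.0
    invert_contrast: bool = False  # dark mouse on light floor (qualitative)
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.scratch_freq_hz < self.fps / 2):
            raise ValueError(
                f"scratch_freq_hz={self.scratch_freq_hz} must lie in (0, fps/2)"
            )
        if not (0 < self.groom_freq_hz < self.fps / 2):
            raise ValueError(f"groom_freq_hz={self.groom_freq_hz} must lie in (0, fps/2)")
        if any(v <= 0 for v in self.dwell_mean_s.values()):
            raise ValueError("dwell means must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


@dataclass
class BehaviourScript:
    """Contiguous behaviour intervals tiling [0, n_frames)."""

    intervals: list[tuple[str, int, int]]  # (behaviour, start, end) inclusive
    n_frames: int

    def labels(self, behaviour: str) -> np.ndarray:
        lab = np.zeros(self.n_frames, dtype=np.uint8)
        for b, s, e in self.intervals:
            if b == behaviour:
                lab[s : e + 1] = 1
        return lab


def script_behaviours(cfg: SynthConfig, rng: np.random.Generator) -> BehaviourScript:
    """Sample a semi-Markov behaviour script.

    Dwell ~ Exp(mean = dwell_mean_s * fps), truncated to >= 5 frames; the
    next behaviour is drawn from the transition weights of the current one
    (never a self-transition).  Behaviours with zero total outgoing weight
    from every other state simply never occur.
    """
    cfg.validate()
    intervals: list[tuple[str, int, int]] = []
    # start state drawn by stationary-ish heuristic: weight of being entered
    entry_w = {
        b: sum(w.get(b, 0.0) for w in cfg.transition_weights.values()) for b in BEHAVIOURS
    }
    tot = sum(entry_w.values())
    if tot <= 0:
        state = "rest"
    else:
        p = np.array([entry_w[b] / tot for b in BEHAVIOURS])
        state = BEHAVIOURS[rng.choice(len(BEHAVIOURS), p=p)]
    t = 0
    while t < cfg.n_frames:
        mean_frames = cfg.dwell_mean_s[state] * cfg.fps
        dwell = max(MIN_DWELL_FRAMES, int(np.ceil(rng.exponential(mean_frames))))
        end = min(t + dwell - 1, cfg.n_frames - 1)
        intervals.append((state, t, end))
        t = end + 1
        weights = cfg.transition_weights.get(state, {})
        names = [b for b in BEHAVIOURS if b != state and weights.get(b, 0.0) > 0]
        if not names:
            names = [b for b in BEHAVIOURS if b != state]
            w = np.ones(len(names))
        else:
            w = np.array([weights[b] for b in names])
        state = names[rng.choice(len(names), p=w / w.sum())]
    return BehaviourScript(intervals, cfg.n_frames)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _ellipse_mask(w: int, h: int, cx: float, cy: float, ax: float, ay: float) -> np.ndarray:
    """Boolean mask of an axis-aligned filled ellipse, evaluated locally."""
    x0, x1 = max(0, int(cx - ax - 1)), min(w, int(cx + ax + 2))
    y0, y1 = max(0, int(cy - ay - 1)), min(h, int(cy + ay + 2))
    mask = np.zeros((h, w), dtype=bool)
    if x1 <= x0 or y1 <= y0:
        return mask
    ys = np.arange(y0, y1)[:, None]
    xs = np.arange(x0, x1)[None, :]
    mask[y0:y1, x0:x1] = ((xs - cx) / ax) ** 2 + ((ys - cy) / ay) ** 2 <= 1.0
    return mask


def _reflect(pos: float, vel: float, lo: float, hi: float) -> tuple[float, float]:
    if pos < lo:
        return 2 * lo - pos, -vel
    if pos > hi:
        return 2 * hi - pos, -vel
    return pos, vel


def iter_rendered_frames(
    script: BehaviourScript, cfg: SynthConfig, rng: np.random.Generator
) -> Iterator[np.ndarray]:
    """Yield uint8 frames one at a time (streaming; nothing is retained)."""
    cfg.validate()
    w, h = cfg.frame_px
    ax, ay = cfg.blob_axes
    margin = max(ax, ay) + cfg.appendage_radius + 4
    cx, cy = w / 2.0, h / 2.0
    vx = vy = 0.0
    heading = rng.uniform(0, 2 * np.pi)  # body orientation for appendage anchors
    behaviour_of_frame: list[str] = [None] * script.n_frames
    for b, s, e in script.intervals:
        for i in range(s, e + 1):
            behaviour_of_frame[i] = b
    phase = 0.0
    prev_b = None
    for t in range(script.n_frames):
        b = behaviour_of_frame[t]
        if b != prev_b:
            phase = 0.0
            if b in ("groom", "scratch"):
                heading = rng.uniform(0, 2 * np.pi)
            prev_b = b
        if b == "locomote":
            s = cfg.locomote_speed_px
            vx = 0.8 * vx + rng.normal(0, 0.6 * s)
            vy = 0.8 * vy + rng.normal(0, 0.6 * s)
            cx, vx = _reflect(cx + vx, vx, margin, w - margin)
            cy, vy = _reflect(cy + vy, vy, margin, h - margin)
            heading = np.arctan2(vy, vx)
        frame = np.full((h, w), cfg.background, dtype=np.float32)
        body = _ellipse_mask(w, h, cx, cy, ax, ay)
        frame[body] = cfg.blob_intensity
        if b in ("groom", "scratch"):
            if b == "scratch":
                freq, amp = cfg.scratch_freq_hz, cfg.scratch_amp_px
                anchor = heading + np.pi  # rear flank
            else:
                freq, amp = cfg.groom_freq_hz, cfg.groom_amp_px
                anchor = heading  # front
            phase += 2 * np.pi * freq / cfg.fps
            # extension in [0, amp]: retracted under the body half the cycle
            ext = amp * np.sin(phase)
            if ext > 0:
                r_body = ax * ay / np.hypot(ay * np.cos(anchor), ax * np.sin(anchor))
                dist = r_body - cfg.appendage_radius + ext
                px = cx + dist * np.cos(anchor)
                py = cy + dist * np.sin(anchor)
                app = _ellipse_mask(w, h, px, py, cfg.appendage_radius, cfg.appendage_radius)
                frame[app] = cfg.blob_intensity
        if cfg.noise_std > 0:
            frame += rng.normal(0, cfg.noise_std, frame.shape).astype(np.float32)
        if cfg.invert_contrast:
            frame = 255.0 - frame
        yield np.clip(np.rint(frame), 0, 255).astype(np.uint8)


def render_frames(
    script: BehaviourScript, cfg: SynthConfig, rng: np.random.Generator
) -> tuple[np.ndarray, FrameLabelTrack]:
    """Materialize all frames plus the ground-truth label tracks."""
    frames = np.stack(list(iter_rendered_frames(script, cfg, rng)))
    labels = FrameLabelTrack(
        script.labels("scratch"), script.labels("groom"), video_id="synthetic"
    )
    return frames, labels


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


def generate_dataset(
    cfg: SynthConfig, n_videos: int, seed: int | None = None
) -> tuple[list[tuple[BehaviourScript, "np.random.Generator"]], dict]:
    """Seeded per-video scripts + render streams, with a manifest.

    Returns ``(videos, manifest)`` where ``videos`` is a list of
    ``(script, frame_rng)`` pairs — pass each to :func:`iter_rendered_frames`
    to stream that video's frames — and the manifest records every script,
    so the exact ground-truth labels are recoverable without the pixels.
    """
    if n_videos < 1:
        raise ValueError("n_videos must be >= 1")
    master = np.random.SeedSequence(cfg.seed if seed is None else seed)
    children = master.spawn(n_videos)
    videos = []
    manifest = {"config": _config_dict(cfg), "videos": []}
    for vi, child in enumerate(children):
        script_rng = np.random.default_rng(child.spawn(1)[0])
        frame_rng = np.random.default_rng(child.spawn(1)[0])
        script = script_behaviours(cfg, script_rng)
        videos.append((script, frame_rng))
        manifest["videos"].append(
            {
                "video_id": f"synth_{vi:02d}",
                "intervals": [[b, int(s), int(e)] for b, s, e in script.intervals],
            }
        )
    return videos, manifest


def _config_dict(cfg: SynthConfig) -> dict:
    d = asdict(cfg)
    d["frame_px"] = list(d["frame_px"])
    d["blob_axes"] = list(d["blob_axes"])
    return d


def write_dataset(
    cfg: SynthConfig, n_videos: int, out_dir: str | Path, seed: int | None = None
) -> dict:
    """Write PNG frame directories, label CSVs, and a manifest JSON."""
    import imageio.v3 as iio
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    videos, manifest = generate_dataset(cfg, n_videos, seed)
    for (script, frame_rng), meta in zip(videos, manifest["videos"]):
        vid = meta["video_id"]
        frame_dir = out_dir / vid
        frame_dir.mkdir(exist_ok=True)
        for i, frame in enumerate(iter_rendered_frames(script, cfg, frame_rng)):
            iio.imwrite(frame_dir / f"frame_{i:06d}.png", frame)
        pd.DataFrame(
            {
                "frame_index": np.arange(script.n_frames),
                "scratch": script.labels("scratch"),
                "grooming": script.labels("groom"),
            }
        ).to_csv(out_dir / f"{vid}.labels.csv", index=False)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
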