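"""Imbalance-aware training and prediction.

Scratching is rare (a few percent of frames), so each training *epoch* is
an upsampled draw rather than a pass over the data: 1500 segments sampled
with replacement from all segments plus 100 from the scratch segments,
shuffled, augmented, and fed to the network in minibatches.  Augmentation
draws one geometric transform per segment — horizontal flip, vertical
flip, and a uniform rotation — and applies it identically to all 21
images at the network input size (200x200 by default; each video's
motion images are anti-alias downscaled once and cached).  Optimisation
is Adam at 1e-4 on binary cross-entropy, 1000 epochs, no early stopping.

Prediction shares the convolutional encoder across overlapping segments:
each motion image of a video is encoded once, and the 21-frame windows
slide over the per-frame features before the recurrent block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .crnn import CRNN, WeightState, bce_loss
from .dataset import Segment, SegmentSet

__all__ = [
    "TrainConfig",
    "TransformParams",
    "sample_epoch",
    "draw_transform",
    "apply_transform",
    "augment_segment",
    "train",
    "predict_video",
    "predict_segments",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters; defaults are the full-scale protocol."""

    n_random: int = 1500  # segments drawn from all segments per epoch
    n_scratch: int = 100  # extra draws from the scratch segments per epoch
    epochs: int = 1000
    learning_rate: float = 1e-4
    resize_px: int = 200
    minibatch: int = 32
    seed: int = 0
    flip_horizontal: bool = True
    flip_vertical: bool = True
    rotate: bool = True

    def validate(self) -> None:
        if self.n_random + self.n_scratch <= 0:
            raise ValueError("n_random + n_scratch must be positive")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate={self.learning_rate} must be > 0")
        if self.minibatch < 1:
            raise ValueError("minibatch must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


# ---------------------------------------------------------------------------
# Epoch sampling
# ---------------------------------------------------------------------------


def sample_epoch(
    segset: SegmentSet, cfg: TrainConfig, rng: np.random.Generator
) -> np.ndarray:
    """Draw one epoch's segment ids: n_random from all + n_scratch from
    the scratch index, both with replacement, shuffled together."""
    if len(segset) == 0:
        raise ValueError("cannot sample from an empty segment set")
    ids = rng.integers(0, len(segset), size=cfg.n_random)
    if cfg.n_scratch > 0:
        if len(segset.scratch_ids) == 0:
            raise ValueError(
                "n_scratch > 0 but the segment set contains no scratch segments"
            )
        extra = segset.scratch_ids[
            rng.integers(0, len(segset.scratch_ids), size=cfg.n_scratch)
        ]
        ids = np.concatenate([ids, extra])
    rng.shuffle(ids)
    return ids


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransformParams:
    flip_horizontal: bool = False
    flip_vertical: bool = False
    angle_deg: float = 0.0

    @property
    def is_identity(self) -> bool:
        return not (self.flip_horizontal or self.flip_vertical or self.angle_deg)


def draw_transform(rng: np.random.Generator, cfg: TrainConfig) -> TransformParams:
    """One transform per segment: each flip with p = 1/2, angle ~ U[0, 360)."""
    return TransformParams(
        flip_horizontal=bool(cfg.flip_horizontal and rng.random() < 0.5),
        flip_vertical=bool(cfg.flip_vertical and rng.random() < 0.5),
        angle_deg=float(rng.uniform(0.0, 360.0)) if cfg.rotate else 0.0,
    )


def _affine_matrix(params: TransformParams, in_px: int, out_px: int) -> np.ndarray:
    """Map output (row, col) to input coordinates: scale∘rotate∘flip about
    the image centre, as a 3x3 homogeneous matrix."""
    c_in = (in_px - 1) / 2.0
    c_out = (out_px - 1) / 2.0
    scale = in_px / out_px
    th = np.deg2rad(params.angle_deg)
    # inverse rotation (output->input), row = y, col = x
    rot = np.array(
        [[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]
    )
    flip = np.diag(
        [-1.0 if params.flip_vertical else 1.0, -1.0 if params.flip_horizontal else 1.0]
    )
    lin = flip @ rot * scale
    offset = np.array([c_in, c_in]) - lin @ np.array([c_out, c_out])
    m = np.eye(3)
    m[:2, :2] = lin
    m[:2, 2] = offset
    return m


def apply_transform(
    images: np.ndarray, params: TransformParams, out_px: int
) -> np.ndarray:
    """Resample (k, H, W) images through one affine map to (k, out_px, out_px).

    Flip, rotation about the centre and the resize are composed into a
    single bilinear resampling (zero fill outside the source), so binary
    inputs come out as interpolated grey values in [0, 1] and are not
    re-binarized.  Downscaling first applies a matching local average
    (anti-aliasing), preserving the energy of thin motion traces.
    """
    images = np.asarray(images)
    in_px = images.shape[1]
    m = _affine_matrix(params, in_px, out_px)
    scale = in_px / out_px
    # anti-alias before downscaling: without a local average, bilinear
    # sampling drops most of a sparse binary motion trace
    smooth = int(round(scale)) if scale > 1.2 else 0
    out = np.empty((images.shape[0], out_px, out_px), dtype=np.float32)
    for i, img in enumerate(images):
        src = img.astype(np.float32)
        if smooth:
            src = ndimage.uniform_filter(src, size=smooth)
        ndimage.affine_transform(
            src,
            m[:2, :2],
            offset=m[:2, 2],
            output_shape=(out_px, out_px),
            output=out[i],
            order=1,
            mode="constant",
            cval=0.0,
        )
    return out


def augment_segment(
    seg: Segment, cfg: TrainConfig, rng: np.random.Generator
) -> tuple[np.ndarray, TransformParams]:
    """Augment one segment: a single drawn transform applied identically to
    all 21 images, then resized; the label is untouched."""
    params = draw_transform(rng, cfg)
    return apply_transform(seg.images, params, cfg.resize_px), params


def downscale_stack(images: np.ndarray, out_px: int) -> np.ndarray:
    """Anti-aliased resize of an (N, H, W) image stack to network resolution.

    Identical to :func:`apply_transform` with the identity transform; used
    to cache a video's motion images once so that per-draw augmentation
    only has to flip/rotate at the (much smaller) network resolution.
    """
    return apply_transform(images, _IDENTITY, out_px)


# ---------------------------------------------------------------------------
# Optimiser
# ---------------------------------------------------------------------------


class Adam:
    """Adaptive-moment estimation with the conventional defaults."""

    def __init__(self, params, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        for p in self.params:
            p.m = np.zeros_like(p.value)
            p.v = np.zeros_like(p.value)

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p in self.params:
            g = p.grad
            p.m *= b1
            p.m += (1 - b1) * g
            p.v *= b2
            p.v += (1 - b2) * np.square(g)
            p.value -= (
                self.lr * (p.m / bias1) / (np.sqrt(p.v / bias2) + self.eps)
            ).astype(p.value.dtype)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------


def train(
    model: CRNN, segset: SegmentSet, cfg: TrainConfig
) -> tuple[WeightState, pd.DataFrame]:
    """Train in upsampled epochs; returns final weights and the loss history.

    The history has one row per epoch: ``epoch``, ``mean_loss`` (mean
    binary cross-entropy over the epoch's 1600 segments) and
    ``scratch_fraction`` of the sampled batch.  One master seed fans out to
    independent sampler, augmentation and dropout streams, so runs are
    bit-reproducible on a fixed backend.  Non-finite loss aborts.
    """
    cfg.validate()
    if model.spec.input_px != cfg.resize_px:
        raise ValueError(
            f"model input {model.spec.input_px}px != cfg.resize_px {cfg.resize_px}"
        )
    ss = np.random.SeedSequence(cfg.seed)
    s_sample, s_augment, s_dropout = ss.spawn(3)
    rng_sample = np.random.default_rng(s_sample)
    rng_augment = np.random.default_rng(s_augment)
    model.set_dropout_rng(np.random.default_rng(s_dropout))
    opt = Adam(model.params(), cfg.learning_rate)
    history = []
    hw = segset.half_window

    # each video's motion images are downscaled (anti-aliased) once; the
    # per-draw transform then only flips/rotates at network resolution
    cache: dict[int, np.ndarray] = {}

    def video_images(vi: int) -> np.ndarray:
        arr = cache.get(vi)
        if arr is None:
            v = segset.videos[vi]
            arr = cache[vi] = downscale_stack(
                v.image_block(1, v.shape[0]), cfg.resize_px
            )
        return arr

    for epoch in range(cfg.epochs):
        ids = sample_epoch(segset, cfg, rng_sample)
        labels = segset.labels[ids].astype(np.float32)
        loss_sum = 0.0
        for s in range(0, len(ids), cfg.minibatch):
            batch_ids = ids[s : s + cfg.minibatch]
            x = np.empty(
                (len(batch_ids), model.spec.seq_len, cfg.resize_px, cfg.resize_px),
                dtype=np.float32,
            )
            for bi, sid in enumerate(batch_ids):
                params = draw_transform(rng_augment, cfg)
                vi, t = segset.index[sid]
                imgs = video_images(vi)[t - hw - 1 : t + hw]  # times t-hw .. t+hw
                x[bi] = apply_transform(imgs, params, cfg.resize_px)
            y = labels[s : s + cfg.minibatch]
            probs = model.forward(x, train=True)
            loss_sum += bce_loss(probs, y) * len(batch_ids)
            model.zero_grad()
            model.backward_bce(probs, y)
            opt.step()
        mean_loss = loss_sum / len(ids)
        if not np.isfinite(mean_loss):
            raise RuntimeError(
                f"training diverged: non-finite loss {mean_loss} at epoch {epoch} "
                "(consider lstm_activation='tanh' or a lower learning rate)"
            )
        history.append((epoch, mean_loss, float(labels.mean())))
    hist = pd.DataFrame(history, columns=["epoch", "mean_loss", "scratch_fraction"])
    return WeightState.capture(model, epochs_run=cfg.epochs), hist


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

_IDENTITY = TransformParams()


def predict_video(
    model: CRNN,
    motion_images: np.ndarray,
    half_window: int,
    t0: int = 1,
    batch: int = 256,
) -> tuple[np.ndarray, np.ndarray]:
    """Scratch probability for every admissible segment of one video.

    Motion images (``motion_images[i]`` at time ``t0 + i``) are resized and
    passed through the convolutional encoder once each; the recurrent block
    then slides over the per-frame feature sequence.  Returns
    ``(centre_times, probabilities)``.
    """
    n = motion_images.shape[0]
    win = 2 * half_window + 1
    if n < win:
        return np.empty(0, dtype=int), np.empty(0, dtype=np.float32)
    px = model.spec.input_px
    feats = np.empty((n, model.spec.frame_feature_len()), dtype=np.float32)
    for s in range(0, n, batch):
        resized = apply_transform(motion_images[s : s + batch], _IDENTITY, px)
        feats[s : s + batch] = model.encode_frames(resized)
    windows = np.lib.stride_tricks.sliding_window_view(feats, win, axis=0)
    # (n-win+1, feat, win) -> (n-win+1, win, feat)
    probs = np.empty(n - win + 1, dtype=np.float32)
    for s in range(0, len(probs), batch):
        blk = np.ascontiguousarray(windows[s : s + batch].transpose(0, 2, 1))
        probs[s : s + batch] = model.forward_from_features(blk)
    times = np.arange(t0 + half_window, t0 + n - half_window)
    return times, probs


def predict_segments(
    model: CRNN, segset: SegmentSet, batch: int = 256
) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Per-video probability tracks for every segment in the set."""
    out = []
    for v in segset.videos:
        n, h, w = v.shape
        motion = v.image_block(1, n)
        times, probs = predict_video(model, motion, segset.half_window)
        out.append((v.video_id, times, probs))
    return out
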