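"""Pixel-probability segmentation of brittle stars in mosaic patches.

The model follows the pyramid scene-parsing design: a convolutional
encoder reduces a 288 x 288 RGB patch to a feature map 1/8 of the input
side, a pyramid pooling module aggregates context at bin sizes
{1, 2, 3, 6}, the pooled branches are up-sampled, concatenated with the
backbone features and fused by 1 x 1 convolutions with dropout, and the
single-channel output is up-sampled bilinearly back to the patch size
with a sigmoid producing per-pixel organism probabilities.

Training minimizes an additive combination of a soft Jaccard loss and a
binary focal loss.  Two encoder profiles exist behind the same
output-stride contract: ``desk`` (a small strided CNN trainable in
minutes on a CPU) and ``full`` (a heavier encoder of the same shape).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .enhancement import EnhancementSpec, apply_enhancement
from .patching import plan_grid, reassemble, slice_patches

PYRAMID_BINS = (1, 2, 3, 6)

_PROFILES = {
    # channel widths per stride-2 stage; last entry is the fusion width
    "desk": {"stages": (8, 16, 32), "branch": 8, "fuse": 32, "deep": False},
    "full": {"stages": (32, 64, 128), "branch": 32, "fuse": 128, "deep": True},
}


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters; the published defaults where stated.

    ``epochs`` defaults to the full-mosaic schedule (500); scaled-down
    experiments override it (the end-to-end synthetic run uses 30).
    """

    learning_rate: float = 0.00012
    batch_size: int = 8
    patch_size: int = 288
    stride: int = 144
    dropout_rate: float = 0.3
    down_sample: int = 8
    epochs: int = 500
    loss_weights: tuple[float, float] = (1.0, 1.0)
    focal_gamma: float = 2.0
    focal_alpha: float = 0.25
    jaccard_smooth: float = 1.0
    seed: int = 0
    enhancement: EnhancementSpec = field(default_factory=EnhancementSpec)
    channel_profile: str = "desk"

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.patch_size % self.down_sample != 0:
            raise ValueError(
                f"down_sample {self.down_sample} must divide patch_size {self.patch_size}"
            )
        if any(w < 0 for w in self.loss_weights):
            raise ValueError("loss weights must be non-negative")
        if self.jaccard_smooth <= 0:
            raise ValueError("jaccard_smooth must be positive")

    def replace(self, **kwargs) -> "TrainConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["enhancement"] = self.enhancement.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        if "loss_weights" in d:
            d["loss_weights"] = tuple(d["loss_weights"])
        if "enhancement" in d and isinstance(d["enhancement"], dict):
            d["enhancement"] = EnhancementSpec.from_dict(d["enhancement"])
        return cls(**d)


# ---------------------------------------------------------------------------
# losses


def jaccard_loss(pred: np.ndarray, truth: np.ndarray, smooth: float = 1.0) -> float:
    """Soft Jaccard loss 1 - (|P∩T|+s)/(|P∪T|+s) over the whole array."""
    loss, _ = _jaccard_with_grad(pred, truth, smooth)
    return loss


def _jaccard_with_grad(pred, truth, smooth):
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    inter = float((pred * truth).sum())
    union = float(pred.sum() + truth.sum()) - inter
    loss = 1.0 - (inter + smooth) / (union + smooth)
    grad = -(truth * (union + smooth) - (inter + smooth) * (1.0 - truth)) / (
        (union + smooth) ** 2
    )
    return loss, grad


def focal_loss(
    pred: np.ndarray, truth: np.ndarray, gamma: float = 2.0, alpha: float = 0.25
) -> float:
    """Mean binary focal loss  -alpha * (1-p_t)^gamma * log(p_t).

    With ``gamma=0, alpha=1`` this reduces to mean binary cross-entropy.
    """
    loss, _ = _focal_with_grad(pred, truth, gamma, alpha)
    return loss


_EPS = 1e-7


def _focal_with_grad(pred, truth, gamma, alpha):
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    p = np.clip(pred, _EPS, 1.0 - _EPS)
    pt = p * truth + (1.0 - p) * (1.0 - truth)
    n = pt.size
    loss = float(np.mean(-alpha * (1.0 - pt) ** gamma * np.log(pt)))
    # d/dpt of -alpha (1-pt)^g log pt ; guard the g=0 branch against 0*inf
    if gamma == 0:
        dpt = -alpha / pt
    else:
        dpt = alpha * (
            gamma * (1.0 - pt) ** (gamma - 1.0) * np.log(pt) - (1.0 - pt) ** gamma / pt
        )
    grad = dpt * (2.0 * truth - 1.0) / n
    grad[(pred < _EPS) | (pred > 1.0 - _EPS)] = 0.0  # clipped region is flat
    return loss, grad


def combined_loss(pred: np.ndarray, truth: np.ndarray, config: TrainConfig) -> float:
    """Weighted additive combination of Jaccard and focal losses."""
    loss, _ = _combined_with_grad(pred, truth, config)
    return loss


def _combined_with_grad(pred, truth, config: TrainConfig):
    wj, wf = config.loss_weights
    lj, gj = _jaccard_with_grad(pred, truth, config.jaccard_smooth)
    lf, gf = _focal_with_grad(pred, truth, config.focal_gamma, config.focal_alpha)
    return wj * lj + wf * lf, wj * gj + wf * gf


# ---------------------------------------------------------------------------
# model


class PyramidSegNet:
    """Encoder + pyramid pooling + fusion + bilinear upsample + sigmoid."""

    def __init__(self, config: TrainConfig, profile: str, rng: np.random.Generator,
                 bins: tuple[int, ...] = PYRAMID_BINS) -> None:
        if profile not in _PROFILES:
            raise ValueError(f"unknown channel profile {profile!r}")
        spec = _PROFILES[profile]
        self.profile = profile
        self.bins = bins
        self.patch_size = config.patch_size
        self.down_sample = config.down_sample
        n_down = int(round(np.log2(config.down_sample)))
        if 2**n_down != config.down_sample:
            raise ValueError("down_sample must be a power of two")
        feat = config.patch_size // config.down_sample
        for b in bins:
            if feat % b != 0:
                raise ValueError(
                    f"feature side {feat} not divisible by pyramid bin {b}"
                )
        self.feat_side = feat

        stages = spec["stages"]
        if len(stages) != n_down:
            # stretch/shrink the stage list to the required depth
            stages = tuple(
                stages[min(i, len(stages) - 1)] for i in range(n_down)
            )
        enc_layers: list[nn.Layer] = []
        c_prev = 3
        for c in stages:
            enc_layers += [nn.Conv2d(c_prev, c, 3, 2, 1, rng), nn.ReLU()]
            if spec["deep"]:
                enc_layers += [nn.Conv2d(c, c, 3, 1, 1, rng), nn.ReLU()]
            c_prev = c
        self.encoder = nn.Sequential(*enc_layers)

        c_feat = c_prev
        c_branch = spec["branch"]
        self.branches = []
        for b in bins:
            pool = nn.avgpool_matrix(feat, b)
            up = nn.bilinear_matrix(b, feat)
            self.branches.append(
                nn.Sequential(
                    nn.AxisResample(pool, pool),
                    nn.Conv2d(c_feat, c_branch, 1, 1, 0, rng),
                    nn.ReLU(),
                    nn.AxisResample(up, up),
                )
            )
        c_cat = c_feat + len(bins) * c_branch
        self.dropout = nn.Dropout(config.dropout_rate)
        self.dropout.rng = rng
        self.head = nn.Sequential(
            nn.Conv2d(c_cat, spec["fuse"], 1, 1, 0, rng),
            nn.ReLU(),
            self.dropout,
            nn.Conv2d(spec["fuse"], 1, 1, 1, 0, rng),
        )
        up_full = nn.bilinear_matrix(feat, config.patch_size)
        self.upsample = nn.AxisResample(up_full, up_full)
        self._split = [c_feat] + [c_branch] * len(bins)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """RGB patches (N, 3, S, S) -> probabilities (N, S, S)."""
        feat = self.encoder.forward(x, train=train)
        parts = [feat] + [br.forward(feat, train=train) for br in self.branches]
        cat = np.concatenate(parts, axis=1)
        z = self.head.forward(cat, train=train)
        z = self.upsample.forward(z, train=train)
        self._z = z
        return nn.sigmoid(z)[:, 0]

    def backward(self, dprob: np.ndarray) -> None:
        """Backprop from dLoss/dprobability (N, S, S)."""
        p = nn.sigmoid(self._z)
        dz = (dprob[:, None] * p * (1.0 - p)).astype(nn.F32)
        dz = self.upsample.backward(dz)
        dcat = self.head.backward(dz)
        splits = np.cumsum(self._split)[:-1]
        parts = np.split(dcat, splits, axis=1)
        dfeat = parts[0].copy()
        for br, dpart in zip(self.branches, parts[1:]):
            dfeat += br.backward(np.ascontiguousarray(dpart))
        self.encoder.backward(dfeat)

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        pairs = self.encoder.parameters()
        for br in self.branches:
            pairs.extend(br.parameters())
        pairs.extend(self.head.parameters())
        return pairs

    def param_count(self) -> int:
        return int(sum(p.size for p, _ in self.parameters()))


@dataclass
class SegmentationModel:
    """Trained state plus metadata (architecture, config, loss history)."""

    net: PyramidSegNet
    config: TrainConfig
    loss_history: list[float] = field(default_factory=list)

    @property
    def metadata(self) -> dict:
        return {
            "architecture": "pyramid-pooling segmentation net",
            "profile": self.net.profile,
            "pyramid_bins": list(self.net.bins),
            "feature_side": self.net.feat_side,
            "param_count": self.net.param_count(),
            "config": self.config.to_dict(),
            "epochs_trained": len(self.loss_history),
        }

    def predict_patches(self, patches: np.ndarray) -> np.ndarray:
        """Forward a batch of (N, S, S, 3) patches to (N, S, S) probabilities."""
        x = np.ascontiguousarray(
            np.transpose(patches, (0, 3, 1, 2)), dtype=np.float32
        )
        return self.net.forward(x, train=False)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        arrays = {
            f"param_{i}": p for i, (p, _) in enumerate(self.net.parameters())
        }
        np.savez(out / "weights.npz", **arrays)
        meta = dict(self.metadata)
        meta["loss_history"] = self.loss_history
        (out / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, model_dir: str | Path) -> "SegmentationModel":
        model_dir = Path(model_dir)
        meta = json.loads((model_dir / "model.json").read_text())
        config = TrainConfig.from_dict(meta["config"])
        model = build_model(config, channel_profile=meta["profile"])
        weights = np.load(model_dir / "weights.npz")
        for i, (p, _) in enumerate(model.net.parameters()):
            p[...] = weights[f"param_{i}"]
        model.loss_history = list(meta.get("loss_history", []))
        return model


def build_model(
    config: TrainConfig, channel_profile: str | None = None
) -> SegmentationModel:
    """Construct an untrained model honouring the output-stride contract."""
    profile = channel_profile or config.channel_profile
    rng = np.random.default_rng(config.seed)
    net = PyramidSegNet(config, profile, rng)
    return SegmentationModel(net=net, config=config)


# ---------------------------------------------------------------------------
# training and inference


def _as_image_mask_pairs(data, variant: str) -> list[tuple[np.ndarray, np.ndarray]]:
    pairs = []
    for item in data:
        if hasattr(item, "image") and hasattr(item, "mask_disc"):
            mask = item.mask_disc if variant == "disc" else item.mask_full
            pairs.append((np.asarray(item.image), np.asarray(mask)))
        else:
            image, mask = item
            pairs.append((np.asarray(image), np.asarray(mask)))
    return pairs


def extract_patch_arrays(
    image: np.ndarray, mask: np.ndarray, config: TrainConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Tile one (image, mask) pair into training patch arrays."""
    image = apply_enhancement(image, config.enhancement)
    grid = plan_grid(*image.shape[:2], config.patch_size, config.stride)
    xs = np.stack(slice_patches(image, grid)).astype(np.float32)
    ys = np.stack(slice_patches(mask.astype(np.float32), grid))
    return xs, ys


def training_patches(scenes, config: TrainConfig, variant: str = "disc"):
    """Patch arrays from synthetic scenes using their exact ground truth."""
    xs, ys = [], []
    for scene in scenes:
        mask = scene.mask_disc if variant == "disc" else scene.mask_full
        x, y = extract_patch_arrays(scene.image, mask, config)
        xs.append(x)
        ys.append(y)
    return np.concatenate(xs), np.concatenate(ys)


def train(
    model: SegmentationModel,
    data,
    config: TrainConfig | None = None,
    epochs: int | None = None,
    variant: str = "disc",
) -> SegmentationModel:
    """Train in place on scenes, (image, mask) pairs or patch arrays.

    ``data`` is a list of synthetic scenes (ground-truth masks taken in
    the given ``variant``), a list of (image, mask) pairs (tiled
    internally with the config's patch size and stride), or a tuple of
    arrays ``(patches (N, S, S, 3), masks (N, S, S))``.  Returns the
    model with its per-epoch loss history filled in.  All randomness
    (shuffling, dropout) derives from ``config.seed``.
    """
    config = config or model.config
    if isinstance(data, tuple) and len(data) == 2 and isinstance(data[0], np.ndarray):
        xs, ys = data
    else:
        pairs = _as_image_mask_pairs(data, variant)
        if not pairs:
            raise ValueError("empty training dataset")
        arrays = [extract_patch_arrays(img, msk, config) for img, msk in pairs]
        xs = np.concatenate([a for a, _ in arrays])
        ys = np.concatenate([b for _, b in arrays])
    if len(xs) == 0:
        raise ValueError("empty training dataset")
    if xs.shape[:1] != ys.shape[:1] or xs.shape[1:3] != ys.shape[1:3]:
        raise ValueError(f"patch/mask shape mismatch: {xs.shape} vs {ys.shape}")

    x_all = np.ascontiguousarray(np.transpose(xs, (0, 3, 1, 2)), dtype=np.float32)
    y_all = ys.astype(np.float32)

    rng = np.random.default_rng(config.seed + 1)
    model.net.dropout.rng = rng
    opt = nn.Adam(model.net.parameters(), lr=config.learning_rate)
    n = len(x_all)
    n_epochs = epochs if epochs is not None else config.epochs
    for _ in range(n_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            pred = model.net.forward(x_all[idx], train=True)
            loss, grad = _combined_with_grad(pred, y_all[idx], config)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss {loss} at epoch {len(model.loss_history)}, "
                    f"batch start {start}; lr={config.learning_rate}"
                )
            model.net.backward(grad.astype(np.float32))
            opt.step()
            losses.append(loss)
        model.loss_history.append(float(np.mean(losses)))
    return model


def predict_mosaic(
    model: SegmentationModel,
    mosaic: np.ndarray,
    config: TrainConfig | None = None,
    batch_size: int = 8,
) -> np.ndarray:
    """Block-process a mosaic into a full-size probability map.

    Mosaics smaller than one patch are reflect-padded, predicted and
    cropped back.  Overlapping patch predictions merge by mean.
    """
    config = config or model.config
    mosaic = apply_enhancement(np.asarray(mosaic), config.enhancement)
    h, w = mosaic.shape[:2]
    pad_h = max(0, config.patch_size - h)
    pad_w = max(0, config.patch_size - w)
    if pad_h or pad_w:
        mosaic = np.pad(mosaic, ((0, pad_h), (0, pad_w), (0, 0)), mode="reflect")
    grid = plan_grid(*mosaic.shape[:2], config.patch_size, config.stride)
    patches = np.stack(slice_patches(mosaic, grid)).astype(np.float32)
    probs = []
    for start in range(0, len(patches), batch_size):
        probs.extend(model.predict_patches(patches[start : start + batch_size]))
    prob = reassemble(probs, grid)
    return prob[:h, :w]


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Strict thresholding: foreground where probability > threshold."""
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    return np.asarray(prob) > threshold
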