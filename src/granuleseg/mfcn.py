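"""The multi-branch fully convolutional network (MFCN).

Architecture
------------
Three modules arranged as in the original design:

* **Multi-scale inception** — the input micrograph passes through parallel
  stride-2 convolutions with different kernel sizes (3x3, 5x5, 7x7 by
  default), one per branch, so each branch starts from features of a
  different granularity.
* **Multi-branch sampling** — each branch is a skip-free encoder-decoder:
  repeated {3x3 stride-2 convolution, batch norm, ReLU} blocks until the
  branch's total reduction (4x / 8x / 16x, counting the inception stride) is
  reached, then symmetric 2x learnable upsampling blocks back to the input
  resolution.  Each branch ends in a 2-channel score map, acting as a binary
  classifier with its own receptive field.
* **Multi-scale ensemble** — the branch score maps are sliced per class,
  concatenated (all background slices, then all granule slices) and fused by
  a 1x1 convolution that learns per-branch weights; softmax over the two
  fused channels yields the per-pixel class probabilities.

Granules occupy only a small fraction of an EM image, so training uses
pixel-wise cross-entropy with inverse-frequency class weighting; the
optimizer is Adam.  Everything is seeded: one master seed fans out to
parameter initialisation and data shuffling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .io_config import GrayImage, RunConfig

_F32 = np.float32


@dataclass(frozen=True)
class NetworkSpec:
    """Topology of the MFCN.

    ``branch_factors[i]`` is the total down/up-sampling of branch *i*, which
    starts with a stride-``inception_stride`` convolution of kernel
    ``inception_kernel_sizes[i]``.  Channel width at encoder level L is
    ``base_channels * channel_growth**L``.
    """

    inception_kernel_sizes: tuple[int, ...] = (3, 5, 7)
    inception_stride: int = 2
    branch_factors: tuple[int, ...] = (4, 8, 16)
    base_channels: int = 16
    channel_growth: int = 2
    n_classes: int = 2
    pad_mode: str = "reflect"

    def __post_init__(self) -> None:
        if len(self.inception_kernel_sizes) != len(self.branch_factors):
            raise ValueError("one inception kernel per branch is required")
        if any(k % 2 == 0 for k in self.inception_kernel_sizes):
            raise ValueError("inception kernels must be odd")
        for f in self.branch_factors:
            q, s = f, self.inception_stride
            if q % s or (q // s) & (q // s - 1):
                raise ValueError(
                    f"branch factor {f} must be a power of 2 times the inception stride"
                )
        if self.n_classes != 2:
            raise ValueError("the network is a 2-class (background/granule) segmenter")

    @property
    def max_factor(self) -> int:
        return max(self.branch_factors)


class MFCN:
    """Multi-branch fully convolutional segmentation network."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.branches = [
            self._build_branch(k, f, rng)
            for k, f in zip(spec.inception_kernel_sizes, spec.branch_factors)
        ]
        b = len(self.branches)
        self.fuse = nn.Conv2d(
            b * spec.n_classes, spec.n_classes, 1, pad_mode=spec.pad_mode, rng=rng
        )
        self._branch_scores = None

    def _build_branch(self, kernel: int, factor: int, rng) -> nn.Sequential:
        s = self.spec
        layers = [
            nn.Conv2d(1, s.base_channels, kernel, stride=s.inception_stride,
                      pad_mode=s.pad_mode, rng=rng),
            nn.BatchNorm2d(s.base_channels),
            nn.ReLU(),
        ]
        n_down = int(np.log2(factor // s.inception_stride))
        c = s.base_channels
        for _ in range(n_down):
            c2 = c * s.channel_growth
            layers += [
                nn.Conv2d(c, c2, 3, stride=2, pad_mode=s.pad_mode, rng=rng),
                nn.BatchNorm2d(c2),
                nn.ReLU(),
            ]
            c = c2
        for _ in range(n_down):
            c2 = c // s.channel_growth
            layers += [
                nn.ConvTranspose2d(c, c2, pad_mode=s.pad_mode, rng=rng),
                nn.BatchNorm2d(c2),
                nn.ReLU(),
            ]
            c = c2
        # final upsampling block undoes the inception stride
        layers += [
            nn.ConvTranspose2d(c, c, pad_mode=s.pad_mode, rng=rng),
            nn.BatchNorm2d(c),
            nn.ReLU(),
            nn.Conv2d(c, s.n_classes, 1, pad_mode=s.pad_mode, rng=rng),
        ]
        return nn.Sequential(*layers)

    # -- parameters ---------------------------------------------------------
    def params(self) -> list[nn.Param]:
        out = []
        for br in self.branches:
            out.extend(br.params())
        out.extend(self.fuse.params())
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Logits (N, 2, H, W) for a normalised input batch (N, 1, H, W)."""
        scores = [br.forward(x, train=train) for br in self.branches]
        if train:
            self._branch_scores = scores
        nc = self.spec.n_classes
        # slice per class, then concatenate: background slices first
        stacked = np.concatenate(
            [s[:, c : c + 1] for c in range(nc) for s in scores], axis=1
        )
        return self.fuse.forward(stacked, train=train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dstacked = self.fuse.backward(dlogits)
        nc, b = self.spec.n_classes, len(self.branches)
        dx = None
        for i, br in enumerate(self.branches):
            ds = np.stack([dstacked[:, c * b + i] for c in range(nc)], axis=1)
            g = br.backward(np.ascontiguousarray(ds))
            dx = g if dx is None else dx + g
        return dx

    # -- image-level API ----------------------------------------------------
    @staticmethod
    def _normalise(pixels: np.ndarray) -> np.ndarray:
        return (pixels.astype(_F32) / 255.0) - 0.5

    def forward_image(self, img: GrayImage) -> np.ndarray:
        """Per-pixel class probabilities, shape (H, W, 2).

        Sizes not divisible by the largest branch factor are reflect-padded
        to the next multiple and the output is cropped back.
        """
        h, w = img.shape
        f = self.spec.max_factor
        ph = (-h) % f
        pw = (-w) % f
        x = self._normalise(img.pixels)
        if ph or pw:
            x = np.pad(x, ((0, ph), (0, pw)), mode="reflect")
        logits = self.forward(x[None, None], train=False)
        probs = nn.softmax_channels(logits)[0, :, :h, :w]
        return np.moveaxis(probs, 0, -1)

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Serialised parameters (npz) plus a JSON sidecar of the topology."""
        path = Path(path)
        arrays = {}
        for i, p in enumerate(self.params()):
            arrays[f"p{i}"] = p.value
        j = 0
        for br in self.branches:
            for layer in br.layers:
                if isinstance(layer, nn.BatchNorm2d):
                    arrays[f"rm{j}"] = layer.running_mean
                    arrays[f"rv{j}"] = layer.running_var
                    j += 1
        np.savez(path, **arrays)
        sidecar = path.with_suffix(path.suffix + ".json")
        with open(sidecar, "w") as fh:
            json.dump({"spec": asdict(self.spec), "seed": self.seed}, fh)

    @classmethod
    def load(cls, path: str | Path) -> "MFCN":
        path = Path(path)
        with open(path.with_suffix(path.suffix + ".json")) as fh:
            meta = json.load(fh)
        spec_d = meta["spec"]
        for key in ("inception_kernel_sizes", "branch_factors"):
            spec_d[key] = tuple(spec_d[key])
        net = cls(NetworkSpec(**spec_d), seed=meta["seed"])
        data = np.load(path)
        for i, p in enumerate(net.params()):
            p.value = data[f"p{i}"]
        j = 0
        for br in net.branches:
            for layer in br.layers:
                if isinstance(layer, nn.BatchNorm2d):
                    layer.running_mean = data[f"rm{j}"]
                    layer.running_var = data[f"rv{j}"]
                    j += 1
        return net


def build_mfcn(spec: NetworkSpec | None = None, seed: int = 0) -> MFCN:
    return MFCN(spec or NetworkSpec(), seed=seed)


@dataclass
class TrainState:
    """Outcome of a training run."""

    network: MFCN
    epochs_completed: int
    loss_history: list[float] = field(default_factory=list)  # one entry per step
    class_weights: tuple[float, float] = (1.0, 1.0)
    seed: int = 0

    def epoch_losses(self) -> list[float]:
        n = self.epochs_completed
        if n == 0:
            return []
        per = len(self.loss_history) // n
        return [float(np.mean(self.loss_history[i * per : (i + 1) * per])) for i in range(n)]


def weighted_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, weights: tuple[float, float]
) -> tuple[float, np.ndarray]:
    """Pixel-wise 2-class cross-entropy with per-class weights.

    Returns the scalar loss and its gradient with respect to the logits.
    """
    probs = nn.softmax_channels(logits)
    y = labels.astype(np.int64)
    w = np.where(y == 1, _F32(weights[1]), _F32(weights[0]))
    p_true = np.take_along_axis(probs, y[:, None], axis=1)[:, 0]
    wsum = w.sum()
    loss = float(-(w * np.log(np.maximum(p_true, 1e-12))).sum() / wsum)
    onehot = np.zeros_like(probs)
    np.put_along_axis(onehot, y[:, None], 1.0, axis=1)
    dlogits = (probs - onehot) * (w[:, None] / wsum)
    return loss, dlogits.astype(_F32)


def inverse_frequency_weights(labels: list[np.ndarray]) -> tuple[float, float]:
    """Class weights proportional to inverse pixel frequency, mean-normalised."""
    n_fg = sum(int((lab > 0).sum()) for lab in labels)
    n_total = sum(lab.size for lab in labels)
    n_bg = n_total - n_fg
    if n_fg == 0 or n_bg == 0:
        return (1.0, 1.0)
    w0, w1 = n_total / (2.0 * n_bg), n_total / (2.0 * n_fg)
    return (float(w0), float(w1))


def train(
    network: MFCN,
    pairs: list[tuple[GrayImage, np.ndarray]],
    cfg: RunConfig,
) -> TrainState:
    """Train the network on (equalized image, binary label) pairs.

    All images in ``pairs`` must share one shape divisible by the largest
    branch factor.  Deterministic given ``cfg.seed`` on a fixed platform.
    """
    if not pairs:
        raise ValueError("training requires at least one (image, label) pair")
    shape = pairs[0][0].shape
    f = network.spec.max_factor
    if shape[0] % f or shape[1] % f:
        raise ValueError(f"training images must be divisible by {f}, got {shape}")
    for img, lab in pairs:
        if img.shape != shape or lab.shape != shape:
            raise ValueError("all training pairs must share one shape")

    xs = np.stack([MFCN._normalise(img.pixels) for img, _ in pairs])[:, None]
    ys = np.stack([(lab > 0).astype(np.int64) for _, lab in pairs])
    weights = inverse_frequency_weights([lab for _, lab in pairs])

    opt = nn.Adam(network.params(), lr=cfg.learning_rate)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    losses: list[float] = []
    n = len(pairs)
    bs = min(cfg.batch_size, n)
    for _epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(n)
        for start in range(0, n - bs + 1, bs):
            idx = order[start : start + bs]
            logits = network.forward(xs[idx], train=True)
            loss, dlogits = weighted_cross_entropy(logits, ys[idx], weights)
            opt.zero_grad()
            network.backward(dlogits)
            opt.step()
            losses.append(loss)
    return TrainState(
        network=network,
        epochs_completed=cfg.epochs,
        loss_history=losses,
        class_weights=weights,
        seed=cfg.seed,
    )


def predict_mask(network: MFCN, img: GrayImage, threshold: float = 0.5) -> np.ndarray:
    """Binary granule mask: 1 where the granule-class probability exceeds
    ``threshold`` (strict inequality; ties go to background)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    probs = network.forward_image(img)
    return (probs[..., 1] > threshold).astype(np.uint8)
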