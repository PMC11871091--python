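"""Dense U-Net assembly, training loop and inference."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from ..imaging_io import CTImage, LabelMask, N_CLASSES
from ._nn import Adam, Conv2D, DenseBlock, InstanceNorm, MaxPool2, ReLU, Upsample2, cross_entropy_grad, softmax

__all__ = ["ModelConfig", "TrainConfig", "TrainedModel", "DenseUNet", "build_dense_unet", "train", "predict", "save_model", "load_model", "desk_model_config", "desk_train_config"]

HU_CLIP = (-1024.0, 1500.0)  # input normalization window


@dataclass(frozen=True)
class ModelConfig:
    depth: int = 4
    base_filters: int = 16
    dense_block_layers: int = 2
    growth_rate: int = 8
    n_classes: int = N_CLASSES
    input_size: int = 128
    skip_connections: bool = True  # ablation toggle; the architecture keeps them on

    def __post_init__(self) -> None:
        if self.n_classes != N_CLASSES:
            raise ValueError(f"n_classes must be {N_CLASSES}")
        if self.input_size % (2**self.depth) != 0:
            raise ValueError(f"input_size {self.input_size} not divisible by 2^depth={2**self.depth}")
        if min(self.depth, self.base_filters, self.dense_block_layers, self.growth_rate) < 1:
            raise ValueError("architecture hyperparameters must be positive")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 2
    learning_rate: float = 1e-4
    epochs: int = 200
    optimizer: str = "adam"
    loss: str = "categorical_crossentropy"
    seed: int = 0
    validation_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("hyperparameters must be positive")
        if self.optimizer != "adam" or self.loss != "categorical_crossentropy":
            raise ValueError("only Adam + categorical cross-entropy are supported")
        if not (0.0 <= self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in [0, 1)")


def desk_model_config() -> ModelConfig:
    """Desk-scale preset: small filters, 128 px, trainable in minutes on CPU."""
    return ModelConfig(depth=4, base_filters=8, dense_block_layers=2, growth_rate=8, input_size=128)


def desk_train_config(seed: int = 0) -> TrainConfig:
    """Desk-scale training preset (reduced epochs, raised learning rate)."""
    return TrainConfig(batch_size=2, learning_rate=2e-3, epochs=20, seed=seed)


class DenseUNet:
    """Encoder-decoder with dense blocks and skip connections.

    Each level: dense block then 1 x 1 transition conv + ReLU to the level's
    filter count; encoder levels max-pool down, decoder levels upsample and
    concatenate the matching encoder feature map before their block. A final
    1 x 1 conv produces per-pixel class logits.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        d, f0 = config.depth, config.base_filters
        L, g = config.dense_block_layers, config.growth_rate
        filters = [f0 * 2**i for i in range(d + 1)]

        self.enc_blocks, self.enc_trans, self.enc_norm, self.enc_relu, self.pools = [], [], [], [], []
        c = 1
        for i in range(d):
            blk = DenseBlock(c, L, g, rng)
            tr = Conv2D(blk.c_out, filters[i], 1, rng)
            self.enc_blocks.append(blk)
            self.enc_trans.append(tr)
            self.enc_norm.append(InstanceNorm(filters[i]))
            self.enc_relu.append(ReLU())
            self.pools.append(MaxPool2())
            c = filters[i]

        self.mid_block = DenseBlock(c, L, g, rng)
        self.mid_trans = Conv2D(self.mid_block.c_out, filters[d], 1, rng)
        self.mid_norm = InstanceNorm(filters[d])
        self.mid_relu = ReLU()
        c = filters[d]

        self.ups, self.dec_blocks, self.dec_trans, self.dec_norm, self.dec_relu = [], [], [], [], []
        for i in reversed(range(d)):
            self.ups.append(Upsample2())
            c_in = c + (filters[i] if config.skip_connections else 0)
            blk = DenseBlock(c_in, L, g, rng)
            tr = Conv2D(blk.c_out, filters[i], 1, rng)
            self.dec_blocks.append(blk)
            self.dec_trans.append(tr)
            self.dec_norm.append(InstanceNorm(filters[i]))
            self.dec_relu.append(ReLU())
            c = filters[i]

        self.head = Conv2D(c, config.n_classes, 1, rng)

    # -- plumbing ----------------------------------------------------------

    def param_layers(self) -> list:
        layers: list = []
        for blk, tr, nm in zip(self.enc_blocks, self.enc_trans, self.enc_norm):
            layers += blk.layers() + [tr, nm]
        layers += self.mid_block.layers() + [self.mid_trans, self.mid_norm]
        for blk, tr, nm in zip(self.dec_blocks, self.dec_trans, self.dec_norm):
            layers += blk.layers() + [tr, nm]
        layers.append(self.head)
        return layers

    def n_params(self) -> int:
        return sum(l.n_params() for l in self.param_layers())

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(B, 1, H, W) normalized input -> (B, n_classes, H, W) softmax probs."""
        skips = []
        for blk, tr, nm, relu, pool in zip(self.enc_blocks, self.enc_trans, self.enc_norm, self.enc_relu, self.pools):
            x = relu.forward(nm.forward(tr.forward(blk.forward(x))))
            skips.append(x)
            x = pool.forward(x)
        x = self.mid_relu.forward(self.mid_norm.forward(self.mid_trans.forward(self.mid_block.forward(x))))
        self._skip_used = []
        for up, blk, tr, nm, relu, skip in zip(self.ups, self.dec_blocks, self.dec_trans, self.dec_norm, self.dec_relu, reversed(skips)):
            x = up.forward(x)
            if self.config.skip_connections:
                x = np.concatenate([skip, x], axis=1)
                self._skip_used.append(skip.shape[1])
            x = relu.forward(nm.forward(tr.forward(blk.forward(x))))
        logits = self.head.forward(x)
        self._probs = softmax(logits, axis=1)
        return self._probs

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.head.backward(dlogits)
        skip_grads = []
        for i, (blk, tr, nm, relu) in enumerate(
            zip(reversed(self.dec_blocks), reversed(self.dec_trans), reversed(self.dec_norm), reversed(self.dec_relu))
        ):
            g = blk.backward(tr.backward(nm.backward(relu.backward(g))))
            if self.config.skip_connections:
                c_skip = self._skip_used[len(self.dec_blocks) - 1 - i]
                skip_grads.append(g[:, :c_skip])
                g = np.ascontiguousarray(g[:, c_skip:])
            else:
                skip_grads.append(None)
            g = self.ups[len(self.ups) - 1 - i].backward(g)
        g = self.mid_block.backward(self.mid_trans.backward(self.mid_norm.backward(self.mid_relu.backward(g))))
        # skip_grads[i] already corresponds to encoder level i (shallow -> deep)
        for i in reversed(range(len(self.enc_blocks))):
            g = self.pools[i].backward(g)
            if skip_grads[i] is not None:
                g = g + skip_grads[i]
            g = self.enc_blocks[i].backward(
                self.enc_trans[i].backward(self.enc_norm[i].backward(self.enc_relu[i].backward(g)))
            )


@dataclass
class TrainedModel:
    """A trained network plus its configs, loss log and provenance."""

    network: DenseUNet
    model_config: ModelConfig
    train_config: TrainConfig
    loss_log: list[float] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def build_dense_unet(config: ModelConfig, seed: int = 0) -> DenseUNet:
    """Instantiate an untrained Dense U-Net."""
    return DenseUNet(config, seed=seed)


def normalize_hu(values: np.ndarray) -> np.ndarray:
    lo, hi = HU_CLIP
    return ((np.clip(values, lo, hi) - lo) / (hi - lo)).astype(np.float32)


def _pad_to_multiple(arr: np.ndarray, mult: int) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = arr.shape[-2:]
    ph, pw = (-h) % mult, (-w) % mult
    if ph or pw:
        pad = [(0, 0)] * (arr.ndim - 2) + [(0, ph), (0, pw)]
        arr = np.pad(arr, pad, mode="reflect")
    return arr, (h, w)


def _as_training_pairs(samples: Sequence) -> list[tuple[np.ndarray, np.ndarray]]:
    """Flatten PhantomSamples or (CTImage, LabelMask) pairs into 2-D slices."""
    pairs = []
    for s in samples:
        if hasattr(s, "image") and hasattr(s, "labels"):
            image, labels = s.image, s.labels
        else:
            image, labels = s
        iv, lv = image.values, labels.classes
        if iv.shape != lv.shape:
            raise ValueError("image/mask shape mismatch")
        if iv.ndim == 3:
            for k in range(iv.shape[0]):
                pairs.append((iv[k], lv[k]))
        else:
            pairs.append((iv, lv))
    return pairs


def train(
    network: DenseUNet,
    samples: Sequence,
    tc: TrainConfig,
    log_every: int | None = None,
) -> TrainedModel:
    """Train with mini-batch Adam on categorical cross-entropy.

    ``samples`` is a sequence of PhantomSamples or (CTImage, LabelMask)
    pairs; 3-D stacks are flattened into slices. Deterministic for a fixed
    ``tc.seed``.
    """
    pairs = _as_training_pairs(samples)
    if len(pairs) < 1:
        raise ValueError("need at least one training slice")
    nc = network.config.n_classes
    xs = np.stack([normalize_hu(p[0]) for p in pairs])[:, None]  # (N,1,H,W)
    eye = np.eye(nc, dtype=np.float32)
    ys = np.stack([eye[p[1]].transpose(2, 0, 1) for p in pairs])  # (N,C,H,W)
    xs, _ = _pad_to_multiple(xs, 2**network.config.depth)
    ys, _ = _pad_to_multiple(ys, 2**network.config.depth)

    rng = np.random.default_rng(tc.seed)
    opt = Adam(network.param_layers(), lr=tc.learning_rate)
    n = xs.shape[0]
    log: list[float] = []
    for epoch in range(tc.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, tc.batch_size):
            idx = order[start : start + tc.batch_size]
            probs = network.forward(xs[idx])
            loss, dlogits = cross_entropy_grad(probs, ys[idx])
            opt.zero_grad()
            network.backward(dlogits)
            opt.step()
            losses.append(loss)
        log.append(float(np.mean(losses)))
        if log_every and (epoch + 1) % log_every == 0:
            print(f"epoch {epoch + 1}/{tc.epochs}  loss {log[-1]:.4f}")
    return TrainedModel(
        network=network,
        model_config=network.config,
        train_config=tc,
        loss_log=log,
        provenance={"n_slices": n, "seed": tc.seed},
    )


def predict(model: TrainedModel | DenseUNet, image: CTImage) -> tuple[np.ndarray, LabelMask]:
    """Run inference on a 2-D slice or 3-D stack.

    Returns the per-pixel class probability mask and the argmax label mask
    (ties resolve to the lower class code). Inputs whose size is not a
    multiple of ``2^depth`` are reflect-padded and cropped back.
    """
    network = model.network if isinstance(model, TrainedModel) else model
    values = image.values
    if values.ndim == 3:
        probs_list, labels_list = [], []
        for k in range(values.shape[0]):
            p, m = predict(model, image.slice(k))
            probs_list.append(p)
            labels_list.append(m.classes)
        return np.stack(probs_list), LabelMask(np.stack(labels_list), image.pixel_spacing, image.slice_thickness)

    x = normalize_hu(values)[None, None]
    x, (h, w) = _pad_to_multiple(x, 2**network.config.depth)
    probs = network.forward(x)[0][:, :h, :w]
    labels = probs.argmax(axis=0).astype(np.uint8)
    return probs, LabelMask(labels, image.pixel_spacing, image.slice_thickness)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Save weights (.npz) plus a JSON manifest alongside."""
    path = Path(path)
    arrays = {}
    for i, lay in enumerate(model.network.param_layers()):
        for name, value in lay.params.items():
            arrays[f"{i}.{name}"] = value
    np.savez_compressed(path, **arrays)
    manifest = {
        "model_config": asdict(model.model_config),
        "train_config": asdict(model.train_config),
        "loss_log": model.loss_log,
        "provenance": model.provenance,
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    mc = ModelConfig(**manifest["model_config"])
    tc = TrainConfig(**manifest["train_config"])
    net = DenseUNet(mc, seed=0)
    data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    for i, lay in enumerate(net.param_layers()):
        for name, value in lay.params.items():
            value[...] = data[f"{i}.{name}"]
    return TrainedModel(net, mc, tc, manifest["loss_log"], manifest["provenance"])
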