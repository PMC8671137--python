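"""Model definitions: patch classifier, context-tile autoencoder, and the
dynamic smoothing-weight head.

The classifier maps one patch to a single logit; tumor probability is the
sigmoid of that logit. The *feature polymer* is the 3x3 tile of a patch and
its 8 spatial neighbors at the same magnification; a small convolutional
encoder, pretrained as an autoencoder on such tiles, summarises the patch's
surroundings, and a two-layer fully connected head maps that summary through
a sigmoid to the raw smoothing weight eps in (0, 1). The effective smoothing
weight used in training is eps' = 0.2 * eps, so eps' is bounded in (0, 0.2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .patching import PatchGroup, SlideImage, crop_multiscale

__all__ = [
    "MainModelConfig",
    "PolymerEncoderConfig",
    "build_main_model",
    "predict_proba",
    "assemble_polymer",
    "polymer_to_input",
    "build_polymer_autoencoder",
    "pretrain_polymer_encoder",
    "build_epsilon_head",
    "compute_epsilon",
    "EPSILON_PRIME_FACTOR",
    "epsilon_prime",
]

EPSILON_PRIME_FACTOR = 0.2  # eps' = 0.2 * eps


@dataclass
class MainModelConfig:
    """Desk-scale patch classifier: a small strided CNN ending in one logit."""

    input_size: int = 64
    channels: tuple[int, ...] = (8, 16, 32, 32)
    hidden: int = 32


@dataclass
class PolymerEncoderConfig:
    """Six convolutional layers + two fully connected layers -> sigmoid(eps)."""

    tile_size: int = 96  # context tile is average-pooled to this side first
    channels: tuple[int, ...] = (8, 8, 16, 16, 16, 8)
    fc_hidden: int = 16

    def __post_init__(self) -> None:
        if len(self.channels) != 6:
            raise ValueError("polymer encoder has exactly six convolutional layers")


def build_main_model(config: MainModelConfig, seed: int = 0) -> nn.Sequential:
    """Seeded classifier; forward of (N,3,S,S) gives (N,1) logits."""
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = [nn.Center(0.5)]
    cin = 3
    size = config.input_size
    for cout in config.channels:
        layers += [nn.Conv2d(cin, cout, 3, stride=2, pad=1, rng=rng), nn.ReLU()]
        cin = cout
        size = (size + 1) // 2
    flat = cin * size * size
    layers += [
        nn.Flatten(),
        nn.Linear(flat, config.hidden, rng=rng),
        nn.ReLU(),
        nn.Linear(config.hidden, 1, rng=rng),
    ]
    model = nn.Sequential(*layers)
    model.input_size = config.input_size  # type: ignore[attr-defined]
    return model


def predict_proba(model: nn.Sequential, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Tumor probabilities sigmoid(logit) for a stack of patches."""
    expected = getattr(model, "input_size", None)
    if expected is not None and x.shape[-1] != expected:
        raise ValueError(f"input side {x.shape[-1]} != model input size {expected}")
    out = np.empty(len(x), dtype=np.float64)
    for i in range(0, len(x), batch_size):
        z = model.forward(x[i : i + batch_size])
        out[i : i + batch_size] = nn.sigmoid(z[:, 0])
    return out


def assemble_polymer(
    slide: SlideImage,
    center: tuple[float, float],
    magnification: float = 20.0,
    out_size: int = 448,
) -> np.ndarray:
    """3x3 tile of the patch and its 8 neighbors at one magnification.

    Neighbor offsets are one patch footprint at the chosen magnification;
    off-slide neighbors come back background-padded from the cropper. The
    central sub-block equals the plain crop at the same center.
    """
    cx, cy = center
    step = out_size * slide.base_magnification / magnification
    tile = np.empty((3 * out_size, 3 * out_size, 3), dtype=np.uint8)
    h, w = slide.shape
    from .patching import BACKGROUND_VALUE

    for i, dy in enumerate((-step, 0.0, step)):
        for j, dx in enumerate((-step, 0.0, step)):
            nx, ny = cx + dx, cy + dy
            if 0 <= nx < w and 0 <= ny < h:
                group = crop_multiscale(slide, (nx, ny), (magnification,), out_size)
                sub = group.crops[magnification]
            else:  # neighbor center off slide: fully padded tile
                sub = np.full((out_size, out_size, 3), BACKGROUND_VALUE, dtype=np.uint8)
            tile[i * out_size : (i + 1) * out_size, j * out_size : (j + 1) * out_size] = sub
    return tile


def polymer_to_input(tile: np.ndarray, config: PolymerEncoderConfig) -> np.ndarray:
    """uint8 HWC tile -> float32 CHW, average-pooled to the encoder side."""
    x = tile.astype(np.float32) / 255.0
    side = tile.shape[0]
    factor = side // config.tile_size
    if factor > 1:
        x = x[: factor * config.tile_size, : factor * config.tile_size]
        x = x.reshape(
            config.tile_size, factor, config.tile_size, factor, 3
        ).mean(axis=(1, 3))
    elif side != config.tile_size:
        from skimage.transform import resize

        x = resize(x, (config.tile_size, config.tile_size), order=1, preserve_range=True)
    return x.transpose(2, 0, 1).astype(np.float32)


def build_polymer_autoencoder(
    config: PolymerEncoderConfig, seed: int = 0
) -> tuple[nn.Sequential, nn.Sequential]:
    """Encoder (6 strided convs) and mirrored decoder for tile reconstruction."""
    rng = np.random.default_rng(seed)
    enc_layers: list[nn.Layer] = []
    cin = 3
    strides = (2, 2, 2, 2, 2, 1)
    for cout, s in zip(config.channels, strides):
        enc_layers += [nn.Conv2d(cin, cout, 3, stride=s, pad=1, rng=rng), nn.ReLU()]
        cin = cout
    encoder = nn.Sequential(*enc_layers)

    dec_layers: list[nn.Layer] = []
    rev = list(config.channels[::-1])  # bottleneck .. first
    for i in range(5):
        dec_layers += [nn.Upsample2x(), nn.Conv2d(cin, rev[i + 1], 3, 1, 1, rng=rng), nn.ReLU()]
        cin = rev[i + 1]
    dec_layers += [nn.Conv2d(cin, 3, 3, 1, 1, rng=rng), nn.Sigmoid()]
    decoder = nn.Sequential(*dec_layers)
    return encoder, decoder


def bottleneck_dim(config: PolymerEncoderConfig) -> int:
    side = config.tile_size // 32  # five stride-2 stages
    return config.channels[-1] * side * side


def pretrain_polymer_encoder(
    tiles: np.ndarray,
    config: PolymerEncoderConfig | None = None,
    seed: int = 0,
    epochs: int = 5,
    batch_size: int = 8,
    lr: float = 1e-3,
) -> tuple[nn.Sequential, nn.Sequential, list[float]]:
    """Autoencoder pretraining of the context encoder (MSE reconstruction).

    ``tiles``: (N, 3, tile_size, tile_size) float32 in [0, 1]. Returns the
    trained encoder, decoder and the per-epoch mean reconstruction error; the
    encoder is frozen downstream (only the fc head trains with the
    classifier).
    """
    if len(tiles) == 0:
        raise ValueError("need at least one tile")
    config = config or PolymerEncoderConfig()
    encoder, decoder = build_polymer_autoencoder(config, seed=seed)
    params = encoder.params() + decoder.params()
    opt = nn.Adam(params, lr=lr)
    rng = np.random.default_rng(seed)
    history: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(len(tiles))
        errs = []
        for i in range(0, len(order), batch_size):
            xb = tiles[order[i : i + batch_size]]
            opt.zero_grad()
            z = encoder.forward(xb)
            recon = decoder.forward(z)
            diff = recon - xb
            errs.append(float(np.mean(diff**2)))
            dout = (2.0 / diff.size) * diff
            encoder.backward(decoder.backward(dout))
            opt.step()
        history.append(float(np.mean(errs)))
    return encoder, decoder, history


def encode_tiles(encoder: nn.Sequential, tiles: np.ndarray, batch_size: int = 16) -> np.ndarray:
    """Frozen-encoder bottleneck features, flattened (N, D)."""
    feats = []
    for i in range(0, len(tiles), batch_size):
        z = encoder.forward(tiles[i : i + batch_size])
        feats.append(z.reshape(z.shape[0], -1).copy())
    return np.concatenate(feats, axis=0)


def build_epsilon_head(config: PolymerEncoderConfig, seed: int = 0) -> nn.Sequential:
    """Two fully connected layers mapping bottleneck features to the eps logit."""
    rng = np.random.default_rng(seed)
    return nn.Sequential(
        nn.Linear(bottleneck_dim(config), config.fc_hidden, rng=rng),
        nn.ReLU(),
        nn.Linear(config.fc_hidden, 1, rng=rng),
    )


def compute_epsilon(head: nn.Sequential, features: np.ndarray) -> np.ndarray:
    """Raw smoothing weight eps = sigmoid(head(features)), strictly in (0,1)."""
    if features.ndim == 1:
        features = features[None]
    logit = head.forward(features)[:, 0]
    return np.asarray(nn.sigmoid(logit), dtype=np.float64)


def epsilon_prime(eps: np.ndarray | float) -> np.ndarray | float:
    """Effective dynamic smoothing weight eps' = 0.2 * eps, in (0, 0.2)."""
    return EPSILON_PRIME_FACTOR * np.asarray(eps, dtype=np.float64)
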