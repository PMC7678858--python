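"""Fully-convolutional phase-unwrapping network.

The first holographic reconstruction recovers the OPD only modulo λ.  This
module trains an image-to-image regression network that maps the wrapped
(L_recons, A_recons) pair to the unwrapped ground-truth pair.  The
architecture is a plain stack of n_blocks repetitions of
[5×5 convolution (n_features) → batch normalization → ReLU] closed by a 5×5
convolution with 2 output features (L and A); no pooling or striding, so the
network accepts any image size and preserves it.

The reference protocol trains the full network (20 blocks, 32 features) with
Adam at learning rate 1e-4 for 10 epochs of 12 800 random 121×121 vignettes;
a reduced network (6 blocks, 16 features) trained on a scaled-down
single/sparse-cell task is used throughout the test suite.  One network is
trained per sample-to-sensor distance Z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, BatchNorm2D, Conv2D, ReLU, Sequential, mse_loss
from .optics import SampleMaps
from .phantoms import TrainingPair

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "TrainedUnwrapper",
    "build_network",
    "expected_n_params",
    "train",
    "predict",
    "save_unwrapper",
    "load_unwrapper",
]

N_OUT_CHANNELS = 2  # L and A


@dataclass
class NetworkSpec:
    """Architecture of the unwrapping network."""

    n_blocks: int = 20
    kernel_size: int = 5
    n_features: int = 32
    scale: str = "full"   # "full" or "reduced"

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")

    @classmethod
    def reduced(cls) -> "NetworkSpec":
        return cls(n_blocks=6, kernel_size=5, n_features=16, scale="reduced")


@dataclass
class TrainConfig:
    """Training protocol settings (reference defaults)."""

    learning_rate: float = 1e-4
    n_epochs: int = 10
    vignettes_per_epoch: int = 12_800
    vignette_size: int = 121
    batch_size: int = 32
    seed: int = 0
    # per-channel normalization: L in units of λ, A already order-unity
    norm_L: float = 0.450
    norm_A: float = 1.0

    def __post_init__(self) -> None:
        for name in ("learning_rate", "n_epochs", "vignettes_per_epoch",
                     "vignette_size", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class TrainedUnwrapper:
    """A trained network plus everything needed to apply it."""

    model: Sequential
    spec: NetworkSpec
    train_config: TrainConfig
    training_Z: float
    loss_history: list[float] = field(default_factory=list)

    @property
    def receptive_field(self) -> int:
        return 1 + (self.spec.n_blocks + 1) * (self.spec.kernel_size - 1)


def build_network(spec: NetworkSpec, rng: np.random.Generator | None = None) -> Sequential:
    """Untrained network per the spec; input and output are 2-channel maps."""
    rng = rng or np.random.default_rng(0)
    layers: list = []
    c_in = N_OUT_CHANNELS
    for _ in range(spec.n_blocks):
        layers += [Conv2D(c_in, spec.n_features, spec.kernel_size, rng),
                   BatchNorm2D(spec.n_features), ReLU()]
        c_in = spec.n_features
    layers.append(Conv2D(c_in, N_OUT_CHANNELS, spec.kernel_size, rng))
    return Sequential(layers)


def expected_n_params(spec: NetworkSpec) -> int:
    """Closed-form trainable-parameter count: Σ k²·c_in·c_out + biases + BN γ,β."""
    k2 = spec.kernel_size ** 2
    n = 0
    c_in = N_OUT_CHANNELS
    for _ in range(spec.n_blocks):
        n += k2 * c_in * spec.n_features + spec.n_features      # conv W + b
        n += 2 * spec.n_features                                 # BN gamma, beta
        c_in = spec.n_features
    n += k2 * c_in * N_OUT_CHANNELS + N_OUT_CHANNELS            # final conv
    return n


def _stack(pairs: list[TrainingPair], cfg: TrainConfig):
    """Normalize vignette pairs into NCHW input/target tensors."""
    x = np.stack([np.stack([p.input.L / cfg.norm_L, p.input.A / cfg.norm_A])
                  for p in pairs])
    y = np.stack([np.stack([p.target.L / cfg.norm_L, p.target.A / cfg.norm_A])
                  for p in pairs])
    return x, y


def train(model: Sequential, vignette_source, config: TrainConfig,
          rng: np.random.Generator, training_Z: float = 1270.0,
          spec: NetworkSpec | None = None) -> TrainedUnwrapper:
    """Adam/MSE training on vignette pairs.

    ``vignette_source(n, rng) -> list[TrainingPair]`` supplies the vignettes
    of one epoch (typically fresh random crops of the simulated training
    images).  Per-epoch mean loss is logged; a NaN loss aborts, returning the
    last finite-loss state.
    """
    opt = Adam(model, lr=config.learning_rate)
    loss_history: list[float] = []
    checkpoint = model.state_dict()
    checkpoint = {k: v.copy() for k, v in checkpoint.items()}

    for epoch in range(config.n_epochs):
        pairs = vignette_source(config.vignettes_per_epoch, rng)
        x, y = _stack(pairs, config)
        order = rng.permutation(len(pairs))
        losses = []
        for start in range(0, len(pairs), config.batch_size):
            idx = order[start:start + config.batch_size]
            model.zero_grad()
            pred = model.forward(x[idx], training=True)
            loss, dloss = mse_loss(pred, y[idx])
            if not np.isfinite(loss):
                model.load_state_dict(checkpoint)
                unw = TrainedUnwrapper(model, spec or NetworkSpec(), config,
                                       training_Z, loss_history)
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}; "
                    f"restored last checkpoint ({len(loss_history)} epochs)")
            model.backward(dloss)
            opt.step()
            losses.append(loss)
        loss_history.append(float(np.mean(losses)))
        checkpoint = {k: v.copy() for k, v in model.state_dict().items()}

    return TrainedUnwrapper(model, spec or NetworkSpec(), config, training_Z,
                            loss_history)


def predict(unwrapper: TrainedUnwrapper, maps: SampleMaps) -> SampleMaps:
    """Unwrapped (L, A) prediction at the input resolution, physical units."""
    cfg = unwrapper.train_config
    k = unwrapper.spec.kernel_size
    if min(maps.shape) < k:
        raise ValueError("input smaller than the kernel footprint")
    x = np.stack([maps.L / cfg.norm_L, maps.A / cfg.norm_A])[None]
    out = unwrapper.model.forward(x, training=False)[0]
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("network produced non-finite output")
    return SampleMaps(out[0] * cfg.norm_L, out[1] * cfg.norm_A, maps.pixel_pitch)


def save_unwrapper(unwrapper: TrainedUnwrapper, path: str) -> None:
    """Serialize weights + spec + normalization + training_Z to an .npz file."""
    meta = dict(
        n_blocks=unwrapper.spec.n_blocks,
        kernel_size=unwrapper.spec.kernel_size,
        n_features=unwrapper.spec.n_features,
        scale=unwrapper.spec.scale,
        norm_L=unwrapper.train_config.norm_L,
        norm_A=unwrapper.train_config.norm_A,
        learning_rate=unwrapper.train_config.learning_rate,
        n_epochs=unwrapper.train_config.n_epochs,
        vignettes_per_epoch=unwrapper.train_config.vignettes_per_epoch,
        vignette_size=unwrapper.train_config.vignette_size,
        batch_size=unwrapper.train_config.batch_size,
        seed=unwrapper.train_config.seed,
        training_Z=unwrapper.training_Z,
    )
    arrays = {f"w/{k}": v for k, v in unwrapper.model.state_dict().items()}
    np.savez(path, loss_history=np.asarray(unwrapper.loss_history),
             **{f"meta/{k}": np.asarray(v) for k, v in meta.items()},
             **arrays)


def load_unwrapper(path: str) -> TrainedUnwrapper:
    data = np.load(path, allow_pickle=False)
    def m(key, cast=float):
        return cast(data[f"meta/{key}"])
    spec = NetworkSpec(n_blocks=m("n_blocks", int), kernel_size=m("kernel_size", int),
                       n_features=m("n_features", int),
                       scale=str(data["meta/scale"]))
    cfg = TrainConfig(learning_rate=m("learning_rate"), n_epochs=m("n_epochs", int),
                      vignettes_per_epoch=m("vignettes_per_epoch", int),
                      vignette_size=m("vignette_size", int),
                      batch_size=m("batch_size", int), seed=m("seed", int),
                      norm_L=m("norm_L"), norm_A=m("norm_A"))
    model = build_network(spec)
    model.load_state_dict({k[2:]: data[k] for k in data.files if k.startswith("w/")})
    return TrainedUnwrapper(model, spec, cfg, m("training_Z"),
                            list(data["loss_history"]))
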