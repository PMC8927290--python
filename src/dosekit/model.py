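"""Trainable dose-prediction model.

The predictor maps each voxel's multi-scale feature vector — the raw
input channels (CT, ROI masks, optional beam mask) plus Gaussian-smoothed
copies of every channel at two spatial scales, which give the voxel local
and regional anatomical context — through a small fully connected network
to a dose value.  Training minimizes voxelwise mean absolute error with
Adam on seeded minibatches of voxels stratified over body, PTV and OAR
regions.  Everything is plain numpy and fully deterministic under (seed,
config), which makes run-to-run bit reproducibility and warm-start
fine-tuning (continue from a saved bundle's weights) straightforward.

The network is a stand-in at desk scale: the experiments this package
runs concern training-data selection, not architecture, so the model only
needs to be able to learn the anatomy-and-beam-setting -> dose mapping of
the synthetic catalog, and its capacity/feature scales are configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .data_prep import TrainingSample

__all__ = [
    "ModelConfig",
    "ModelBundle",
    "extract_features",
    "init_model",
    "train_model",
    "finetune",
    "predict_dose",
    "mae",
]


@dataclass(frozen=True)
class ModelConfig:
    """Model and optimizer hyperparameters.

    ``hidden`` are the fully connected layer widths; ``smoothing_sigmas``
    the Gaussian feature scales in voxels; ``voxels_per_case`` how many
    voxels per training case enter the (stratified) training matrix.
    """

    hidden: tuple[int, ...] = (32, 32)
    smoothing_sigmas: tuple[float, ...] = (2.0, 6.0)
    epochs: int = 20
    learning_rate: float = 3e-3
    batch_size: int = 2048
    #: optimizer batches drawn per epoch; fixed so every design gets the
    #: same optimization budget regardless of its training-set size
    steps_per_epoch: int = 50
    voxels_per_case: int = 4000

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if not self.hidden:
            raise ValueError("need at least one hidden layer")


def extract_features(sample: TrainingSample, sigmas) -> np.ndarray:
    """Per-voxel feature matrix ``(n_voxels, n_features)``.

    Features are every input channel, a Gaussian-smoothed copy per scale
    in ``sigmas`` (sigma in voxels, isotropic in index space), and the
    voxel's room-frame coordinates normalized to [-1, 1].  The coordinate
    features give the network the fixed-gantry-frame spatial awareness a
    convolutional predictor has: learned dose patterns are tied to room
    position, so anatomy presented in an unfamiliar orientation (e.g. a
    prone patient after supine-only training) is out of distribution.
    """
    feats = [ch.astype(float) for ch in sample.channels]
    for sigma in sigmas:
        feats.extend(gaussian_filter(ch.astype(float), sigma) for ch in sample.channels)
    center = sample.grid.center_mm()
    half = np.maximum(np.asarray(sample.grid.extent_mm) / 2.0, 1e-9)
    coords = (sample.grid.voxel_centers() - center) / half
    feats.extend(coords[..., a] for a in range(3))
    return np.stack([f.ravel() for f in feats], axis=1)


def _stratified_voxels(sample: TrainingSample, n: int, rng) -> np.ndarray:
    """Seeded voxel subsample: quarters from the PTV, the OAR union, the
    body, and the whole volume, so dosimetrically relevant regions are
    well represented while out-of-body voxels still anchor the zero level."""
    nvox = sample.dose_gy.size
    everywhere = np.arange(nvox)
    body = np.flatnonzero(sample.channel("body").ravel() > 0.5)
    ptv = np.flatnonzero(sample.channel("ptv").ravel() > 0.5)
    oars = np.zeros(nvox, dtype=bool)
    for name in ("bladder", "rectum", "spinal_cord", "femoral_head_l", "femoral_head_r"):
        oars |= sample.channel(name).ravel() > 0.5
    oar_idx = np.flatnonzero(oars)
    pools = [
        (everywhere, n - 3 * (n // 4)),
        (body if len(body) else everywhere, n // 4),
        (ptv if len(ptv) else body, n // 4),
        (oar_idx if len(oar_idx) else body, n // 4),
    ]
    picks = [rng.choice(pool, size=k, replace=len(pool) < k) for pool, k in pools]
    return np.concatenate(picks)


def _init_weights(n_in: int, hidden, rng) -> list:
    """He-initialized fully connected stack with a small linear head."""
    sizes = [n_in, *hidden, 1]
    layers = []
    for i in range(len(sizes) - 1):
        scale = np.sqrt(2.0 / sizes[i])
        if i == len(sizes) - 2:
            scale *= 0.1  # small head: untrained model predicts near zero
        layers.append(
            (rng.normal(0.0, scale, (sizes[i], sizes[i + 1])), np.zeros(sizes[i + 1]))
        )
    return layers


def _forward(weights, X):
    h = X
    acts = [h]
    for W, b in weights[:-1]:
        h = np.maximum(h @ W + b, 0.0)
        acts.append(h)
    W, b = weights[-1]
    return (h @ W + b)[:, 0], acts


def _backward(weights, acts, grad_out):
    grads = []
    g = grad_out[:, None]
    for i in range(len(weights) - 1, -1, -1):
        W, _ = weights[i]
        grads.append((acts[i].T @ g, g.sum(axis=0)))
        if i > 0:
            g = (g @ W.T) * (acts[i] > 0)
    return grads[::-1]


@dataclass
class ModelBundle:
    """Trained network weights plus everything needed to reuse them.

    ``scaler`` holds the per-feature mean/SD frozen at first training so a
    fine-tuned model sees identically scaled features; ``loss_log`` has
    one mean-absolute-error entry per epoch.
    """

    weights: list
    config: ModelConfig
    scaler: tuple[np.ndarray, np.ndarray]
    loss_log: list[float]
    seed: int
    channel_names: tuple[str, ...]
    adam_state: dict = field(default_factory=dict)

    def copy(self) -> "ModelBundle":
        return ModelBundle(
            weights=[(W.copy(), b.copy()) for W, b in self.weights],
            config=self.config,
            scaler=(self.scaler[0].copy(), self.scaler[1].copy()),
            loss_log=list(self.loss_log),
            seed=self.seed,
            channel_names=self.channel_names,
        )

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for i, (W, b) in enumerate(self.weights):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        arrays["scaler_mean"], arrays["scaler_sd"] = self.scaler
        np.savez(directory / "weights.npz", **arrays)
        meta = {
            "config": {
                **{k: getattr(self.config, k) for k in (
                    "epochs", "learning_rate", "batch_size", "steps_per_epoch",
                    "voxels_per_case")},
                "hidden": list(self.config.hidden),
                "smoothing_sigmas": list(self.config.smoothing_sigmas),
            },
            "loss_log": self.loss_log,
            "seed": self.seed,
            "channel_names": list(self.channel_names),
            "n_layers": len(self.weights),
        }
        (directory / "bundle.json").write_text(json.dumps(meta, indent=1))
        return directory

    @classmethod
    def load(cls, directory) -> "ModelBundle":
        directory = Path(directory)
        meta = json.loads((directory / "bundle.json").read_text())
        data = np.load(directory / "weights.npz")
        weights = [
            (data[f"W{i}"], data[f"b{i}"]) for i in range(meta["n_layers"])
        ]
        cfg = meta["config"]
        config = ModelConfig(
            hidden=tuple(cfg["hidden"]),
            smoothing_sigmas=tuple(cfg["smoothing_sigmas"]),
            epochs=cfg["epochs"],
            learning_rate=cfg["learning_rate"],
            batch_size=cfg["batch_size"],
            steps_per_epoch=cfg["steps_per_epoch"],
            voxels_per_case=cfg["voxels_per_case"],
        )
        return cls(
            weights=weights,
            config=config,
            scaler=(data["scaler_mean"], data["scaler_sd"]),
            loss_log=list(meta["loss_log"]),
            seed=meta["seed"],
            channel_names=tuple(meta["channel_names"]),
        )


def _check_channels(samples) -> tuple[str, ...]:
    if not samples:
        raise ValueError("no training samples given")
    names = samples[0].channel_names
    for s in samples[1:]:
        if s.channel_names != names:
            raise ValueError(
                f"inconsistent channel layout: {s.channel_names} vs {names}"
            )
    return names


def _training_matrix(samples, config: ModelConfig, rng):
    Xs, ys = [], []
    for s in samples:
        feats = extract_features(s, config.smoothing_sigmas)
        idx = _stratified_voxels(s, config.voxels_per_case, rng)
        Xs.append(feats[idx])
        ys.append(s.dose_gy.ravel()[idx].astype(float))
    return np.concatenate(Xs), np.concatenate(ys)


def init_model(samples, config: ModelConfig, seed: int) -> ModelBundle:
    """Untrained bundle: seeded weights plus a feature scaler fitted on
    ``samples`` (the scaler is frozen for the bundle's whole life)."""
    names = _check_channels(samples)
    rng = np.random.default_rng(seed)
    X, _ = _training_matrix(samples, config, np.random.default_rng(seed + 1))
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    weights = _init_weights(X.shape[1], config.hidden, rng)
    return ModelBundle(
        weights=weights,
        config=config,
        scaler=(mean, sd),
        loss_log=[],
        seed=seed,
        channel_names=names,
    )


def _train_in_place(bundle: ModelBundle, samples, config: ModelConfig, seed: int):
    rng = np.random.default_rng(seed + 2)
    X, y = _training_matrix(samples, config, np.random.default_rng(seed + 1))
    X = (X - bundle.scaler[0]) / bundle.scaler[1]
    weights = bundle.weights
    # Adam state
    m = [(np.zeros_like(W), np.zeros_like(b)) for W, b in weights]
    v = [(np.zeros_like(W), np.zeros_like(b)) for W, b in weights]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    n = len(X)
    for _ in range(config.epochs):
        for _step in range(config.steps_per_epoch):
            batch = rng.integers(0, n, size=min(config.batch_size, n))
            xb, yb = X[batch], y[batch]
            pred, acts = _forward(weights, xb)
            g_out = np.sign(pred - yb) / len(batch)  # d(MAE)/d(pred)
            grads = _backward(weights, acts, g_out)
            t += 1
            lr_t = config.learning_rate * np.sqrt(1 - beta2**t) / (1 - beta1**t)
            for i, ((gW, gb), (W, b)) in enumerate(zip(grads, weights)):
                mW, mb = m[i]
                vW, vb = v[i]
                mW[:] = beta1 * mW + (1 - beta1) * gW
                mb[:] = beta1 * mb + (1 - beta1) * gb
                vW[:] = beta2 * vW + (1 - beta2) * gW**2
                vb[:] = beta2 * vb + (1 - beta2) * gb**2
                weights[i] = (
                    W - lr_t * mW / (np.sqrt(vW) + eps),
                    b - lr_t * mb / (np.sqrt(vb) + eps),
                )
        pred, _ = _forward(weights, X)
        bundle.loss_log.append(float(np.abs(pred - y).mean()))
    return bundle


def train_model(samples, config: ModelConfig | None = None, seed: int = 0) -> ModelBundle:
    """Train a dose predictor from scratch; deterministic under (seed, config)."""
    config = config or ModelConfig()
    if len(samples) < 2:
        raise ValueError(f"need at least 2 training samples, got {len(samples)}")
    bundle = init_model(samples, config, seed)
    return _train_in_place(bundle, samples, config, seed)


def finetune(
    base: ModelBundle,
    samples,
    config: ModelConfig | None = None,
    seed: int | None = None,
) -> ModelBundle:
    """Continue training from ``base``'s weights on a (sub)set of samples.

    The base's architecture and feature scaler are kept; ``config`` may
    change only the optimization settings (epochs, learning rate, batch
    size, voxel budget).  Zero epochs returns an identical copy.
    """
    config = config or base.config
    if config.hidden != base.config.hidden or config.smoothing_sigmas != base.config.smoothing_sigmas:
        raise ValueError("finetune cannot change the architecture or feature scales")
    names = _check_channels(samples)
    if names != base.channel_names:
        raise ValueError(
            f"channel layout {names} does not match the base model {base.channel_names}"
        )
    out = base.copy()
    out.config = config
    if config.epochs == 0:
        return out
    return _train_in_place(out, samples, config, base.seed if seed is None else seed)


def predict_dose(bundle: ModelBundle, sample: TrainingSample) -> np.ndarray:
    """Predict the full dose volume for one sample (clipped at 0 Gy)."""
    if sample.channel_names != bundle.channel_names:
        raise ValueError(
            f"channel layout {sample.channel_names} does not match model "
            f"{bundle.channel_names}"
        )
    X = extract_features(sample, bundle.config.smoothing_sigmas)
    X = (X - bundle.scaler[0]) / bundle.scaler[1]
    pred, _ = _forward(bundle.weights, X)
    return np.maximum(pred, 0.0).reshape(sample.grid.shape)


def mae(bundle: ModelBundle, samples) -> float:
    """Mean absolute voxel error of the model over ``samples``."""
    errs = [
        float(np.abs(predict_dose(bundle, s) - s.dose_gy).mean()) for s in samples
    ]
    return float(np.mean(errs))
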