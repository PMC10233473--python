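"""Recurrent convolutional background-removal network (M-PReNet).

A progressive recurrent restoration network mapping epi-illumination images
to light-sheet-like images.  One shared parameter set is applied over T
stages; each stage concatenates the original input with the previous
stage's output and passes it through four blocks:

* ``f_in``   — batch normalization, 3x3 convolution, ReLU (the BN on the
  raw 2-channel input lets the network learn its own input scaling);
* ``f_lstm`` — a convolutional LSTM cell whose hidden/cell state persists
  across stages;
* ``f_res``  — five stacked residual blocks (conv-ReLU-conv + skip);
* ``f_out``  — a 1x1 convolution back to one channel.

Training minimizes the mean-squared error of the final stage's output
against the light-sheet target with Adam.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import _autodiff as ad
from .dataset import NormAffine, TrainingPatch, normalize_patch

__all__ = [
    "MPReNetConfig",
    "MPReNet",
    "build_model",
    "forward",
    "mse_loss",
    "train",
    "predict_large",
    "save_model",
    "load_model",
]


@dataclass
class MPReNetConfig:
    """Architecture and optimizer settings.

    Optimizer defaults are the published Adam settings (lr 1e-3, beta1 0.9,
    beta2 0.999, eps 1e-8, batch 128); ``n_stages``/``n_channels`` default
    to the customary 6/32 of the progressive recurrent design and are fully
    configurable.  ``desk()`` gives a CPU-scale profile for tests and demos.
    """

    n_stages: int = 6
    n_channels: int = 32
    n_resblocks: int = 5
    global_residual: bool = False  # stage output added to the input image
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    batch_size: int = 128
    n_epochs: int = 100
    seed: int = 0
    norm_source: str = "target"
    lo_pct: float = 0.1
    hi_pct: float = 99.9

    def __post_init__(self) -> None:
        if self.n_stages < 1:
            raise ValueError("n_stages must be >= 1")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.lr < 0:
            raise ValueError("lr must be non-negative")
        if not 0 < self.beta1 < self.beta2 < 1:
            raise ValueError("need 0 < beta1 < beta2 < 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    @classmethod
    def desk(cls, **overrides) -> "MPReNetConfig":
        base = dict(n_stages=3, n_channels=16, batch_size=16, n_epochs=10)
        base.update(overrides)
        return cls(**base)


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = int(np.prod(shape[1:]))
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class MPReNet:
    """The four shared blocks plus their BN running statistics.

    The same parameter set is reused at every recurrence stage, so the
    parameter count is independent of ``n_stages``.
    """

    def __init__(self, config: MPReNetConfig, seed: int | None = None):
        self.config = config
        self.norm_tag = config.norm_source
        # optional fixed input normalization (photon units); when set, the
        # same affine is used at inference so amplitudes stay faithful
        self.input_affine: NormAffine | None = None
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
        c = config.n_channels
        rng = np.random.default_rng(config.seed if seed is None else seed)
        p = {}
        # f_in: BN over the 2-channel concat, then 3x3 conv -> C, ReLU
        p["fin_bn_gamma"] = ad.parameter(np.ones(2, np.float32))
        p["fin_bn_beta"] = ad.parameter(np.zeros(2, np.float32))
        p["fin_conv_w"] = ad.parameter(_kaiming(rng, (c, 2, 3, 3)))
        p["fin_conv_b"] = ad.parameter(np.zeros(c, np.float32))
        # f_lstm: one conv producing the 4 gates from [x, h]
        p["lstm_w"] = ad.parameter(_kaiming(rng, (4 * c, 2 * c, 3, 3)))
        p["lstm_b"] = ad.parameter(np.zeros(4 * c, np.float32))
        # f_res: stacked residual blocks
        for i in range(config.n_resblocks):
            p[f"res{i}_w1"] = ad.parameter(_kaiming(rng, (c, c, 3, 3)))
            p[f"res{i}_b1"] = ad.parameter(np.zeros(c, np.float32))
            p[f"res{i}_w2"] = ad.parameter(_kaiming(rng, (c, c, 3, 3)))
            p[f"res{i}_b2"] = ad.parameter(np.zeros(c, np.float32))
        # f_out: 1x1 conv back to a single channel
        p["fout_w"] = ad.parameter(_kaiming(rng, (1, c, 1, 1)))
        p["fout_b"] = ad.parameter(np.zeros(1, np.float32))
        self.params = p
        self.bn_state = ad.BatchNormState(2)

    # -- plumbing ----------------------------------------------------------
    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())

    @property
    def receptive_radius(self) -> int:
        """Radius (px) outside which a pixel cannot influence the output:
        one px per 3x3 convolution, accumulated over all stages."""
        per_stage = 1 + 1 + 2 * self.config.n_resblocks  # f_in, lstm, f_res
        return self.config.n_stages * per_stage

    def parameters(self):
        return list(self.params.values())

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {k: v.data.copy() for k, v in self.params.items()}
        out["_bn_running_mean"] = self.bn_state.running_mean.copy()
        out["_bn_running_var"] = self.bn_state.running_var.copy()
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = state[k].astype(np.float32).copy()
        self.bn_state.running_mean = state["_bn_running_mean"].astype(np.float32).copy()
        self.bn_state.running_var = state["_bn_running_var"].astype(np.float32).copy()

    # -- forward -----------------------------------------------------------
    def _stage(self, x, prev, h, c_state, training):
        p = self.params
        z = ad.concat_channels([x, prev])
        z = ad.batchnorm2d(z, p["fin_bn_gamma"], p["fin_bn_beta"], self.bn_state, training)
        z = ad.relu(ad.conv2d(z, p["fin_conv_w"], p["fin_conv_b"]))
        gates = ad.conv2d(ad.concat_channels([z, h]), p["lstm_w"], p["lstm_b"])
        nc = self.config.n_channels
        i_g = ad.sigmoid(ad.slice_channels(gates, 0, nc))
        f_g = ad.sigmoid(ad.slice_channels(gates, nc, 2 * nc))
        o_g = ad.sigmoid(ad.slice_channels(gates, 2 * nc, 3 * nc))
        g_g = ad.tanh(ad.slice_channels(gates, 3 * nc, 4 * nc))
        c_state = ad.add(ad.mul(f_g, c_state), ad.mul(i_g, g_g))
        h = ad.mul(o_g, ad.tanh(c_state))
        z = h
        for i in range(self.config.n_resblocks):
            inner = ad.relu(ad.conv2d(z, p[f"res{i}_w1"], p[f"res{i}_b1"]))
            inner = ad.conv2d(inner, p[f"res{i}_w2"], p[f"res{i}_b2"])
            z = ad.relu(ad.add(z, inner))
        out = ad.conv2d(z, p["fout_w"], p["fout_b"])
        if self.config.global_residual:
            # hook: the stage predicts a correction (e.g. minus the
            # background) added to the original input
            out = ad.add(x, out)
        return out, h, c_state

    def forward_tensor(self, x: "ad.Tensor", training: bool = False) -> "ad.Tensor":
        n, _, hh, ww = x.shape
        nc = self.config.n_channels
        h = ad.constant(np.zeros((n, nc, hh, ww), np.float32))
        c_state = ad.constant(np.zeros((n, nc, hh, ww), np.float32))
        pred = x
        for _ in range(self.config.n_stages):
            pred, h, c_state = self._stage(x, pred, h, c_state, training)
        return pred

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Run the recurrence on one image or an (N, H, W) batch."""
        x = np.asarray(x, np.float32)
        if not np.all(np.isfinite(x)):
            raise ValueError("input contains non-finite values")
        squeeze = x.ndim == 2
        if squeeze:
            x = x[None]
        out = self.forward_tensor(ad.constant(x[:, None]), training).data[:, 0]
        return out[0] if squeeze else out

    __call__ = forward


def build_model(config: MPReNetConfig, seed: int | None = None) -> MPReNet:
    """Seeded deterministic construction of an untrained network."""
    return MPReNet(config, seed=seed)


def forward(model: MPReNet, x: np.ndarray) -> np.ndarray:
    """Evaluation-mode forward pass (BN uses running statistics)."""
    return model.forward(x, training=False)


def mse_loss(prediction: np.ndarray, target: np.ndarray) -> float:
    """Mean of squared pixel differences."""
    prediction = np.asarray(prediction, float)
    target = np.asarray(target, float)
    if prediction.shape != target.shape:
        raise ValueError("prediction and target must share a shape")
    return float(np.mean((prediction - target) ** 2))


def _as_batches(patches: list[TrainingPatch]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([p.input_img for p in patches]).astype(np.float32)[:, None]
    y = np.stack([p.target_img for p in patches]).astype(np.float32)[:, None]
    return x, y


def train(
    model: MPReNet,
    train_set: list[TrainingPatch],
    val_set: list[TrainingPatch] | None = None,
    config: MPReNetConfig | None = None,
    max_iterations: int | None = None,
) -> MPReNet:
    """Adam training on the final-stage MSE; returns the best-validation model.

    Shuffling is seeded from the config; per-epoch train/val losses are
    appended to ``model.history``.  ``max_iterations`` caps the total number
    of optimizer steps (desk-scale profile).
    """
    if not train_set:
        raise ValueError("training set is empty")
    config = config or model.config
    x_all, y_all = _as_batches(train_set)
    xv, yv = _as_batches(val_set) if val_set else (None, None)
    opt = ad.Adam(
        model.parameters(), config.lr, config.beta1, config.beta2, config.epsilon
    )
    rng = np.random.default_rng(config.seed + 1)
    best_val = np.inf
    best_state = model.state_arrays()
    iters = 0
    n = x_all.shape[0]
    bs = min(config.batch_size, n)
    for _epoch in range(config.n_epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            xb = ad.constant(x_all[idx])
            yb = ad.constant(y_all[idx])
            opt.zero_grad()
            pred = model.forward_tensor(xb, training=True)
            loss = ad.mse(pred, yb)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at iteration {iters}"
                )
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
            iters += 1
            if max_iterations is not None and iters >= max_iterations:
                break
        model.history["train_loss"].append(float(np.mean(epoch_losses)))
        if xv is not None:
            vpred = model.forward_tensor(ad.constant(xv), training=False)
            vloss = mse_loss(vpred.data, yv)
            model.history["val_loss"].append(vloss)
            if vloss < best_val:
                best_val = vloss
                best_state = model.state_arrays()
        else:
            best_state = model.state_arrays()
        if max_iterations is not None and iters >= max_iterations:
            break
    model.load_state_arrays(best_state)
    return model


def predict_large(
    model: MPReNet,
    image: np.ndarray,
    tile: int = 256,
    overlap: int = 32,
    affine: NormAffine | None = None,
) -> np.ndarray:
    """Tiled inference on an arbitrarily large field.

    The input is normalized with the dataset percentile convention (or an
    explicit affine), processed in overlapping tiles and mapped back to the
    input intensity scale.  Each tile contributes only pixels at least a
    receptive-field margin away from its borders (those are exact for the
    fully convolutional network); contributions are blended with a linear
    feather across the remaining overlap.  Images no larger than ``tile``
    get a single full-frame pass.
    """
    if tile <= 2 * overlap:
        raise ValueError("tile must exceed twice the overlap")
    if tile < 16:
        raise ValueError("tile smaller than the network minimum")
    image = np.asarray(image, float)
    h, w = image.shape
    if affine is None:
        norm, affine = normalize_patch(image, model.config.lo_pct, model.config.hi_pct)
    else:
        norm = affine.apply(image)
    if h <= tile and w <= tile:
        return affine.invert(model.forward(norm.astype(np.float32)))

    margin = min(overlap // 2, model.receptive_radius)
    blend = max(overlap - 2 * margin, 1)
    out = np.zeros((h, w), float)
    weight = np.zeros((h, w), float)
    step = tile - overlap

    def feather(n0, n, total):
        d = np.arange(n, dtype=float)
        wgt = np.minimum(
            np.clip((d - margin + 1) / blend, 0.0, 1.0),
            np.clip((n - 1 - d - margin + 1) / blend, 0.0, 1.0),
        )
        if n0 == 0:
            wgt[: margin + blend] = 1.0
        if n0 + n >= total:
            wgt[-(margin + blend) :] = 1.0
        return wgt

    for r0 in range(0, max(h - overlap, 1), step):
        r0 = min(r0, max(h - tile, 0))
        rn = min(tile, h - r0)
        for c0 in range(0, max(w - overlap, 1), step):
            c0 = min(c0, max(w - tile, 0))
            cn = min(tile, w - c0)
            patch = norm[r0 : r0 + rn, c0 : c0 + cn].astype(np.float32)
            pred = model.forward(patch)
            wgt = np.outer(feather(r0, rn, h), feather(c0, cn, w))
            out[r0 : r0 + rn, c0 : c0 + cn] += pred * wgt
            weight[r0 : r0 + rn, c0 : c0 + cn] += wgt
            if c0 + tile >= w:
                break
        if r0 + tile >= h:
            break
    return affine.invert(out / np.maximum(weight, 1e-12))


def save_model(model: MPReNet, path) -> None:
    """Single-file checkpoint: parameters + config + normalization record."""
    state = model.state_arrays()
    state["_config_json"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8
    )
    if model.input_affine is not None:
        state["_input_affine"] = np.array(
            [
                model.input_affine.lo,
                model.input_affine.hi,
                float(model.input_affine.clip),
            ]
        )
    np.savez(path, **state)


def load_model(path) -> MPReNet:
    with np.load(path) as data:
        cfg = MPReNetConfig(**json.loads(bytes(data["_config_json"]).decode()))
        model = MPReNet(cfg)
        extras = {"_config_json", "_input_affine"}
        state = {k: data[k] for k in data.files if k not in extras}
        model.load_state_arrays(state)
        if "_input_affine" in data.files:
            lo, hi, clip = data["_input_affine"]
            model.input_affine = NormAffine(float(lo), float(hi), clip=bool(clip))
    return model
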