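"""Compact residual CNN with a fuzzy scoring output stage.

The network is a small, self-contained numpy implementation (explicit
im2col convolutions, hand-written reverse pass, Adam updates): three
strided convolutions, one cascaded residual block whose inner
convolutions may receive all preceding inputs (dense intra-block
wiring), global average pooling, and a fully connected head emitting
per-class energies E (negative logits, so P = softmax(-E)).

With the fuzzy head enabled, the output-layer error signal is the
plain error modulated per sample by the true class's window-centroid
distance |i - V0|, normalized to unit maximum: confident samples
contribute a damped signal, ambiguous and misclassified ones a full
one. The modulation ramps in over the first fifth of the schedule
(early training has no confident samples to damp). Hidden layers
backpropagate the modulated signal unchanged. Training is fully
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fswolf.fuzzy import (
    FuzzyScoringConfig,
    GaussianMemberships,
    fit_gaussian_memberships,
    redistributed_vector,
    tune_memberships_grid,
    window_centroid,
)

__all__ = [
    "ConvSpec",
    "ResidualBlockSpec",
    "NetworkConfig",
    "Conv2d",
    "ResidualBlock",
    "residual_forward",
    "FSResNet",
    "build_fs_resnet",
    "train_fs_resnet",
    "predict",
]


@dataclass
class ConvSpec:
    filters: int
    kernel: int
    stride: int = 1


@dataclass
class ResidualBlockSpec:
    """Residual mapping F plus shortcut kind.

    ``dense`` wires every inner convolution to the concatenation of the
    block input and all preceding convolution outputs. The shortcut is
    the identity when input and output channels match, else a 1x1
    linear projection W_s.
    """

    inner: list[ConvSpec] = field(default_factory=lambda: [ConvSpec(16, 3), ConvSpec(16, 3)])
    shortcut: str = "identity"  # "identity" | "projection"
    dense: bool = True


@dataclass
class NetworkConfig:
    """Architecture and optimizer settings of the FS-ResNet."""

    input_side: int = 64
    input_channels: int = 3
    # stride-1 first stage: dyadic downsampling before the first nonlinearity
    # aliases the high-frequency texture energy that separates the classes
    convs: list[ConvSpec] = field(
        default_factory=lambda: [ConvSpec(8, 5, 1), ConvSpec(12, 3, 2), ConvSpec(16, 3, 2)]
    )
    block: ResidualBlockSpec = field(default_factory=ResidualBlockSpec)
    m: int = 2
    learning_rate: float = 1e-3
    batch_size: int = 16
    weight_decay: float = 1e-4
    epochs: int = 25
    seed: int = 0
    restore_best: bool = False  # restore the best-validation-epoch parameters
    dtype: str = "float32"  # compute/parameter precision of the network
    # fraction of the schedule over which the fuzzy modulation ramps in;
    # the damping concerns confident samples, which do not exist early on
    fuzzy_warmup_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("need at least two classes")


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _im2col_indices(C: int, H: int, W: int, k: int, stride: int, pad: int):
    out_h = (H + 2 * pad - k) // stride + 1
    out_w = (W + 2 * pad - k) // stride + 1
    if out_h < 1 or out_w < 1:
        raise ValueError("kernel larger than padded input")
    i0 = np.tile(np.repeat(np.arange(k), k), C)
    j0 = np.tile(np.arange(k), k * C)
    i1 = stride * np.repeat(np.arange(out_h), out_w)
    j1 = stride * np.tile(np.arange(out_w), out_h)
    i = i0[:, None] + i1[None, :]
    j = j0[:, None] + j1[None, :]
    ch = np.repeat(np.arange(C), k * k)[:, None]
    return ch, i, j, out_h, out_w


class Conv2d:
    """2-D convolution (NCHW) with same-style padding k//2 and He init."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int, rng, dtype=np.float32):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride = kernel, stride
        self.pad = kernel // 2
        self.dtype = np.dtype(dtype)
        fan_in = in_ch * kernel * kernel
        self.W = (rng.standard_normal((out_ch, fan_in)) * np.sqrt(2.0 / fan_in)).astype(self.dtype)
        self.b = np.zeros(out_ch, dtype=self.dtype)
        self._idx_cache: dict[tuple, tuple] = {}
        self._fwd = None

    def params(self):
        return {"W": self.W, "b": self.b}

    def _indices(self, H: int, W: int):
        key = (H, W)
        if key not in self._idx_cache:
            self._idx_cache[key] = _im2col_indices(
                self.in_ch, H, W, self.kernel, self.stride, self.pad
            )
        return self._idx_cache[key]

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        if C != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {C}")
        ch, i, j, out_h, out_w = self._indices(H, W)
        x = x.astype(self.dtype, copy=False)
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        cols = xp[:, ch, i, j]  # (N, C*k*k, L)
        y = np.matmul(self.W, cols) + self.b[None, :, None]
        self._fwd = (x.shape, cols)
        return y.reshape(N, self.out_ch, out_h, out_w)

    def backward(self, dy: np.ndarray):
        (x_shape, cols) = self._fwd
        N, C, H, W = x_shape
        ch, i, j, out_h, out_w = self._indices(H, W)
        dy_flat = dy.astype(self.dtype, copy=False).reshape(N, self.out_ch, -1)
        dW = np.einsum("nol,nkl->ok", dy_flat, cols)
        db = dy_flat.sum(axis=(0, 2))
        dcols = np.matmul(self.W.T, dy_flat)
        dxp = np.zeros((N, C, H + 2 * self.pad, W + 2 * self.pad), dtype=self.dtype)
        np.add.at(dxp, (np.arange(N)[:, None, None], ch, i, j), dcols)
        dx = (
            dxp[:, :, self.pad : self.pad + H, self.pad : self.pad + W]
            if self.pad
            else dxp
        )
        return dx, {"W": dW, "b": db}

    def out_side(self, side: int) -> int:
        return (side + 2 * self.pad - self.kernel) // self.stride + 1


class ResidualBlock:
    """y = relu(F(x) + shortcut(x)) with optional dense intra-block wiring."""

    def __init__(self, channels: int, spec: ResidualBlockSpec, rng, dtype=np.float32):
        self.spec = spec
        self.channels = channels
        self.convs: list[Conv2d] = []
        in_ch = channels
        for k, cs in enumerate(spec.inner):
            if cs.stride != 1:
                raise ValueError("residual block convolutions must be stride 1")
            self.convs.append(Conv2d(in_ch, cs.filters, cs.kernel, 1, rng, dtype))
            in_ch = channels + cs.filters if spec.dense else cs.filters
        out_ch = spec.inner[-1].filters
        if spec.shortcut == "identity":
            if out_ch != channels:
                raise ValueError(
                    "identity shortcut requires matching channels; use a projection"
                )
            self.proj = None
        elif spec.shortcut == "projection":
            self.proj = Conv2d(channels, out_ch, 1, 1, rng, dtype)
        else:
            raise ValueError("shortcut must be 'identity' or 'projection'")
        self._fwd = None

    def layers(self):
        out = list(self.convs)
        if self.proj is not None:
            out.append(self.proj)
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = x
        acts = []  # per inner conv: (input, pre-activation) for the backward pass
        for k, conv in enumerate(self.convs):
            pre = conv.forward(h)
            acts.append(pre)
            if k < len(self.convs) - 1:
                r = _relu(pre)
                h = np.concatenate([x, r], axis=1) if self.spec.dense else r
            else:
                h = pre  # F(x): no nonlinearity before the addition
        shortcut = x if self.proj is None else self.proj.forward(x)
        out_pre = h + shortcut
        self._fwd = (x, acts, out_pre)
        return _relu(out_pre)

    def backward(self, dy: np.ndarray):
        x, acts, out_pre = self._fwd
        grads: dict[str, np.ndarray] = {}
        dpre = dy * (out_pre > 0)
        if self.proj is None:
            dx = dpre.copy()
        else:
            dx, g = self.proj.backward(dpre)
            grads["proj"] = g
        dh = dpre
        for k in range(len(self.convs) - 1, -1, -1):
            if k < len(self.convs) - 1:
                # dh is the gradient at this conv's post-relu (possibly concat) output
                if self.spec.dense:
                    dx += dh[:, : self.channels]
                    dh = dh[:, self.channels :]
                dh = dh * (acts[k] > 0)
            din, g = self.convs[k].backward(dh)
            grads[f"conv{k}"] = g
            dh = din
        dx += dh
        return dx, grads


def residual_forward(x: np.ndarray, block: ResidualBlock) -> np.ndarray:
    """Functional residual mapping: relu(F(x) + shortcut(x)).

    Accepts (C,H,W) or (N,C,H,W) activation tensors.
    """
    arr = np.asarray(x, dtype=np.float64)
    single = arr.ndim == 3
    if single:
        arr = arr[None]
    out = block.forward(arr)
    return out[0] if single else out


class _Adam:
    def __init__(self, lr: float, weight_decay: float):
        self.lr = lr
        self.wd = weight_decay
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m: dict[int, np.ndarray] = {}
        self.v: dict[int, np.ndarray] = {}

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for idx, (p, g) in enumerate(zip(params, grads)):
            if p.ndim > 1:  # decay weights, not biases
                g = g + self.wd * p
            m = self.m.setdefault(idx, np.zeros_like(p))
            v = self.v.setdefault(idx, np.zeros_like(p))
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            mhat = m / (1 - self.beta1**self.t)
            vhat = v / (1 - self.beta2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class FSResNet:
    """Conv x3 -> cascaded residual block -> global average pool -> fuzzy head."""

    def __init__(self, config: NetworkConfig, fuzzy: FuzzyScoringConfig | None = None):
        if fuzzy is None:
            fuzzy = FuzzyScoringConfig(m=config.m)
        if fuzzy.m != config.m:
            raise ValueError("fuzzy config class count must match the network's")
        self.config = config
        self.fuzzy = fuzzy
        self.fuzzy_enabled = True
        rng = np.random.default_rng(config.seed)
        self.dtype = np.dtype(config.dtype)
        self.convs: list[Conv2d] = []
        ch = config.input_channels
        side = config.input_side
        for cs in config.convs:
            conv = Conv2d(ch, cs.filters, cs.kernel, cs.stride, rng, self.dtype)
            side = conv.out_side(side)
            if side < 1:
                raise ValueError("network downsamples below 1 pixel; reduce strides")
            self.convs.append(conv)
            ch = cs.filters
        block_spec = config.block
        if block_spec.inner[-1].filters != ch:
            block_spec = ResidualBlockSpec(
                inner=[ConvSpec(ch, cs.kernel, cs.stride) for cs in block_spec.inner],
                shortcut=block_spec.shortcut,
                dense=block_spec.dense,
            )
        self.block = ResidualBlock(ch, block_spec, rng, self.dtype)
        self.feature_dim = ch
        self.fc_W = (rng.standard_normal((ch, config.m)) * np.sqrt(1.0 / ch)).astype(self.dtype)
        self.fc_b = np.zeros(config.m, dtype=self.dtype)
        self.memberships: GaussianMemberships | None = None
        self.trained = False
        self._fuzzy_ramp = 1.0
        self._fwd = None

    # ---- parameter plumbing -------------------------------------------------
    def _param_list(self) -> list[np.ndarray]:
        out = []
        for conv in self.convs + self.block.layers():
            out.extend([conv.W, conv.b])
        out.extend([self.fc_W, self.fc_b])
        return out

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self._param_list()))

    # ---- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Per-class energies E for a batch (N,C,H,W). P = softmax(-E)."""
        h = x.astype(self.dtype, copy=False)
        pres = []
        for conv in self.convs:
            pre = conv.forward(h)
            pres.append(pre)
            h = _relu(pre)
        h = self.block.forward(h)
        pooled = h.mean(axis=(2, 3))
        logits = pooled @ self.fc_W + self.fc_b
        self._fwd = (x.shape, pres, h.shape, pooled, logits)
        return -logits  # energies

    def _backward(self, dlogits: np.ndarray) -> list[np.ndarray]:
        x_shape, pres, h_shape, pooled, _ = self._fwd
        dfc_W = pooled.T @ dlogits
        dfc_b = dlogits.sum(axis=0)
        dpooled = dlogits @ self.fc_W.T
        N, C, H, W = h_shape
        dh = np.broadcast_to(
            dpooled[:, :, None, None] / (H * W), (N, C, H, W)
        ).copy()
        dh, bgrads = self.block.backward(dh)
        grads_rev = []
        for k in range(len(self.convs) - 1, -1, -1):
            dh = dh * (pres[k] > 0)
            dh, g = self.convs[k].backward(dh)
            grads_rev.append(g)
        out: list[np.ndarray] = []
        for k, conv in enumerate(self.convs):
            g = grads_rev[len(self.convs) - 1 - k]
            out.extend([g["W"], g["b"]])
        for k in range(len(self.block.convs)):
            out.extend([bgrads[f"conv{k}"]["W"], bgrads[f"conv{k}"]["b"]])
        if self.block.proj is not None:
            out.extend([bgrads["proj"]["W"], bgrads["proj"]["b"]])
        out.extend([dfc_W, dfc_b])
        return out

    def probabilities(self, x: np.ndarray, batch: int = 64) -> np.ndarray:
        parts = []
        for i in range(0, x.shape[0], batch):
            E = self.forward(x[i : i + batch])
            z = np.exp(-(E - E.min(axis=1, keepdims=True)))
            parts.append(z / z.sum(axis=1, keepdims=True))
        return np.concatenate(parts, axis=0)

    def penultimate(self, x: np.ndarray, batch: int = 64) -> np.ndarray:
        parts = []
        for i in range(0, x.shape[0], batch):
            self.forward(x[i : i + batch])
            parts.append(self._fwd[3])
        return np.concatenate(parts, axis=0)

    # ---- training -----------------------------------------------------------
    def _head_gradient(self, P: np.ndarray, y_onehot: np.ndarray) -> np.ndarray:
        """Output-layer error at the logits, averaged over the batch.

        Plain head: dL/dz = P - y (the negated plain error eps).

        Fuzzy head: each sample's error is modulated by its true
        class's window-centroid distance |i - V0|, normalized to unit
        maximum (|i - V0| <= max(a, b)), so a misclassified or
        ambiguous sample keeps the full signal while a confidently
        correct sample — V0 pulled onto i, the phi <= 0 damping regime
        — contributes a vanishing one. For the binary head this factor
        is exactly 1 - P_i. Substituting the raw redistributed
        probability for P in the error instead makes the signal grow
        with confidence and training diverges, so the bounded distance
        ratio is the operative form of the modified error.
        """
        dz = P - y_onehot
        if self.fuzzy_enabled:
            dist_max = max(self.fuzzy.a, self.fuzzy.b)
            m = self.config.m
            if m == 2 and self.fuzzy.a >= 1 and self.fuzzy.b >= 1:
                # full window: V0 = 1 + P_2, so |i - V0| = 1 - P_true
                mod = (1.0 - P[y_onehot.astype(bool)]) / dist_max
            else:
                mod = np.empty(P.shape[0])
                for s in range(P.shape[0]):
                    i = int(np.argmax(y_onehot[s])) + 1
                    v0 = window_centroid(P[s], i, self.fuzzy.a, self.fuzzy.b)
                    mod[s] = abs(i - v0) / dist_max
            ramp = self._fuzzy_ramp  # 0 = plain error, 1 = full modulation
            dz *= (1.0 - ramp + ramp * mod)[:, None]
        return dz / P.shape[0]

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> list[dict]:
        """Mini-batch Adam training; returns the per-epoch history."""
        cfg = self.config
        y = np.asarray(y, dtype=int)
        rng = np.random.default_rng(cfg.seed + 1)
        opt = _Adam(cfg.learning_rate, cfg.weight_decay)
        history: list[dict] = []
        eye = np.eye(cfg.m)
        best_val = -np.inf
        best_params: list[np.ndarray] | None = None
        warmup = max(1, int(np.ceil(cfg.fuzzy_warmup_frac * cfg.epochs)))
        for epoch in range(cfg.epochs):
            self._fuzzy_ramp = min(1.0, epoch / warmup)
            # step decay stabilizes the late phase of the short schedules used
            if epoch >= int(0.9 * cfg.epochs):
                opt.lr = cfg.learning_rate * 0.1
            elif epoch >= int(0.7 * cfg.epochs):
                opt.lr = cfg.learning_rate * 0.3
            order = rng.permutation(X.shape[0])
            for start in range(0, X.shape[0], cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                E = self.forward(X[idx])
                P = np.exp(-(E - E.min(axis=1, keepdims=True)))
                P /= P.sum(axis=1, keepdims=True)
                dlogits = self._head_gradient(P, eye[y[idx]])
                grads = self._backward(dlogits)
                opt.step(self._param_list(), grads)
            rec = {"epoch": epoch}
            rec.update(self._monitor(X, y, "train"))
            if X_val is not None and y_val is not None:
                rec.update(self._monitor(X_val, np.asarray(y_val, dtype=int), "val"))
                if cfg.restore_best and rec["val_accuracy"] > best_val:
                    best_val = rec["val_accuracy"]
                    best_params = [p.copy() for p in self._param_list()]
            if not np.isfinite(rec["train_loss"]):
                raise RuntimeError(
                    f"NaN loss at epoch {epoch}: learning rate likely too high"
                )
            history.append(rec)
        if best_params is not None:
            for p, q in zip(self._param_list(), best_params):
                p[...] = q
        self._fuzzy_ramp = 1.0
        self.trained = True
        acts = self.penultimate(X)
        self.memberships = fit_gaussian_memberships(acts, y, class_weights=self.fc_W.T)
        return history

    def _monitor(self, X: np.ndarray, y: np.ndarray, tag: str) -> dict:
        P = self.probabilities(X)
        eps = 1e-12
        loss = float(-np.mean(np.log(P[np.arange(len(y)), y] + eps)))
        acc = float((P.argmax(axis=1) == y).mean())
        return {f"{tag}_loss": loss, f"{tag}_accuracy": acc}

    def tune_head(self, X_val: np.ndarray, y_val: np.ndarray) -> None:
        """Grid-tune spread scaling and thresholds on a validation set."""
        P = self.probabilities(X_val)
        self.fuzzy = tune_memberships_grid(self.fuzzy, P, np.asarray(y_val, dtype=int))
        if self.memberships is not None:
            self.memberships.spread_scale = self.fuzzy.spread_scale


def build_fs_resnet(
    config: NetworkConfig, fuzzy: FuzzyScoringConfig | None = None
) -> FSResNet:
    """Construct the network; raises at build time on inconsistent shapes."""
    return FSResNet(config, fuzzy)


def images_to_tensor(images: list[np.ndarray]) -> np.ndarray:
    """Stack HxWxC images into an NCHW batch tensor."""
    return np.stack([np.moveaxis(np.asarray(im, dtype=np.float64), 2, 0) for im in images])


def train_fs_resnet(
    model: FSResNet,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> tuple[FSResNet, list[dict]]:
    """Train in place and return (model, per-epoch history)."""
    history = model.fit(X_train, y_train, X_val, y_val)
    return model, history


def predict(
    model: FSResNet, X: np.ndarray, ids: list[str] | None = None
) -> pd.DataFrame:
    """Per-sample probabilities, fuzzy scores and thresholded labels.

    The predicted label is the threshold-gated positive call (malignant
    iff its probability strictly exceeds the positive-class threshold);
    an exact tie with the threshold falls to the lower class index and
    is flagged uncertain. The continuous score Stilde is the window
    centroid V0 around the predicted class, a decimal class index.
    """
    if not model.trained:
        raise RuntimeError("model has not been trained")
    P = model.probabilities(X)
    thr = model.fuzzy.thresholds[1]
    records = []
    for s in range(P.shape[0]):
        p = P[s]
        label = int(p[1] > thr + 1e-12)
        uncertain = bool(abs(p[1] - thr) <= 1e-9)
        i = label + 1
        v0 = window_centroid(p, i, model.fuzzy.a, model.fuzzy.b)
        p_tilde = redistributed_vector(p, model.fuzzy.a, model.fuzzy.b)[label]
        records.append(
            {
                "id": ids[s] if ids is not None else str(s),
                "P_benign": float(p[0]),
                "P_malignant": float(p[1]),
                "P_tilde": float(p_tilde),
                "V0": float(v0),
                "score": float(v0),
                "label": label,
                "uncertain": uncertain,
            }
        )
    return pd.DataFrame.from_records(records)
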