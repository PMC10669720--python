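"""Capsule network for binary heart-sound classification.

The network maps a 128 x 16 MFCC spectrum through a ReLU convolution, a
second convolution reshaped into primary capsule vectors, iterative
dynamic routing to two digit capsules (normal / abnormal), and a
fully-connected decoder that reconstructs the input spectrum from the
masked digit capsule.  A capsule's vector orientation encodes the pose
of a feature and its Euclidean length, kept in [0, 1) by the squash
nonlinearity, encodes the probability that the feature is present; the
class whose digit capsule is longest wins, and a per-class hinge-style
margin loss drives training.

Dynamic routing by agreement: each primary capsule i makes a prediction
u_{j|i} = W_ij s_i for every digit capsule j; coupling coefficients
c_ij = softmax_j(b_ij) start uniform (b = 0) and, over R iterations, the
logits grow by the dot-product agreement u_{j|i} . v_j between the
prediction and the routed output v_j = squash(sum_i c_ij u_{j|i}).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor, conv2d, einsum, relu, sigmoid, softmax

__all__ = [
    "ConvSpec",
    "NetworkConfig",
    "MarginLossParams",
    "RoutingState",
    "CapsNet",
    "PRESETS",
    "squash",
    "dynamic_routing",
    "digitize",
    "margin_loss",
    "count_params",
]

_EPS = 1e-12


@dataclass(frozen=True)
class ConvSpec:
    """A valid-padding strided convolution layer."""

    filters: int
    kernel: int
    stride: int
    activation: str = "relu"

    def out_hw(self, h: int, w: int) -> tuple[int, int]:
        if self.kernel > h or self.kernel > w:
            raise ValueError(f"kernel {self.kernel} exceeds input {h}x{w}")
        return (h - self.kernel) // self.stride + 1, (w - self.kernel) // self.stride + 1

    def n_params(self, in_channels: int) -> int:
        return self.kernel * self.kernel * in_channels * self.filters + self.filters


@dataclass(frozen=True)
class MarginLossParams:
    """Margin-loss and digitization constants.

    m_plus / m_minus are the upper and lower length margins, lambda_down
    down-weights the absent-class term, and threshold is the digitization
    cutoff T on capsule length.
    """

    m_plus: float = 0.9
    m_minus: float = 0.1
    lambda_down: float = 0.5
    threshold: float = 0.5

    def __post_init__(self):
        if not (0.0 < self.m_minus < self.m_plus <= 1.0):
            raise ValueError("need 0 < m_minus < m_plus <= 1")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("need 0 < threshold < 1")
        if self.lambda_down <= 0:
            raise ValueError("lambda_down must be positive")


@dataclass(frozen=True)
class NetworkConfig:
    """Geometry of one capsule-network preset.

    The primary-capsule convolution uses capsule_dim x primary_channels
    filters whose output is reshaped into vectors of length capsule_dim.
    """

    name: str = "5s"
    input_shape: tuple[int, int, int] = (128, 16, 1)
    conv1: ConvSpec = ConvSpec(filters=256, kernel=9, stride=2)
    capsule_dim: int = 16
    primary_channels: int = 16
    primary_kernel: int = 4
    primary_stride: int = 1
    digit_dim: int = 16
    n_classes: int = 2
    decoder_hidden: tuple[int, ...] = (1024, 2048)
    routings: int = 5
    batch_size: int = 8
    w_reconstruction: float = 0.0005

    @property
    def primary_conv(self) -> ConvSpec:
        return ConvSpec(
            filters=self.capsule_dim * self.primary_channels,
            kernel=self.primary_kernel,
            stride=self.primary_stride,
            activation="linear",
        )

    def shapes(self) -> dict[str, tuple]:
        """Output shape of every layer in forward order."""
        h, w, c = self.input_shape
        h1, w1 = self.conv1.out_hw(h, w)
        h2, w2 = self.primary_conv.out_hw(h1, w1)
        flat = h2 * w2 * self.primary_conv.filters
        if flat % self.capsule_dim:
            raise ValueError(
                f"primary conv output {flat} not divisible by capsule_dim {self.capsule_dim}"
            )
        n_primary = flat // self.capsule_dim
        return {
            "input_1": (h, w, c),
            "conv1": (h1, w1, self.conv1.filters),
            "primarycap_conv2d": (h2, w2, self.primary_conv.filters),
            "primarycap_reshape": (n_primary, self.capsule_dim),
            "digitcaps": (self.n_classes, self.digit_dim),
            "capsnet": (self.n_classes,),
            "decoder": (h, w, c),
        }

    @property
    def n_primary(self) -> int:
        return self.shapes()["primarycap_reshape"][0]


#: Geometry presets per segment length; "5s" reproduces the reference
#: architecture, "tiny" is a reduced network for fast experiments.
PRESETS: dict[str, NetworkConfig] = {
    "5s": NetworkConfig(),
    "10s": NetworkConfig(
        name="10s", input_shape=(128, 32, 1), primary_stride=2, batch_size=8
    ),
    "3s": NetworkConfig(
        name="3s",
        input_shape=(128, 10, 1),
        conv1=ConvSpec(filters=128, kernel=7, stride=1),
        capsule_dim=8,
        primary_channels=16,
        batch_size=16,
    ),
    "1s": NetworkConfig(
        name="1s",
        input_shape=(128, 4, 1),
        conv1=ConvSpec(filters=224, kernel=3, stride=1),
        capsule_dim=32,
        primary_channels=8,
        primary_kernel=2,
        batch_size=32,
    ),
    "tiny": NetworkConfig(
        name="tiny",
        conv1=ConvSpec(filters=32, kernel=9, stride=2),
        capsule_dim=8,
        primary_channels=4,
        digit_dim=8,
        decoder_hidden=(128, 256),
        routings=2,
        batch_size=16,
    ),
}


@dataclass
class RoutingState:
    """Routing internals for inspection: per-iteration logits b_ij and
    couplings c_ij (lists of arrays, one per iteration), plus the
    prediction vectors u_{j|i} and per-iteration digit outputs."""

    logits: list[np.ndarray] = field(default_factory=list)
    couplings: list[np.ndarray] = field(default_factory=list)
    predictions: np.ndarray | None = None
    digit_outputs: list[np.ndarray] = field(default_factory=list)

    @property
    def iterations(self) -> int:
        return len(self.couplings)


# ---------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------
def squash(v: Tensor | np.ndarray, axis: int = -1) -> Tensor:
    """Squash nonlinearity: (|v|^2 / (1 + |v|^2)) * v / |v|.

    Rescales vector length into [0, 1) preserving direction; the zero
    vector maps to itself.
    """
    if not isinstance(v, Tensor):
        v = Tensor(v)
    ss = (v**2.0).sum(axis=axis, keepdims=True)
    scale = ss / (1.0 + ss) / (ss + _EPS) ** 0.5
    return v * scale


def _norm(v: Tensor, axis: int = -1) -> Tensor:
    return ((v**2.0).sum(axis=axis) + _EPS) ** 0.5


def dynamic_routing(
    u_hat: Tensor, routings: int, state: RoutingState | None = None
) -> Tensor:
    """Routing by agreement over prediction vectors.

    u_hat has shape (..., M, J, D): M primary capsules, J digit
    capsules, D output dims.  Each iteration computes couplings
    c = softmax_j(b), the weighted sums s_j = sum_i c_ij u_{j|i}, the
    outputs v_j = squash(s_j), and then updates the logits by the
    agreement b_ij += u_{j|i} . v_j.  Logits start at zero, so the first
    couplings are uniform over digit capsules; with R = 1 no logit
    update affects the returned output.
    """
    if routings < 1:
        raise ValueError("routings must be >= 1")
    b = Tensor(np.zeros(u_hat.shape[:-1]))  # (..., M, J)
    v = None
    for r in range(routings):
        c = softmax(b, axis=-1)
        if state is not None:
            state.logits.append(b.data.copy())
            state.couplings.append(c.data.copy())
        s = (c.reshape(*c.shape, 1) * u_hat).sum(axis=-3)  # (..., J, D)
        v = squash(s, axis=-1)
        if state is not None:
            state.digit_outputs.append(v.data.copy())
        if r < routings - 1:
            # agreement update; logits are routing bookkeeping, not
            # parameters, so the update uses current values only
            agreement = np.einsum(
                "...mjd,...jd->...mj", u_hat.data, v.data
            )
            b = Tensor(b.data + agreement)
    return v


def digitize(digit_norms: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binarize capsule lengths: 1 where |v_j|^2 > T^2 (strict), else 0."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    norms = np.asarray(digit_norms)
    return (norms**2 > threshold**2).astype(int)


def margin_loss(
    digit_norms: Tensor | np.ndarray,
    labels_onehot: np.ndarray,
    params: MarginLossParams = MarginLossParams(),
) -> Tensor:
    """Per-class margin loss on capsule lengths, averaged over the batch.

    L = sum_c [ T_c max(0, m+ - |v_c|)^2
                + lambda (1 - T_c) max(0, |v_c| - m-)^2 ]
    """
    if not isinstance(digit_norms, Tensor):
        digit_norms = Tensor(digit_norms)
    t = np.asarray(labels_onehot, dtype=np.float64)
    present = relu(params.m_plus - digit_norms) ** 2.0
    absent = relu(digit_norms - params.m_minus) ** 2.0
    per_class = Tensor(t) * present + params.lambda_down * Tensor(1.0 - t) * absent
    total = per_class.sum(axis=-1)
    if total.ndim == 0:
        return total
    return total.mean()


def count_params(config: NetworkConfig = PRESETS["5s"]) -> dict[str, int]:
    """Analytic trainable-parameter count per layer plus total.

    Convolutions count K*K*C*F + F; digit capsules count
    M * n_classes * D_in * D_out per-pair transforms without bias; the
    decoder is a biased dense stack ending in an h*w sigmoid layer.
    """
    h, w, c = config.input_shape
    shapes = config.shapes()
    counts = {
        "input_1": 0,
        "conv1": config.conv1.n_params(c),
        "primarycap_conv2d": config.primary_conv.n_params(config.conv1.filters),
        "primarycap_reshape": 0,
        "digitcaps": config.n_primary
        * config.n_classes
        * config.capsule_dim
        * config.digit_dim,
    }
    widths = (
        [config.n_classes * config.digit_dim]
        + list(config.decoder_hidden)
        + [h * w * c]
    )
    counts["decoder"] = sum(
        widths[i] * widths[i + 1] + widths[i + 1] for i in range(len(widths) - 1)
    )
    counts["total"] = sum(counts.values())
    return counts


# ---------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------
class CapsNet:
    """A trainable capsule network.

    Parameters are numpy tensors tracked by the autodiff engine;
    ``forward`` returns digit-capsule norms, the binary prediction, and
    the decoder reconstruction.  Weight initialization is seeded
    truncated-normal-style (He scaling for convolutions), so two models
    built with the same seed are identical.
    """

    def __init__(self, config: NetworkConfig = PRESETS["5s"],
                 loss_params: MarginLossParams = MarginLossParams(),
                 seed: int = 0):
        self.config = config
        self.loss_params = loss_params
        self.seed = seed
        rng = np.random.default_rng(seed)
        h, w, c = config.input_shape
        c1 = config.conv1
        pc = config.primary_conv

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.w_conv1 = Tensor(
            he((c1.kernel, c1.kernel, c, c1.filters), c1.kernel**2 * c),
            requires_grad=True,
        )
        self.b_conv1 = Tensor(np.zeros(c1.filters), requires_grad=True)
        self.w_primary = Tensor(
            he((pc.kernel, pc.kernel, c1.filters, pc.filters),
               pc.kernel**2 * c1.filters),
            requires_grad=True,
        )
        self.b_primary = Tensor(np.zeros(pc.filters), requires_grad=True)
        # per-pair digit transforms, no bias
        self.w_digit = Tensor(
            rng.normal(0.0, 0.05,
                       size=(config.n_primary, config.n_classes,
                             config.digit_dim, config.capsule_dim)),
            requires_grad=True,
        )
        widths = ([config.n_classes * config.digit_dim]
                  + list(config.decoder_hidden) + [h * w * c])
        self.decoder_w: list[Tensor] = []
        self.decoder_b: list[Tensor] = []
        for i in range(len(widths) - 1):
            self.decoder_w.append(
                Tensor(he((widths[i], widths[i + 1]), widths[i]), requires_grad=True)
            )
            self.decoder_b.append(Tensor(np.zeros(widths[i + 1]), requires_grad=True))
        # input scaling fitted on the training set (identity by default)
        self.input_offset = 0.0
        self.input_scale = 1.0

    # -- parameters ----------------------------------------------------
    def parameters(self) -> list[Tensor]:
        return [self.w_conv1, self.b_conv1, self.w_primary, self.b_primary,
                self.w_digit, *self.decoder_w, *self.decoder_b]

    def n_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- forward pieces ------------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        h, w, c = self.config.input_shape
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None, :, :, None]
        elif x.ndim == 3:
            x = x[None]
        if x.shape[1:] != (h, w, c):
            raise ValueError(
                f"input shape {x.shape[1:]} does not match preset "
                f"'{self.config.name}' expecting {(h, w, c)}"
            )
        return x

    def primary_capsules(self, features: Tensor) -> Tensor:
        """Second convolution, reshape to capsule vectors, squash."""
        cfg = self.config
        z = conv2d(features, self.w_primary, self.b_primary, cfg.primary_stride)
        n = z.shape[0]
        caps = z.reshape(n, cfg.n_primary, cfg.capsule_dim)
        return squash(caps, axis=-1)

    def forward(self, x: np.ndarray, labels_onehot: np.ndarray | None = None,
                with_state: bool = False) -> dict:
        """Full pass; returns dict with norms, prediction, digit capsules,
        reconstruction, and optionally the routing state.

        The decoder reconstructs the input from the digit capsules with
        all but one class zeroed (masked): the true class when labels are
        given (training), else the longest capsule (inference).
        """
        cfg = self.config
        x = self._check_input(x)
        xs = (x - self.input_offset) / self.input_scale
        xt = Tensor(xs)
        feats = relu(conv2d(xt, self.w_conv1, self.b_conv1, cfg.conv1.stride))
        primary = self.primary_capsules(feats)  # (N, M, D)
        u_hat = einsum("bmi,mjdi->bmjd", primary, self.w_digit)
        state = RoutingState(predictions=u_hat.data.copy()) if with_state else None
        digit = dynamic_routing(u_hat, cfg.routings, state)  # (N, J, D_out)
        norms = _norm(digit, axis=-1)  # (N, J)
        pred = digitize(norms.data, self.loss_params.threshold)
        # mask for the decoder
        if labels_onehot is not None:
            mask = np.asarray(labels_onehot, dtype=np.float64)
        else:
            mask = np.eye(cfg.n_classes)[norms.data.argmax(axis=-1)]
        masked = digit * Tensor(mask[:, :, None])
        hdim = masked.shape[0]
        hvec = masked.reshape(hdim, cfg.n_classes * cfg.digit_dim)
        for i, (wd, bd) in enumerate(zip(self.decoder_w, self.decoder_b)):
            hvec = hvec @ wd + bd
            hvec = sigmoid(hvec) if i == len(self.decoder_w) - 1 else relu(hvec)
        recon = hvec.reshape(hdim, *cfg.input_shape)
        out = {
            "digit_caps": digit,
            "norms": norms,
            "prediction": pred,
            "reconstruction": recon,
            "input_scaled": xs,
        }
        if with_state:
            out["routing_state"] = state
        return out

    def loss(self, out: dict, labels_onehot: np.ndarray) -> tuple[Tensor, Tensor]:
        """(total loss, margin loss); total adds the weighted MSE
        reconstruction error."""
        ml = margin_loss(out["norms"], labels_onehot, self.loss_params)
        total = ml
        if self.config.w_reconstruction > 0:
            err = out["reconstruction"] - Tensor(out["input_scaled"])
            total = ml + self.config.w_reconstruction * (err**2.0).mean()
        return total, ml

    def scores(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Digit-capsule norms (N, n_classes), batched, gradient-free."""
        x = self._check_input(x)
        outs = []
        for i in range(0, len(x), batch_size):
            outs.append(self.forward(x[i : i + batch_size])["norms"].data)
        return np.concatenate(outs, axis=0)

    # -- weights state -------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights):
            if p.data.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p.data = w.copy()

    def save(self, path) -> None:
        """Checkpoint: config + loss params + seed (JSON) and weights
        (npz) side by side."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "config": asdict(self.config),
            "loss_params": asdict(self.loss_params),
            "seed": self.seed,
            "input_offset": self.input_offset,
            "input_scale": self.input_scale,
        }
        (path / "model.json").write_text(json.dumps(meta, indent=2))
        np.savez(path / "weights.npz",
                 **{f"p{i}": w for i, w in enumerate(self.get_weights())})

    @classmethod
    def load(cls, path) -> "CapsNet":
        path = Path(path)
        meta = json.loads((path / "model.json").read_text())
        ccfg = dict(meta["config"])
        ccfg["conv1"] = ConvSpec(**ccfg["conv1"])
        ccfg["input_shape"] = tuple(ccfg["input_shape"])
        ccfg["decoder_hidden"] = tuple(ccfg["decoder_hidden"])
        model = cls(NetworkConfig(**ccfg),
                    MarginLossParams(**meta["loss_params"]), seed=meta["seed"])
        with np.load(path / "weights.npz") as z:
            model.set_weights([z[f"p{i}"] for i in range(len(z.files))])
        model.input_offset = meta["input_offset"]
        model.input_scale = meta["input_scale"]
        return model
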