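"""Score-regression network: CNN, residual, ECA-style attention, Bi-LSTM.

The network maps a standardized 2-s gait window (200 samples x 12 IMU
channels) to a normalized Berg Balance Scale score in [0, 1]. Four blocks
are composed in a fixed order, each individually switchable so every
ablation arm (CNN only, Bi-LSTM only, CNN+Bi-LSTM, Bi-LSTM with attention,
full model) is constructible from the same class:

* **CNN block** — Conv1D (32 filters, kernel 3, 'same') + batch norm + ReLU;
  local feature extraction over time.
* **Residual block** — two routes merged by channel concatenation: a second
  conv/BN/ReLU stack (32 filters, kernel 3) learning expanded features, and
  a stride-1 max pool (kernel 3) preserving the input feature space; a
  dropout of 0.2 follows the merge.
* **Attention block** — F1 expands channels with a conv/BN/ReLU stack to
  ``min(2C, 128)`` and is combined with a 1x1-projected copy of its input
  (element-wise addition); an ECA gate (global average pool over time, 1-D
  convolution across the channel axis with an adaptively sized kernel,
  sigmoid) re-weights channels; F3 is a 1x1 convolution to the squeeze
  width (32) followed by a global average over time, yielding one 32-vector
  per window.
* **Bi-LSTM head** — forward and backward LSTMs of 32 hidden units each,
  final states concatenated to 64, dropout 0.3, then fully connected layers
  (64 -> 16 -> 1, linear output). When fed from the attention block the
  32-vector is treated as a length-32 sequence of scalars; when attention
  is off, the time-major feature map is the sequence.

The ECA kernel follows ``k = log2(D)/tau + a/tau`` rounded to the nearest
odd integer, with the original ECA defaults tau=2, a=1 (so D=32 gives k=3).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .nn import (
    Adam,
    BatchNorm1D,
    BiLSTM,
    Conv1D,
    Dense,
    Dropout,
    Layer,
    MaxPool1D,
    ReLU,
    Sigmoid,
)

__all__ = [
    "ModelConfig",
    "BbsNet",
    "eca_kernel_size",
    "build_network",
    "ablation_arms",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ModelConfig:
    """Architectural hyperparameters and block on/off toggles."""

    conv_filters: int = 32
    conv_kernel: int = 3
    residual_dropout: float = 0.2
    attention_max_dim: int = 128
    eca_tau: float = 2.0
    eca_a: float = 1.0
    squeeze_dim: int = 32
    lstm_hidden: int = 32
    head_dropout: float = 0.3
    fc_hidden: int = 16
    use_cnn: bool = True
    use_residual: bool = True
    use_attention: bool = True
    use_bilstm: bool = True
    input_window: int = 200
    input_channels: int = 12

    def __post_init__(self) -> None:
        for name in ("conv_filters", "conv_kernel", "attention_max_dim",
                     "squeeze_dim", "lstm_hidden", "fc_hidden",
                     "input_window", "input_channels"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("residual_dropout", "head_dropout"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ValueError(f"{name} must be in [0, 1)")
        if self.eca_tau <= 0:
            raise ValueError("eca_tau must be positive")
        if not (self.use_cnn or self.use_bilstm):
            raise ValueError("at least one of use_cnn/use_bilstm must be enabled")
        if self.use_residual and not self.use_cnn:
            raise ValueError("use_residual requires use_cnn")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


def eca_kernel_size(channel_dim: int, tau: float = 2.0, a: float = 1.0) -> int:
    """Adaptive ECA kernel: log2(D)/tau + a/tau, rounded to the nearest odd.

    Always odd and at least 1, and non-decreasing in ``channel_dim`` for
    fixed ``tau``/``a``.
    """
    if channel_dim < 1:
        raise ValueError("channel_dim must be >= 1")
    if tau <= 0:
        raise ValueError("tau must be positive")
    k = np.log2(channel_dim) / tau + a / tau
    odd = 2 * int(round((k - 1) / 2)) + 1
    return max(odd, 1)


class BbsNet:
    """The composed network with explicit forward/backward passes.

    Construction is deterministic given ``(cfg, seed)``: weight
    initialisation and dropout masks all derive from one ``Generator``.
    """

    def __init__(self, cfg: ModelConfig, seed: int = 0) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        F, K = cfg.conv_filters, cfg.conv_kernel
        feat_ch = cfg.input_channels

        if cfg.use_cnn:
            self.conv1 = Conv1D(feat_ch, F, K, rng, bias=False)  # BN follows
            self.bn1 = BatchNorm1D(F)
            self.relu1 = ReLU()
            feat_ch = F
            if cfg.use_residual:
                self.res_conv = Conv1D(F, F, K, rng, bias=False)
                self.res_bn = BatchNorm1D(F)
                self.res_relu = ReLU()
                self.res_pool = MaxPool1D(K)
                self.res_drop = Dropout(cfg.residual_dropout, rng)
                feat_ch = 2 * F

        if cfg.use_attention:
            E = min(2 * feat_ch, cfg.attention_max_dim)
            self.att_conv = Conv1D(feat_ch, E, K, rng, bias=False)
            self.att_bn = BatchNorm1D(E)
            self.att_relu = ReLU()
            self.att_proj = Conv1D(feat_ch, E, 1, rng)
            k = eca_kernel_size(E, cfg.eca_tau, cfg.eca_a)
            self.eca_conv = Conv1D(1, 1, k, rng, bias=False)
            self.eca_sig = Sigmoid()
            self.f3 = Conv1D(E, cfg.squeeze_dim, 1, rng)
            self.expanded_dim = E
            feat_dim = cfg.squeeze_dim
        else:
            feat_dim = feat_ch

        if cfg.use_bilstm:
            lstm_in = 1 if cfg.use_attention else feat_ch
            self.bilstm = BiLSTM(lstm_in, cfg.lstm_hidden, rng)
            head_in = 2 * cfg.lstm_hidden
        else:
            head_in = feat_dim

        self.head_drop = Dropout(cfg.head_dropout, rng)
        self.fc1 = Dense(head_in, cfg.fc_hidden, rng)
        self.fc_relu = ReLU()
        self.fc2 = Dense(cfg.fc_hidden, 1, rng)

    # -- plumbing ---------------------------------------------------------

    def _param_layers(self) -> list[Layer]:
        out: list[Layer] = []
        for ly in self._ordered_layers():
            if isinstance(ly, BiLSTM):
                out.extend(ly.sublayers)
            else:
                out.append(ly)
        return out

    def _ordered_layers(self) -> list:
        names = ["conv1", "bn1", "relu1", "res_conv", "res_bn", "res_relu",
                 "res_pool", "res_drop", "att_conv", "att_bn", "att_relu",
                 "att_proj", "eca_conv", "eca_sig", "f3", "bilstm",
                 "head_drop", "fc1", "fc_relu", "fc2"]
        return [getattr(self, n) for n in names if hasattr(self, n)]

    def make_optimizer(self, lr: float = 1e-3) -> Adam:
        return Adam(self._param_layers(), lr=lr)

    def n_parameters(self) -> int:
        return int(sum(p.size for ly in self._param_layers()
                       for p in ly.params.values()))

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, ly in enumerate(self._param_layers()):
            for k, v in ly.params.items():
                state[f"{i}.{k}"] = v.copy()
            if isinstance(ly, BatchNorm1D):
                state[f"{i}.running_mean"] = ly.running_mean.copy()
                state[f"{i}.running_var"] = ly.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, ly in enumerate(self._param_layers()):
            for k in ly.params:
                ly.params[k][...] = state[f"{i}.{k}"]
            if isinstance(ly, BatchNorm1D):
                ly.running_mean[...] = state[f"{i}.running_mean"]
                ly.running_var[...] = state[f"{i}.running_var"]

    def snapshot(self) -> dict[str, np.ndarray]:
        return copy.deepcopy(self.state_dict())

    # -- forward / backward ----------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Predict normalized scores for a batch of (B, 200, 12) windows."""
        cfg = self.cfg
        if x.ndim != 3 or x.shape[1] != cfg.input_window or x.shape[2] != cfg.input_channels:
            raise ValueError(
                f"expected (B, {cfg.input_window}, {cfg.input_channels}) input, "
                f"got {x.shape}")
        h = x
        if cfg.use_cnn:
            h = self.relu1.forward(self.bn1.forward(self.conv1.forward(h, train), train), train)
            if cfg.use_residual:
                a = self.res_relu.forward(
                    self.res_bn.forward(self.res_conv.forward(h, train), train), train)
                b = self.res_pool.forward(h, train)
                h = self.res_drop.forward(np.concatenate([a, b], axis=2), train)
        if cfg.use_attention:
            f = self.att_relu.forward(
                self.att_bn.forward(self.att_conv.forward(h, train), train), train)
            p = self.att_proj.forward(h, train)
            y1 = f + p
            self._y1 = y1
            s = y1.mean(axis=1)                                    # (B, E)
            gate = self.eca_sig.forward(
                self.eca_conv.forward(s[:, :, None], train)[:, :, 0], train)
            self._gate = gate
            y2 = y1 * gate[:, None, :]
            z = self.f3.forward(y2, train)                         # (B, T, 32)
            self._att_T = z.shape[1]
            h = z.mean(axis=1)                                     # (B, 32)
            self._att_out = h
        if cfg.use_bilstm:
            seq = h[:, :, None] if cfg.use_attention else h
            h = self.bilstm.forward(seq, train)
        elif not cfg.use_attention:
            self._gap_T = h.shape[1]
            h = h.mean(axis=1)
        h = self.head_drop.forward(h, train)
        h = self.fc2.forward(self.fc_relu.forward(self.fc1.forward(h, train), train), train)
        return h[:, 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cfg = self.cfg
        g = dout[:, None]
        g = self.fc1.backward(self.fc_relu.backward(self.fc2.backward(g)))
        g = self.head_drop.backward(g)
        if cfg.use_bilstm:
            g = self.bilstm.backward(g)
            if cfg.use_attention:
                g = g[:, :, 0]
        elif not cfg.use_attention:
            g = np.repeat(g[:, None, :], self._gap_T, axis=1) / self._gap_T
        if cfg.use_attention:
            T = self._att_T
            dz = np.repeat(g[:, None, :], T, axis=1) / T
            dy2 = self.f3.backward(dz)
            dy1 = dy2 * self._gate[:, None, :]
            dgate = (dy2 * self._y1).sum(axis=1)
            dpre = self.eca_sig.backward(dgate)
            ds = self.eca_conv.backward(dpre[:, :, None])[:, :, 0]
            dy1 = dy1 + ds[:, None, :] / T
            df = self.att_conv.backward(self.att_bn.backward(self.att_relu.backward(dy1)))
            dp = self.att_proj.backward(dy1)
            g = df + dp
        if cfg.use_cnn:
            if cfg.use_residual:
                g = self.res_drop.backward(g)
                F = self.cfg.conv_filters
                ga = self.res_conv.backward(self.res_bn.backward(self.res_relu.backward(g[:, :, :F])))
                gb = self.res_pool.backward(g[:, :, F:])
                g = ga + gb
            g = self.conv1.backward(self.bn1.backward(self.relu1.backward(g)))
        return g

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Eval-mode forward in chunks; returns normalized scores (B,)."""
        out = [self.forward(x[i:i + batch_size], train=False)
               for i in range(0, len(x), batch_size)]
        return np.concatenate(out) if out else np.empty(0)


def build_network(cfg: ModelConfig, seed: int = 0) -> BbsNet:
    """Construct the network for ``cfg``; deterministic in ``seed``."""
    return BbsNet(cfg, seed=seed)


def ablation_arms() -> dict[str, ModelConfig]:
    """The five module-combination arms compared in the ablation study."""
    return {
        "cnn": ModelConfig(use_cnn=True, use_residual=True,
                           use_attention=False, use_bilstm=False),
        "bilstm": ModelConfig(use_cnn=False, use_residual=False,
                              use_attention=False, use_bilstm=True),
        "cnn+bilstm": ModelConfig(use_cnn=True, use_residual=True,
                                  use_attention=False, use_bilstm=True),
        "bilstm+attention": ModelConfig(use_cnn=False, use_residual=False,
                                        use_attention=True, use_bilstm=True),
        "cnn+bilstm+attention": ModelConfig(),
    }


def save_checkpoint(net: BbsNet, path: str | Path, extra: dict | None = None) -> None:
    """Write weights (.npz) plus a JSON sidecar with the full config."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **net.state_dict())
    sidecar = {"model_config": net.cfg.to_dict()}
    if extra:
        sidecar.update(extra)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> BbsNet:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    net = BbsNet(ModelConfig.from_dict(sidecar["model_config"]))
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        net.load_state_dict({k: z[k] for k in z.files})
    return net
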