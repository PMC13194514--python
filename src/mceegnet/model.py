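"""The multi-cue EEG network: three parallel EEGNet-style branches.

Each branch processes the epochs of one emotional cue (happy / fear / sad)
through a temporal convolution (frequency-selective filters), a depthwise
spatial convolution spanning all electrodes, and a separable temporal
convolution, with batch normalization, ELU activations, dropout and average
pooling between stages. The three flattened branch outputs are concatenated
into a single multi-cue feature vector feeding a softmax classification
head (depressed vs. control) and/or a linear regression head (normalized
PHQ-9 severity).

Branch layer order::

    Conv(1 x temporal_kernel, f1, same) -> BN -> ELU
    -> DepthwiseConv(C x 1, depth D)    -> BN -> ELU -> Dropout -> AvgPool(1 x pool1)
    -> SeparableConv(1 x sep_kernel, same) -> BN -> ELU -> Dropout -> AvgPool(1 x pool2)
    -> flatten

The three branches have independent (non-shared) weights. Convolutions are
bias-free and batch norm is affine, so the per-branch trainable-parameter
count has the closed form
``f1*K_t + 2*f1 + D*f1*C + 2*f2 + f2*K_s + f2^2 + 2*f2`` with ``f2 = f1*D``
(for the 128-channel, 125-sample configuration: 3440 per branch).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from . import _nn
from .data_io import CueTripletBatch

__all__ = [
    "BranchConfig",
    "MCEEGNetConfig",
    "MCEEGNet",
    "ContractError",
    "build_model",
    "feature_dim",
    "count_parameters",
    "forward",
    "save_checkpoint",
    "load_checkpoint",
]


class ContractError(ValueError):
    """A model configuration or input violates a structural contract."""


@dataclass(frozen=True)
class BranchConfig:
    """Shape and hyper-parameters of one EEGNet-style branch."""

    n_channels: int = 128
    n_samples: int = 125
    f1: int = 8                 # temporal filters
    temporal_kernel: int = 100  # taps of the 1 x K temporal convolution
    depth_multiplier: int = 2   # spatial filters per temporal filter
    sep_kernel: int = 16
    pool1: int = 4
    pool2: int = 8
    dropout_p: float = 0.5

    @property
    def f2(self) -> int:
        return self.f1 * self.depth_multiplier

    @property
    def pooled_samples(self) -> int:
        return (self.n_samples // self.pool1) // self.pool2

    def validate(self) -> None:
        if min(self.n_channels, self.n_samples, self.f1, self.temporal_kernel,
               self.depth_multiplier, self.sep_kernel, self.pool1, self.pool2) < 1:
            raise ContractError("all branch dimensions must be positive")
        if not (0 <= self.dropout_p < 1):
            raise ContractError(f"dropout_p must be in [0, 1), got {self.dropout_p}")
        if self.pooled_samples < 1:
            raise ContractError(
                f"n_samples={self.n_samples} too small for pooling "
                f"{self.pool1}x{self.pool2}; need at least {self.pool1 * self.pool2}"
            )


@dataclass(frozen=True)
class MCEEGNetConfig:
    branch: BranchConfig = field(default_factory=BranchConfig)
    n_classes: int = 2
    mode: str = "classify"  # classify | regress | joint

    def validate(self) -> None:
        self.branch.validate()
        if self.mode not in ("classify", "regress", "joint"):
            raise ContractError(f"unknown mode {self.mode!r}")
        if self.mode in ("classify", "joint") and self.n_classes < 2:
            raise ContractError("classification needs n_classes >= 2")


def feature_dim(cfg: MCEEGNetConfig) -> int:
    """Length of the concatenated multi-cue feature vector.

    Closed form ``3 * f2 * floor(floor(T / pool1) / pool2)``; guaranteed to
    equal the built model's actual concatenated feature length.
    """
    cfg.validate()
    b = cfg.branch
    return 3 * b.f2 * b.pooled_samples


def count_parameters(cfg: MCEEGNetConfig) -> int:
    """Closed-form trainable parameter count (convs bias-free, BN affine)."""
    cfg.validate()
    b = cfg.branch
    per_branch = (b.f1 * b.temporal_kernel + 2 * b.f1
                  + b.depth_multiplier * b.f1 * b.n_channels + 2 * b.f2
                  + b.f2 * b.sep_kernel + b.f2 ** 2 + 2 * b.f2)
    fdim = feature_dim(cfg)
    heads = 0
    if cfg.mode in ("classify", "joint"):
        heads += fdim * cfg.n_classes + cfg.n_classes
    if cfg.mode in ("regress", "joint"):
        heads += fdim + 1
    return 3 * per_branch + heads


def _make_branch(b: BranchConfig, rng: np.random.Generator,
                 dropout_rng: np.random.Generator) -> _nn.Sequential:
    return _nn.Sequential([
        _nn.TemporalConv(b.f1, b.temporal_kernel, rng),
        _nn.BatchNorm(b.f1),
        _nn.ELU(),
        _nn.SpatialDepthwiseConv(b.f1, b.depth_multiplier, b.n_channels, rng),
        _nn.BatchNorm(b.f2),
        _nn.ELU(),
        _nn.Dropout(b.dropout_p, dropout_rng),
        _nn.AvgPoolTime(b.pool1),
        _nn.SeparableConvTime(b.f2, b.sep_kernel, rng),
        _nn.BatchNorm(b.f2),
        _nn.ELU(),
        _nn.Dropout(b.dropout_p, dropout_rng),
        _nn.AvgPoolTime(b.pool2),
        _nn.Flatten(),
    ])


class MCEEGNet:
    """Three independent branches + shared-feature heads, with backprop."""

    CUES = ("happy", "fear", "sad")

    def __init__(self, cfg: MCEEGNetConfig, seed: int):
        cfg.validate()
        self.cfg = cfg
        self.seed = int(seed)
        ss = np.random.SeedSequence(self.seed)
        init_ss, drop_ss = ss.spawn(2)
        rng = np.random.default_rng(init_ss)
        self._dropout_rng = np.random.default_rng(drop_ss)
        self.branches = [_make_branch(cfg.branch, rng, self._dropout_rng)
                         for _ in range(3)]
        fdim = feature_dim(cfg)
        self._branch_dim = fdim // 3
        self.head_cls: Optional[_nn.Linear] = None
        self.head_reg: Optional[_nn.Linear] = None
        if cfg.mode in ("classify", "joint"):
            self.head_cls = _nn.Linear(fdim, cfg.n_classes, rng, "head_cls")
        if cfg.mode in ("regress", "joint"):
            self.head_reg = _nn.Linear(fdim, 1, rng, "head_reg")

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> List[_nn.Param]:
        ps = [p for br in self.branches for p in br.params()]
        for head in (self.head_cls, self.head_reg):
            if head is not None:
                ps.extend(head.params())
        return ps

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def _stacks(self) -> list:
        return self.branches + [h for h in (self.head_cls, self.head_reg) if h is not None]

    def state(self) -> List[np.ndarray]:
        return _nn.snapshot(self._stacks())

    def load_state(self, state: List[np.ndarray]) -> None:
        _nn.restore(self._stacks(), state)

    # -- forward / backward -------------------------------------------------
    def _check_batch(self, batch: CueTripletBatch) -> None:
        b = self.cfg.branch
        for name, x in (("x_happy", batch.x_happy), ("x_fear", batch.x_fear),
                        ("x_sad", batch.x_sad)):
            if x.shape[1:] != (b.n_channels, b.n_samples):
                raise ContractError(
                    f"{name} has shape {x.shape[1:]}, model expects "
                    f"({b.n_channels}, {b.n_samples})"
                )

    def forward(self, batch: CueTripletBatch, train_mode: bool = False) -> Dict[str, np.ndarray]:
        """Run the network; returns ``class_probs`` / ``logits`` and/or ``scores``.

        ``scores`` are on the normalized label scale (unbounded reals); rows
        of ``class_probs`` sum to 1. With ``train_mode=False`` the op is a
        pure deterministic function of (parameters, input).
        """
        self._check_batch(batch)
        feats = []
        for br, x in zip(self.branches, (batch.x_happy, batch.x_fear, batch.x_sad)):
            xin = np.ascontiguousarray(x[:, None], dtype=_nn.DTYPE)  # (N,1,C,T)
            feats.append(br.forward(xin, train_mode))
        fcat = np.concatenate(feats, axis=1)
        self._fcat_dim = fcat.shape[1]
        out: Dict[str, np.ndarray] = {"features": fcat}
        if self.head_cls is not None:
            logits = self.head_cls.forward(fcat, train_mode)
            out["logits"] = logits
            out["class_probs"] = _nn.softmax(logits.astype(np.float64)).astype(_nn.DTYPE)
        if self.head_reg is not None:
            out["scores"] = self.head_reg.forward(fcat, train_mode)[:, 0]
        return out

    def backward(self, dlogits: Optional[np.ndarray] = None,
                 dscores: Optional[np.ndarray] = None) -> None:
        """Backpropagate head gradients through the branches."""
        d = np.zeros((self._last_n(dlogits, dscores), self._fcat_dim), dtype=_nn.DTYPE)
        if dlogits is not None:
            d += self.head_cls.backward(dlogits.astype(_nn.DTYPE))
        if dscores is not None:
            d += self.head_reg.backward(dscores.astype(_nn.DTYPE)[:, None])
        k = self._branch_dim
        for i, br in enumerate(self.branches):
            br.backward(d[:, i * k:(i + 1) * k])

    @staticmethod
    def _last_n(dlogits, dscores) -> int:
        for g in (dlogits, dscores):
            if g is not None:
                return g.shape[0]
        raise ValueError("backward needs at least one head gradient")


def build_model(cfg: MCEEGNetConfig, seed: int) -> MCEEGNet:
    """Construct the network with deterministic initialization under ``seed``."""
    return MCEEGNet(cfg, seed)


def forward(model: MCEEGNet, batch: CueTripletBatch, train_mode: bool = False):
    """Functional alias for :meth:`MCEEGNet.forward`."""
    return model.forward(batch, train_mode)


# ---------------------------------------------------------------------------
# Checkpoints: npz weights + JSON config sidecar
# ---------------------------------------------------------------------------

def save_checkpoint(model: MCEEGNet, path: str | Path) -> None:
    path = Path(path)
    state = model.state()
    np.savez(path, **{f"arr_{i}": a for i, a in enumerate(state)})
    sidecar = path.with_suffix(path.suffix + ".json")
    cfg = {"branch": asdict(model.cfg.branch), "n_classes": model.cfg.n_classes,
           "mode": model.cfg.mode, "seed": model.seed}
    sidecar.write_text(json.dumps(cfg, indent=2))


def load_checkpoint(path: str | Path) -> MCEEGNet:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    cfg_d = json.loads(sidecar.read_text())
    cfg = MCEEGNetConfig(branch=BranchConfig(**cfg_d["branch"]),
                         n_classes=cfg_d["n_classes"], mode=cfg_d["mode"])
    model = MCEEGNet(cfg, cfg_d["seed"])
    with np.load(path) as z:
        state = [z[f"arr_{i}"] for i in range(len(z.files))]
    model.load_state(state)
    return model
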