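"""The TCN basecalling model: stacked residual blocks, two time-distributed
fully connected layers, and a softmax over the five CTC symbols.

The network maps a standardized signal window X = [x_1..x_T] to a T x 5
row-stochastic probability matrix O; row t gives the probability of each
symbol (A, C, G, T, blank) at time point t.  All convolutions are causal, so
row t depends only on samples at times <= t, and the stacked dilations give
the top block a receptive field wide enough to cover the samples produced
while a base (and its k-mer context) traverses the pore.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nn import DilatedCausalConv, Param, ReLU, ResidualBlock, log_softmax, receptive_field

__all__ = [
    "ModelConfig",
    "TCNModel",
    "receptive_field",
    "SYMBOLS",
    "N_SYMBOLS",
    "BLANK",
]

# Symbol order of the output channels; blank last, as is conventional for CTC.
SYMBOLS = "ACGT-"
N_SYMBOLS = 5
BLANK = 4


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults mirror the full-scale basecaller: five residual blocks with
    doubling dilations, filter size 3, 256 filters, FC widths 128 and 5, and
    no bias terms anywhere.  ``reduced()`` gives a desk-scale configuration
    that trains in minutes on one CPU.
    """

    n_blocks: int = 5
    dilations: tuple[int, ...] = (1, 2, 4, 8, 16)
    filter_size: int = 3
    n_filters: int = 256
    fc1_channels: int = 128
    fc2_channels: int = 5
    use_bias: bool = False

    def __post_init__(self) -> None:
        self.dilations = tuple(self.dilations)
        if len(self.dilations) != self.n_blocks:
            raise ValueError("need one dilation factor per block")
        if self.fc2_channels != N_SYMBOLS:
            raise ValueError(f"fc2_channels must be {N_SYMBOLS} (A, C, G, T, blank)")

    @classmethod
    def reduced(cls) -> "ModelConfig":
        """Desk-scale configuration: 2 blocks, 32 filters.

        Dilations (1, 8) keep the stacked receptive field gap-free (a first
        layer at dilation 1 sees every sample; coarser-only dilations would
        leave periodic holes), filter size 5 widens each tap over the ~8
        samples of a typical dwell, and zero-initialized biases are enabled
        (at full scale the network carries no bias terms).
        """
        return cls(
            n_blocks=2, dilations=(1, 8), filter_size=5, n_filters=32,
            fc1_channels=64, use_bias=True,
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        d = json.loads(s)
        d["dilations"] = tuple(d["dilations"])
        return cls(**d)


class TCNModel:
    """Stacked residual blocks + two 1x1 (time-distributed) FC layers + softmax."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0) -> None:
        self.config = config or ModelConfig()
        rng = np.random.default_rng(seed)
        cfg = self.config
        self.blocks: list[ResidualBlock] = []
        in_ch = 1
        for i, d in enumerate(cfg.dilations):
            self.blocks.append(
                ResidualBlock(
                    in_ch, cfg.n_filters, cfg.filter_size, d,
                    use_bias=cfg.use_bias, rng=rng, name=f"block{i}",
                )
            )
            in_ch = cfg.n_filters
        self.fc1 = DilatedCausalConv(
            cfg.n_filters, cfg.fc1_channels, 1, 1,
            weight_norm=False, use_bias=cfg.use_bias, rng=rng, name="fc1",
        )
        self.fc1_act = ReLU()
        self.fc2 = DilatedCausalConv(
            cfg.fc1_channels, cfg.fc2_channels, 1, 1,
            weight_norm=False, use_bias=cfg.use_bias, rng=rng, name="fc2",
        )
        self.params: list[Param] = []
        for blk in self.blocks:
            self.params += blk.params
        self.params += self.fc1.params + self.fc2.params

    @property
    def total_receptive_field(self) -> int:
        """Past context of the full stack (1x1 layers add nothing)."""
        return sum(b.receptive_field for b in self.blocks)

    def forward_logits(self, segments: np.ndarray) -> np.ndarray:
        """(B, T) standardized windows -> (B, 5, T) unnormalized scores."""
        x = np.asarray(segments, dtype=np.float64)
        if x.ndim == 1:
            x = x[None, :]
        if x.ndim != 2:
            raise ValueError(f"expected (batch, T) input, got shape {x.shape}")
        h = x[:, None, :]
        for blk in self.blocks:
            h = blk.forward(h)
        h = self.fc1_act.forward(self.fc1.forward(h))
        return self.fc2.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(logits)."""
        dh = self.fc2.backward(dlogits)
        dh = self.fc1.backward(self.fc1_act.backward(dh))
        for blk in reversed(self.blocks):
            dh = blk.backward(dh)

    def forward_log_probs(self, segments: np.ndarray) -> np.ndarray:
        """(B, T) -> (B, T, 5) log-probabilities (rows log-sum to 0)."""
        logits = self.forward_logits(segments)  # (B, 5, T)
        return log_softmax(np.transpose(logits, (0, 2, 1)), axis=-1)

    def forward_probs(self, segments: np.ndarray) -> np.ndarray:
        """(B, T) -> (B, T, 5) row-stochastic probability matrices."""
        return np.exp(self.forward_log_probs(segments))

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def renormalize_weight_norm(self) -> None:
        """Reset every weight-normalized filter direction to unit norm
        (function-preserving; see DilatedCausalConv.renormalize)."""
        for blk in self.blocks:
            blk.conv1.renormalize()
            blk.conv2.renormalize()

    def get_state(self) -> dict[str, np.ndarray]:
        return {f"p{i}_{p.name}": p.value.copy() for i, p in enumerate(self.params)}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params):
            key = f"p{i}_{p.name}"
            if key not in state:
                raise KeyError(f"checkpoint missing parameter {key}")
            if state[key].shape != p.value.shape:
                raise ValueError(f"shape mismatch for {key}")
            p.value = state[key].astype(np.float64).copy()

    # ------------------------------------------------------------------
    # Checkpoint format: one .npz with named parameter arrays and the
    # serialized ModelConfig (including the symbol order) alongside.
    # ------------------------------------------------------------------

    def save_checkpoint(self, path: str | Path) -> None:
        meta = json.dumps({"config": json.loads(self.config.to_json()), "symbols": SYMBOLS})
        np.savez(path, __meta__=np.bytes_(meta.encode()), **self.get_state())

    @classmethod
    def load_checkpoint(cls, path: str | Path) -> "TCNModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            config = ModelConfig.from_json(json.dumps(meta["config"]))
            model = cls(config)
            state = {k: data[k] for k in data.files if k != "__meta__"}
        model.set_state(state)
        return model
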