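"""Dilated residual convolutional splice-site scorer.

The scorer maps a one-hot DNA sequence to per-position probabilities over
three classes (non-splice, acceptor, donor). An initial 1x1 convolution
lifts the 4 nucleotide channels to ``channels`` feature channels; a stack of
residual units (each: BN -> LeakyReLU -> dilated conv, twice) widens the
receptive field; every ``skip_every``-th unit taps into a skip pathway via a
1x1 convolution; a final 1x1 convolution maps the skip sum to 3 logit
channels, which are cropped by CL/2 per side and softmaxed.

The cropping length obeys ``CL = 2 * sum(AR_i * (W_i - 1))``; for the four
standard configurations (flank 80 / 400 / 2,000 / 10,000 nt) CL equals the
flanking size, so a window of ``5000 + flank`` positions yields exactly
5,000 predictions.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np

from .nn.core import BatchNorm1d, Conv1d, Layer, LeakyReLU, Param, softmax

__all__ = [
    "ModelConfig",
    "compute_cropping",
    "SpliceScorer",
    "build_scorer",
    "save_checkpoint",
    "load_checkpoint",
    "STANDARD_KERNELS",
    "STANDARD_DILATIONS",
]

# The four standard configurations, keyed by flanking size.
STANDARD_KERNELS: dict[int, tuple[int, ...]] = {
    80: (11, 11, 11, 11),
    400: (11,) * 8,
    2000: (11,) * 8 + (21,) * 4,
    10000: (11,) * 8 + (21,) * 4 + (41,) * 4,
}
STANDARD_DILATIONS: dict[int, tuple[int, ...]] = {
    80: (1, 1, 1, 1),
    400: (1,) * 4 + (4,) * 4,
    2000: (1,) * 4 + (4,) * 4 + (10,) * 4,
    10000: (1,) * 4 + (4,) * 4 + (10,) * 4 + (25,) * 4,
}


def compute_cropping(kernels, dilations) -> int:
    """Cropping length CL = 2 * sum(AR_i * (W_i - 1)).

    This is the total number of output positions removed (CL/2 per side) so
    that predictions align with positions whose full receptive field lies
    inside the input.
    """
    kernels = list(kernels)
    dilations = list(dilations)
    if len(kernels) != len(dilations):
        raise ValueError(
            f"kernel vector (len {len(kernels)}) and dilation vector "
            f"(len {len(dilations)}) must have equal length"
        )
    if any(w < 1 for w in kernels) or any(d < 1 for d in dilations):
        raise ValueError("kernel widths and dilation rates must be >= 1")
    return 2 * sum(d * (w - 1) for w, d in zip(kernels, dilations))


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``flank`` is the nominal flanking size; for the standard configs it
    equals the derived cropping length ``cl``. ``channels`` is the hidden
    width L (the published tables omit it; 32 is the predecessor's value).
    """

    flank: int
    kernels: tuple[int, ...]
    dilations: tuple[int, ...]
    channels: int = 32
    skip_every: int = 4

    def __post_init__(self):
        object.__setattr__(self, "kernels", tuple(self.kernels))
        object.__setattr__(self, "dilations", tuple(self.dilations))
        compute_cropping(self.kernels, self.dilations)  # validates lengths
        n = len(self.kernels)
        if n == 0 or n % self.skip_every != 0:
            raise ValueError(
                f"residual-unit count {n} must be a positive multiple of "
                f"skip_every={self.skip_every}; override skip_every to change "
                "the skip placement"
            )

    @property
    def cl(self) -> int:
        return compute_cropping(self.kernels, self.dilations)

    @property
    def n_residual_units(self) -> int:
        return len(self.kernels)

    @property
    def n_skip_connections(self) -> int:
        return len(self.kernels) // self.skip_every

    @classmethod
    def for_flank(cls, flank: int, channels: int = 32) -> "ModelConfig":
        """One of the four standard configurations (flank 80/400/2000/10000)."""
        if flank not in STANDARD_KERNELS:
            raise ValueError(
                f"no standard configuration for flank={flank}; "
                f"choose one of {sorted(STANDARD_KERNELS)} or build a custom ModelConfig"
            )
        return cls(flank=flank, kernels=STANDARD_KERNELS[flank], dilations=STANDARD_DILATIONS[flank], channels=channels)

    @classmethod
    def tiny(cls, channels: int = 8) -> "ModelConfig":
        """A small configuration for CPU tests: 4 units, W=5, CL=flank=32."""
        return cls(flank=32, kernels=(5, 5, 5, 5), dilations=(1, 1, 1, 1), channels=channels)

    def to_dict(self) -> dict:
        return {
            "flank": self.flank,
            "kernels": list(self.kernels),
            "dilations": list(self.dilations),
            "channels": self.channels,
            "skip_every": self.skip_every,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(
            flank=d["flank"],
            kernels=tuple(d["kernels"]),
            dilations=tuple(d["dilations"]),
            channels=d["channels"],
            skip_every=d.get("skip_every", 4),
        )


class _ResidualUnit(Layer):
    """BN -> LeakyReLU -> conv -> BN -> LeakyReLU -> conv, with identity add."""

    def __init__(self, channels: int, width: int, dilation: int, rng) -> None:
        self.bn1 = BatchNorm1d(channels)
        self.act1 = LeakyReLU(0.1)
        self.conv1 = Conv1d(channels, channels, width, dilation, rng)
        self.bn2 = BatchNorm1d(channels)
        self.act2 = LeakyReLU(0.1)
        self.conv2 = Conv1d(channels, channels, width, dilation, rng)
        self._sub = [self.bn1, self.act1, self.conv1, self.bn2, self.act2, self.conv2]

    def params(self):
        out = []
        for i, layer in enumerate(self._sub):
            for name, p in layer.params():
                out.append((f"{i}.{name}", p))
        return out

    def buffers(self):
        out = []
        for i, layer in enumerate(self._sub):
            for name, b in layer.buffers():
                out.append((f"{i}.{name}", b))
        return out

    def forward(self, x, training=False):
        h = x
        for layer in self._sub:
            h = layer.forward(h, training)
        return x + h

    def backward(self, dy):
        dh = dy
        for layer in reversed(self._sub):
            dh = layer.backward(dh)
        return dh + dy


class SpliceScorer:
    """The scorer: parameters, config and provenance metadata.

    ``forward`` consumes one-hot input of shape ``(n, length, 4)`` (or a
    single ``(length, 4)`` sequence) with ``length > cl`` and returns
    probabilities of shape ``(n, length - cl, 3)`` aligned to input
    positions ``cl/2 .. length - cl/2 - 1``.
    """

    def __init__(self, config: ModelConfig, seed: int | None = None) -> None:
        self.config = config
        self.seed = seed
        self.metadata: dict = {}
        rng = np.random.default_rng(seed)
        ch = config.channels
        self.conv_in = Conv1d(4, ch, 1, 1, rng)
        self.skip_in = Conv1d(ch, ch, 1, 1, rng)
        self.units: list[_ResidualUnit] = []
        self.skip_convs: list[Conv1d] = []
        for w, d in zip(config.kernels, config.dilations):
            self.units.append(_ResidualUnit(ch, w, d, rng))
        for _ in range(config.n_skip_connections):
            self.skip_convs.append(Conv1d(ch, ch, 1, 1, rng))
        self.conv_out = Conv1d(ch, 3, 1, 1, rng)

    # -- structure -----------------------------------------------------
    @property
    def cl(self) -> int:
        return self.config.cl

    def _layers(self) -> list[tuple[str, Layer]]:
        out = [("conv_in", self.conv_in), ("skip_in", self.skip_in)]
        for i, u in enumerate(self.units):
            out.append((f"unit{i}", u))
        for i, s in enumerate(self.skip_convs):
            out.append((f"skip{i}", s))
        out.append(("conv_out", self.conv_out))
        return out

    def named_params(self) -> list[tuple[str, Param]]:
        out = []
        for lname, layer in self._layers():
            for pname, p in layer.params():
                out.append((f"{lname}.{pname}", p))
        return out

    def parameters(self) -> list[Param]:
        return [p for _, p in self.named_params()]

    def named_buffers(self) -> list[tuple[str, np.ndarray]]:
        out = []
        for lname, layer in self._layers():
            for bname, b in layer.buffers():
                out.append((f"{lname}.{bname}", b))
        return out

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())

    # -- forward / backward --------------------------------------------
    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Cropped logits of shape (n, length - cl, 3); input (n, length, 4)."""
        squeeze = x.ndim == 2
        if squeeze:
            x = x[None]
        n, length, c = x.shape
        if c != 4:
            raise ValueError(f"expected one-hot input with 4 channels, got {c}")
        cl = self.cl
        if length <= cl:
            raise ValueError(
                f"input length {length} must exceed the cropping length {cl} "
                f"(minimum {cl + 1} nt)"
            )
        h = np.ascontiguousarray(np.transpose(x, (0, 2, 1)), dtype=np.float32)
        t = self.conv_in.forward(h, training)
        skip = self.skip_in.forward(t, training)
        tap = 0
        self._skip_tapped: list[int] = []
        for i, unit in enumerate(self.units):
            t = unit.forward(t, training)
            if (i + 1) % self.config.skip_every == 0:
                skip = skip + self.skip_convs[tap].forward(t, training)
                self._skip_tapped.append(i)
                tap += 1
        logits = self.conv_out.forward(skip, training)
        half = cl // 2
        self._full_len = length
        out = logits[:, :, half : length - half]
        out = np.transpose(out, (0, 2, 1))
        return out[0] if squeeze else out

    def backward_from_logits(self, dlogits: np.ndarray) -> None:
        """Backpropagate d(loss)/d(cropped logits) into parameter gradients."""
        if dlogits.ndim == 2:
            dlogits = dlogits[None]
        n, lout, _ = dlogits.shape
        half = self.cl // 2
        full = np.zeros((n, 3, self._full_len), dtype=np.float32)
        full[:, :, half : half + lout] = np.transpose(dlogits, (0, 2, 1))
        dskip = self.conv_out.backward(full)
        dt = np.zeros_like(dskip)
        tap = len(self.skip_convs) - 1
        for i in range(len(self.units) - 1, -1, -1):
            if (i + 1) % self.config.skip_every == 0:
                dt = dt + self.skip_convs[tap].backward(dskip)
                tap -= 1
            dt = self.units[i].backward(dt)
        dt = dt + self.skip_in.backward(dskip)
        self.conv_in.backward(dt)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Per-position class probabilities (rows sum to 1)."""
        return softmax(self.forward_logits(x, training), axis=-1)

    # predict-module protocol: batch scoring on (n, L, 4) -> (n, L-cl, 3)
    def score_batch(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, training=False)

    # -- state ----------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param:{n}": p.value for n, p in self.named_params()}
        state.update({f"buffer:{n}": b for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for n, p in self.named_params():
            src = state[f"param:{n}"]
            if src.shape != p.value.shape:
                raise ValueError(f"shape mismatch for parameter {n}: {src.shape} vs {p.value.shape}")
            p.value[...] = src
        for n, b in self.named_buffers():
            b[...] = state[f"buffer:{n}"]


def build_scorer(config: ModelConfig, seed: int | None = None) -> SpliceScorer:
    """Instantiate a scorer with seeded weight initialization."""
    return SpliceScorer(config, seed=seed)


def save_checkpoint(scorer: SpliceScorer, path) -> None:
    """Serialize parameters, buffers, config and seed to an .npz file."""
    meta = {
        "config": scorer.config.to_dict(),
        "seed": scorer.seed,
        "metadata": scorer.metadata,
    }
    arrays = dict(scorer.state_dict())
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path, config: ModelConfig | None = None) -> SpliceScorer:
    """Load a checkpoint; refuses to load into a mismatched config."""
    with np.load(path) as npz:
        arrays = {k: npz[k] for k in npz.files}
    meta = json.loads(bytes(arrays.pop("__meta__")).decode())
    stored = ModelConfig.from_dict(meta["config"])
    if config is not None and config != stored:
        for fld in ("flank", "kernels", "dilations", "channels", "skip_every"):
            if getattr(config, fld) != getattr(stored, fld):
                raise ValueError(
                    f"checkpoint config mismatch in field '{fld}': "
                    f"checkpoint has {getattr(stored, fld)}, requested {getattr(config, fld)}"
                )
    scorer = SpliceScorer(stored, seed=meta.get("seed"))
    scorer.metadata = meta.get("metadata", {})
    scorer.load_state_dict(arrays)
    return scorer
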