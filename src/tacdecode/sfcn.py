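"""SFCN: a lightweight fully convolutional 3D classifier.

The architecture follows the simple fully convolutional network used for
brain-MRI prediction tasks: a stack of feature blocks, each a 3x3x3
convolution + (optional) batch norm + ReLU, most followed by 2x max
pooling, then a final block with a 1x1x1 convolution, and a head of global
average pooling + dropout + a fully connected layer producing class scores.
The last feature block's ReLU output is the Grad-CAM target layer.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn


@dataclass(frozen=True)
class SFCNConfig:
    """Architecture knobs.

    ``block_channels`` sets one output width per block; every block except
    the last uses a 3x3x3 kernel and the last a 1x1x1 kernel.
    ``pool_blocks`` flags which blocks end in 2x max pooling (default: all
    but the last).  The published full-scale widths are
    (32, 64, 128, 256, 256, 64); the default here is the scaled-down
    6-block variant.  Note that k pooling blocks shrink each axis 2**k-fold:
    on small grids use ``scaled_down`` so the saliency layer keeps a usable
    spatial extent.
    """

    in_channels: int = 1
    block_channels: tuple = (8, 16, 32, 32, 32, 16)
    pool_blocks: tuple | None = None
    n_classes: int = 2
    batch_norm: bool = True
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.block_channels) < 1:
            raise ValueError("at least one block required")
        if self.pool_blocks is not None \
                and len(self.pool_blocks) != len(self.block_channels):
            raise ValueError("pool_blocks length must match block_channels")

    @property
    def pools(self) -> tuple:
        if self.pool_blocks is not None:
            return tuple(self.pool_blocks)
        n = len(self.block_channels)
        return tuple(i < n - 1 for i in range(n))

    @classmethod
    def full_scale(cls, **kw) -> "SFCNConfig":
        return cls(block_channels=(32, 64, 128, 256, 256, 64), **kw)

    @classmethod
    def scaled_down(cls, grid_shape=(32, 32, 32), **kw) -> "SFCNConfig":
        """Desk-scale variant: 3 blocks (8, 16, 16) pooling only once.

        A 32-voxel axis keeps a 16-voxel saliency map and the last
        convolutional block's receptive field stays at 8 voxels, about one
        ROI diameter — deeper/more-pooled variants smear Grad-CAM maps over
        neighbouring regions at this grid size.
        """
        return cls(block_channels=(8, 16, 16),
                   pool_blocks=(True, False, False), **kw)

    def validate_grid(self, grid_shape) -> None:
        """Raise if the pooling chain would exhaust the grid."""
        n_pools = sum(self.pools)
        for ax in grid_shape:
            if ax // (2 ** n_pools) < 1 or ax % (2 ** n_pools):
                raise ValueError(
                    f"grid {tuple(grid_shape)} cannot sustain {n_pools} "
                    "2x poolings; use fewer blocks/pools or a larger grid")

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=list, indent=2)


class SFCN:
    """The classifier: ``features`` (conv blocks) then ``head`` (GAP + FC).

    ``forward`` returns class scores (logits); ``forward_with_activation``
    additionally returns a named feature activation, and
    ``backward_to_activation`` the gradient of a class score with respect
    to it — the two hooks Grad-CAM needs.
    """

    def __init__(self, config: SFCNConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        layers = []
        c_prev = config.in_channels
        n = len(config.block_channels)
        for i, c in enumerate(config.block_channels):
            k = 1 if i == n - 1 else 3
            blk = f"block{i + 1}"
            layers.append(nn.Conv3d(c_prev, c, k=k, bias=not config.batch_norm,
                                    rng=rng, name=f"{blk}.conv"))
            if config.batch_norm:
                layers.append(nn.BatchNorm3d(c, name=f"{blk}.bn"))
            layers.append(nn.ReLU(name=f"{blk}.relu"))
            if config.pools[i]:
                layers.append(nn.MaxPool3d(name=f"{blk}.pool"))
            c_prev = c
        self.features = nn.Sequential(layers, name="features")
        self.head = nn.Sequential([
            nn.GlobalAvgPool(name="gap"),
            nn.Dropout(config.dropout, rng=np.random.default_rng(
                [config.seed, 1]), name="dropout"),
            nn.Linear(c_prev, config.n_classes, rng=rng, name="fc"),
        ], name="head")
        #: default Grad-CAM target: the last conv block's ReLU output
        self.gradcam_layer = f"block{n}.relu"

    # -- parameter plumbing -------------------------------------------------
    def params(self):
        return self.features.params() + self.head.params()

    def n_parameters(self) -> int:
        return nn.count_parameters(self)

    def zero_grads(self):
        nn.zero_grads(self)

    def get_state(self) -> dict:
        state = nn.get_state(self)
        for layer in self.features.layers:
            if isinstance(layer, nn.BatchNorm3d):
                state[f"{layer.name}.running_mean"] = layer.running_mean.copy()
                state[f"{layer.name}.running_var"] = layer.running_var.copy()
        return state

    def set_state(self, state: dict):
        nn.set_state(self, state)
        for layer in self.features.layers:
            if isinstance(layer, nn.BatchNorm3d):
                layer.running_mean[...] = state[f"{layer.name}.running_mean"]
                layer.running_var[...] = state[f"{layer.name}.running_var"]

    # -- computation --------------------------------------------------------
    def _check_input(self, x):
        if x.ndim != 5:
            raise ValueError("input must be (N, C, D, H, W)")
        self.config.validate_grid(x.shape[2:])

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._check_input(x)
        return self.head.forward(self.features.forward(x, train=train),
                                 train=train)

    def forward_with_activation(self, x: np.ndarray, layer: str | None = None,
                                train: bool = False):
        self._check_input(x)
        layer = self.gradcam_layer if layer is None else layer
        feats, act = self.features.forward(x, train=train, capture=layer)
        logits = self.head.forward(feats, train=train)
        return logits, act

    def backward(self, dlogits: np.ndarray, need_dx: bool = False):
        """Backprop from the logits; accumulates parameter gradients."""
        dfeat = self.head.backward(dlogits, need_dx=True)
        return self.features.backward(dfeat, need_dx=need_dx)

    def backward_to_activation(self, dlogits: np.ndarray,
                               layer: str | None = None) -> np.ndarray:
        """Gradient of ``sum(dlogits * logits)`` w.r.t. a named feature
        activation (stops there; parameter grads above it still accumulate)."""
        layer = self.gradcam_layer if layer is None else layer
        if layer not in self.features.layer_names():
            raise KeyError(f"unknown layer {layer!r}; available: "
                           f"{self.features.layer_names()}")
        dfeat = self.head.backward(dlogits, need_dx=True)
        return self.features.backward(dfeat, need_dx=True, stop_at=layer)

    def predict(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Argmax class predictions in eval mode, batched."""
        out = []
        for i in range(0, len(x), batch_size):
            out.append(self.forward(x[i:i + batch_size]).argmax(axis=1))
        return np.concatenate(out) if out else np.empty(0, dtype=int)


def build_sfcn(config: SFCNConfig) -> SFCN:
    """Construct an SFCN classifier from its configuration."""
    return SFCN(config)


def count_parameters(model) -> int:
    """Exact number of trainable scalars (convenience re-export)."""
    return nn.count_parameters(model)


def save_checkpoint(model: SFCN, path) -> None:
    """Weights as .npz plus a JSON architecture sidecar."""
    state = model.get_state()
    np.savez_compressed(str(path), **state)
    sidecar = str(path) + ".json"
    with open(sidecar, "w") as fh:
        fh.write(model.config.to_json())


def load_checkpoint(config: SFCNConfig, path) -> SFCN:
    model = SFCN(config)
    with np.load(str(path)) as data:
        model.set_state({k: data[k] for k in data.files})
    return model
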