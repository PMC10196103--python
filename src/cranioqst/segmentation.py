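"""Feature-swapping U-Net for multi-tissue sellar segmentation.

A 2D encoder-decoder segments each sagittal slice into the seven classes.
The distinctive element is a *feature-swapping layer* between encoder and
decoder: encoder feature maps of different resolutions are exchanged —
each level receives the others' features resampled to its own grid
(strided subsampling downward, bilinear upsampling upward), projected by a
1x1 convolution and added — so that fine levels see semantic context and
coarse levels retain the localization of small structures (pituitary,
cistern) that aggressive downsampling would otherwise lose.  Deep
supervision attaches auxiliary heads to intermediate decoder resolutions
to stabilise training; the loss is an equally weighted sum of softmax
cross-entropy and multi-class soft Dice.

Because the slice thickness (6 mm) is large relative to the in-plane
resolution, training and inference are purely 2D: a volume is processed as
its stack of sagittal slices and re-assembled.

The default configuration is desk-scale (depth 3, width 8, 64 x 64
slices) so that training runs in minutes on one CPU; depth and width are
free parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .label_schema import N_CLASSES, LabelMap, MRIVolume
from .nn.core import Module

__all__ = [
    "NetworkConfig",
    "SwapLayer",
    "SwapUNet",
    "SwapUNetSegmenter",
    "build_network",
    "feature_swap",
    "train_segmentation",
    "predict_segmentation",
    "slices_from_cohort",
]


@dataclass
class NetworkConfig:
    """Architecture and training settings for the segmentation network."""

    depth: int = 3
    base_width: int = 8
    swap_pairs: tuple = ((0, 1), (1, 2))
    n_classes: int = N_CLASSES
    in_channels: int = 1
    supervision_decay: float = 0.5     # aux-head weight halves per coarser level
    dice_weight: float = 0.5           # vs (1 - dice_weight) cross-entropy
    lr: float = 3e-3
    epochs: int = 30
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        for i, j in self.swap_pairs:
            if not (0 <= i < self.depth and 0 <= j < self.depth and i != j):
                raise ValueError(f"swap pair ({i},{j}) references invalid levels")
        if not 0.0 <= self.dice_weight <= 1.0:
            raise ValueError("dice_weight must lie in [0,1]")

    @property
    def supervision_weights(self) -> np.ndarray:
        """Normalized per-level loss weights, full resolution first."""
        n_sup = max(1, self.depth - 1)
        w = self.supervision_decay ** np.arange(n_sup)
        return w / w.sum()


class _ConvBlock(Module):
    def __init__(self, c_in, c_out, rng):
        self.conv1 = nn.Conv2d(c_in, c_out, 3, rng)
        self.act1 = nn.LeakyReLU()
        self.conv2 = nn.Conv2d(c_out, c_out, 3, rng)
        self.act2 = nn.LeakyReLU()

    def forward(self, x):
        return self.act2.forward(self.conv2.forward(self.act1.forward(self.conv1.forward(x))))

    def backward(self, g):
        return self.conv1.backward(self.act1.backward(self.conv2.backward(self.act2.backward(g))))


class SwapLayer(Module):
    """Cross-resolution feature exchange over an encoder pyramid.

    For every pair ``(i, j)`` with ``i < j`` the layer adds to level ``j``
    a 1x1-projected, stride-subsampled copy of level ``i``, and to level
    ``i`` a 1x1-projected bilinear upsampling of level ``j``.  All
    contributions are computed from the *input* pyramid, so the exchange
    is symmetric and order-independent.  With no pairs the layer is the
    identity and owns no parameters.
    """

    def __init__(self, channels: list[int], swap_pairs, rng):
        self.pairs = []
        self.proj_down = []   # per pair: Conv1x1 C_i -> C_j
        self.proj_up = []     # per pair: Conv1x1 C_j -> C_i
        self.down_ops = []
        self.up_ops = []
        for i, j in swap_pairs:
            i, j = (i, j) if i < j else (j, i)
            factor = 2 ** (j - i)
            self.pairs.append((i, j))
            self.proj_down.append(nn.Conv2d(channels[i], channels[j], 1, rng))
            self.proj_up.append(nn.Conv2d(channels[j], channels[i], 1, rng))
            self.down_ops.append(nn.Subsample(factor))
            self.up_ops.append(nn.UpsampleBilinear(factor))

    def forward(self, pyramid: list[np.ndarray]) -> list[np.ndarray]:
        out = [p.copy() for p in pyramid]
        for (i, j), pd, pu, down, up in zip(
            self.pairs, self.proj_down, self.proj_up, self.down_ops, self.up_ops
        ):
            out[j] += pd.forward(down.forward(pyramid[i]))
            out[i] += pu.forward(up.forward(pyramid[j]))
        return out

    def backward(self, grads: list[np.ndarray]) -> list[np.ndarray]:
        gin = [g.copy() for g in grads]
        for (i, j), pd, pu, down, up in zip(
            self.pairs, self.proj_down, self.proj_up, self.down_ops, self.up_ops
        ):
            gin[i] += down.backward(pd.backward(grads[j]))
            gin[j] += up.backward(pu.backward(grads[i]))
        return gin


class SwapUNet(Module):
    """Encoder-decoder with feature swapping and deep supervision.

    ``forward`` maps a batch of slices ``(N, in_channels, H, W)`` to a list
    of logits, one per supervised decoder level (full resolution first,
    each subsequent level at half the previous resolution), every one with
    ``n_classes`` channels.
    """

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        d, w = cfg.depth, cfg.base_width
        self.channels = [w * 2**k for k in range(d)]
        c_prev = cfg.in_channels
        self.enc_blocks = []
        self.pools = []
        for k in range(d):
            self.enc_blocks.append(_ConvBlock(c_prev, self.channels[k], rng))
            c_prev = self.channels[k]
            if k < d - 1:
                self.pools.append(nn.MaxPool2())
        self.swap = SwapLayer(self.channels, cfg.swap_pairs, rng)
        self.ups = []
        self.dec_blocks = []
        for k in range(d - 2, -1, -1):
            self.ups.append(nn.UpsampleNearest2())
            self.dec_blocks.append(
                _ConvBlock(self.channels[k + 1] + self.channels[k], self.channels[k], rng)
            )
        # heads at decoder levels 0 .. d-2 (full resolution first)
        self.heads = [
            nn.Conv2d(self.channels[k], cfg.n_classes, 1, rng) for k in range(max(1, d - 1))
        ]

    # -- forward -----------------------------------------------------------
    def forward(self, x: np.ndarray) -> list[np.ndarray]:
        d = self.cfg.depth
        enc = []
        h = x
        for k in range(d):
            h = self.enc_blocks[k].forward(h)
            enc.append(h)
            if k < d - 1:
                h = self.pools[k].forward(h)
        swapped = self.swap.forward(enc)
        self._n_levels = d
        dec = {d - 1: swapped[d - 1]}
        for step, k in enumerate(range(d - 2, -1, -1)):
            u = self.ups[step].forward(dec[k + 1])
            cat = np.concatenate([u, swapped[k]], axis=1)
            dec[k] = self.dec_blocks[step].forward(cat)
        self._dec_levels = [k for k in range(0, max(1, d - 1))]
        logits = [self.heads[i].forward(dec[k]) for i, k in enumerate(self._dec_levels)]
        return logits

    def backward(self, grads: list[np.ndarray]) -> None:
        """Backpropagate per-level logit gradients; accumulates parameter grads."""
        d = self.cfg.depth
        gdec = {k: self.heads[i].backward(g) for (i, k), g in zip(enumerate(self._dec_levels), grads)}
        for k in range(1, d):
            gdec.setdefault(k, 0.0)
        gswap = [None] * d
        # walk decoder from fine to coarse: dec[k] depends on dec[k+1]
        for step, k in zip(range(d - 2, -1, -1), range(0, d - 1)):
            gcat = self.dec_blocks[step].backward(gdec[k])
            c_up = self.channels[k + 1]
            gu, gskip = gcat[:, :c_up], gcat[:, c_up:]
            gdec[k + 1] = gdec[k + 1] + self.ups[step].backward(gu)
            gswap[k] = gskip
        gswap[d - 1] = gdec[d - 1]
        genc = self.swap.backward(gswap)
        g = None
        for k in range(d - 1, -1, -1):
            gk = genc[k] if g is None else genc[k] + self.pools[k].backward(g)
            g = self.enc_blocks[k].backward(gk)


def build_network(cfg: NetworkConfig) -> SwapUNet:
    """Construct a seeded segmentation network from a config."""
    return SwapUNet(cfg)


def feature_swap(pyramid: list[np.ndarray], swap_layer: SwapLayer) -> list[np.ndarray]:
    """Apply a feature-swapping layer to an encoder pyramid."""
    return swap_layer.forward(pyramid)


# --------------------------------------------------------------------------

def _downsample_labels(y: np.ndarray, factor: int) -> np.ndarray:
    return y[:, ::factor, ::factor]


def _normalize_slices(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=(1, 2), keepdims=True)
    sd = x.std(axis=(1, 2), keepdims=True)
    return (x - mu) / np.maximum(sd, 1e-6)


class SwapUNetSegmenter(BaseEstimator):
    """sklearn-style estimator wrapping :class:`SwapUNet` training/inference.

    ``fit(X, y)`` takes slices ``X`` of shape (n, H, W) (float intensities,
    z-scored internally) and integer label slices ``y`` of the same shape,
    and minimises the combined soft-Dice + cross-entropy loss with
    deep-supervision weighting.  ``predict(X)`` returns per-pixel argmax
    labels; ``predict_volume`` runs a whole sagittal stack.
    """

    def __init__(self, depth=3, base_width=8, swap_pairs=((0, 1), (1, 2)),
                 supervision_decay=0.5, dice_weight=0.5, lr=3e-3, epochs=30,
                 batch_size=8, random_state=0):
        self.depth = depth
        self.base_width = base_width
        self.swap_pairs = swap_pairs
        self.supervision_decay = supervision_decay
        self.dice_weight = dice_weight
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    def _config(self) -> NetworkConfig:
        return NetworkConfig(
            depth=self.depth, base_width=self.base_width,
            swap_pairs=tuple(tuple(p) for p in self.swap_pairs),
            supervision_decay=self.supervision_decay, dice_weight=self.dice_weight,
            lr=self.lr, epochs=self.epochs, batch_size=self.batch_size,
            seed=self.random_state,
        )

    def _batch_loss(self, net, xb, yb, sup_w):
        logits = net.forward(xb)
        total = 0.0
        grads = []
        for lvl, (lg, w) in enumerate(zip(logits, sup_w)):
            yl = _downsample_labels(yb, 2**lvl)
            l_ce, g_ce = nn.softmax_cross_entropy(lg, yl)
            l_dc, g_dc = nn.soft_dice_loss(lg, yl)
            dw = self.dice_weight
            total += w * ((1 - dw) * l_ce + dw * l_dc)
            grads.append(w * ((1 - dw) * g_ce + dw * g_dc))
        return total, logits, grads

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 3 or X.shape != y.shape:
            raise ValueError("X and y must be matching (n, H, W) stacks")
        if X.shape[0] < 1:
            raise ValueError("need at least one training slice")
        cfg = self._config()
        net = build_network(cfg)
        opt = nn.Adam(net.params(), lr=cfg.lr)
        rng = np.random.default_rng(cfg.seed + 1)
        Xn = _normalize_slices(X)[:, None]     # (n, 1, H, W)
        sup_w = cfg.supervision_weights
        n = X.shape[0]
        history = []
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            n_batches = 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                loss, _, grads = self._batch_loss(net, Xn[idx], y[idx], sup_w)
                opt.zero_grad()
                net.backward(grads)
                opt.step()
                epoch_loss += loss
                n_batches += 1
            history.append(epoch_loss / n_batches)
        self.network_ = net
        self.config_ = cfg
        self.loss_history_ = np.asarray(history)
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        squeeze = X.ndim == 2
        if squeeze:
            X = X[None]
        Xn = _normalize_slices(X)[:, None]
        out = []
        for start in range(0, X.shape[0], self.batch_size):
            logits = self.network_.forward(Xn[start : start + self.batch_size])
            out.append(np.argmax(logits[0], axis=1))
        pred = np.concatenate(out, axis=0).astype(np.int16)
        return pred[0] if squeeze else pred

    def predict_volume(self, vol: MRIVolume) -> LabelMap:
        labels = self.predict(vol.voxels)
        return LabelMap(labels, spacing=vol.spacing)


def train_segmentation(data, cfg: NetworkConfig | None = None):
    """Train on paired (MRI slice stack, label slice stack) data.

    ``data`` is a list of ``(MRIVolume, LabelMap)`` pairs (sliced along
    axis 0) or a pre-built ``(X, y)`` tuple of (n, H, W) stacks.  Returns
    the fitted :class:`SwapUNetSegmenter` and its per-epoch loss history.
    """
    cfg = cfg or NetworkConfig()
    if isinstance(data, tuple):
        X, y = data
    else:
        X, y = slices_from_cohort(data)
    est = SwapUNetSegmenter(
        depth=cfg.depth, base_width=cfg.base_width, swap_pairs=cfg.swap_pairs,
        supervision_decay=cfg.supervision_decay, dice_weight=cfg.dice_weight,
        lr=cfg.lr, epochs=cfg.epochs, batch_size=cfg.batch_size,
        random_state=cfg.seed,
    ).fit(X, y)
    return est, est.loss_history_


def predict_segmentation(network, vol: MRIVolume) -> LabelMap:
    """Per-slice argmax segmentation of a whole volume."""
    if isinstance(network, SwapUNetSegmenter):
        return network.predict_volume(vol)
    est = SwapUNetSegmenter()
    est.network_ = network
    return est.predict_volume(vol)


def slices_from_cohort(cohort) -> tuple[np.ndarray, np.ndarray]:
    """Stack all sagittal slices of a phantom cohort into (X, y) arrays."""
    xs, ys = [], []
    for item in cohort:
        mri, lm = item[0], item[1]
        xs.append(mri.voxels)
        ys.append(lm.voxels)
    return np.concatenate(xs, axis=0), np.concatenate(ys, axis=0)
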