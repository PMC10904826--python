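"""Convolutional classifier with attention-map access.

The architecture mirrors the standard attention-guided set-up: a
convolutional feature extractor, global average pooling, dropout and a
fully connected head.  Because the head is linear on the pooled features,
the gradient of a class score with respect to the last-layer feature maps
is spatially constant and available in closed form:

    d f_y / d A_k(i, j) = W[y, k] * drop_k * inv_sigma_k / (m * n)

(inv_sigma_k comes from the fixed pooled-feature calibration; see
``CNNClassifier.calibrate``)

so the gradient-weighted class-activation map used during training is the
exact Grad-CAM of this architecture, and back-propagating through it needs
no second-order machinery.

The reference recipe's 50-layer pretrained backbone is not available in
this offline build; the registry provides small fully-trainable CNN
backbones ("tiny", "small") suitable for CPU experiments, and rejects
unavailable identifiers with a clear error.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .attention import AttentionMap, FeatureStack, LossConfig
from .autodiff import Tensor

__all__ = ["BACKBONES", "CNNClassifier", "build_model"]

# name -> list of (out_channels, stride) conv blocks, 3x3 kernels
BACKBONES = {
    "tiny": ((8, 2), (16, 2)),
    "small": ((8, 2), (16, 2), (32, 2)),
}

_UNAVAILABLE = {
    "resnet50": "requires a deep-learning framework with pretrained weights, "
    "which is not available in this offline build",
}


def _kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class CNNClassifier:
    """Feature extractor -> GAP -> dropout -> linear head."""

    def __init__(self, backbone: str = "tiny", n_classes: int = 3,
                 dropout_rate: float = 0.25, in_channels: int = 1,
                 seed: int = 0, pretrained: bool = False,
                 normalize_input: bool = True):
        if backbone in _UNAVAILABLE:
            raise ValueError(f"backbone {backbone!r} unavailable: {_UNAVAILABLE[backbone]}")
        if backbone not in BACKBONES:
            raise ValueError(
                f"unknown backbone {backbone!r}; valid: {sorted(BACKBONES)}"
            )
        if pretrained:
            raise ValueError("pretrained weights are not available offline")
        if not 0.0 <= dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        self.backbone = backbone
        self.n_classes = int(n_classes)
        self.dropout_rate = float(dropout_rate)
        self.blocks = BACKBONES[backbone]
        rng = np.random.Generator(np.random.PCG64(seed))
        self.conv_w: list[Tensor] = []
        self.conv_b: list[Tensor] = []
        cin = in_channels
        for cout, _stride in self.blocks:
            fan_in = cin * 9
            self.conv_w.append(
                Tensor(_kaiming_uniform(rng, (cout, cin, 3, 3), fan_in),
                       requires_grad=True)
            )
            self.conv_b.append(Tensor(np.zeros(cout), requires_grad=True))
            cin = cout
        self.feature_channels = cin
        # Kaiming-uniform initialised FC head
        self.fc_w = Tensor(
            _kaiming_uniform(rng, (self.n_classes, cin), cin), requires_grad=True
        )
        self.fc_b = Tensor(np.zeros(self.n_classes), requires_grad=True)
        self.normalize_input = bool(normalize_input)
        # fixed affine calibration of the pooled features (see calibrate())
        self.feat_mu = np.zeros(cin)
        self.feat_inv_sigma = np.ones(cin)

    # -- parameter plumbing --------------------------------------------------
    @property
    def parameters(self) -> list[Tensor]:
        return [*self.conv_w, *self.conv_b, self.fc_w, self.fc_b]

    def state_dict(self) -> dict:
        state = {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters)}
        state["feat_mu"] = self.feat_mu.copy()
        state["feat_inv_sigma"] = self.feat_inv_sigma.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, p in enumerate(self.parameters):
            p.data = np.array(state[f"p{i}"], dtype=np.float64, copy=True)
        if "feat_mu" in state:
            self.feat_mu = np.array(state["feat_mu"], dtype=np.float64, copy=True)
            self.feat_inv_sigma = np.array(
                state["feat_inv_sigma"], dtype=np.float64, copy=True
            )

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.load_state_dict({k: data[k] for k in data.files})

    # -- forward -------------------------------------------------------------
    def calibrate(self, images: np.ndarray) -> None:
        """Fix the pooled-feature affine from a calibration batch.

        Standardises each pooled channel to zero mean / unit variance over
        the given images; channels whose spread is below 2% of the largest
        are treated as dead and zeroed.  Run once before training: without
        it the pooled features of a freshly initialised extractor are tiny
        against their common-mode component and the head learns extremely
        slowly.  A no-op affine (mu=0, 1/sigma=1) is the default.
        """
        _logits, features, _mask = self.forward(images)
        pooled = features.data.mean(axis=(2, 3))
        std = pooled.std(axis=0)
        alive = std >= 0.02 * max(std.max(), 1e-12)
        self.feat_mu = pooled.mean(axis=0)
        self.feat_inv_sigma = np.where(alive, 1.0 / np.where(alive, std, 1.0), 0.0)

    def forward(self, images: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        """Run a batch of (N, H, W) float images.

        Returns (logits Tensor (N, K), features Tensor (N, C, m, n),
        dropout mask (N, C) used on the calibrated pooled vector).
        """
        x = np.asarray(images, dtype=np.float64)
        if x.ndim == 3:
            x = x[:, None, :, :]
        if self.normalize_input:
            mu = x.mean(axis=(2, 3), keepdims=True)
            sd = x.std(axis=(2, 3), keepdims=True)
            x = (x - mu) / (sd + 1e-6)
        t = Tensor(x)
        for w, b, (_c, stride) in zip(self.conv_w, self.conv_b, self.blocks):
            t = ad.relu(ad.conv2d(t, w, b, stride=stride))
        features = t  # (N, C, m, n)
        pooled = ad.tmean(features, axis=(2, 3))  # (N, C)
        calibrated = (pooled - self.feat_mu) * self.feat_inv_sigma
        n = pooled.data.shape[0]
        if train and self.dropout_rate > 0:
            if rng is None:
                raise ValueError("training-mode forward needs an rng for dropout")
            keep = 1.0 - self.dropout_rate
            drop_mask = (rng.random((n, self.feature_channels)) < keep) / keep
        else:
            drop_mask = np.ones((n, self.feature_channels))
        dropped = calibrated * drop_mask
        logits = ad.matmul(dropped, self.fc_w_t()) + self.fc_b
        return logits, features, drop_mask

    def fc_w_t(self) -> Tensor:
        """Transpose of the head weight as a graph node."""
        w = self.fc_w
        out_data = w.data.T

        def backward(g):
            if w.requires_grad:
                w._accumulate(g.T)

        return Tensor._from_op(out_data, (w,), backward)

    # -- attention access ----------------------------------------------------
    def cam_weights(self, class_idx: int, drop_row: np.ndarray | None = None,
                    spatial_size: int = 1, as_tensor: bool = False):
        """Closed-form Grad-CAM channel weights for one sample.

        ``drop_row`` is the (C,) dropout scaling applied to the pooled
        vector (ones at evaluation time).  When ``as_tensor`` is true the
        weights stay connected to the head parameters so the attention loss
        also trains the head.
        """
        scale = self.feat_inv_sigma / float(spatial_size)
        if drop_row is None:
            drop_row = np.ones(self.feature_channels)
        if as_tensor:
            return self.fc_w[int(class_idx)] * (drop_row * scale)
        return self.fc_w.data[int(class_idx)] * drop_row * scale

    def feature_stack(self, image: np.ndarray, target_class: int) -> FeatureStack:
        """Evaluation-mode features + analytic score gradients for one image."""
        _logits, features, _mask = self.forward(image[None])
        maps = features.data[0]  # (C, m, n)
        m, n = maps.shape[1:]
        w = self.cam_weights(target_class, spatial_size=m * n)
        grads = np.broadcast_to(w[:, None, None], maps.shape).copy()
        return FeatureStack(maps=maps, gradients=grads)

    def predict(self, images: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Argmax class indices for a stack of images."""
        images = np.asarray(images, dtype=np.float64)
        out = []
        for i in range(0, len(images), batch_size):
            logits, _f, _m = self.forward(images[i : i + batch_size])
            out.append(np.argmax(logits.data, axis=1))
        return np.concatenate(out) if out else np.zeros(0, dtype=np.intp)

    def gradcam(self, image: np.ndarray, target_class: int,
                config: LossConfig | None = None) -> AttentionMap:
        """Evaluation-mode attention map for one image and class."""
        from .attention import compute_gradcam

        stack = self.feature_stack(image, target_class)
        amap = compute_gradcam(stack, config or LossConfig(),
                               target_class=target_class)
        return amap


def build_model(config, n_classes: int) -> CNNClassifier:
    """Build a classifier from a TrainConfig-like object."""
    return CNNClassifier(
        backbone=getattr(config, "backbone", "tiny"),
        n_classes=n_classes,
        dropout_rate=getattr(config, "dropout_rate", 0.25),
        seed=getattr(config, "seed", 0),
        pretrained=getattr(config, "pretrained", False),
    )
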