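"""Dual-branch architecture: CNN on the original volume, convolutional
auto-encoder (CAE) on the synthetic ROI image, with cross-branch channel
concatenation after every convolution stage.

Per modality (MRI, PET) the model runs two parallel encoders of three
convolution stages each (conv -> ReLU -> batch norm -> 2x max pool). After
each stage, the CNN's feature maps and the CAE encoder's feature maps are
concatenated along channels and fed to the next stage of both branches,
so each branch sees the other's features at every depth. The CAE's final
maps are compressed by a fully connected layer into a latent vector z
(z = f(x_syn)); a mirrored three-stage decoder (upsample -> conv) maps z
back to image space, and its reconstruction is trained against the
synthetic image restricted to the 32 AD-related regions — forcing
attention to those regions. Flattened final maps from all modalities are
concatenated, passed through dropout and a small FC stack, and a softmax
gives the two class probabilities.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from ..features import ad_roi_indices, gm_roi_volumes, paint_synthetic_image, pet_roi_means
from ..phantom import AtlasLabelMap, PhantomSubject
from . import autodiff as ad
from .autodiff import DTYPE, Tensor
from .layers import BatchNorm, Conv3d, Linear

MODALITIES = ("MRI", "PET")
CROSS_MODES = ("bidirectional", "cae_to_cnn", "cnn_to_cae", "none")


@dataclasses.dataclass(frozen=True)
class BranchConfig:
    """Architecture knobs for one modality's branch pair.

    The three-stage structure is fixed; channel widths, kernel size,
    latent width Z and dropout are free. `input_shape` must be divisible
    by 8 (three 2x poolings).
    """

    input_shape: tuple[int, int, int] = (32, 32, 32)
    conv_channels: tuple[int, int, int] = (8, 8, 8)
    kernel_size: int = 3
    pool: str = "max2"
    latent_dim: int = 128
    dropout_rate: float = 0.5
    #: running-statistics update rate for batch norm; high by framework
    #: standards because desk-scale schedules see few optimizer steps
    bn_momentum: float = 0.5

    def __post_init__(self):
        if len(self.conv_channels) != 3:
            raise ValueError("exactly three convolution stages per branch")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.pool not in ("max2", "none"):
            raise ValueError("pool must be 'max2' or 'none'")
        if self.pool == "max2" and any(s % 8 for s in self.input_shape):
            raise ValueError("input_shape must be divisible by 8 with max2 pooling")


@dataclasses.dataclass(frozen=True)
class LossWeights:
    lambda_recon: float = 1.0
    lambda_cls: float = 1.0

    def __post_init__(self):
        if self.lambda_recon < 0 or self.lambda_cls < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.lambda_recon == 0 and self.lambda_cls == 0:
            raise ValueError("at least one loss weight must be positive")


class _ModalityBranches:
    """CNN + CAE encoder/decoder stack for one modality."""

    def __init__(self, cfg: BranchConfig, rng, init: str, cross_mode: str,
                 use_cae: bool):
        self.cfg = cfg
        self.cross_mode = cross_mode
        self.use_cae = use_cae
        ch = cfg.conv_channels
        k = cfg.kernel_size
        cnn_gets_cae = use_cae and cross_mode in ("bidirectional", "cae_to_cnn")
        cae_gets_cnn = cross_mode in ("bidirectional", "cnn_to_cae")
        self.cnn_convs, self.cnn_bns = [], []
        self.cae_convs, self.cae_bns = [], []
        cin_cnn, cin_cae = 1, 1
        for i in range(3):
            self.cnn_convs.append(Conv3d(cin_cnn, ch[i], k, rng, init))
            self.cnn_bns.append(BatchNorm(ch[i], momentum=cfg.bn_momentum))
            if use_cae:
                self.cae_convs.append(Conv3d(cin_cae, ch[i], k, rng, init))
                self.cae_bns.append(BatchNorm(ch[i], momentum=cfg.bn_momentum))
            cin_cnn = ch[i] * 2 if cnn_gets_cae else ch[i]
            cin_cae = ch[i] * 2 if cae_gets_cnn else ch[i]
        div = 8 if cfg.pool == "max2" else 1
        self.final_shape = tuple(s // div for s in cfg.input_shape)
        nspatial = int(np.prod(self.final_shape))
        self.flat_cae = ch[2] * nspatial
        if use_cae:
            self.enc_fc = Linear(self.flat_cae, cfg.latent_dim, rng, init)
            self.dec_fc = Linear(cfg.latent_dim, self.flat_cae, rng, init)
            # decoder mirrors the encoder: three (upsample, conv) stages
            self.dec_convs = [
                Conv3d(ch[2], ch[1], k, rng, init),
                Conv3d(ch[1], ch[0], k, rng, init),
                Conv3d(ch[0], 1, k, rng, init),
            ]
        n_cls_ch = ch[2] * 2 if (use_cae and cross_mode != "none") else ch[2]
        self.feature_dim = n_cls_ch * nspatial

    def parameters(self) -> list[Tensor]:
        params = []
        for lyr in self.cnn_convs + self.cnn_bns + self.cae_convs + self.cae_bns:
            params.extend(lyr.parameters())
        if self.use_cae:
            params.extend(self.enc_fc.parameters())
            params.extend(self.dec_fc.parameters())
            for lyr in self.dec_convs:
                params.extend(lyr.parameters())
        return params

    def _pool(self, t: Tensor) -> Tensor:
        return ad.maxpool2(t) if self.cfg.pool == "max2" else t

    def forward(self, x_orig: Tensor, x_syn: Tensor | None, training: bool):
        """Returns (classifier features, latent z or None, x_hat or None)."""
        a, s = x_orig, x_syn
        for i in range(3):
            a_out = self._pool(self.cnn_bns[i](ad.relu(self.cnn_convs[i](a)),
                                               training))
            if self.use_cae:
                s_out = self._pool(self.cae_bns[i](ad.relu(self.cae_convs[i](s)),
                                                   training))
            if self.use_cae and self.cross_mode in ("bidirectional", "cae_to_cnn"):
                a = ad.concat([a_out, s_out])
            else:
                a = a_out
            if self.use_cae and self.cross_mode in ("bidirectional", "cnn_to_cae"):
                s = ad.concat([s_out, a_out])
            elif self.use_cae:
                s = s_out
        if not self.use_cae:
            n = a.shape[0]
            return ad.reshape(a, (n, -1)), None, None
        n = s_out.shape[0]
        z = self.enc_fc(ad.reshape(s_out, (n, self.flat_cae)))
        d = ad.relu(self.dec_fc(z))
        d = ad.reshape(d, (n, self.cfg.conv_channels[2]) + self.final_shape)
        for i, conv in enumerate(self.dec_convs):
            if self.cfg.pool == "max2":
                d = ad.upsample2(d)
            d = conv(d)
            if i < len(self.dec_convs) - 1:
                d = ad.relu(d)
        if self.cross_mode != "none":
            feats = ad.concat([a_out, s_out])
        else:
            feats = a_out
        return ad.reshape(feats, (n, -1)), z, d


class DualBranchModel:
    """The full multimodal classifier + auto-encoder ensemble.

    `cross_mode` selects the cross-branch wiring ("bidirectional" is the
    default; "none" severs it, for ablations), `use_cae=False` drops the
    auto-encoder branches entirely (CNN-only ablation).
    """

    def __init__(self, configs: Mapping[str, BranchConfig], seed: int = 0,
                 init: str = "he", cross_mode: str = "bidirectional",
                 use_cae: bool = True, fc_hidden: int = 64):
        if not configs:
            raise ValueError("at least one modality is required")
        for m in configs:
            if m not in MODALITIES:
                raise ValueError(f"unknown modality {m!r}; valid: {MODALITIES}")
        if cross_mode not in CROSS_MODES:
            raise ValueError(f"cross_mode must be one of {CROSS_MODES}")
        shapes = {cfg.input_shape for cfg in configs.values()}
        if len(shapes) > 1:
            raise ValueError(f"modalities have incompatible input shapes: {shapes}")
        self.modalities = tuple(m for m in MODALITIES if m in configs)
        self.configs = dict(configs)
        self.cross_mode = cross_mode
        self.use_cae = use_cae
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.branches = {m: _ModalityBranches(configs[m], rng, init,
                                              cross_mode, use_cae)
                         for m in self.modalities}
        total_feat = sum(b.feature_dim for b in self.branches.values())
        self.fc1 = Linear(total_feat, fc_hidden, rng, init)
        self.fc2 = Linear(fc_hidden, 2, rng, init)
        self.dropout_rate = max(configs[m].dropout_rate for m in self.modalities)
        self._dropout_rng = np.random.default_rng(rng.integers(2 ** 31))

    def parameters(self) -> list[Tensor]:
        params = []
        for b in self.branches.values():
            params.extend(b.parameters())
        params.extend(self.fc1.parameters())
        params.extend(self.fc2.parameters())
        return params

    def forward(self, inputs: Mapping[str, tuple[np.ndarray, np.ndarray | None]],
                training: bool = False):
        """Run the model.

        `inputs[m] = (x_orig, x_syn)`, each (N, D, H, W) float arrays
        (x_syn may be None when the CAE branch is disabled). Returns
        (class-probability array (N, 2), logits Tensor, {m: x_hat Tensor}).
        """
        missing = [m for m in self.modalities if m not in inputs]
        if missing:
            raise ValueError(f"missing input for modalities {missing}")
        feats, recons = [], {}
        for m in self.modalities:
            x_orig, x_syn = inputs[m]
            xo = Tensor(np.asarray(x_orig, DTYPE)[:, None])
            xs = Tensor(np.asarray(x_syn, DTYPE)[:, None]) if x_syn is not None else None
            if self.use_cae and xs is None:
                raise ValueError(f"modality {m} needs a synthetic image input")
            f, _z, xhat = self.branches[m].forward(xo, xs, training)
            feats.append(f)
            if xhat is not None:
                recons[m] = xhat
        h = ad.concat(feats, axis=1)
        h = ad.dropout(h, self.dropout_rate, self._dropout_rng, training)
        h = ad.relu(self.fc1(h))
        logits = self.fc2(h)
        z = logits.data - logits.data.max(axis=1, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=1, keepdims=True)
        return probs, logits, recons

    def encode(self, modality: str, x_syn: np.ndarray) -> np.ndarray:
        """Latent representation z = f(x_syn) for one modality (eval mode)."""
        if not self.use_cae:
            raise ValueError("model built without CAE branches")
        b = self.branches[modality]
        xs = Tensor(np.asarray(x_syn, DTYPE)[:, None])
        xo = Tensor(np.zeros_like(xs.data))
        _f, zt, _x = b.forward(xo, xs, training=False)
        return zt.data.copy()


def build_model(configs: Mapping[str, BranchConfig], seed: int = 0,
                **kwargs) -> DualBranchModel:
    """Construct a :class:`DualBranchModel` for the requested modalities."""
    return DualBranchModel(configs, seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# losses (reporting-scale, plain NumPy) and reconstruction targets


def reconstruction_loss(x_hat: np.ndarray, target: np.ndarray) -> float:
    """Mean over voxels of the squared reconstruction error."""
    x_hat = np.asarray(x_hat, dtype=float)
    target = np.asarray(target, dtype=float)
    if x_hat.shape != target.shape:
        raise ValueError(f"shape mismatch: {x_hat.shape} vs {target.shape}")
    return float(np.mean((x_hat - target) ** 2))


def classification_loss(probabilities: Sequence[float], label: int,
                        eps: float = 1e-12) -> float:
    """Two-class cross-entropy: -log p(true class), with clipping at eps."""
    p = np.asarray(probabilities, dtype=float)
    if p.shape != (2,):
        raise ValueError(f"probabilities must have length 2, got shape {p.shape}")
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"invalid probability vector {p}")
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label}")
    return float(-np.log(max(p[label], eps)))


def total_loss(cls_loss: float, recon_losses: Mapping[str, float],
               weights: LossWeights) -> float:
    """lambda_cls * classification + lambda_recon * sum of reconstructions."""
    return float(weights.lambda_cls * cls_loss
                 + weights.lambda_recon * sum(recon_losses.values()))


def reconstruction_target(subject: PhantomSubject, atlas: AtlasLabelMap,
                          modality: str,
                          roi_subset: Sequence[int] | None = None) -> np.ndarray:
    """The CAE's training target: the synthetic image masked to the AD ROIs.

    Features are extracted from the subject's own volumes (GM fractions
    for MRI, ROI means for PET) and painted back restricted to
    `roi_subset` (default: the 32 AD-related regions).
    """
    if roi_subset is None:
        roi_subset = ad_roi_indices().indices
    if modality == "MRI":
        feats = gm_roi_volumes(subject.gm_map, atlas, subject.subject_id)
    elif modality == "PET":
        feats = pet_roi_means(subject.pet_volume, atlas, subject.subject_id)
    else:
        raise ValueError(f"unknown modality {modality!r}")
    subset = [r for r in roi_subset if r in feats.values]
    return paint_synthetic_image(feats, atlas, subset)


def synthetic_inputs(subject: PhantomSubject, atlas: AtlasLabelMap,
                     modality: str) -> np.ndarray:
    """The full-parcellation synthetic image fed to the CAE encoder."""
    if modality == "MRI":
        feats = gm_roi_volumes(subject.gm_map, atlas, subject.subject_id)
    elif modality == "PET":
        feats = pet_roi_means(subject.pet_volume, atlas, subject.subject_id)
    else:
        raise ValueError(f"unknown modality {modality!r}")
    return paint_synthetic_image(feats, atlas)
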