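"""Training loop: Adam on the joint classification + reconstruction loss.

The objective is lambda_cls * cross-entropy(softmax head) +
lambda_recon * sum over modalities of MSE(x_hat, 32-ROI synthetic
target) — both branches and the fusion head are optimized jointly in a
single stage.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ..features import ad_roi_indices
from ..phantom import AtlasLabelMap, PhantomSubject
from . import autodiff as ad
from .autodiff import DTYPE, Tensor
from .layers import Adam
from .model import (BranchConfig, DualBranchModel, LossWeights,
                    reconstruction_target, synthetic_inputs)


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    Defaults are desk-scale (small phantoms, a few epochs, lr 1e-3);
    the reference large-scale settings are Adam with lr 1e-4, 100
    epochs and batch size 30.
    """

    lr: float = 2e-3
    epochs: int = 10
    batch_size: int = 16
    loss_weights: LossWeights = LossWeights()
    shuffle: bool = True


@dataclasses.dataclass
class ModelDataset:
    """Network-ready arrays for a list of subjects.

    x_orig[m], x_syn[m], target[m]: (N, D, H, W); y: (N,) int labels.
    Synthetic images and reconstruction targets are computed from each
    subject's own volumes, so slicing by index never mixes subjects.
    """

    x_orig: Mapping[str, np.ndarray]
    x_syn: Mapping[str, np.ndarray]
    target: Mapping[str, np.ndarray]
    y: np.ndarray
    subject_ids: list[str]
    modalities: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, idx: np.ndarray) -> "ModelDataset":
        return ModelDataset(
            x_orig={m: v[idx] for m, v in self.x_orig.items()},
            x_syn={m: v[idx] for m, v in self.x_syn.items()},
            target={m: v[idx] for m, v in self.target.items()},
            y=self.y[idx],
            subject_ids=[self.subject_ids[i] for i in idx],
            modalities=self.modalities)


def block_mean(volume: np.ndarray, factor: int) -> np.ndarray:
    """Average-pool a 3D volume by an integer factor (dims must divide)."""
    if factor == 1:
        return volume
    d, h, w = volume.shape
    if d % factor or h % factor or w % factor:
        raise ValueError(f"volume shape {volume.shape} not divisible by {factor}")
    return volume.reshape(d // factor, factor, h // factor, factor,
                          w // factor, factor).mean(axis=(1, 3, 5))


def prepare_dataset(subjects: Sequence[PhantomSubject], atlas: AtlasLabelMap,
                    labels: Sequence[int], modalities: Sequence[str] = ("MRI", "PET"),
                    roi_subset: Sequence[int] | None = None,
                    downsample: int = 1) -> ModelDataset:
    """Extract features, paint synthetic images and stack network inputs.

    `downsample` block-averages every network input (and reconstruction
    target) by that factor: feature extraction and painting still happen
    on the native atlas grid, only the network's working resolution
    shrinks.
    """
    if roi_subset is None and len(atlas.region_index_set) >= 90:
        roi_subset = ad_roi_indices().indices
    elif roi_subset is None:
        roi_subset = atlas.region_index_set
    x_orig = {m: [] for m in modalities}
    x_syn = {m: [] for m in modalities}
    target = {m: [] for m in modalities}
    for s in subjects:
        for m in modalities:
            orig = s.mri_volume if m == "MRI" else s.pet_volume
            x_orig[m].append(np.asarray(block_mean(orig, downsample), DTYPE))
            x_syn[m].append(np.asarray(
                block_mean(synthetic_inputs(s, atlas, m), downsample), DTYPE))
            target[m].append(np.asarray(block_mean(
                reconstruction_target(s, atlas, m, roi_subset), downsample),
                DTYPE))
    return ModelDataset(
        x_orig={m: np.stack(v) for m, v in x_orig.items()},
        x_syn={m: np.stack(v) for m, v in x_syn.items()},
        target={m: np.stack(v) for m, v in target.items()},
        y=np.asarray(labels, dtype=np.int64),
        subject_ids=[s.subject_id for s in subjects],
        modalities=tuple(modalities))


def _batch_inputs(ds: ModelDataset, idx: np.ndarray, use_cae: bool):
    return {m: (ds.x_orig[m][idx], ds.x_syn[m][idx] if use_cae else None)
            for m in ds.modalities}


def train_step(model: DualBranchModel, ds: ModelDataset, idx: np.ndarray,
               opt: Adam, weights: LossWeights) -> float:
    """One joint optimizer step on a minibatch; returns the total loss."""
    opt.zero_grad()
    probs, logits, recons = model.forward(
        _batch_inputs(ds, idx, model.use_cae), training=True)
    ce, _ = ad.softmax_cross_entropy(logits, ds.y[idx])
    terms, lam = [ce], [weights.lambda_cls]
    for m, xhat in recons.items():
        terms.append(ad.mse(xhat, ds.target[m][idx][:, None]))
        lam.append(weights.lambda_recon)
    loss = ad.weighted_sum(terms, lam)
    loss.backward()
    opt.step()
    return loss.item()


def train_model(model: DualBranchModel, ds: ModelDataset, config: TrainConfig,
                seed: int = 0) -> pd.DataFrame:
    """Train in place; returns the per-epoch loss log as a DataFrame."""
    opt = Adam(model.parameters(), lr=config.lr)
    rng = np.random.default_rng(seed)
    n = len(ds)
    log = []
    for epoch in range(config.epochs):
        order = rng.permutation(n) if config.shuffle else np.arange(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            losses.append(train_step(model, ds, idx, opt, config.loss_weights))
        log.append({"epoch": epoch, "mean_total_loss": float(np.mean(losses))})
    return pd.DataFrame(log)


def predict_proba(model: DualBranchModel, ds: ModelDataset,
                  batch_size: int = 32) -> np.ndarray:
    """Positive-class probabilities in evaluation mode (dropout off)."""
    out = []
    for start in range(0, len(ds), batch_size):
        idx = np.arange(start, min(start + batch_size, len(ds)))
        probs, _, _ = model.forward(_batch_inputs(ds, idx, model.use_cae),
                                    training=False)
        out.append(probs[:, 1])
    return np.concatenate(out)
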