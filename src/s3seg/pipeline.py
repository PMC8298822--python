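"""End-to-end pipeline: S3VM pseudo-labeling into CNN training and evaluation.

Stage 1 featurizes patches of all training images, reveals patch labels
(majority vote of the ground-truth mask, ties to tumor) only for the
labeled subset of images, fits the semi-supervised SVM, and pseudo-labels
the remaining patches — dropping pseudo-labels whose decision-value
magnitude falls below a fraction of the median (uncertain patches).
Stage 2 trains the patch CNN on true plus retained pseudo labels with
mu-law companded inputs, polynomial learning-rate decay, and the
OHEM-weighted cross-entropy.  Stage 3 segments held-out images by sliding
window and reports overlap metrics per image and macro-averaged.

Every random draw derives from the single pipeline seed; a resolved config
snapshot and a seed registry are written next to all run outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from . import losses, metrics, s3vm, segnet, synthetic
from .data import FeatureMatrix, PartialLabels
from .errors import DataError, S3SegError
from .graph import featurize_patches

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PhantomBlock:
    n_images: int = 40
    size: int = 64
    tumor_count: int = 1
    noise_sigma: float = 0.05
    bias_strength: float = 0.3


@dataclass
class S3VMBlock:
    patch_size: int = 16
    patch_stride: int = 8
    labeled_image_fraction: float = 0.5
    lambda1: float = 1.0
    lambda2: float = 0.1
    k: int = 10
    c_embed: int = 2
    gamma_unlabeled: float = 0.1
    max_iter: int = 10
    tol: float = 1e-6
    min_margin_frac: float = 0.1  # pseudo-labels below this fraction of the
    #                               median |decision| are dropped


@dataclass
class NetworkBlock:
    preset: str = "tiny"
    num_classes: int = 2
    dropout_p: float = 0.5


@dataclass
class TrainBlock:
    epochs: int = 120
    batch_size: int = 16
    init_lr: float = 0.005
    power: float = 0.9
    eta: float = 0.7
    c_weight: float = 1.10
    mode: str = "combined"


@dataclass
class EvalBlock:
    stride: int = 4


@dataclass
class PipelineConfig:
    phantom: PhantomBlock = field(default_factory=PhantomBlock)
    s3vm: S3VMBlock = field(default_factory=S3VMBlock)
    network: NetworkBlock = field(default_factory=NetworkBlock)
    training: TrainBlock = field(default_factory=TrainBlock)
    evaluation: EvalBlock = field(default_factory=EvalBlock)
    seed: int = 0
    out_dir: Optional[str] = None

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        blocks = {
            "phantom": PhantomBlock, "s3vm": S3VMBlock, "network": NetworkBlock,
            "training": TrainBlock, "evaluation": EvalBlock,
        }
        kwargs = {}
        for key, val in raw.items():
            if key in blocks:
                kwargs[key] = blocks[key](**(val or {}))
            else:
                kwargs[key] = val
        return cls(**kwargs)


@dataclass
class PipelineResult:
    per_image: list
    aggregate: dict
    history: dict
    pseudo_label_stats: dict
    config: PipelineConfig


def _patch_stack(image: np.ndarray, patch: int, stride: int) -> np.ndarray:
    C, H, W = image.shape
    wins = np.lib.stride_tricks.sliding_window_view(image, (patch, patch), axis=(1, 2))
    wins = wins[:, ::stride, ::stride]
    # (C, nr, nc, p, p) -> (nr*nc, C, p, p)
    return wins.transpose(1, 2, 0, 3, 4).reshape(-1, C, patch, patch)


def _patch_labels(mask: np.ndarray, patch: int, stride: int) -> np.ndarray:
    """Majority vote of mask pixels per patch; exact ties count as tumor."""
    wins = np.lib.stride_tricks.sliding_window_view(mask, (patch, patch))
    wins = wins[::stride, ::stride]
    frac = wins.reshape(wins.shape[0] * wins.shape[1], -1).mean(axis=1)
    return np.where(frac >= 0.5, 1, -1)


def run_pipeline(config: Optional[PipelineConfig] = None) -> PipelineResult:
    """Run phantom generation, pseudo-labeling, training, and evaluation."""
    config = config or PipelineConfig()
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: int(s.generate_state(1)[0] % (2**31))
             for name, s in zip(
                 ["phantoms", "split", "labeled_subset", "net_init", "train"],
                 ss.spawn(5))}
    stage = "generate"
    try:
        pb = config.phantom
        phantoms = [synthetic.generate_phantom(
            size=pb.size, tumor_count=pb.tumor_count, noise_sigma=pb.noise_sigma,
            bias_strength=pb.bias_strength, seed=seeds["phantoms"] + i)
            for i in range(pb.n_images)]
        has_tumor = np.array([int(p.mask.any()) for p in phantoms])
        train_idx, test_idx = synthetic.stratified_split(
            has_tumor, ratio=(7, 3), seed=seeds["split"])

        stage = "pseudo-label"
        sb = config.s3vm
        n_train = train_idx.size
        n_labeled = max(1, int(round(sb.labeled_image_fraction * n_train)))
        rng = np.random.default_rng(seeds["labeled_subset"])
        labeled_imgs = set(rng.choice(train_idx, size=n_labeled, replace=False).tolist())

        feats, patches, labels_true, revealed = [], [], [], []
        for i in train_idx:
            ph = phantoms[i]
            fm = featurize_patches(ph.image, sb.patch_size, sb.patch_stride)
            y = _patch_labels(ph.mask, sb.patch_size, sb.patch_stride)
            feats.append(fm.values)
            patches.append(_patch_stack(ph.image, sb.patch_size, sb.patch_stride))
            labels_true.append(y)
            revealed.append(np.full(y.size, i in labeled_imgs))
        X = np.vstack(feats)
        patches = np.vstack(patches)
        labels_true = np.concatenate(labels_true)
        revealed = np.concatenate(revealed)

        pseudo_stats = {"n_patches": int(labels_true.size),
                        "n_revealed": int(revealed.sum())}
        revealed_classes = np.unique(labels_true[revealed])
        if revealed.all():
            logger.info("all training images labeled; pseudo-labeling is a no-op")
            train_patches, train_labels = patches, labels_true
            pseudo_stats.update({"n_pseudo": 0, "n_dropped": 0})
        elif revealed_classes.size < 2:
            # the labeled subset shows only one class; the SVM has nothing
            # to separate, so train on the revealed patches alone
            logger.warning("revealed patch labels are single-class; "
                           "skipping pseudo-labeling")
            train_patches = patches[revealed]
            train_labels = labels_true[revealed]
            pseudo_stats.update({"n_pseudo": 0,
                                 "n_dropped": int((~revealed).sum())})
        else:
            partial = np.where(revealed, labels_true, 0)
            fm_all = FeatureMatrix(X, [f"p{i}" for i in range(X.shape[0])])
            params = s3vm.S3VMParams(
                lambda1=sb.lambda1, lambda2=sb.lambda2, k=sb.k,
                c_embed=sb.c_embed, gamma_unlabeled=sb.gamma_unlabeled,
                max_iter=sb.max_iter, tol=sb.tol)
            model = s3vm.fit(fm_all, PartialLabels(partial), params)
            dec = X @ model.w + model.b
            unl = ~revealed
            med = np.median(np.abs(dec[unl])) if unl.any() else 0.0
            confident = np.abs(dec) >= sb.min_margin_frac * med
            keep = revealed | (unl & confident)
            n_dropped = int((unl & ~confident).sum())
            logger.info("dropped %d uncertain pseudo-labels", n_dropped)
            train_labels = np.where(revealed, labels_true, model.y_full)[keep]
            train_patches = patches[keep]
            pseudo_stats.update({"n_pseudo": int((unl & confident).sum()),
                                 "n_dropped": n_dropped})

        stage = "train"
        nb, tb = config.network, config.training
        if nb.preset == "tiny":
            net_cfg = segnet.SegNetConfig.tiny(num_classes=nb.num_classes)
        elif nb.preset == "paper":
            net_cfg = segnet.SegNetConfig.paper(num_classes=nb.num_classes)
        else:
            raise DataError(f"unknown network preset {nb.preset!r}")
        net_cfg = dataclasses.replace(net_cfg, dropout_p=nb.dropout_p)
        net_params = segnet.init_params(net_cfg, seed=seeds["net_init"])
        class_labels = (train_labels > 0).astype(int)
        loss_params = losses.OhemWceParams(eta=tb.eta, c_weight=tb.c_weight,
                                           mode=tb.mode)
        sched = losses.LrSchedule(init_lr=tb.init_lr, power=tb.power,
                                  max_epoch=tb.epochs)
        net_params, history = losses.train(
            net_cfg, net_params, train_patches, class_labels,
            loss_params=loss_params, sched=sched, seed=seeds["train"],
            epochs=tb.epochs, batch_size=tb.batch_size)
        normalizer = history["normalizer"]

        stage = "evaluate"
        per_image = []
        for i in test_idx:
            ph = phantoms[i]
            img = normalizer.transform(ph.image)
            label_map, _ = segnet.segment_image(
                net_cfg, net_params, img, stride=config.evaluation.stride)
            per_image.append(metrics.overlap_metrics(ph.mask, label_map))
        aggregate = metrics.aggregate_reports(per_image)

        result = PipelineResult(
            per_image=per_image, aggregate=aggregate,
            history={"loss": history["loss"], "lr": history["lr"]},
            pseudo_label_stats=pseudo_stats, config=config)
    except S3SegError as exc:
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc

    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        config.to_yaml(os.path.join(config.out_dir, "config.yaml"))
        with open(os.path.join(config.out_dir, "seeds.json"), "w") as fh:
            json.dump({"seed": config.seed, "derived": seeds}, fh, indent=2)
        report = {
            "aggregate": aggregate,
            "per_image": [r.as_dict() for r in per_image],
            "pseudo_labels": pseudo_stats,
            "loss": history["loss"],
            "lr": history["lr"],
        }
        with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2)
        segnet.save_checkpoint(os.path.join(config.out_dir, "model.npz"),
                               net_cfg, net_params)
    return result
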