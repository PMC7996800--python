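"""Leakage-safe cross-validated augmentation study.

Five-fold cross-validation where each fold's training portion (4/5 of the
data) serves double duty: it is the only material the per-class GANs ever
see, and — mixed with the images those GANs generate — it trains the
classifier.  The held-out fifth contains only original images and is used
exclusively for evaluation.  Four augmentation cases control the mix: the
generated-to-original multiplier m ∈ {0, 1, 5, 9}, so a 2020-image training
fold grows to 2020 / 4040 / 12120 / 20200 images.  A hyperparameter grid
(architecture × GAN epochs × case × solver × batch size × epochs) is searched
exhaustively; each grid point is scored by its five-fold mean micro/macro AUC
tuple and ranked.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, replace
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import KFold, StratifiedKFold

from .classifiers import TrainSpec, build_alexnet, build_vgg16, predict_scores, train_classifier
from .dataset import ImageDataset
from .evaluation import (
    FoldSummary,
    ModelScoreTuple,
    aggregate_folds,
    rank_models,
    roc_auc,
    summarize_grid,
)
from .gan import DESK_GEN_CHANNELS, FULL_GEN_CHANNELS, GanTrainConfig, Generator, train_gan
from .synthetic import SyntheticDatasetConfig, generate_dataset

__all__ = [
    "FoldSplit",
    "AugmentationCase",
    "GridPoint",
    "ExperimentRecord",
    "PipelineConfig",
    "LeakageError",
    "CASE_MULTIPLIERS",
    "make_folds",
    "build_augmented_training_set",
    "GanCache",
    "run_experiment",
    "run_grid",
    "load_config",
]

logger = logging.getLogger(__name__)

#: Augmentation case -> generated-to-original multiplier.
CASE_MULTIPLIERS = {1: 0, 2: 1, 3: 5, 4: 9}


class LeakageError(RuntimeError):
    """A generated image, or GAN training material, reached a test fold."""


@dataclass(frozen=True)
class FoldSplit:
    """One train/test partition; indices refer to the original dataset."""

    fold_id: int
    train_indices: np.ndarray
    test_indices: np.ndarray

    def __post_init__(self) -> None:
        tr = np.asarray(self.train_indices)
        te = np.asarray(self.test_indices)
        if np.intersect1d(tr, te).size:
            raise ValueError(f"fold {self.fold_id}: train/test overlap")
        object.__setattr__(self, "train_indices", tr)
        object.__setattr__(self, "test_indices", te)


@dataclass(frozen=True)
class AugmentationCase:
    """Training-set composition: m generated images per original image."""

    case_id: int

    @property
    def multiplier(self) -> int:
        return CASE_MULTIPLIERS[self.case_id]


@dataclass(frozen=True)
class GridPoint:
    """One cell of the hyperparameter grid."""

    architecture: str  # "alexnet" | "vgg16"
    gan_epochs: int
    case_id: int
    solver: str
    batch_size: int
    epochs: int
    seed: int = 0

    def key(self) -> str:
        return (
            f"{self.architecture}_g{self.gan_epochs}_c{self.case_id}_"
            f"{self.solver}_b{self.batch_size}_e{self.epochs}_s{self.seed}"
        )


@dataclass(frozen=True)
class ExperimentRecord:
    """Grid point + its five-fold summary and ranking tuple."""

    point: GridPoint
    summary: FoldSummary
    score: ModelScoreTuple


def make_folds(
    dataset: ImageDataset, k: int = 5, seed: int = 0, stratified: bool = True
) -> list[FoldSplit]:
    """k disjoint, covering train/test splits (class-stratified by default)."""
    if len(dataset) < k:
        raise ValueError(f"dataset of {len(dataset)} images cannot make {k} folds")
    if stratified:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(len(dataset)), dataset.labels)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(len(dataset)))
    return [
        FoldSplit(fold_id=i + 1, train_indices=tr, test_indices=te)
        for i, (tr, te) in enumerate(splits)
    ]


def check_no_leakage(fold: FoldSplit, dataset: ImageDataset) -> None:
    """Hard guard: every test image must be an original dataset image."""
    prov = dataset.provenance[fold.test_indices]
    if np.any(prov != "original"):
        raise LeakageError(
            f"fold {fold.fold_id}: generated image(s) found in the test set"
        )


def build_augmented_training_set(
    train: ImageDataset,
    per_class_generators: dict[int, Generator] | None,
    case: AugmentationCase,
    seed: int = 0,
) -> ImageDataset:
    """Mix a training fold with m generated images per original image.

    Generated counts are allocated per class proportionally to that class's
    original training count (m × count each), and every generated image is
    tagged ``provenance="generated"`` with its class label.
    """
    m = case.multiplier
    if m == 0:
        return train
    if per_class_generators is None:
        raise ValueError(f"case {case.case_id} needs per-class generators")
    parts = [train]
    counts = train.class_counts()
    for cls, count in enumerate(counts):
        n_gen = m * int(count)
        if n_gen == 0:
            continue
        if cls not in per_class_generators:
            raise ValueError(f"no generator for class {cls} ({train.class_names[cls]})")
        gen_seed = int(np.random.SeedSequence([seed, case.case_id, cls]).generate_state(1)[0] % 2**31)
        imgs = per_class_generators[cls].generate(n_gen, gen_seed)
        parts.append(
            ImageDataset(
                imgs,
                np.full(n_gen, cls, dtype=np.int64),
                train.class_names,
                np.full(n_gen, "generated", dtype=object),
                np.full(n_gen, gen_seed, dtype=np.int64),
            )
        )
    return ImageDataset.concatenate(parts)


class GanCache:
    """Per-(fold, class, gan_epochs) generator store.

    Each generator is trained only on the requesting fold's training images of
    one class — the cross-validation leakage contract.  Artifacts are cached
    in memory and keyed (fold_id, class, gan_epochs, seed).
    """

    def __init__(self, dataset: ImageDataset, folds: Sequence[FoldSplit],
                 gan_config: GanTrainConfig) -> None:
        self.dataset = dataset
        self.folds = {f.fold_id: f for f in folds}
        self.gan_config = gan_config
        self._cache: dict[tuple, Generator] = {}

    def get(self, fold_id: int, cls: int, gan_epochs: int) -> Generator:
        key = (fold_id, cls, gan_epochs, self.gan_config.seed)
        if key not in self._cache:
            fold = self.folds[fold_id]
            idx = fold.train_indices[self.dataset.labels[fold.train_indices] == cls]
            sub = self.dataset.subset(idx)
            cfg = replace(
                self.gan_config,
                epochs=gan_epochs,
                seed=int(np.random.SeedSequence(
                    [self.gan_config.seed, fold_id, cls, gan_epochs]
                ).generate_state(1)[0] % 2**31),
                milestones=(),
            )
            t0 = time.perf_counter()
            gen, _ = train_gan(sub, cfg)
            logger.info(
                "GAN fold=%d class=%d epochs=%d trained in %.1fs",
                fold_id, cls, gan_epochs, time.perf_counter() - t0,
            )
            self._cache[key] = gen
        return self._cache[key]

    def generators_for(self, fold_id: int, gan_epochs: int) -> dict[int, Generator]:
        return {
            cls: self.get(fold_id, cls, gan_epochs)
            for cls in range(self.dataset.n_classes)
        }


def _build_classifier(architecture: str, reduced: bool, seed: int):
    if architecture == "alexnet":
        return build_alexnet(reduced=reduced, seed=seed)
    if architecture == "vgg16":
        return build_vgg16(reduced=reduced, seed=seed)
    raise ValueError(f"unknown architecture {architecture!r}")


def run_experiment(
    point: GridPoint,
    folds: Sequence[FoldSplit],
    dataset: ImageDataset,
    gan_cache: GanCache | None = None,
    reduced: bool = True,
) -> ExperimentRecord:
    """Evaluate one grid point over all folds.

    Per fold: (re)train the classifier on the case-augmented training portion,
    score the untouched test portion, and compute micro and macro score-sweep
    AUCs; the five AUC pairs are aggregated into the ranking tuple.  Raises
    :class:`LeakageError` if any test fold contains a generated image.
    """
    case = AugmentationCase(point.case_id)
    auc_micro, auc_macro = [], []
    for fold in folds:
        check_no_leakage(fold, dataset)
        train_ds = dataset.subset(fold.train_indices)
        gens = None
        if case.multiplier > 0:
            if gan_cache is None:
                raise ValueError(f"case {point.case_id} requires a GAN cache")
            gens = gan_cache.generators_for(fold.fold_id, point.gan_epochs)
        aug = build_augmented_training_set(train_ds, gens, case, seed=point.seed)
        model = _build_classifier(
            point.architecture, reduced,
            seed=int(np.random.SeedSequence([point.seed, fold.fold_id]).generate_state(1)[0] % 2**31),
        )
        spec = TrainSpec(
            solver=point.solver, batch_size=point.batch_size,
            epochs=point.epochs,
            seed=int(np.random.SeedSequence([point.seed, fold.fold_id, 1]).generate_state(1)[0] % 2**31),
        )
        train_classifier(model, aug, spec)
        test_ds = dataset.subset(fold.test_indices)
        scores = predict_scores(model, test_ds)
        _, mi = roc_auc(scores, test_ds.labels, "micro")
        _, ma = roc_auc(scores, test_ds.labels, "macro")
        auc_micro.append(mi)
        auc_macro.append(ma)
    summary = aggregate_folds(auc_micro, auc_macro)
    score = ModelScoreTuple(
        summary.mean_auc_micro, summary.mean_auc_macro,
        summary.sigma_auc_micro, summary.sigma_auc_macro,
        hyperparameters=point.__dict__.copy(),
    )
    return ExperimentRecord(point, summary, score)


# ------------------------------------------------------------------ config


@dataclass(frozen=True)
class PipelineConfig:
    """Structured configuration for a full grid run.

    The desk profile (default) trains reduced-width networks on small images;
    the full profile reproduces the published-scale architectures.
    """

    dataset: SyntheticDatasetConfig = SyntheticDatasetConfig()
    architectures: tuple = ("alexnet",)
    gan_epochs: tuple = (100, 250, 500, 1000)
    cases: tuple = (1, 2, 3, 4)
    solvers: tuple = ("Adam", "RMSprop", "AdaDelta", "AdaMax", "AdaGrad")
    batch_sizes: tuple = (4, 8, 16, 32)
    classifier_epochs: tuple = tuple(range(4, 11))
    k_folds: int = 5
    seed: int = 0
    profile: str = "desk"  # "desk" | "full"
    gan: GanTrainConfig = GanTrainConfig()
    out_dir: str = "results"

    @property
    def reduced(self) -> bool:
        return self.profile == "desk"

    def grid_points(self) -> list[GridPoint]:
        return [
            GridPoint(a, g, c, s, b, e, seed=self.seed)
            for a, g, c, s, b, e in product(
                self.architectures, self.gan_epochs, self.cases,
                self.solvers, self.batch_sizes, self.classifier_epochs,
            )
        ]


def load_config(path: str | Path) -> PipelineConfig:
    """Read a PipelineConfig from a YAML mapping (missing keys -> defaults)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    ds = SyntheticDatasetConfig(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in raw.pop("dataset", {}).items()
    })
    gan_cfg = GanTrainConfig(**{
        k: tuple(v) if isinstance(v, list) else v
        for k, v in raw.pop("gan", {}).items()
    })
    kwargs = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
    return PipelineConfig(dataset=ds, gan=gan_cfg, **kwargs)


_REPORT_COLUMNS = [
    "Case", "GAN Epochs", "Architecture", "Solver", "Batch Size",
    "Number of Epochs", "AUC_micro_mean", "sigma_AUC_micro",
    "AUC_macro_mean", "sigma_AUC_macro",
]


def _record_row(rec: ExperimentRecord) -> dict:
    p = rec.point
    return {
        "Case": p.case_id, "GAN Epochs": p.gan_epochs, "Architecture": p.architecture,
        "Solver": p.solver, "Batch Size": p.batch_size, "Number of Epochs": p.epochs,
        "AUC_micro_mean": rec.summary.mean_auc_micro,
        "sigma_AUC_micro": rec.summary.sigma_auc_micro,
        "AUC_macro_mean": rec.summary.mean_auc_macro,
        "sigma_AUC_macro": rec.summary.sigma_auc_macro,
    }


def run_grid(config: PipelineConfig, dataset: ImageDataset | None = None):
    """Run the whole grid and write the ranked report.

    Returns (records, ranked_records, summary_dict).  Completed grid points
    are checkpointed as JSON under ``out_dir/records`` and skipped on re-run,
    so interrupted grids resume idempotently.
    """
    points = config.grid_points()
    if not points:
        raise ValueError("empty grid")
    if dataset is None:
        dataset = generate_dataset(config.dataset)
    folds = make_folds(dataset, k=config.k_folds, seed=config.seed, stratified=True)
    needs_gan = any(CASE_MULTIPLIERS[c] > 0 for c in config.cases)
    gan_cfg = config.gan
    if config.reduced and tuple(gan_cfg.channels) == FULL_GEN_CHANNELS:
        gan_cfg = replace(gan_cfg, channels=DESK_GEN_CHANNELS)
    cache = GanCache(dataset, folds, gan_cfg) if needs_gan else None

    out = Path(config.out_dir)
    rec_dir = out / "records"
    rec_dir.mkdir(parents=True, exist_ok=True)
    records: list[ExperimentRecord] = []
    for point in points:
        ckpt = rec_dir / f"{point.key()}.json"
        if ckpt.exists():
            data = json.loads(ckpt.read_text())
            sd = {k: tuple(v) if isinstance(v, list) else v for k, v in data["summary"].items()}
            summary = FoldSummary(**sd)
            score = ModelScoreTuple(*data["score"], hyperparameters=point.__dict__.copy())
            records.append(ExperimentRecord(point, summary, score))
            logger.info("grid point %s: restored from checkpoint", point.key())
            continue
        t0 = time.perf_counter()
        rec = run_experiment(point, folds, dataset, cache, reduced=config.reduced)
        logger.info("grid point %s: %.1fs, mean micro AUC %.3f",
                    point.key(), time.perf_counter() - t0, rec.summary.mean_auc_micro)
        ckpt.write_text(json.dumps({
            "summary": rec.summary.__dict__,
            "score": rec.score.astuple(),
        }))
        records.append(rec)

    ranked_scores = rank_models([r.score for r in records])
    order = {id(s): i for i, s in enumerate(ranked_scores)}
    ranked = sorted(records, key=lambda r: order[id(r.score)])
    pd.DataFrame([_record_row(r) for r in records], columns=_REPORT_COLUMNS).to_csv(
        out / "results.csv", index=False
    )
    pd.DataFrame([_record_row(r) for r in ranked], columns=_REPORT_COLUMNS).to_csv(
        out / "ranked.csv", index=False
    )
    summary = summarize_grid([r.score for r in records])
    pd.DataFrame([summary]).to_csv(out / "grid_summary.csv", index=False)
    return records, ranked, summary
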