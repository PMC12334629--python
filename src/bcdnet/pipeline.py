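"""End-to-end pipeline: denoise -> segment -> augment -> featurize -> classify.

The pipeline configuration mirrors each stage's tunables in one nested
record, loadable from YAML with unknown keys rejected. A single global
seed fans out to per-stage child seeds by fixed offsets so every stage is
independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .augment import AugmentSpec, augment_dataset
from .classifier import TrainConfig, predict, train
from .evaluation import Metrics, compute_metrics, confusion_from_predictions
from .features import FeatureConfig, extract_features
from .imageio import GrayImage, read_image, read_manifest
from .kalman import AkfConfig, akf_filter
from .phantom import LabeledSample
from .segmenter import (SegArchitecture, binarize, forward_batch, train_with_jso,
                        _prepare_batch)
from .jellyfish import JsoConfig

__all__ = ["PipelineConfig", "SegmenterSettings", "EvaluationReport", "run_pipeline",
           "load_samples"]

# per-stage child-seed offsets from the global seed
_SEED_SPLIT, _SEED_SEG, _SEED_AUG, _SEED_CLF = 11, 23, 37, 53


@dataclass
class SegmenterSettings:
    """Segmenter architecture and its jellyfish-search training budget."""

    encoder_channels: tuple[int, ...] = (6, 8)
    pyramid_scales: tuple[int, ...] = (1, 2, 3)
    reduction_channels: int = 2
    input_size: int = 32
    population: int = 15
    iterations: int = 80
    weight_bound: float = 2.0
    threshold: float = 0.5
    train_subset: int = 16  # images used to evaluate the training fitness

    def arch(self) -> SegArchitecture:
        return SegArchitecture(tuple(self.encoder_channels), tuple(self.pyramid_scales),
                               self.reduction_channels, self.input_size)


@dataclass
class PipelineConfig:
    """One sub-record per pipeline stage; every field has a default."""

    seed: int = 0
    test_fraction: float = 1 / 3
    output_dir: str | None = None
    akf: AkfConfig = field(default_factory=AkfConfig)
    segmenter: SegmenterSettings = field(default_factory=SegmenterSettings)
    augment: AugmentSpec = field(default_factory=lambda: AugmentSpec(copies_per_image=1))
    features: FeatureConfig = field(default_factory=FeatureConfig)
    classifier: TrainConfig = field(default_factory=TrainConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        def build(dc_type, payload):
            names = {f.name for f in dataclasses.fields(dc_type)}
            unknown = set(payload) - names
            if unknown:
                raise ValueError(f"unknown config keys for {dc_type.__name__}: {sorted(unknown)}")
            return dc_type(**payload)

        data = dict(data)
        kwargs = {}
        for name, dc_type in (("akf", AkfConfig), ("segmenter", SegmenterSettings),
                              ("augment", AugmentSpec), ("features", FeatureConfig),
                              ("classifier", TrainConfig)):
            if name in data:
                sub = data.pop(name)
                kwargs[name] = build(dc_type, sub) if isinstance(sub, dict) else sub
        top_names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - top_names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj):
                return {f.name: convert(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, (tuple, list)):
                return [convert(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        return convert(self)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class EvaluationReport:
    accuracy: float
    sensitivity: float
    specificity: float
    tp: int
    tn: int
    fp: int
    fn: int
    n_train: int
    n_test: int
    segmenter_fitness: float
    config_hash: str
    seed: int

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def load_samples(manifest_path, root: str | None = None) -> list[LabeledSample]:
    """Load (image, mask, label) samples referenced by a manifest CSV."""
    df = read_manifest(manifest_path)
    root = root or os.path.dirname(os.fspath(manifest_path))
    samples = []
    for i, row in df.iterrows():
        img_path = os.path.join(root, row["filename"])
        try:
            image = read_image(img_path)
        except OSError as exc:
            raise OSError(f"manifest row {i}: {exc}") from exc
        mask_name = row["mask_filename"]
        if isinstance(mask_name, str) and mask_name:
            mask = (read_image(os.path.join(root, mask_name)).pixels > 127).astype(np.uint8)
        else:
            mask = np.zeros(image.shape, dtype=np.uint8)
        samples.append(LabeledSample(image=image, mask=mask, label=int(row["label"])))
    return samples


def _stratified_split(labels: np.ndarray, test_fraction: float, seed: int):
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_test = int(round(test_fraction * idx.size))
        test_idx.extend(idx[:n_test])
        train_idx.extend(idx[n_test:])
    return np.sort(train_idx).astype(int), np.sort(test_idx).astype(int)


def run_pipeline(config: PipelineConfig, manifest=None, samples: list[LabeledSample] | None = None,
                 ) -> EvaluationReport:
    """Execute the full pipeline and return the evaluation report.

    Input is either a manifest CSV (``manifest``) or in-memory ``samples``.
    Stages run in order: adaptive Kalman denoising; jellyfish-search
    training of the segmenter on a subset of the training split; mask
    prediction for every sample; augmentation of the training split only;
    feature extraction; classifier training; confusion-matrix metrics on
    the held-out split. Artifacts are written under ``config.output_dir``
    when set.
    """
    if samples is None:
        if manifest is None:
            raise ValueError("either manifest or samples must be provided")
        samples = load_samples(manifest)
    labels = np.array([s.label for s in samples], dtype=int)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # 1. preprocess
    filtered = stage("preprocess", lambda: [
        LabeledSample(akf_filter(s.image, config.akf), s.mask, s.label) for s in samples
    ])

    # 2. split, then train the segmenter on (a subset of) the training split
    train_idx, test_idx = _stratified_split(labels, config.test_fraction,
                                            config.seed + _SEED_SPLIT)
    seg = config.segmenter
    arch = seg.arch()
    rng = np.random.default_rng(config.seed + _SEED_SEG)
    seg_pool = [i for i in train_idx if samples[i].mask.any()] or list(train_idx)
    seg_train = [filtered[i] for i in rng.permutation(seg_pool)[:seg.train_subset]]
    jso_cfg = JsoConfig(population=seg.population, iterations=seg.iterations,
                        bounds=(-seg.weight_bound, seg.weight_bound),
                        seed=config.seed + _SEED_SEG)
    theta, jso_result = stage("segment-train", train_with_jso, seg_train, arch, jso_cfg,
                              seg.weight_bound)

    # 3. predict masks for every sample
    def predict_masks():
        from skimage.transform import resize

        batch = _prepare_batch([s.image for s in filtered], arch)
        prob = forward_batch(batch, theta, arch)
        masks = []
        for p, s in zip(prob, filtered):
            m = binarize(p, seg.threshold).astype(float)
            if m.shape != s.image.shape:
                m = resize(m, s.image.shape, order=0, preserve_range=True)
            masks.append(m.astype(np.uint8))
        return masks

    pred_masks = stage("segment-apply", predict_masks)
    segmented = [LabeledSample(s.image, m, s.label) for s, m in zip(filtered, pred_masks)]

    # 4. augment the training split only
    aug_spec = dataclasses.replace(config.augment, seed=config.seed + _SEED_AUG)
    train_samples = stage("augment", augment_dataset, [segmented[i] for i in train_idx], aug_spec)
    test_samples = [segmented[i] for i in test_idx]

    # 5. features
    def featurize(batch):
        return [extract_features(s.image, s.mask, config.features) for s in batch]

    train_records = stage("featurize", featurize, train_samples)
    test_records = stage("featurize", featurize, test_samples)

    # 6. classify
    clf_cfg = dataclasses.replace(config.classifier, seed=config.seed + _SEED_CLF)
    state = stage("train", train, train_records, [s.label for s in train_samples], clf_cfg)
    y_pred, _ = stage("predict", predict, state, test_records)

    # 7. metrics
    counts = confusion_from_predictions(labels[test_idx], y_pred)
    metrics = compute_metrics(counts)
    report = EvaluationReport(
        accuracy=metrics.accuracy, sensitivity=metrics.sensitivity,
        specificity=metrics.specificity, tp=counts.tp, tn=counts.tn,
        fp=counts.fp, fn=counts.fn, n_train=len(train_idx), n_test=len(test_idx),
        segmenter_fitness=float(jso_result.best_fitness),
        config_hash=config.config_hash(), seed=config.seed,
    )

    if config.output_dir:
        os.makedirs(config.output_dir, exist_ok=True)
        with open(os.path.join(config.output_dir, "report.json"), "w") as fh:
            fh.write(report.to_json())
        with open(os.path.join(config.output_dir, "run_log.json"), "w") as fh:
            json.dump({"config": config.to_dict(), "config_hash": config.config_hash(),
                       "seed": config.seed}, fh, indent=2)
        pd.DataFrame({"iteration": np.arange(1, jso_result.history.size + 1),
                      "best_fitness": jso_result.history}).to_csv(
            os.path.join(config.output_dir, "segmenter_training_curve.csv"), index=False)
    return report
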