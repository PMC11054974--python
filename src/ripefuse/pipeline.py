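"""End-to-end seeded experiments.

``run_stage_experiment`` reproduces the unimodal-versus-fusion comparison on
phantoms: generate, preprocess, train the three unimodal extractors on a
shared fruit-level split, cache their feature taps, splice, train the fused
residual classifier, and report metrics for all four models.

``run_heterogeneous_experiment`` reproduces the internal/external ripening
validation: three categories that look identical from outside (negative1,
negative2, positive), features taken from the frozen stage-trained
extractors, a fused classifier trained on category labels, and an 18-sample
validation confusion matrix, alongside image-only and haptic-only baselines
that expose each modality's blind spot.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import nn
from .config import RunConfig
from .datatypes import HETEROGENEITY_CATEGORIES, STAGES, FusedFeature, Heterogeneity
from .evaluation import MetricsReport, evaluate_classifier
from .features import (
    build_haptic_lstm,
    build_image_extractor,
    build_spectral_cnn,
    prepare_haptic_batch,
    prepare_image_batch,
    prepare_spectrum_batch,
    train_unimodal,
)
from .fusion import DatasetSplit, make_split, train_fusion
from .phantom import Manifest, generate_manifest, iter_samples, read_sample
from .preprocess import butterworth_lowpass, correct_spectrum, segment_image

__all__ = [
    "ModalityArrays",
    "build_modality_arrays",
    "batch_features",
    "StageExperimentResult",
    "run_stage_experiment",
    "HeterogeneousResult",
    "run_heterogeneous_experiment",
]

STAGE_NAMES = [s.value for s in STAGES]
CATEGORY_NAMES = [c.value for c in HETEROGENEITY_CATEGORIES]


@dataclass
class ModalityArrays:
    """Preprocessed per-acquisition arrays, aligned across modalities."""

    x_image: np.ndarray  # (N, 3, S, S)
    x_spectrum: np.ndarray  # (N, 1, L)
    x_haptic: np.ndarray  # (N, 1, T)
    y: np.ndarray  # int class index
    classes: List[str]
    fruit_ids: List[str]
    rotations: List[int]


def build_modality_arrays(
    manifest: Manifest,
    config: RunConfig,
    label_key: str = "stage",
) -> ModalityArrays:
    """Generate and preprocess every acquisition of a manifest in memory.

    ``label_key`` selects the classification target: maturity ``stage`` or
    heterogeneity ``category``.
    """
    classes = STAGE_NAMES if label_key == "stage" else CATEGORY_NAMES
    images, spectra, traces, y, fruit_ids, rotations = [], [], [], [], [], []
    for sample in iter_samples(manifest, config.phantom):
        images.append(segment_image(sample.image, out_size=config.image.input_size))
        spectra.append(correct_spectrum(sample.spectrum).r_corrected)
        traces.append(butterworth_lowpass(sample.haptic))
        target = sample.label.stage.value if label_key == "stage" else sample.label.category
        y.append(classes.index(target))
        fruit_ids.append(sample.fruit_id)
        rotations.append(sample.rotation_index)
    return ModalityArrays(
        x_image=prepare_image_batch(images, config.image.input_size),
        x_spectrum=prepare_spectrum_batch(spectra),
        x_haptic=prepare_haptic_batch(traces),
        y=np.asarray(y, dtype=int),
        classes=list(classes),
        fruit_ids=fruit_ids,
        rotations=rotations,
    )


def arrays_from_dataset_dir(
    dataset_dir, config: RunConfig, label_key: str = "stage"
) -> ModalityArrays:
    """Like :func:`build_modality_arrays` but reading a written dataset tree."""
    from .phantom import load_manifest

    manifest = load_manifest(dataset_dir)
    classes = STAGE_NAMES if label_key == "stage" else CATEGORY_NAMES
    images, spectra, traces, y, fruit_ids, rotations = [], [], [], [], [], []
    for fruit in manifest.fruits:
        for rot in range(manifest.n_rotations):
            sample = read_sample(dataset_dir, manifest, fruit["fruit_id"], rot)
            images.append(segment_image(sample.image, out_size=config.image.input_size))
            spectra.append(correct_spectrum(sample.spectrum).r_corrected)
            traces.append(butterworth_lowpass(sample.haptic))
            target = sample.label.stage.value if label_key == "stage" else sample.label.category
            y.append(classes.index(target))
            fruit_ids.append(sample.fruit_id)
            rotations.append(sample.rotation_index)
    return ModalityArrays(
        x_image=prepare_image_batch(images, config.image.input_size),
        x_spectrum=prepare_spectrum_batch(spectra),
        x_haptic=prepare_haptic_batch(traces),
        y=np.asarray(y, dtype=int),
        classes=list(classes),
        fruit_ids=fruit_ids,
        rotations=rotations,
    )


def batch_features(model: nn.TapModel, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
    """Eval-mode feature taps for a whole array, batched."""
    return np.concatenate(
        [model.features(x[i : i + batch_size]) for i in range(0, len(x), batch_size)], axis=0
    )


def fuse_arrays(feats: Dict[str, np.ndarray]) -> np.ndarray:
    """Row-wise splice in the fixed [image | spectrum | haptic] order."""
    return np.concatenate([feats["image"], feats["spectrum"], feats["haptic"]], axis=1)


@dataclass
class StageExperimentResult:
    config: RunConfig
    manifest: Manifest
    split: DatasetSplit
    unimodal_reports: Dict[str, MetricsReport]
    fusion_report: MetricsReport
    models: Dict[str, nn.Layer]
    features: Dict[str, np.ndarray]
    fused: np.ndarray
    arrays: ModalityArrays
    split_indices: Dict[str, np.ndarray] = field(default_factory=dict)
    timings: Dict[str, float] = field(default_factory=dict)

    @property
    def test_accuracies(self) -> Dict[str, float]:
        out = {m: r.splits["test"]["accuracy"] for m, r in self.unimodal_reports.items()}
        out["fusion"] = self.fusion_report.splits["test"]["accuracy"]
        return out

    def comparison_table(self) -> str:
        rows = [
            {"Model": m, "Test accuracy": f"{a * 100:.1f}%"}
            for m, a in self.test_accuracies.items()
        ]
        return pd.DataFrame(rows).to_string(index=False)


class StageFailure(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""


def _run_stage(name: str, timings: Dict[str, float], fn):
    start = time.perf_counter()
    try:
        out = fn()
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        raise StageFailure(f"stage {name!r} failed: {exc}") from exc
    timings[name] = time.perf_counter() - start
    return out


def run_stage_experiment(
    config: Optional[RunConfig] = None, out_dir=None
) -> StageExperimentResult:
    """Three-stage maturity classification: unimodal models versus fusion."""
    config = config or RunConfig.desk()
    timings: Dict[str, float] = {}
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    manifest = _run_stage(
        "generate",
        timings,
        lambda: generate_manifest(
            *config.n_fruits,
            n_rotations=config.n_rotations,
            seed=config.seed,
            config=config.phantom,
        ),
    )
    arrays = _run_stage(
        "preprocess", timings, lambda: build_modality_arrays(manifest, config)
    )
    split = _run_stage(
        "split",
        timings,
        lambda: make_split(manifest, fractions=config.fractions, seed=config.seed + 1),
    )
    split_indices = split.indices(arrays.fruit_ids)

    builders = {
        "image": (build_image_extractor, config.image, config.image_train, arrays.x_image),
        "spectrum": (build_spectral_cnn, config.spectral, config.spectral_train, arrays.x_spectrum),
        "haptic": (build_haptic_lstm, config.haptic, config.haptic_train, arrays.x_haptic),
    }
    models: Dict[str, nn.Layer] = {}
    unimodal_reports: Dict[str, MetricsReport] = {}
    feats: Dict[str, np.ndarray] = {}
    for modality, (builder, mod_cfg, train_cfg, x) in builders.items():
        def train(builder=builder, mod_cfg=mod_cfg, train_cfg=train_cfg, x=x):
            model = builder(mod_cfg)
            return train_unimodal(
                model, x, arrays.y, split_indices, train_cfg, classes=arrays.classes
            )
        models[modality], _, unimodal_reports[modality] = _run_stage(
            f"train_{modality}", timings, train
        )
        feats[modality] = _run_stage(
            f"extract_{modality}", timings, lambda m=models[modality], x=x: batch_features(m, x)
        )

    fused = fuse_arrays(feats)
    fusion_cfg = config.fusion
    if fusion_cfg.input_dim != fused.shape[1]:
        raise StageFailure(
            f"stage 'fuse' failed: fused dim {fused.shape[1]} != configured {fusion_cfg.input_dim}"
        )
    fusion_model, _, fusion_report = _run_stage(
        "train_fusion",
        timings,
        lambda: train_fusion(fused, arrays.y, split_indices, fusion_cfg, classes=arrays.classes),
    )
    models["fusion"] = fusion_model

    result = StageExperimentResult(
        config=config,
        manifest=manifest,
        split=split,
        unimodal_reports=unimodal_reports,
        fusion_report=fusion_report,
        models=models,
        features=feats,
        fused=fused,
        arrays=arrays,
        split_indices=split_indices,
        timings=timings,
    )
    if out_dir is not None:
        _write_stage_artifacts(result, out_dir)
    return result


def _write_stage_artifacts(result: StageExperimentResult, out_dir: Path) -> None:
    (out_dir / "run_manifest.json").write_text(
        json.dumps(
            {
                "seed": result.config.seed,
                "preset": result.config.preset,
                "config_hash": result.config.config_hash(),
                "timings_s": {k: round(v, 3) for k, v in result.timings.items()},
            },
            indent=2,
            sort_keys=True,
        )
    )
    for modality, report in result.unimodal_reports.items():
        (out_dir / f"report_{modality}.json").write_text(report.to_json())
    (out_dir / "report_fusion.json").write_text(result.fusion_report.to_json())
    (out_dir / "comparison.txt").write_text(result.comparison_table() + "\n")
    history = result.fusion_report.loss_history or {}
    if history.get("train_loss"):
        pd.DataFrame(history).to_csv(out_dir / "fusion_loss.csv", index_label="epoch")


@dataclass
class HeterogeneousResult:
    config: RunConfig
    fusion_report: MetricsReport
    image_report: MetricsReport
    haptic_report: MetricsReport
    binary_accuracies: Dict[str, float]  # positive-vs-negative, per model

    def validation_confusion(self):
        return self.fusion_report.confusions["val"]


def _binary_pos_vs_neg_accuracy(cm) -> float:
    """Collapse a 3-category confusion matrix to positive-vs-not and score it."""
    pos = cm.classes.index(Heterogeneity.POSITIVE.value)
    counts = cm.counts
    correct = counts[pos, pos]
    for i in range(len(cm.classes)):
        for j in range(len(cm.classes)):
            if i != pos and j != pos:
                correct += counts[i, j]
    return float(correct) / cm.total


def run_heterogeneous_experiment(
    config: Optional[RunConfig] = None,
    stage_result: Optional[StageExperimentResult] = None,
    out_dir=None,
) -> HeterogeneousResult:
    """Internal/external ripening validation with frozen stage extractors.

    Trains the fused classifier (and image-only / haptic-only baseline heads)
    on category-labelled heterogeneous phantoms, then evaluates on a held-out
    validation set (default 6 per category = 18 samples).
    """
    config = config or RunConfig.desk()
    if stage_result is None:
        stage_result = run_stage_experiment(config)

    n_train, n_val = config.het_train_per_category, config.het_val_per_category
    per_cat = n_train + n_val
    manifest = generate_manifest(
        0,
        0,
        0,
        n_rotations=1,
        seed=config.seed + 7,
        het_counts={c: per_cat for c in HETEROGENEITY_CATEGORIES},
        config=config.phantom,
    )
    arrays = build_modality_arrays(manifest, config, label_key="category")

    # deterministic fruit-level holdout: the last n_val fruits of each category
    rng = np.random.default_rng(config.seed + 8)
    train_idx, val_idx = [], []
    for cat in CATEGORY_NAMES:
        cat_idx = [i for i, fid in enumerate(arrays.fruit_ids) if fid.startswith(cat)]
        cat_idx = [cat_idx[i] for i in rng.permutation(len(cat_idx))]
        val_idx += cat_idx[:n_val]
        train_idx += cat_idx[n_val:]
    split_indices = {"train": np.asarray(train_idx), "val": np.asarray(val_idx)}

    feats = {
        m: batch_features(stage_result.models[m], x)
        for m, x in (
            ("image", arrays.x_image),
            ("spectrum", arrays.x_spectrum),
            ("haptic", arrays.x_haptic),
        )
    }
    fused = fuse_arrays(feats)

    from .fusion import FusionNetConfig

    fus_cfg = FusionNetConfig(
        input_dim=fused.shape[1],
        hidden_widths=config.fusion.hidden_widths,
        dropout=config.fusion.dropout,
        epochs=config.fusion.epochs,
        seed=config.seed + 9,
    )
    _, _, fusion_report = train_fusion(
        fused, arrays.y, split_indices, fus_cfg, classes=arrays.classes
    )

    def baseline(feat: np.ndarray, seed: int) -> MetricsReport:
        rng_b = np.random.default_rng(seed)
        head = nn.Sequential(nn.Linear(feat.shape[1], 3, rng_b))
        nn.fit_classifier(
            head,
            feat[split_indices["train"]],
            arrays.y[split_indices["train"]],
            epochs=60,
            batch_size=16,
            lr=1e-2,
            seed=seed,
        )
        return evaluate_classifier(head, feat, arrays.y, split_indices, classes=arrays.classes)

    image_report = baseline(feats["image"], config.seed + 10)
    haptic_report = baseline(feats["haptic"], config.seed + 11)

    binary = {
        name: _binary_pos_vs_neg_accuracy(rep.confusions["val"])
        for name, rep in (
            ("fusion", fusion_report),
            ("image", image_report),
            ("haptic", haptic_report),
        )
    }
    result = HeterogeneousResult(
        config=config,
        fusion_report=fusion_report,
        image_report=image_report,
        haptic_report=haptic_report,
        binary_accuracies=binary,
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "heterogeneous_fusion.json").write_text(fusion_report.to_json())
        (out_dir / "heterogeneous_image.json").write_text(image_report.to_json())
        (out_dir / "heterogeneous_haptic.json").write_text(haptic_report.to_json())
        (out_dir / "heterogeneous_binary.json").write_text(
            json.dumps(binary, indent=2, sort_keys=True)
        )
    return result
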