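"""Canonical reference experiments on synthetic epigenomes.

These fix the study conditions used to validate the toolkit end to end —
the strong-signal recovery regime, the complementary-marks stacking
regime, the zero-effect null, and the shuffled-label permutation null —
so tests, scripts and documentation all run the same experiments.

Problem sizes are desk-scale (sub-megabase genomes, thousands of windows)
with reduced C/gamma sub-grids; signal effects are set so each regime is
unambiguous: strong signal is clearly recoverable, the null carries no
label information at all.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from enhancerstack.base_forest import ForestConfig, confidence_scores, train_base
from enhancerstack.evaluation import roc_auc
from enhancerstack.features import (
    FeatureMatrix,
    LabeledDataset,
    map_signal,
    minmax_normalize,
)
from enhancerstack.genomic_io import make_windows, read_broadpeak, read_chrom_sizes
from enhancerstack.meta_svm import SvmConfig, build_meta_features, predict_meta
from enhancerstack.pipeline import config_from_study, predict, read_truth_table, train
from enhancerstack.synthetic_data import MarkSpec, SynthSpec, simulate_study

#: reduced search grid (a sub-grid of the full C in {2..50}, gamma in {2..200})
REDUCED_SVM = SvmConfig(C_grid=(2, 8, 32), gamma_grid=(2, 20, 100), n_folds=10)


def strong_signal_spec(seed: int = 7) -> SynthSpec:
    """Strong-signal study: two enhancer-mark analogues with a clear
    lognormal signal lift at enhancer windows (peaks aligned to the grid),
    one uninformative repressive-mark analogue; ~2% enhancer windows,
    half shared across 4 tissues."""
    return SynthSpec(
        chrom_sizes={"chrA": 400_000, "chrB": 200_000},
        marks=[
            MarkSpec("H3K4me1", effect=4.0, noise_sd=0.25),
            MarkSpec("H3K27ac", effect=3.0, noise_sd=0.25),
            MarkSpec("H3K9me3", effect=0.0),
        ],
        peak_width_range=(200, 200),
        n_tissues=4,
        seed=seed,
    )


def strong_signal_run(workdir: str | Path, seed: int = 7) -> dict:
    """Train on 3 strong-signal tissues, test on the held-out 4th."""
    workdir = Path(workdir)
    study = simulate_study(strong_signal_spec(seed), workdir / "study")
    config = config_from_study(
        study, workdir / "results", test_tissue="tissue3", seed=seed, svm=REDUCED_SVM
    )
    bundle, report = train(config)
    grid, scores, labels = predict(bundle, config, "tissue3")
    truth = read_truth_table(study.truth_path, "tissue3")
    y = np.array([truth[w] for w in grid.window_ids()])
    return {
        "study": study,
        "config": config,
        "bundle": bundle,
        "report": report,
        "grid": grid,
        "scores": scores,
        "pred_labels": labels,
        "y_true": y,
        "test_auc": roc_auc(y, scores).auc,
    }


def complementary_spec(seed: int) -> SynthSpec:
    """Complementary-marks study: 6 tissues in two triplets; tissue t (and
    its held-out clone t+3) carries signal only on mark t, so each base
    classifier learns a different mark and no single base can cover all
    three held-out tissues."""
    effect = 4.0
    per_tissue = lambda t: [effect if i % 3 == t else 0.0 for i in range(6)]
    return SynthSpec(
        chrom_sizes={"chrA": 400_000},
        marks=[
            MarkSpec("m1", effect=per_tissue(0), noise_sd=0.3, background_rate=0.03),
            MarkSpec("m2", effect=per_tissue(1), noise_sd=0.3, background_rate=0.03),
            MarkSpec("m3", effect=per_tissue(2), noise_sd=0.3, background_rate=0.03),
        ],
        peak_width_range=(200, 200),
        n_tissues=6,
        seed=seed,
    )


def stacking_replicate(workdir: str | Path, seed: int) -> tuple[float, float]:
    """One stacking replicate: train on tissues 0-2, evaluate base vs meta
    AUC on the pooled windows of held-out tissues 3-5.

    Returns (meta AUC, best single-base AUC).
    """
    workdir = Path(workdir)
    study = simulate_study(complementary_spec(seed), workdir / "study")
    config = config_from_study(
        study,
        workdir / "results",
        seed=seed,
        tissue_names=["tissue0", "tissue1", "tissue2"],
        svm=REDUCED_SVM,
    )
    bundle, _ = train(config)
    grid = make_windows(read_chrom_sizes(study.chrom_sizes_path), config.window_width)
    metas, confs, ys = [], [], []
    for tf in study.tissues[3:]:
        peaks = {m: read_broadpeak(p) for m, p in sorted(tf.peak_paths.items())}
        feats = minmax_normalize(map_signal(peaks, grid))
        metas.append(build_meta_features(bundle.base_models, feats.values).meta_features)
        confs.append(
            np.column_stack([confidence_scores(m, feats.values) for m in bundle.base_models])
        )
        ys.append(tf.labels)
    X, C, y = np.vstack(metas), np.vstack(confs), np.concatenate(ys)
    scores, _ = predict_meta(bundle.meta_model, X)
    meta_auc = roc_auc(y, scores).auc
    best_base_auc = max(roc_auc(y, C[:, j]).auc for j in range(C.shape[1]))
    return meta_auc, best_base_auc


def null_spec(seed: int) -> SynthSpec:
    """Zero-effect null: every mark is background-only, so features are
    independent of the enhancer labels."""
    return SynthSpec(
        chrom_sizes={"chrA": 300_000},
        marks=[
            MarkSpec("m1", effect=0.0, background_rate=0.15),
            MarkSpec("m2", effect=0.0, background_rate=0.15),
            MarkSpec("m3", effect=0.0, background_rate=0.15),
        ],
        peak_width_range=(200, 200),
        n_tissues=4,
        seed=seed,
    )


def null_run(workdir: str | Path, seed: int) -> float:
    """Held-out-tissue AUC under the zero-effect null (expected ~0.5)."""
    workdir = Path(workdir)
    study = simulate_study(null_spec(seed), workdir / "study")
    config = config_from_study(
        study,
        workdir / "results",
        test_tissue="tissue3",
        seed=seed,
        svm=SvmConfig(C_grid=(2, 8), gamma_grid=(2, 20), n_folds=10),
    )
    bundle, _ = train(config)
    grid, scores, _ = predict(bundle, config, "tissue3")
    truth = read_truth_table(study.truth_path, "tissue3")
    y = np.array([truth[w] for w in grid.window_ids()])
    return roc_auc(y, scores).auc


def shuffled_label_precision(
    seeds: range | list[int], n: int = 600, prevalence: float = 0.3
) -> tuple[float, float]:
    """Permutation null for the base classifier.

    Features are informative for the original labels, but the labels are
    shuffled before training; held-out precision pooled over seeds should
    match the positive prevalence.  Returns (pooled precision, prevalence).
    """
    tp = fp = 0
    for seed in seeds:
        rng = np.random.default_rng(seed)
        y = (rng.random(n) < prevalence).astype(int)
        X = rng.normal(size=(n, 4))
        X[y == 1] += 1.5
        y_shuffled = rng.permutation(y)
        ds = LabeledDataset(
            FeatureMatrix([f"w{i}" for i in range(n)], list("abcd"), X), y_shuffled, "perm"
        )
        model = train_base(ds, ForestConfig(seed=seed))
        tp += model.heldout_confusion.tp
        fp += model.heldout_confusion.fp
    if tp + fp == 0:
        raise RuntimeError("permutation null produced no positive predictions")
    return tp / (tp + fp), prevalence
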