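"""End-to-end orchestration: train, predict, evaluate.

One pipeline serves both published-style workflows — peak-signal features
with EP300-style labels, or peak-signal/k-mer features with CAGE-enhancer
labels — because they differ only in inputs.  Per tissue the stages are

    read peaks -> map to windows -> min-max normalize -> label ->
    k-means-guided 1:10 negative sub-sampling -> 60/40 random forest

then the base models' pooled 40% held-out windows are scored by every base
model to build the meta-feature matrix, and the RBF-SVM main classifier is
grid-searched on it.  Each tissue's matrix is normalized on its own
min/max, so no statistic crosses the training/test tissue boundary.

All randomness flows from the single top-level seed through named
per-stage substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import joblib
import numpy as np
import yaml

from enhancerstack.base_forest import BaseModel, ForestConfig, train_base
from enhancerstack.evaluation import (
    MetricsReport,
    RocCurve,
    confusion,
    metrics,
    roc_auc,
    write_metrics_table,
)
from enhancerstack.features import (
    LabeledDataset,
    kmer_feature_matrix,
    label_windows,
    map_signal,
    minmax_normalize,
)
from enhancerstack.genomic_io import (
    WindowGrid,
    make_windows,
    read_bed,
    read_broadpeak,
    read_chrom_sizes,
    write_predictions_bed,
)
from enhancerstack.imbalance import SamplingConfig, subsample_negatives
from enhancerstack.meta_svm import MetaModel, SvmConfig, build_meta_features, grid_search_svm, predict_meta

logger = logging.getLogger(__name__)


def stage_seed(seed: int, name: str) -> int:
    """Deterministic per-stage substream seed derived from the master seed."""
    return (seed * 1_000_003 + zlib.crc32(name.encode())) % 2**31


@dataclass
class TissueManifest:
    name: str
    marks: dict[str, str]
    labels: str | None = None


@dataclass
class PipelineConfig:
    chrom_sizes: str
    tissues: list[TissueManifest]
    test_tissue: str | None = None
    window_width: int = 200
    feature_mode: str = "signal"  # or "kmer"
    genome_fasta: str | None = None
    aggregate: str = "max"
    min_label_overlap: float = 0.5
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    forest: ForestConfig = field(default_factory=ForestConfig)
    svm: SvmConfig = field(default_factory=SvmConfig)
    out_dir: str = "."
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_mode not in ("signal", "kmer"):
            raise ValueError(f"feature_mode must be 'signal' or 'kmer', got {self.feature_mode!r}")
        if self.feature_mode == "kmer" and not self.genome_fasta:
            raise ValueError("kmer feature mode requires genome_fasta")
        names = [t.name for t in self.tissues]
        if len(set(names)) != len(names):
            raise ValueError("duplicate tissue names in config")
        if self.test_tissue is not None and self.test_tissue not in names:
            raise ValueError(f"test_tissue {self.test_tissue!r} not among tissues {names}")
        if len(self.training_tissues()) < 2:
            raise ValueError("need at least 2 training tissues (stacking is meaningless with 1)")

    def training_tissues(self) -> list[TissueManifest]:
        return [t for t in self.tissues if t.name != self.test_tissue]

    def tissue(self, name: str) -> TissueManifest:
        for t in self.tissues:
            if t.name == name:
                return t
        raise KeyError(name)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["tissues"] = [TissueManifest(**t) for t in d["tissues"]]
        for key, sub in (("sampling", SamplingConfig), ("forest", ForestConfig), ("svm", SvmConfig)):
            if key in d and isinstance(d[key], dict):
                block = dict(d[key])
                for grid_key in ("C_grid", "gamma_grid"):
                    if grid_key in block:
                        block[grid_key] = tuple(block[grid_key])
                d[key] = sub(**block)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ModelBundle:
    """Everything needed to score a new tissue: base forests + meta-SVM."""

    base_models: list[BaseModel]
    meta_model: MetaModel
    mark_names: list[str]
    feature_mode: str
    window_width: int
    aggregate: str = "max"

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "ModelBundle":
        bundle = joblib.load(path)
        if not isinstance(bundle, ModelBundle):
            raise TypeError(f"{path} does not contain a model bundle")
        return bundle


def _file_checksums(paths: list[Path]) -> dict[str, str]:
    return {str(p): hashlib.sha256(p.read_bytes()).hexdigest() for p in paths}


def load_tissue_dataset(
    config: PipelineConfig, grid: WindowGrid, manifest: TissueManifest, require_labels: bool = True
) -> LabeledDataset:
    """Featurize and label one tissue; features min-max normalized on this
    tissue's own matrix."""
    if config.feature_mode == "kmer":
        raw = kmer_feature_matrix(grid, config.genome_fasta)
    else:
        peaks = {mark: read_broadpeak(path) for mark, path in sorted(manifest.marks.items())}
        raw = map_signal(peaks, grid, aggregate=config.aggregate)
    feats = minmax_normalize(raw)
    if manifest.labels is None:
        if require_labels:
            raise ValueError(f"tissue {manifest.name} has no label file")
        labels = np.zeros(grid.n_windows, dtype=int)
    else:
        labels = label_windows(grid, read_bed(manifest.labels), config.min_label_overlap)
    return LabeledDataset(feats, labels, manifest.name)


def _check_inputs_exist(config: PipelineConfig) -> list[Path]:
    paths = [Path(config.chrom_sizes)]
    if config.genome_fasta:
        paths.append(Path(config.genome_fasta))
    for t in config.training_tissues():
        paths.extend(Path(p) for p in t.marks.values())
        if t.labels:
            paths.append(Path(t.labels))
    missing = [p for p in paths if not p.exists()]
    if missing:
        raise FileNotFoundError(f"missing input files: {[str(p) for p in missing]}")
    return paths


def train(config: PipelineConfig) -> tuple[ModelBundle, dict]:
    """Run the full training workflow and serialize the model bundle."""
    inputs = _check_inputs_exist(config)
    grid = make_windows(read_chrom_sizes(config.chrom_sizes), config.window_width)
    training = config.training_tissues()

    mark_sets = [sorted(t.marks) for t in training]
    if config.feature_mode == "signal" and any(m != mark_sets[0] for m in mark_sets):
        raise ValueError(f"tissues disagree on mark sets: {mark_sets}")

    base_models: list[BaseModel] = []
    report: dict = {"tissues": {}, "seed": config.seed}
    for manifest in training:
        logger.info("tissue %s: loading features", manifest.name)
        ds = load_tissue_dataset(config, grid, manifest)
        n_pos = ds.n_positive
        sampling = SamplingConfig(
            ratio=config.sampling.ratio,
            n_clusters=config.sampling.n_clusters,
            max_iter=config.sampling.max_iter,
            seed=stage_seed(config.seed, f"sample:{manifest.name}"),
        )
        balanced = subsample_negatives(ds, sampling)
        forest_cfg = ForestConfig(
            n_trees=config.forest.n_trees,
            max_depth=config.forest.max_depth,
            min_samples_split=config.forest.min_samples_split,
            features_per_split=config.forest.features_per_split,
            seed=stage_seed(config.seed, f"forest:{manifest.name}"),
        )
        model = train_base(balanced, forest_cfg)
        base_models.append(model)
        report["tissues"][manifest.name] = {
            "n_windows": grid.n_windows,
            "n_positive": n_pos,
            "n_balanced": len(balanced.labels),
            "heldout_fscore": model.heldout_fscore,
            "heldout_metrics": model.heldout_report.to_dict(),
        }
        logger.info(
            "tissue %s: %d pos, balanced n=%d, held-out F=%.3f",
            manifest.name,
            n_pos,
            len(balanced.labels),
            model.heldout_fscore,
        )

    pooled_X = np.vstack([m.heldout_features for m in base_models])
    pooled_y = np.concatenate([m.heldout_labels for m in base_models])
    meta = build_meta_features(base_models, pooled_X, pooled_y)
    svm_cfg = SvmConfig(
        C_grid=config.svm.C_grid,
        gamma_grid=config.svm.gamma_grid,
        n_folds=config.svm.n_folds,
        tol=config.svm.tol,
        seed=stage_seed(config.seed, "svm"),
    )
    logger.info("grid-searching SVM on %d pooled held-out windows", len(pooled_y))
    meta_model = grid_search_svm(meta, svm_cfg)
    report["meta"] = {
        "n_pooled": int(len(pooled_y)),
        "chosen_C": meta_model.chosen_C,
        "chosen_gamma": meta_model.chosen_gamma,
        "cv_balanced_error": meta_model.cv_balanced_error,
    }
    logger.info(
        "meta-SVM: C=%g gamma=%g CV BER=%.4f",
        meta_model.chosen_C,
        meta_model.chosen_gamma,
        meta_model.cv_balanced_error,
    )

    bundle = ModelBundle(
        base_models=base_models,
        meta_model=meta_model,
        mark_names=base_models[0].feature_names,
        feature_mode=config.feature_mode,
        window_width=config.window_width,
        aggregate=config.aggregate,
    )

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle.save(out_dir / "model_bundle.joblib")
    write_metrics_table(
        {m.tissue: m.heldout_report for m in base_models}, out_dir / "base_training_report.tsv"
    )
    meta_model.dump_cv_surface(svm_cfg, out_dir / "svm_cv_ber_surface.tsv")
    manifest_out = {
        "seed": config.seed,
        "config": _config_as_dict(config),
        "input_sha256": _file_checksums(inputs),
        "report": report,
    }
    with open(out_dir / "training_manifest.json", "w") as fh:
        json.dump(manifest_out, fh, indent=2)
    return bundle, report


def _config_as_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["svm"]["C_grid"] = list(d["svm"]["C_grid"])
    d["svm"]["gamma_grid"] = list(d["svm"]["gamma_grid"])
    return d


def predict(
    bundle: ModelBundle,
    config: PipelineConfig,
    tissue_name: str,
    out_dir: str | Path | None = None,
) -> tuple[WindowGrid, np.ndarray, np.ndarray]:
    """Score every window of a tissue with the trained stack.

    Returns (grid, decision scores, 0/1 labels); optionally writes a BED6
    prediction track (score column = logistic-squashed decision value) and
    a scores TSV.
    """
    manifest = config.tissue(tissue_name)
    if bundle.feature_mode == "signal":
        got = sorted(manifest.marks)
        expected = sorted(bundle.mark_names)
        if got != expected:
            raise ValueError(
                f"tissue {tissue_name} marks differ from bundle: "
                f"missing {sorted(set(expected) - set(got))}, extra {sorted(set(got) - set(expected))}"
            )
    grid = make_windows(read_chrom_sizes(config.chrom_sizes), bundle.window_width)
    ds = load_tissue_dataset(config, grid, manifest, require_labels=False)
    meta = build_meta_features(bundle.base_models, ds.features.values)
    scores, labels = predict_meta(bundle.meta_model, meta.meta_features)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        squashed = 1.0 / (1.0 + np.exp(-scores))
        write_predictions_bed(grid.windows, squashed, labels, out_dir / f"{tissue_name}_predictions.bed")
        with open(out_dir / f"{tissue_name}_scores.tsv", "w") as fh:
            fh.write("window\tscore\tlabel\n")
            for w, s, lab in zip(grid.windows, scores, labels):
                fh.write(f"{w.id}\t{s:.6g}\t{lab}\n")
    return grid, scores, labels


def evaluate(
    window_ids: list[str],
    scores: np.ndarray,
    pred_labels: np.ndarray,
    truth: dict[str, int],
    out_dir: str | Path | None = None,
    name: str = "predictions",
) -> tuple[MetricsReport, RocCurve]:
    """Join predictions with truth on window id; metrics + ROC/AUC.

    Raises if the window sets differ (reporting counts) or truth has a
    single class.
    """
    missing = [w for w in window_ids if w not in truth]
    if missing or len(truth) != len(window_ids):
        raise ValueError(
            f"window sets differ: {len(window_ids)} predicted, {len(truth)} truth, "
            f"{len(missing)} predicted windows missing from truth"
        )
    y = np.array([truth[w] for w in window_ids], dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("truth labels contain a single class; metrics/ROC undefined")
    rep = metrics(confusion(y, pred_labels))
    roc = roc_auc(y, scores)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_metrics_table({name: rep}, out_dir / f"{name}_metrics.tsv")
        roc.to_tsv(out_dir / f"{name}_roc.tsv")
    return rep, roc


def config_from_study(
    study,
    out_dir: str | Path,
    test_tissue: str | None = None,
    seed: int = 0,
    tissue_names: list[str] | None = None,
    **overrides,
) -> PipelineConfig:
    """Build a PipelineConfig pointing at a simulated study's files.

    ``tissue_names`` restricts the manifest to a subset of the study's
    tissues; extra keyword arguments override PipelineConfig fields.
    """
    tissues = [
        TissueManifest(tf.name, {m: str(p) for m, p in tf.peak_paths.items()}, str(tf.label_path))
        for tf in study.tissues
        if tissue_names is None or tf.name in tissue_names
    ]
    return PipelineConfig(
        chrom_sizes=str(study.chrom_sizes_path),
        tissues=tissues,
        test_tissue=test_tissue,
        seed=seed,
        out_dir=str(out_dir),
        **overrides,
    )


def read_truth_table(path: str | Path, tissue: str | None = None) -> dict[str, int]:
    """Read a truth table TSV (window [tissue] label) into window -> label."""
    truth: dict[str, int] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            row = dict(zip(header, parts))
            if tissue is not None and row.get("tissue") not in (None, tissue):
                continue
            truth[row["window"]] = int(row["label"])
    return truth
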