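"""End-to-end pipeline: simulate -> preprocess -> split -> train -> evaluate
-> profile -> match.

Each stage writes its artefacts under one run directory
(``simulate/``, ``preprocess/``, ...) and registers them, with SHA-256
checksums, in ``manifest.json``.  Re-running with the same configuration and
seeds reproduces every metric file bit-for-bit (all computation is seeded
numpy on CPU); deleting a stage's outputs and resuming recomputes that
stage and everything downstream, leaving upstream stages untouched.

Three model branches are trained per split: the BF CNN (six z-planes), the
FL CNN (five stain channels) and the engineered-feature MLP benchmark
("CP").  The evaluate/profile/match stages then emit machine-readable
analogues of the headline analyses: per-split macro-F1 and pooled
per-class F1 tables, normalized confusion matrices, compound-level
accuracy and cross-branch agreement, accuracy-versus-grit curves, cosine
within/across MoA summaries, plate-correlation matrices, and the sphering
regularization sweep of mean average precision.
"""

from __future__ import annotations

import dataclasses
import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, io, preprocess, profiling, splits as splits_mod
from .classifier import (ImageDataset, TrainedModel, extract_features,
                         predict, train_classifier, train_feature_mlp)
from .config import DMSO_LABEL, ModelConfig, ScreenConfig
from .preprocess import DEFAULT_KERNEL_FRAC, PlateChannelStats
from .synthetic import (feature_columns, generate_feature_table,
                        generate_layout, ground_truth, render_site,
                        site_table)

STAGE_ORDER = ["simulate", "preprocess", "split", "train", "evaluate",
               "profile", "match"]
STAGE_DEPS = {
    "simulate": [],
    "preprocess": ["simulate"],
    "split": ["simulate"],
    "train": ["preprocess", "split"],
    "evaluate": ["train"],
    "profile": ["preprocess", "train"],
    "match": ["train", "profile"],
}

CNN_BRANCHES = ("BF", "FL")
ALL_BRANCHES = ("BF", "FL", "CP")


@dataclass
class PipelineConfig:
    """One reproducible end-to-end run.

    Seeds are split per stage (layout/rendering live in ``screen.seed``;
    ``split_seed`` and ``train_seed`` are independent) so stages can be
    varied without disturbing the others.
    """

    screen: ScreenConfig = field(default_factory=ScreenConfig)
    n_splits: int = 5
    train_splits: tuple[int, ...] | None = None  # 1-based; None = all
    modalities: tuple[str, ...] = CNN_BRANCHES
    include_feature_mlp: bool = True
    normalization: str = "dmso"  # "dmso" | "site"
    kernel_frac: float = DEFAULT_KERNEL_FRAC
    conv_widths: tuple[int, ...] = (16, 32, 64)
    hidden_dim: int = 512
    lr: float = 3e-3
    epochs: int = 15
    batch_size: int = 32
    patience: int = 5
    augment: bool = True
    split_seed: int = 1
    train_seed: int = 2
    lambda_sweep: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0)
    map_lambda: float = 0.1
    n_grit_bins: int = 10

    def __post_init__(self) -> None:
        if self.normalization not in ("dmso", "site"):
            raise ValueError("normalization must be 'dmso' or 'site'")
        bad = [m for m in self.modalities if m not in CNN_BRANCHES]
        if bad:
            raise ValueError(f"unknown modalities {bad}")

    @property
    def split_indices(self) -> list[int]:
        if self.train_splits is None:
            return list(range(1, self.n_splits + 1))
        return sorted(self.train_splits)

    @property
    def branches(self) -> list[str]:
        out = list(self.modalities)
        if self.include_feature_mlp:
            out.append("CP")
        return out

    def model_config(self, branch: str) -> ModelConfig:
        channels = {"BF": self.screen.bf_planes, "FL": self.screen.fl_channels,
                    "CP": self.screen.n_features}[branch]
        return ModelConfig(
            backbone="smallcnn" if branch != "CP" else "mlp",
            input_channels=channels,
            n_classes=len(self.screen.class_labels),
            conv_widths=self.conv_widths, hidden_dim=self.hidden_dim,
            lr=self.lr, epochs=self.epochs, batch_size=self.batch_size,
            patience=self.patience, augment=self.augment,
            seed=self.train_seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["screen"] = self.screen.to_dict()
        for key in ("modalities", "conv_widths", "lambda_sweep"):
            d[key] = list(d[key])
        if d["train_splits"] is not None:
            d["train_splits"] = list(d["train_splits"])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        data["screen"] = ScreenConfig.from_dict(data.get("screen", {}))
        for key in ("modalities", "conv_widths", "lambda_sweep"):
            if key in data:
                data[key] = tuple(data[key])
        if data.get("train_splits") is not None:
            data["train_splits"] = tuple(data["train_splits"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def demo_config(seed: int = 0) -> PipelineConfig:
    """A minutes-scale demo screen exercising every stage."""
    screen = ScreenConfig(
        n_plates=2, wells_per_plate=96, sites_per_well=2,
        moa_compound_counts={"MoA-A": 5, "MoA-B": 5, "MoA-C": 5},
        dmso_wells_per_plate=8, technical_reps=3, biological_rep_plates=2,
        image_size=32, effect_size=5.0, n_features=32, seed=seed)
    return PipelineConfig(
        screen=screen, n_splits=2, conv_widths=(8, 16), epochs=10,
        batch_size=16, patience=10, kernel_frac=0.3,
        split_seed=seed + 1, train_seed=seed + 2,
        lambda_sweep=(1e-3, 1e-1, 1.0), map_lambda=0.1, n_grit_bins=5)


# ---------------------------------------------------------------------------
# Manifest


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Traceability record: config snapshot, seeds, per-stage checksums."""

    path: Path
    config: dict
    stages: dict = field(default_factory=dict)

    @classmethod
    def open(cls, run_dir: Path, config: "PipelineConfig") -> "RunManifest":
        path = run_dir / "manifest.json"
        snapshot = config.to_dict()
        if path.exists():
            data = io.read_json(path)
            if data.get("config") == snapshot:
                return cls(path=path, config=snapshot,
                           stages=data.get("stages", {}))
        return cls(path=path, config=snapshot)

    def record(self, stage: str, inputs: dict[str, str],
               outputs: list[Path], run_dir: Path) -> None:
        self.stages[stage] = {
            "inputs": inputs,
            "outputs": {str(p.relative_to(run_dir)): _sha256(p)
                        for p in outputs},
            "completed_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        self.save()

    def save(self) -> None:
        io.write_json({"config": self.config, "stages": self.stages},
                      self.path)

    def outputs_intact(self, stage: str, run_dir: Path) -> bool:
        rec = self.stages.get(stage)
        if rec is None:
            return False
        for rel, sha in rec["outputs"].items():
            p = run_dir / rel
            if not p.exists() or _sha256(p) != sha:
                return False
        return True


# ---------------------------------------------------------------------------
# Stage implementations


def _images_dir(run_dir: Path, modality: str, corrected: bool) -> Path:
    if modality == "BF" and corrected:
        return run_dir / "preprocess" / "images_BF"
    return run_dir / "simulate" / f"images_{modality}"


def _stage_simulate(cfg: PipelineConfig, run_dir: Path) -> list[Path]:
    out = run_dir / "simulate"
    out.mkdir(parents=True, exist_ok=True)
    platemap = generate_layout(cfg.screen)
    io.write_table(platemap, out / "platemap.csv")
    features = generate_feature_table(cfg.screen)
    io.write_table(features, out / "features.csv")
    truth = ground_truth(cfg.screen)
    outputs = [out / "platemap.csv", out / "features.csv"]
    for name, table in truth.items():
        p = out / f"ground_truth_{name}.csv"
        table.to_csv(p, index=name == "feature_plate_offsets")
        outputs.append(p)
    sites = site_table(platemap, cfg.screen.sites_per_well)
    for modality in cfg.modalities:
        img_dir = out / f"images_{modality}"
        img_dir.mkdir(exist_ok=True)
        for rec in sites.to_dict("records"):
            image = render_site(rec, cfg.screen, modality)
            p = img_dir / io.site_tiff_name(
                image.plate_id, image.well, image.site_index, modality)
            io.write_site_tiff(image, p)
            outputs.append(p)
    return outputs


def _stage_preprocess(cfg: PipelineConfig, run_dir: Path) -> list[Path]:
    out = run_dir / "preprocess"
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    platemap = io.read_platemap(run_dir / "simulate" / "platemap.csv")
    sites = site_table(platemap, cfg.screen.sites_per_well)

    if "BF" in cfg.modalities:
        bf_dir = out / "images_BF"
        bf_dir.mkdir(exist_ok=True)
        for rec in sites.to_dict("records"):
            name = io.site_tiff_name(rec["plate_id"], rec["well"],
                                     rec["site_index"], "BF")
            image = io.read_site_tiff(run_dir / "simulate" / "images_BF" / name)
            corrected = preprocess.correct_background(image, cfg.kernel_frac)
            io.write_site_tiff(corrected, bf_dir / name)
            outputs.append(bf_dir / name)

    for modality in cfg.modalities:
        frames = []
        dmso_sites = sites[sites.compound_id == DMSO_LABEL]
        img_dir = _images_dir(run_dir, modality, corrected=True)
        for plate, sub in dmso_sites.groupby("plate_id"):
            images = [io.read_site_tiff(
                img_dir / io.site_tiff_name(r["plate_id"], r["well"],
                                            r["site_index"], modality))
                for r in sub.to_dict("records")]
            frames.append(preprocess.compute_dmso_stats(images).to_frame())
        p = out / f"pixel_stats_{modality}.csv"
        io.write_table(pd.concat(frames, ignore_index=True), p)
        outputs.append(p)

    features = io.read_table(run_dir / "simulate" / "features.csv")
    fcols = feature_columns(features)
    normed = preprocess.normalize_feature_table(features, fcols)
    io.write_table(normed, out / "features_norm.csv")
    outputs.append(out / "features_norm.csv")
    return outputs


def _stage_split(cfg: PipelineConfig, run_dir: Path) -> list[Path]:
    out = run_dir / "split"
    out.mkdir(parents=True, exist_ok=True)
    platemap = io.read_platemap(run_dir / "simulate" / "platemap.csv")
    split_set = splits_mod.make_splits(platemap, n_splits=cfg.n_splits,
                                       seed=cfg.split_seed)
    io.write_table(split_set.to_frame(), out / "splits.csv")
    (out / "dmso_wells.json").write_text(split_set.dmso_wells_json())
    return [out / "splits.csv", out / "dmso_wells.json"]


def _load_split_set(run_dir: Path) -> splits_mod.SplitSet:
    table = io.read_table(run_dir / "split" / "splits.csv")
    dmso = io.read_json(run_dir / "split" / "dmso_wells.json")
    assignments = []
    for s, sub in table.groupby("split_index"):
        assignments.append(splits_mod.SplitAssignment(
            split_index=int(s),
            compound_partition=dict(zip(sub.compound_id, sub.partition)),
            dmso_wells=dmso))
    return splits_mod.SplitSet(assignments=assignments)


def _load_images(cfg: PipelineConfig, run_dir: Path, sites: pd.DataFrame,
                 modality: str) -> ImageDataset:
    img_dir = _images_dir(run_dir, modality, corrected=True)
    stats = None
    if cfg.normalization == "dmso":
        table = io.read_table(run_dir / "preprocess"
                              / f"pixel_stats_{modality}.csv")
        stats = {p: PlateChannelStats.from_frame(sub)
                 for p, sub in table.groupby("plate_id")}
    arrays, meta_rows = [], []
    for rec in sites.to_dict("records"):
        name = io.site_tiff_name(rec["plate_id"], rec["well"],
                                 rec["site_index"], modality)
        image = io.read_site_tiff(img_dir / name)
        if cfg.normalization == "dmso":
            image = preprocess.normalize_dmso_plate(image,
                                                    stats[image.plate_id])
        else:
            image = preprocess.normalize_site(image)
        arrays.append(image.pixels)
        meta_rows.append(rec)
    return ImageDataset(images=np.stack(arrays).astype(np.float32),
                        meta=pd.DataFrame(meta_rows))


def _stage_train(cfg: PipelineConfig, run_dir: Path) -> list[Path]:
    out = run_dir / "train"
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    platemap = io.read_platemap(run_dir / "simulate" / "platemap.csv")
    sites = site_table(platemap, cfg.screen.sites_per_well)
    split_set = _load_split_set(run_dir)
    labels = cfg.screen.class_labels
    features = io.read_table(run_dir / "preprocess" / "features_norm.csv")
    fcols = feature_columns(features)

    for assignment in split_set:
        s = assignment.split_index
        if s not in cfg.split_indices:
            continue
        test_sites = splits_mod.partition_sites(sites, assignment, "test")
        for branch in cfg.branches:
            tag = f"{branch}_s{s}"
            if branch == "CP":
                model = train_feature_mlp(features, assignment,
                                          cfg.model_config("CP"), fcols, labels)
                x_test = splits_mod.partition_sites(
                    features, assignment, "test")
                test_x = x_test[fcols].to_numpy()
                test_meta = x_test[[c for c in x_test.columns
                                    if c not in fcols]]
            else:
                train_pool = pd.concat([
                    splits_mod.partition_sites(sites, assignment, "train"),
                    splits_mod.partition_sites(sites, assignment, "val"),
                ], ignore_index=True)
                dataset = _load_images(cfg, run_dir, train_pool, branch)
                model = train_classifier(dataset, assignment,
                                         cfg.model_config(branch), labels)
                test_ds = _load_images(cfg, run_dir, test_sites, branch)
                test_x, test_meta = test_ds.images, test_ds.meta
            model.save(out / f"{tag}_model")
            preds = predict(model, test_x, test_meta)
            preds.insert(0, "split_index", s)
            io.write_table(preds, out / f"{tag}_test_predictions.csv")
            emb = extract_features(model, test_x, test_meta)
            emb.insert(0, "split_index", s)
            io.write_table(emb, out / f"{tag}_test_embeddings.csv")
            log = pd.DataFrame(model.log)
            log.to_json(out / f"{tag}_log.jsonl", orient="records",
                        lines=True)
            outputs += [out / f"{tag}_model.npz", out / f"{tag}_model.json",
                        out / f"{tag}_test_predictions.csv",
                        out / f"{tag}_test_embeddings.csv",
                        out / f"{tag}_log.jsonl"]
    return outputs


def _branch_predictions(cfg: PipelineConfig, run_dir: Path,
                        branch: str) -> dict[int, pd.DataFrame]:
    out = {}
    for s in cfg.split_indices:
        p = run_dir / "train" / f"{branch}_s{s}_test_predictions.csv"
        out[s] = io.read_table(p)
    return out


def _branch_embeddings(cfg: PipelineConfig, run_dir: Path,
                       branch: str) -> pd.DataFrame:
    frames = [io.read_table(run_dir / "train"
                            / f"{branch}_s{s}_test_embeddings.csv")
              for s in cfg.split_indices]
    return pd.concat(frames, ignore_index=True)


def _stage_evaluate(cfg: PipelineConfig, run_dir: Path) -> list[Path]:
    out = run_dir / "evaluate"
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    labels = cfg.screen.class_labels
    metrics: dict = {"normalization": cfg.normalization, "macro_f1": {}}
    acc_tables: dict[str, pd.DataFrame] = {}
    per_class = {}
    for branch in cfg.branches:
        by_split = _branch_predictions(cfg, run_dir, branch)
        metrics["macro_f1"][branch] = {
            str(s): evaluation.macro_f1(recs) for s, recs in by_split.items()}
        pooled_f1, _ = evaluation.pooled_per_class_f1(
            by_split, labels, expected_splits=cfg.n_splits)
        per_class[branch] = pooled_f1
        pooled = pd.concat(by_split.values(), ignore_index=True)
        cm = evaluation.confusion_matrix(pooled, labels, normalize=True)
        cm.to_csv(out / f"confusion_{branch}.csv")
        outputs.append(out / f"confusion_{branch}.csv")
        acc = evaluation.compound_accuracy(pooled)
        io.write_table(acc, out / f"compound_accuracy_{branch}.csv")
        outputs.append(out / f"compound_accuracy_{branch}.csv")
        acc_tables[branch] = acc
    pc = pd.DataFrame(per_class)
    pc.index.name = "class"
    pc.to_csv(out / "per_class_f1.csv")
    outputs.append(out / "per_class_f1.csv")

    if set(ALL_BRANCHES) <= set(cfg.branches):
        try:
            agr = evaluation.modality_agreement(
                acc_tables["BF"], acc_tables["FL"], acc_tables["CP"])
            metrics["agreement"] = {
                "pearson_bf_fl": agr.pearson_ab,
                "pearson_bf_cp": agr.pearson_ac,
                "consistently_better_bf": agr.better_set,
                "consistently_worse_bf": agr.worse_set,
            }
        except ValueError as err:
            metrics["agreement"] = {"undefined": str(err)}
    io.write_json(metrics, out / "metrics.json")
    outputs.append(out / "metrics.json")
    return outputs


def _well_grit(cfg: PipelineConfig, run_dir: Path) -> pd.DataFrame:
    """Grit per well from the normalized engineered-feature profiles."""
    features = io.read_table(run_dir / "preprocess" / "features_norm.csv")
    fcols = feature_columns(features)
    wells = profiling.aggregate_sites_to_wells(features, fcols)
    return profiling.grit(wells, fcols).scores


def _stage_profile(cfg: PipelineConfig, run_dir: Path) -> list[Path]:
    out = run_dir / "profile"
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    features = io.read_table(run_dir / "preprocess" / "features_norm.csv")
    fcols = feature_columns(features)
    wells = profiling.aggregate_sites_to_wells(features, fcols)
    io.write_table(wells, out / "well_profiles_cp.csv")
    outputs.append(out / "well_profiles_cp.csv")
    grit_scores = _well_grit(cfg, run_dir)
    io.write_table(grit_scores, out / "grit.csv")
    outputs.append(out / "grit.csv")

    for branch in cfg.branches:
        pooled = pd.concat(_branch_predictions(cfg, run_dir, branch).values(),
                           ignore_index=True)
        joined = pooled.merge(
            grit_scores[["plate_id", "well", "grit"]], on=["plate_id", "well"])
        joined = joined[np.isfinite(joined.grit)]
        curve = profiling.bin_accuracy_by_grit(
            (joined.moa_label == joined.pred_label).to_numpy(),
            joined.grit.to_numpy(),
            n_bins=min(cfg.n_grit_bins, max(1, len(joined))))
        io.write_table(curve, out / f"grit_accuracy_{branch}.csv")
        outputs.append(out / f"grit_accuracy_{branch}.csv")

        emb = _branch_embeddings(cfg, run_dir, branch)
        ecols = feature_columns(emb)
        treated = emb[emb.moa_label != DMSO_LABEL]
        sep = profiling.cosine_within_across(
            treated[ecols].to_numpy(), treated.moa_label.to_numpy())
        io.write_json({
            "within_mean": float(sep.within.mean()),
            "across_mean": float(sep.across.mean()),
            "separation": sep.separation,
        }, out / f"cosine_{branch}.json")
        outputs.append(out / f"cosine_{branch}.json")

        ctrl = emb[emb.moa_label == DMSO_LABEL]
        pcm = profiling.plate_correlation_matrix(ctrl, ecols)
        pcm.to_csv(out / f"plate_correlation_{branch}.csv")
        outputs.append(out / f"plate_correlation_{branch}.csv")
    return outputs


def _stage_match(cfg: PipelineConfig, run_dir: Path) -> list[Path]:
    out = run_dir / "match"
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    grit_scores = io.read_table(run_dir / "profile" / "grit.csv")
    for branch in cfg.branches:
        emb = _branch_embeddings(cfg, run_dir, branch)
        ecols = feature_columns(emb)
        wells = profiling.aggregate_sites_to_wells(emb, ecols)
        ctrl = wells[wells.moa_label == DMSO_LABEL][ecols].to_numpy()
        sweep_rows = []
        for lam in cfg.lambda_sweep:
            transform = profiling.fit_sphering(ctrl, lam)
            sphered = transform.apply_frame(wells, ecols)
            map_score, _ = profiling.mean_average_precision(sphered, ecols)
            sweep_rows.append(dict(lambda_reg=lam, map=map_score))
        io.write_table(pd.DataFrame(sweep_rows),
                       out / f"map_by_lambda_{branch}.csv")
        outputs.append(out / f"map_by_lambda_{branch}.csv")

        transform = profiling.fit_sphering(ctrl, cfg.map_lambda)
        sphered = transform.apply_frame(wells, ecols)
        _, ap_table = profiling.mean_average_precision(sphered, ecols)
        ap = ap_table.merge(grit_scores[["plate_id", "well", "grit"]],
                            on=["plate_id", "well"])
        ap = ap[np.isfinite(ap.grit)]
        curve = profiling.bin_accuracy_by_grit(
            ap.average_precision.to_numpy(), ap.grit.to_numpy(),
            n_bins=min(cfg.n_grit_bins, max(1, len(ap))))
        curve = curve.rename(columns={"accuracy": "mean_ap"})
        io.write_table(curve, out / f"map_vs_grit_{branch}.csv")
        outputs.append(out / f"map_vs_grit_{branch}.csv")
    return outputs


_STAGE_FN = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "split": _stage_split,
    "train": _stage_train,
    "evaluate": _stage_evaluate,
    "profile": _stage_profile,
    "match": _stage_match,
}


def run_pipeline(config: PipelineConfig, run_dir: str | Path,
                 resume: bool = True,
                 stages: list[str] | None = None) -> RunManifest:
    """Execute the pipeline under ``run_dir``, stage by stage.

    With ``resume`` (default), a stage whose recorded outputs are intact
    and whose upstream stages did not rerun is skipped.  ``stages`` limits
    execution to a subset (dependencies must already be satisfied).
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(run_dir / "config.yaml")
    manifest = RunManifest.open(run_dir, config)
    reran: set[str] = set()
    todo = STAGE_ORDER if stages is None else stages
    for stage in STAGE_ORDER:
        if stage not in todo:
            continue
        upstream_changed = any(dep in reran for dep in STAGE_DEPS[stage])
        if resume and not upstream_changed and manifest.outputs_intact(
                stage, run_dir):
            continue
        try:
            outputs = _STAGE_FN[stage](config, run_dir)
        except Exception as err:
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err
        inputs = {}
        for dep in STAGE_DEPS[stage]:
            inputs.update(manifest.stages.get(dep, {}).get("outputs", {}))
        manifest.record(stage, inputs, outputs, run_dir)
        reran.add(stage)
    return manifest
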