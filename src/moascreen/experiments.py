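"""Canned study protocols built on the library.

These are the desk-scale experiments the package uses to validate itself:

* :func:`graded_recovery` — a screen whose compounds carry five graded
  effect-size levels; after training CNNs on all five splits and pooling
  the test predictions, both classification accuracy and mean average
  precision must increase with the mean grit score of the injected levels;
* :func:`chance_control` — the same screen with zero effect size;
  classification must sit inside the Monte-Carlo chance band and mAP
  inside its label-permutation null;
* :func:`sphering_diagnostics` — control profiles with pronounced plate
  offsets; regularized sphering must halve the plate-cluster silhouette
  and drive the control covariance to identity.

The configurations here are the package's reference study conditions; the
functions are reused verbatim by the test suite and the acceptance script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.metrics import silhouette_score

from . import profiling
from .classifier import (ImageDataset, extract_features, predict,
                         train_classifier)
from .config import (DEFAULT_MOA_COMPOUND_COUNTS, DMSO_LABEL, ModelConfig,
                     ScreenConfig)
from .evaluation import macro_f1
from .preprocess import (compute_dmso_stats, correct_background,
                         normalize_dmso_plate, normalize_feature_table,
                         normalize_site)
from .splits import make_splits, partition_sites
from .synthetic import (feature_columns, generate_feature_table,
                        generate_layout, render_site, site_table)

#: Graded per-compound effect multipliers (five levels, cycled within MoA).
GRADED_LEVELS = (0.5, 1.0, 2.0, 4.0, 8.0)

#: Background-smoothing kernel for desk-scale renders.  The kernel must sit
#: between the cell scale (~0.05 of the image side) and the illumination
#: scale (~the full side); 0.3 of the side achieves at 48-96 px the same
#: cell-to-kernel ratio a 101 px kernel has on a full-resolution 20x
#: acquisition.
DESK_KERNEL_FRAC = 0.3


def study_screen_config(seed: int, effect_size: float = 1.0,
                        graded: bool = False,
                        sites_per_well: int = 2) -> ScreenConfig:
    """The two-plate, ten-MoA desk-scale screen used for self-validation.

    Ten compounds per MoA (100 compounds, six replicate wells each) on one
    biological-replicate plate pair, 48 px sites.  With ``graded`` the
    compounds of each MoA cycle through :data:`GRADED_LEVELS` twice, so
    every level is represented in training whenever one of its compounds
    is held out.
    """
    moas = {m: 10 for m in DEFAULT_MOA_COMPOUND_COUNTS}
    cfg = ScreenConfig(
        n_plates=2, wells_per_plate=384, sites_per_well=sites_per_well,
        moa_compound_counts=moas, image_size=48, effect_size=effect_size,
        n_features=32, seed=seed)
    if graded:
        cfg.effect_size_by_compound = {
            f"{m}_{k + 1:02d}": GRADED_LEVELS[k % len(GRADED_LEVELS)]
            for m in moas for k in range(10)}
    return cfg


def study_model_config(cfg: ScreenConfig, modality: str, seed: int,
                       epochs: int = 12) -> ModelConfig:
    return ModelConfig(
        input_channels=cfg.channels(modality),
        n_classes=len(cfg.class_labels), conv_widths=(8, 16, 32),
        epochs=epochs, patience=epochs, batch_size=32, seed=seed)


def build_image_dataset(cfg: ScreenConfig, modality: str,
                        normalization: str = "dmso") -> ImageDataset:
    """Render the whole screen in memory and normalize it one way.

    BF sites are background-corrected before any statistics are taken.
    """
    platemap = generate_layout(cfg)
    sites = site_table(platemap, cfg.sites_per_well)
    records = sites.to_dict("records")
    rendered = [render_site(r, cfg, modality) for r in records]
    if modality == "BF":
        rendered = [correct_background(im, DESK_KERNEL_FRAC)
                    for im in rendered]
    if normalization == "dmso":
        stats = {}
        for plate in sites.plate_id.unique():
            stats[plate] = compute_dmso_stats(
                [im for im, r in zip(rendered, records)
                 if r["compound_id"] == DMSO_LABEL and r["plate_id"] == plate])
        rendered = [normalize_dmso_plate(im, stats[im.plate_id])
                    for im in rendered]
    elif normalization == "site":
        rendered = [normalize_site(im) for im in rendered]
    else:
        raise ValueError("normalization must be 'dmso' or 'site'")
    return ImageDataset(
        images=np.stack([im.pixels for im in rendered]).astype(np.float32),
        meta=sites)


def pooled_test_predictions(cfg: ScreenConfig, dataset: ImageDataset,
                            n_splits: int = 5, split_seed: int = 0,
                            train_seed: int = 0, epochs: int = 12,
                            modality: str = "FL") -> pd.DataFrame:
    """Train one CNN per split and pool the test-set predictions."""
    platemap = generate_layout(cfg)
    meta = dataset.meta.assign(_row=np.arange(len(dataset.meta)))
    frames = []
    for assignment in make_splits(platemap, n_splits=n_splits,
                                  seed=split_seed):
        mc = study_model_config(cfg, modality, seed=train_seed, epochs=epochs)
        model = train_classifier(dataset, assignment, mc, cfg.class_labels)
        test = partition_sites(meta, assignment, "test")
        pr = predict(model, dataset.images[test._row.to_numpy()],
                     test.drop(columns="_row"))
        pr.insert(0, "split_index", assignment.split_index)
        frames.append(pr)
    return pd.concat(frames, ignore_index=True)


def control_well_grit_and_map(cfg: ScreenConfig, map_lambda: float = 0.1
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Grit per well and per-well AP on sphered feature-space profiles."""
    table = generate_feature_table(cfg)
    fcols = feature_columns(table)
    table = normalize_feature_table(table, fcols)
    wells = profiling.aggregate_sites_to_wells(table, fcols)
    grit_scores = profiling.grit(wells, fcols).scores
    ctrl = wells[wells.compound_id == DMSO_LABEL][fcols].to_numpy()
    sphered = profiling.fit_sphering(ctrl, map_lambda).apply_frame(
        wells, fcols)
    _, ap_table = profiling.mean_average_precision(sphered, fcols)
    return grit_scores, ap_table


def graded_recovery(seeds: tuple[int, ...], epochs: int = 12,
                    modality: str = "FL") -> dict:
    """Effect-size recovery across graded levels (three-seed protocol).

    For each seed: a graded screen, CNNs on all five splits, pooled test
    predictions; grit and per-well AP from the feature-space profiles.
    Per injected level the mean grit, classification accuracy and mean AP
    are pooled over seeds; the returned Spearman coefficients measure how
    accuracy and AP increase with the levels' mean grit, and how grit and
    AP increase with the injected level itself.  The ten-equal-count-bin
    accuracy curve is returned alongside.
    """
    pred_frames, level_frames = [], []
    for seed in seeds:
        cfg = study_screen_config(seed, effect_size=0.75, graded=True)
        truth = cfg.effect_size_by_compound
        dataset = build_image_dataset(cfg, modality)
        preds = pooled_test_predictions(
            cfg, dataset, split_seed=seed + 1, train_seed=seed + 2,
            epochs=epochs, modality=modality)
        grit_scores, ap_table = control_well_grit_and_map(cfg)
        g = grit_scores[np.isfinite(grit_scores.grit)].copy()
        g["level"] = g.compound_id.map(truth)
        joined = preds.merge(g[["plate_id", "well", "grit", "level"]],
                             on=["plate_id", "well"])
        joined["correct"] = joined.moa_label == joined.pred_label
        pred_frames.append(joined)
        ap = ap_table.merge(g[["plate_id", "well", "grit", "level"]],
                            on=["plate_id", "well"])
        level_frames.append(ap)
    preds = pd.concat(pred_frames, ignore_index=True)
    aps = pd.concat(level_frames, ignore_index=True)

    by_level = preds.groupby("level").agg(
        mean_grit=("grit", "mean"), accuracy=("correct", "mean"))
    ap_by_level = aps.groupby("level").agg(
        mean_grit=("grit", "mean"), mean_ap=("average_precision", "mean"))
    curve = profiling.bin_accuracy_by_grit(
        preds.correct.to_numpy(), preds.grit.to_numpy(), n_bins=10)
    ap_curve = profiling.bin_accuracy_by_grit(
        aps.average_precision.to_numpy(), aps.grit.to_numpy(),
        n_bins=10).rename(columns={"accuracy": "mean_ap"})
    return {
        "by_level": by_level,
        "ap_by_level": ap_by_level,
        "bin_curve": curve,
        "ap_bin_curve": ap_curve,
        "rho_accuracy_vs_grit": float(spearmanr(
            by_level.mean_grit, by_level.accuracy).statistic),
        "rho_map_vs_grit": float(spearmanr(
            ap_by_level.mean_grit, ap_by_level.mean_ap).statistic),
        "rho_grit_vs_level": float(spearmanr(
            by_level.index, by_level.mean_grit).statistic),
        "rho_map_vs_level": float(spearmanr(
            ap_by_level.index, ap_by_level.mean_ap).statistic),
        "rho_accuracy_vs_grit_bins": float(spearmanr(
            curve.mean_grit, curve.accuracy).statistic),
        "rho_map_vs_grit_bins": float(spearmanr(
            ap_curve.mean_grit, ap_curve.mean_ap).statistic),
        "pooled_macro_f1": macro_f1(preds),
    }


def macro_f1_permutation_band(records: pd.DataFrame, n_perm: int,
                              rng: np.random.Generator) -> np.ndarray:
    """Null macro-F1 distribution: predicted labels shuffled across sites."""
    out = np.empty(n_perm)
    shuffled = records.copy()
    preds = records.pred_label.to_numpy()
    for i in range(n_perm):
        shuffled["pred_label"] = rng.permutation(preds)
        out[i] = macro_f1(shuffled)
    return out


def map_permutation_null(profiles: pd.DataFrame, feature_cols: list[str],
                         n_perm: int, rng: np.random.Generator,
                         label_key: str = "moa_label") -> np.ndarray:
    """Null mAP distribution under label shuffling (rankings precomputed)."""
    sub = profiles[profiles[label_key] != DMSO_LABEL].reset_index(drop=True)
    x = sub[feature_cols].to_numpy(dtype=np.float64)
    xn = x / np.linalg.norm(x, axis=1, keepdims=True)
    sim = xn @ xn.T
    n = len(sub)
    rankings = np.empty((n, n - 1), dtype=int)
    for i in range(n):
        others = np.delete(np.arange(n), i)
        rankings[i] = others[np.argsort(-sim[i, others], kind="stable")]
    labels = sub[label_key].to_numpy()
    out = np.empty(n_perm)
    for p in range(n_perm):
        perm = rng.permutation(labels)
        aps = np.empty(n)
        for i in range(n):
            hits = perm[rankings[i]] == perm[i]
            aps[i] = profiling.average_precision_from_ranking(hits)
        out[p] = aps.mean()
    return out


def chance_control(seed: int, epochs: int = 6, n_perm: int = 200,
                   modality: str = "FL") -> dict:
    """Zero-effect negative control: classification and matching at chance."""
    cfg = study_screen_config(seed, effect_size=0.0)
    dataset = build_image_dataset(cfg, modality)
    platemap = generate_layout(cfg)
    assignment = make_splits(platemap, n_splits=5,
                             seed=seed + 1).assignments[0]
    mc = study_model_config(cfg, modality, seed=seed + 2, epochs=epochs)
    model = train_classifier(dataset, assignment, mc, cfg.class_labels)
    meta = dataset.meta.assign(_row=np.arange(len(dataset.meta)))
    test = partition_sites(meta, assignment, "test")
    preds = predict(model, dataset.images[test._row.to_numpy()],
                    test.drop(columns="_row"))
    f1 = macro_f1(preds)
    rng = np.random.default_rng([seed, 31])
    f1_null = macro_f1_permutation_band(preds, n_perm, rng)

    table = generate_feature_table(cfg)
    fcols = feature_columns(table)
    wells = profiling.aggregate_sites_to_wells(table, fcols)
    ctrl = wells[wells.compound_id == DMSO_LABEL][fcols].to_numpy()
    sphered = profiling.fit_sphering(ctrl, 0.1).apply_frame(wells, fcols)
    map_obs, _ = profiling.mean_average_precision(sphered, fcols)
    map_null = map_permutation_null(sphered, fcols, n_perm, rng)
    return {
        "macro_f1": f1,
        "accuracy": float((preds.moa_label == preds.pred_label).mean()),
        "chance_rate": 1.0 / len(cfg.class_labels),
        "macro_f1_null_mean": float(f1_null.mean()),
        "macro_f1_null_sd": float(f1_null.std()),
        "map": map_obs,
        "map_null_mean": float(map_null.mean()),
        "map_null_sd": float(map_null.std()),
        "map_z": float((map_obs - map_null.mean()) / map_null.std()),
    }


def sphering_diagnostics(seed: int, lambda_reg: float = 1e-3,
                         d: int = 20, wells_per_plate_factor: int = 50
                         ) -> dict:
    """Plate-effect suppression by sphering on control profiles.

    Ten plates of control wells with pronounced injected plate offsets
    (n = 50 * d profiles); reports the plate-cluster silhouette before and
    after the transform and the Frobenius distance of the transformed
    control covariance from identity.
    """
    n_plates = 10
    dmso_per_plate = wells_per_plate_factor * d // n_plates
    cfg = ScreenConfig(
        n_plates=n_plates, wells_per_plate=dmso_per_plate + 3,
        sites_per_well=1, moa_compound_counts={"X": 5},
        dmso_wells_per_plate=dmso_per_plate, technical_reps=1,
        biological_rep_plates=1, n_features=d, plate_offset_sd=2.0,
        seed=seed)
    table = generate_feature_table(cfg)
    fcols = feature_columns(table)
    wells = profiling.aggregate_sites_to_wells(table, fcols)
    ctrl = wells[wells.compound_id == DMSO_LABEL]
    x = ctrl[fcols].to_numpy()
    plates = ctrl.plate_id.to_numpy()
    before = float(silhouette_score(x, plates))
    transform = profiling.fit_sphering(x, lambda_reg)
    xt = transform(x)
    after = float(silhouette_score(xt, plates))
    frob = float(np.linalg.norm(np.cov(xt, rowvar=False, ddof=1)
                                - np.eye(d)))
    return {
        "silhouette_before": before,
        "silhouette_after": after,
        "reduction": 1.0 - after / before,
        "cov_frobenius": frob,
        "frobenius_bound": 0.1 * d,
        "n": x.shape[0], "d": d,
    }
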