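"""Synthetic high-content screen generator.

Emulates the plate, replicate and phenotype structure of a 384-well
compound screen so that every downstream stage (normalization, splitting,
classification, grit, sphering, matching) can be exercised without any
external data.  Three artefacts are produced:

* a plate map (:func:`generate_layout`) placing every compound in
  ``technical_reps`` wells on each of ``biological_rep_plates`` plates, with
  replicate wells at different coordinates on the biological-replicate
  plates, plus DMSO control wells on every plate;
* rendered site images (:func:`render_site`): randomly placed Gaussian-blob
  "cells" whose per-channel brightness is modulated by an MoA-specific
  direction vector scaled by the compound's effect size, on top of per-plate
  gain/offset batch effects, a smooth low-frequency illumination field for
  brightfield, and pixel noise;
* per-site feature tables (:func:`generate_feature_table`): a Gaussian
  class-mean + compound-offset + plate-offset + noise model standing in for
  engineered morphology features.

Every nuisance parameter the generator injects (plate gains/offsets,
per-compound effect sizes, the illumination field) is recoverable through
:func:`ground_truth` and :func:`illumination_field`, so recovery tests can
assert against the exact injected values.  All draws are keyed on
``(config.seed, stream, entity indices)`` which makes the generator
bit-reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DMSO_LABEL, ScreenConfig

# Independent seed streams, so layout, phenotype parameters, plate effects
# and per-site rendering can be varied independently.
_STREAM_LAYOUT = 1
_STREAM_PHENO = 2
_STREAM_PLATE = 3
_STREAM_RENDER = 4
_STREAM_FEATURES = 5
_STREAM_ILLUM = 6


@dataclass
class SiteImage:
    """One imaging site: a (channels, H, W) stack plus its provenance."""

    pixels: np.ndarray
    modality: str
    plate_id: str
    well: str
    site_index: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be (channels, H, W)")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if self.modality not in ("BF", "FL"):
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]


class LayoutCapacityError(ValueError):
    """A plate cannot hold the wells the configuration requires."""


# ---------------------------------------------------------------------------
# Plate layout


def plate_shape(wells_per_plate: int) -> tuple[int, int]:
    """(rows, cols) of the densest at-most-square grid, e.g. 384 -> (16, 24)."""
    r = int(np.sqrt(wells_per_plate))
    while r > 1 and wells_per_plate % r:
        r -= 1
    return r, wells_per_plate // r


def well_name(row: int, col: int) -> str:
    letters = ""
    r = row
    while True:
        letters = chr(ord("A") + r % 26) + letters
        r = r // 26 - 1
        if r < 0:
            break
    return f"{letters}{col + 1:02d}"


def generate_layout(config: ScreenConfig) -> pd.DataFrame:
    """Build the plate map.

    Compounds are stratified per MoA across plate groups (each group holds
    the ``biological_rep_plates`` plates of one biological replicate set) and
    placed at seeded random free wells, re-drawing so that a compound's
    technical-replicate wells never reuse a coordinate across the plates of
    its group.

    Returns a DataFrame with columns ``plate_id, well, well_row, well_col,
    compound_id, moa_label, biological_rep_index, technical_rep_index``.
    """
    rng = np.random.default_rng([config.seed, _STREAM_LAYOUT])
    n_rows, n_cols = plate_shape(config.wells_per_plate)
    n_groups = config.n_plates // config.biological_rep_plates
    plate_ids = [f"P{i + 1:02d}" for i in range(config.n_plates)]
    groups = [
        plate_ids[g * config.biological_rep_plates:(g + 1) * config.biological_rep_plates]
        for g in range(n_groups)
    ]

    # Stratified round-robin assignment of compounds to plate groups.
    group_compounds: list[list[tuple[str, str]]] = [[] for _ in range(n_groups)]
    cursor = 0
    for moa in sorted(config.moa_compound_counts):
        n = config.moa_compound_counts[moa]
        ids = [f"{moa}_{k + 1:02d}" for k in range(n)]
        rng.shuffle(ids)
        for cid in ids:
            group_compounds[cursor % n_groups].append((cid, moa))
            cursor += 1

    capacity = config.wells_per_plate - config.dmso_wells_per_plate
    for gi, comps in enumerate(group_compounds):
        need = len(comps) * config.technical_reps
        if need > capacity:
            raise LayoutCapacityError(
                f"plate {groups[gi][0]} needs {need} compound wells but only "
                f"{capacity} are free (deficit {need - capacity})"
            )

    all_wells = [(r, c) for r in range(n_rows) for c in range(n_cols)]
    records: list[dict] = []
    for gi, (plates, comps) in enumerate(zip(groups, group_compounds)):
        used_by_compound: dict[str, set[tuple[int, int]]] = {c: set() for c, _ in comps}
        for bio_idx, plate in enumerate(plates):
            free = list(all_wells)
            rng.shuffle(free)
            dmso_wells = [free.pop() for _ in range(config.dmso_wells_per_plate)]
            for t, (r, c) in enumerate(sorted(dmso_wells)):
                records.append(dict(
                    plate_id=plate, well=well_name(r, c), well_row=r, well_col=c,
                    compound_id=DMSO_LABEL, moa_label=DMSO_LABEL,
                    biological_rep_index=bio_idx, technical_rep_index=t,
                ))
            for cid, moa in comps:
                taken = used_by_compound[cid]
                chosen: list[tuple[int, int]] = []
                skipped: list[tuple[int, int]] = []
                while len(chosen) < config.technical_reps:
                    if not free:
                        raise LayoutCapacityError(
                            f"plate {plate}: cannot place compound {cid} at "
                            f"coordinates unused by its biological replicates"
                        )
                    w = free.pop()
                    (skipped if w in taken else chosen).append(w)
                free.extend(skipped)
                taken.update(chosen)
                for t, (r, c) in enumerate(chosen):
                    records.append(dict(
                        plate_id=plate, well=well_name(r, c), well_row=r, well_col=c,
                        compound_id=cid, moa_label=moa,
                        biological_rep_index=bio_idx, technical_rep_index=t,
                    ))
    platemap = pd.DataFrame.from_records(records)
    return platemap.sort_values(
        ["plate_id", "well_row", "well_col"], ignore_index=True
    )


def site_table(platemap: pd.DataFrame, sites_per_well: int) -> pd.DataFrame:
    """Expand a plate map to one row per imaging site."""
    reps = platemap.loc[platemap.index.repeat(sites_per_well)].reset_index(drop=True)
    reps["site_index"] = np.tile(np.arange(sites_per_well), len(platemap))
    return reps


# ---------------------------------------------------------------------------
# Injected parameters (the ground truth of the screen)


def _unit(rng: np.random.Generator, d: int) -> np.ndarray:
    v = rng.standard_normal(d)
    return v / np.linalg.norm(v)


_pheno_cache: dict[tuple, tuple[dict, dict]] = {}


def _phenotype_directions(config: ScreenConfig, d: int, stream_tag: int
                          ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-MoA unit directions and per-compound directions in a d-dim space.

    Returns per-MoA unit directions and per-compound unit offset vectors;
    :func:`phenotype_vector` combines them so compounds within an MoA are
    similar but distinguishable.
    """
    key = (config.seed, config.compound_offset_frac, d, stream_tag,
           tuple(sorted(config.moa_compound_counts.items())))
    if key in _pheno_cache:
        return _pheno_cache[key]
    moa_dirs: dict[str, np.ndarray] = {}
    cpd_dirs: dict[str, np.ndarray] = {}
    for mi, moa in enumerate(sorted(config.moa_compound_counts)):
        mrng = np.random.default_rng([config.seed, _STREAM_PHENO, stream_tag, mi])
        moa_dirs[moa] = _unit(mrng, d)
        for k in range(config.moa_compound_counts[moa]):
            crng = np.random.default_rng(
                [config.seed, _STREAM_PHENO, stream_tag, mi, k + 1])
            cpd_dirs[f"{moa}_{k + 1:02d}"] = _unit(crng, d)
    _pheno_cache[key] = (moa_dirs, cpd_dirs)
    return moa_dirs, cpd_dirs


def phenotype_vector(config: ScreenConfig, compound_id: str,
                     d: int) -> np.ndarray:
    """The injected mean phenotype of one compound in a d-dim space.

    ``effect * moa_direction + base_effect * offset_frac * compound_unit``:
    the MoA component scales with the compound's (possibly graded) effect
    size while the compound-identity offset keeps a fixed magnitude, so
    strong compounds converge toward their MoA axis instead of drifting
    away from it.  DMSO maps to the origin.
    """
    if compound_id == DMSO_LABEL:
        return np.zeros(d)
    moa_dirs, cpd_units = _phenotype_directions(config, d, stream_tag=d)
    moa = compound_id.rsplit("_", 1)[0]
    return (_compound_effect(config, compound_id) * moa_dirs[moa]
            + config.effect_size * config.compound_offset_frac
            * cpd_units[compound_id])


def _compound_effect(config: ScreenConfig, compound_id: str) -> float:
    scale = 1.0
    if config.effect_size_by_compound is not None:
        scale = config.effect_size_by_compound.get(compound_id, 1.0)
    return 0.0 if compound_id == DMSO_LABEL else config.effect_size * scale


def _plate_index(plate_id: str) -> int:
    return int(plate_id.lstrip("P"))


_plate_cache: dict[tuple, pd.DataFrame] = {}


def plate_effects(config: ScreenConfig, modality: str) -> pd.DataFrame:
    """Injected per-(plate, channel) multiplicative gain and additive offset."""
    key = (config.seed, modality, config.n_plates, config.channels(modality),
           config.plate_gain_sd, config.plate_offset_sd)
    if key in _plate_cache:
        return _plate_cache[key]
    n_ch = config.channels(modality)
    rows = []
    for p in range(1, config.n_plates + 1):
        rng = np.random.default_rng(
            [config.seed, _STREAM_PLATE, 0 if modality == "BF" else 1, p])
        gains = 1.0 + config.plate_gain_sd * rng.standard_normal(n_ch)
        offsets = config.plate_offset_sd * 0.1 * rng.standard_normal(n_ch)
        for c in range(n_ch):
            rows.append(dict(plate_id=f"P{p:02d}", modality=modality,
                             channel=c, gain=gains[c], offset=offsets[c]))
    _plate_cache[key] = pd.DataFrame(rows)
    return _plate_cache[key]


def feature_plate_offsets(config: ScreenConfig) -> np.ndarray:
    """Injected per-plate offset vectors in feature space, (n_plates, d)."""
    out = np.empty((config.n_plates, config.n_features))
    for p in range(1, config.n_plates + 1):
        rng = np.random.default_rng([config.seed, _STREAM_PLATE, 2, p])
        out[p - 1] = config.plate_offset_sd * rng.standard_normal(config.n_features)
    return out


def illumination_field(config: ScreenConfig, plate_id: str) -> np.ndarray:
    """The smooth BF illumination inhomogeneity injected on one plate.

    A low-order cosine surface in [0, 1], fixed per plate (an optical
    property of the acquisition, shared by all wells and sites).
    """
    n = config.image_size
    rng = np.random.default_rng([config.seed, _STREAM_ILLUM, _plate_index(plate_id)])
    fx, fy = rng.uniform(0.5, 1.2, size=2)
    px, py = rng.uniform(0, 2 * np.pi, size=2)
    x = np.arange(n) / n
    field = np.cos(2 * np.pi * fx * x[None, :] + px) * np.cos(
        2 * np.pi * fy * x[:, None] + py)
    return (field + 1.0) / 2.0


def ground_truth(config: ScreenConfig) -> dict[str, pd.DataFrame]:
    """All injected nuisance/effect parameters, for recovery tests."""
    comp_rows = []
    for moa in sorted(config.moa_compound_counts):
        for k in range(config.moa_compound_counts[moa]):
            cid = f"{moa}_{k + 1:02d}"
            comp_rows.append(dict(compound_id=cid, moa_label=moa,
                                  effect_size=_compound_effect(config, cid)))
    offsets = feature_plate_offsets(config)
    return {
        "compound_effects": pd.DataFrame(comp_rows),
        "plate_effects_bf": plate_effects(config, "BF"),
        "plate_effects_fl": plate_effects(config, "FL"),
        "feature_plate_offsets": pd.DataFrame(
            offsets, index=[f"P{p + 1:02d}" for p in range(config.n_plates)]
        ),
    }


# ---------------------------------------------------------------------------
# Image rendering


def _cell_mask(rng: np.random.Generator, n: int, radius_mult: float = 1.0,
               density_mult: float = 1.0) -> np.ndarray:
    """Random Gaussian-blob cell texture on an n x n grid, values >= 0."""
    density = 20 * (n / 96.0) ** 2 * density_mult
    n_cells = max(1, rng.poisson(density))
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float64)
    mask = np.zeros((n, n))
    cx = rng.uniform(0, n, n_cells)
    cy = rng.uniform(0, n, n_cells)
    radius = radius_mult * rng.uniform(0.03 * n, 0.07 * n, n_cells)
    amp = rng.uniform(0.6, 1.0, n_cells)
    for k in range(n_cells):
        mask += amp[k] * np.exp(
            -((xx - cx[k]) ** 2 + (yy - cy[k]) ** 2) / (2 * radius[k] ** 2))
    return mask


def render_site(record, config: ScreenConfig, modality: str) -> SiteImage:
    """Render one site image for a plate-map record.

    The compound's phenotype lives in ``n_channels + 2`` dimensions: the
    first ``n_channels`` entries modulate per-channel cell brightness
    (``exp(0.25 * v_c)``), the last two modulate cell radius and cell
    density (``exp(0.15 * v)``) — MoAs alter morphology, not only staining
    intensity.  On top of the resulting cell texture come per-plate
    gain/offset, the per-plate smooth illumination field (BF only), and
    Gaussian pixel noise.  DMSO renders with zero effect.  Deterministic
    per ``(seed, plate, well, site)``.
    """
    n_ch = config.channels(modality)
    n = config.image_size
    plate_id = record["plate_id"]
    site_idx = int(record.get("site_index", 0))
    rng = np.random.default_rng([
        config.seed, _STREAM_RENDER, 0 if modality == "BF" else 1,
        _plate_index(plate_id), int(record["well_row"]),
        int(record["well_col"]), site_idx,
    ])
    compound_id = record["compound_id"]
    v = phenotype_vector(config, compound_id, n_ch + 2)
    mask = _cell_mask(rng, n, radius_mult=float(np.exp(0.15 * v[n_ch])),
                      density_mult=float(np.exp(0.15 * v[n_ch + 1])))
    base = np.linspace(0.6, 1.0, n_ch)
    mult = np.exp(0.25 * v[:n_ch])

    img = 0.2 + base[:, None, None] * mult[:, None, None] * mask[None, :, :]

    pe = plate_effects(config, modality)
    pe = pe[pe.plate_id == plate_id].sort_values("channel")
    img = pe.gain.to_numpy()[:, None, None] * img \
        + pe.offset.to_numpy()[:, None, None]

    if modality == "BF" and config.bf_illumination_amp > 0:
        img = img + config.bf_illumination_amp * illumination_field(
            config, plate_id)[None, :, :]

    if config.noise_sd > 0:
        img = img + config.noise_sd * rng.standard_normal(img.shape)
    np.clip(img, 0.0, None, out=img)
    return SiteImage(pixels=img, modality=modality, plate_id=plate_id,
                     well=record["well"], site_index=site_idx)


def render_screen(platemap: pd.DataFrame, config: ScreenConfig,
                  modality: str) -> list[SiteImage]:
    """Render every site of a plate map (convenience for small screens)."""
    sites = site_table(platemap, config.sites_per_well)
    return [render_site(rec, config, modality) for rec in
            sites.to_dict("records")]


# ---------------------------------------------------------------------------
# Feature tables


def generate_feature_table(config: ScreenConfig, seed: int | None = None
                           ) -> pd.DataFrame:
    """Per-site feature vectors from the Gaussian phenotype model.

    ``x_site = effect * v_compound + plate_offset + noise`` with
    ``v_compound`` a per-compound direction around its MoA mean (DMSO has
    zero mean).  Metadata columns come from the generated plate map.
    """
    if seed is not None:
        config = ScreenConfig.from_dict({**config.to_dict(), "seed": seed})
    platemap = generate_layout(config)
    sites = site_table(platemap, config.sites_per_well)
    d = config.n_features
    offsets = feature_plate_offsets(config)

    means = np.zeros((len(sites), d))
    for cid, idx in sites.groupby("compound_id").indices.items():
        if cid == DMSO_LABEL:
            continue
        means[idx] = phenotype_vector(config, cid, d)
    plate_idx = sites.plate_id.map(_plate_index).to_numpy() - 1
    means += offsets[plate_idx]

    rng = np.random.default_rng([config.seed, _STREAM_FEATURES])
    x = means + config.feature_noise_sd * rng.standard_normal(means.shape)
    feats = pd.DataFrame(x, columns=[f"f{j}" for j in range(d)])
    meta = sites[["plate_id", "well", "well_row", "well_col", "compound_id",
                  "moa_label", "biological_rep_index", "technical_rep_index",
                  "site_index"]].reset_index(drop=True)
    return pd.concat([meta, feats], axis=1)


FEATURE_COLUMN_PREFIX = "f"


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the numeric feature columns of a generated/derived table."""
    return [c for c in table.columns
            if c.startswith(FEATURE_COLUMN_PREFIX) and c[1:].isdigit()]
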