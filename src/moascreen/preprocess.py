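"""Background correction and image normalization.

Two normalization strategies are compared throughout the pipeline:

* **DMSO plate-level**: each channel is standardized by the pooled pixel
  mean/sd of the plate's DMSO control wells, which mitigates plate effects
  while preserving relative intensity between treatments on a plate;
* **site-level**: each image channel is standardized by its own mean/sd,
  which removes per-image gain entirely — and with it all relative
  intensity information.

Brightfield images additionally carry a smooth illumination inhomogeneity;
it is removed before any statistics are computed by subtracting a heavily
Gaussian-smoothed copy of each z-plane (the classic unsharp background
estimate).  Fluorescence images bypass this correction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .synthetic import SiteImage

#: Default smoothing kernel, as a fraction of the image side (101 px on a
#: 2160 px acquisition).
DEFAULT_KERNEL_FRAC = 101.0 / 2160.0

_SIGMA_MIN = 1e-8


@dataclass
class PlateChannelStats:
    """Pooled per-channel DMSO pixel statistics of one plate."""

    plate_id: str
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.sd = np.asarray(self.sd, dtype=np.float64)
        if self.mean.shape != self.sd.shape or self.mean.ndim != 1:
            raise ValueError("mean and sd must be 1-D arrays of equal length")
        if np.any(self.sd < 0):
            raise ValueError("sd must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "plate_id": self.plate_id,
            "channel": np.arange(self.mean.size),
            "mean": self.mean,
            "sd": self.sd,
        })

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PlateChannelStats":
        frame = frame.sort_values("channel")
        (plate_id,) = frame.plate_id.unique()
        return cls(plate_id=plate_id, mean=frame["mean"].to_numpy(),
                   sd=frame["sd"].to_numpy())


def correct_background(image: SiteImage,
                       kernel_frac: float = DEFAULT_KERNEL_FRAC) -> SiteImage:
    """Subtract the Gaussian-smoothed background from each BF z-plane.

    The smoothing kernel side is ``kernel_frac * image_side`` pixels with
    sigma = side / 4 and reflective boundaries.  Constant planes map to
    zero, and additive offsets cancel, so the output mean per plane is ~0
    up to boundary effects.
    """
    if image.modality != "BF":
        raise ValueError("background correction applies to BF images only; "
                         "FL images bypass it")
    if not 0 < kernel_frac < 1:
        raise ValueError("kernel_frac must be in (0, 1)")
    side = image.pixels.shape[-1]
    kernel_side = kernel_frac * side
    if kernel_side > side:
        raise ValueError("smoothing kernel larger than the image")
    sigma = kernel_side / 4.0
    background = gaussian_filter(image.pixels, sigma=(0, sigma, sigma),
                                 mode="reflect")
    return replace(image, pixels=image.pixels - background)


def compute_dmso_stats(images: Iterable[SiteImage]) -> PlateChannelStats:
    """Pool pixel mean/sd per channel over all DMSO sites of one plate.

    BF inputs are expected background-corrected.  Raises for an empty site
    list, for sites from several plates, or for a degenerate (constant)
    channel.
    """
    images = list(images)
    if not images:
        raise ValueError("no DMSO sites supplied for this plate")
    plates = {im.plate_id for im in images}
    if len(plates) != 1:
        raise ValueError(f"DMSO sites span several plates: {sorted(plates)}")
    pixels = np.concatenate(
        [im.pixels.reshape(im.n_channels, -1) for im in images], axis=1)
    mean = pixels.mean(axis=1)
    sd = pixels.std(axis=1)
    if np.any(sd < _SIGMA_MIN):
        bad = np.flatnonzero(sd < _SIGMA_MIN).tolist()
        raise ValueError(
            f"degenerate plate {images[0].plate_id}: constant DMSO channel(s) {bad}")
    return PlateChannelStats(plate_id=images[0].plate_id, mean=mean, sd=sd)


def normalize_dmso_plate(image: SiteImage,
                         stats: PlateChannelStats) -> SiteImage:
    """Standardize each channel by the plate's pooled DMSO mean/sd."""
    if image.plate_id != stats.plate_id:
        raise ValueError(
            f"image plate {image.plate_id!r} does not match stats plate "
            f"{stats.plate_id!r}")
    if image.n_channels != stats.mean.size:
        raise ValueError("channel count mismatch between image and stats")
    pixels = (image.pixels - stats.mean[:, None, None]) / stats.sd[:, None, None]
    return replace(image, pixels=pixels)


def normalize_site(image: SiteImage) -> SiteImage:
    """Standardize each channel by its own pixel mean/sd.

    Idempotent, and maps gain-differing copies of a scene to identical
    outputs (all relative intensity information is discarded).
    """
    flat = image.pixels.reshape(image.n_channels, -1)
    mean = flat.mean(axis=1)
    sd = flat.std(axis=1)
    if np.any(sd < _SIGMA_MIN):
        bad = np.flatnonzero(sd < _SIGMA_MIN).tolist()
        raise ValueError(f"constant channel(s) {bad} cannot be site-normalized")
    pixels = (image.pixels - mean[:, None, None]) / sd[:, None, None]
    return replace(image, pixels=pixels)


def normalize_feature_table(table: pd.DataFrame,
                            feature_cols: list[str],
                            dmso_label: str = "DMSO") -> pd.DataFrame:
    """DMSO plate-level standardization of a per-site feature table.

    Mirrors the image-side DMSO normalization for engineered features: each
    feature is standardized per plate by the mean/sd of that plate's DMSO
    sites.
    """
    out = table.copy()
    for plate, idx in table.groupby("plate_id").indices.items():
        sub = table.iloc[idx]
        ctrl = sub[sub.compound_id == dmso_label][feature_cols]
        if ctrl.empty:
            raise ValueError(f"plate {plate} has no DMSO sites to normalize by")
        mu = ctrl.mean(axis=0)
        sd = ctrl.std(axis=0, ddof=0)
        if (sd < _SIGMA_MIN).any():
            raise ValueError(f"degenerate DMSO feature on plate {plate}")
        out.iloc[idx, [out.columns.get_loc(c) for c in feature_cols]] = \
            ((sub[feature_cols] - mu) / sd).to_numpy()
    return out
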