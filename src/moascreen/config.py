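"""Configuration objects for the synthetic screen and the classifiers.

The defaults of :class:`ScreenConfig` encode the layout of the assay the
pipeline emulates: 18 microwell plates in 384-well format, ten mechanism-of-
action (MoA) classes plus the DMSO solvent control, 231 compounds replicated
six times (three technical replicates on a plate, on each of two biological
replicate plates), and five imaging sites per well.  Fluorescence (FL) sites
carry five stain channels; brightfield (BF) sites carry six z-planes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import yaml

#: Compound counts of the ten MoA classes in the emulated assay.
DEFAULT_MOA_COMPOUND_COUNTS: dict[str, int] = {
    "ATPase-i": 18,
    "AuroraK-i": 20,
    "HDAC-i": 33,
    "HSP-i": 24,
    "JAK-i": 21,
    "PARP-i": 21,
    "Prot.Synth.-i": 23,
    "Ret.Rec.Ag": 19,
    "Topo.-i": 32,
    "Tub.Pol.-i": 20,
}

#: Label used for the solvent-control class throughout the package.
DMSO_LABEL = "DMSO"


@dataclass
class ScreenConfig:
    """Parameters of one synthetic screen.

    ``effect_size`` is the phenotype strength: it scales the MoA-specific
    channel modulation in rendered images and the class-mean magnitude in
    generated feature tables.  ``effect_size_by_compound`` optionally grades
    it per compound (values multiply ``effect_size``).
    """

    n_plates: int = 18
    wells_per_plate: int = 384
    sites_per_well: int = 5
    moa_compound_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_MOA_COMPOUND_COUNTS)
    )
    dmso_wells_per_plate: int = 8
    technical_reps: int = 3
    biological_rep_plates: int = 2
    image_size: int = 96
    fl_channels: int = 5
    bf_planes: int = 6
    effect_size: float = 3.0
    effect_size_by_compound: dict[str, float] | None = None
    plate_gain_sd: float = 0.1
    plate_offset_sd: float = 0.5
    bf_illumination_amp: float = 0.3
    noise_sd: float = 0.1
    n_features: int = 64
    feature_noise_sd: float = 1.0
    compound_offset_frac: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_plates",
            "wells_per_plate",
            "sites_per_well",
            "dmso_wells_per_plate",
            "technical_reps",
            "biological_rep_plates",
            "image_size",
            "fl_channels",
            "bf_planes",
            "n_features",
        ):
            value = getattr(self, name)
            if not isinstance(value, int) or value < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {value!r}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.effect_size_by_compound is not None and any(
            v < 0 for v in self.effect_size_by_compound.values()
        ):
            raise ValueError("per-compound effect sizes must be >= 0")
        for name in ("plate_gain_sd", "plate_offset_sd", "bf_illumination_amp",
                     "noise_sd", "feature_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.moa_compound_counts:
            raise ValueError("moa_compound_counts must not be empty")
        if any(n < 1 for n in self.moa_compound_counts.values()):
            raise ValueError("every MoA needs at least one compound")
        if DMSO_LABEL in self.moa_compound_counts:
            raise ValueError(f"{DMSO_LABEL!r} is reserved for the control class")
        bad_names = [m for m in self.moa_compound_counts if "_" in m]
        if bad_names:
            # compound ids are "<moa>_<k>"; underscores would break parsing
            raise ValueError(f"MoA names must not contain '_': {bad_names}")
        if self.n_plates % self.biological_rep_plates != 0:
            raise ValueError(
                "n_plates must be a multiple of biological_rep_plates "
                f"({self.n_plates} % {self.biological_rep_plates} != 0)"
            )

    @property
    def n_compounds(self) -> int:
        return sum(self.moa_compound_counts.values())

    @property
    def moa_labels(self) -> list[str]:
        return list(self.moa_compound_counts)

    @property
    def class_labels(self) -> list[str]:
        """The classification vocabulary: the MoAs plus the control class."""
        return self.moa_labels + [DMSO_LABEL]

    def channels(self, modality: str) -> int:
        if modality == "FL":
            return self.fl_channels
        if modality == "BF":
            return self.bf_planes
        raise ValueError(f"unknown modality {modality!r}; expected 'BF' or 'FL'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "ScreenConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown ScreenConfig fields: {sorted(unknown)}")
        return cls(**dict(data))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class ModelConfig:
    """Hyper-parameters for the image CNN and the feature-table MLP.

    ``conv_widths`` sets the channel widths of the convolutional stages of the
    desk-scale backbone; the penultimate feature dimension equals the last
    width for the CNN and ``hidden_dim`` for the MLP.
    """

    backbone: str = "smallcnn"
    input_channels: int = 5
    n_classes: int = 11
    conv_widths: tuple[int, ...] = (16, 32, 64)
    hidden_dim: int = 512
    lr: float = 3e-3
    epochs: int = 15
    batch_size: int = 32
    patience: int = 5
    augment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.input_channels < 1:
            raise ValueError("input_channels must be >= 1")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        self.conv_widths = tuple(int(w) for w in self.conv_widths)
        if not self.conv_widths:
            raise ValueError("conv_widths must not be empty")

    @property
    def feature_dim(self) -> int:
        return self.conv_widths[-1]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conv_widths"] = list(self.conv_widths)
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "ModelConfig":
        data = dict(data)
        if "conv_widths" in data:
            data["conv_widths"] = tuple(data["conv_widths"])
        return cls(**data)
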