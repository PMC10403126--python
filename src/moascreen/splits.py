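"""Compound-level stratified train/validation/test splits.

The unit of splitting is the compound, never the image: all wells and
sites of a compound follow it into its partition, so no test compound is
ever visible during training.  Five splits are built whose test sets are
disjoint and together cover every compound; within each split the non-test
compounds are shuffled and assigned 80/20 to train/validation, stratified
per MoA.  DMSO control wells are assigned once per plate — five wells to
train, one to validation, two to test — and the same physical wells are
reused by every split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DMSO_LABEL

DMSO_WELLS_TRAIN = 5
DMSO_WELLS_VAL = 1
DMSO_WELLS_TEST = 2

PARTITIONS = ("train", "val", "test")


@dataclass
class SplitAssignment:
    """One split: compound -> partition, plus the fixed DMSO well lists."""

    split_index: int
    compound_partition: dict[str, str]
    dmso_wells: dict[str, dict[str, list[str]]]  # plate -> partition -> wells

    def compounds(self, partition: str) -> list[str]:
        if partition not in PARTITIONS:
            raise ValueError(f"unknown partition {partition!r}")
        return sorted(c for c, p in self.compound_partition.items()
                      if p == partition)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "split_index": self.split_index,
            "compound_id": list(self.compound_partition),
            "partition": list(self.compound_partition.values()),
        })


@dataclass
class SplitSet:
    """The full collection of splits over one plate map."""

    assignments: list[SplitAssignment]
    seed: int = 0

    def __iter__(self):
        return iter(self.assignments)

    def __len__(self) -> int:
        return len(self.assignments)

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([a.to_frame() for a in self.assignments],
                         ignore_index=True)

    def dmso_wells_json(self) -> str:
        return json.dumps(self.assignments[0].dmso_wells, sort_keys=True,
                          indent=2)


def _dmso_assignment(platemap: pd.DataFrame, rng: np.random.Generator,
                     counts: tuple[int, int, int]
                     ) -> dict[str, dict[str, list[str]]]:
    n_train, n_val, n_test = counts
    need = n_train + n_val + n_test
    out: dict[str, dict[str, list[str]]] = {}
    dmso = platemap[platemap.compound_id == DMSO_LABEL]
    for plate, sub in dmso.groupby("plate_id"):
        wells = sorted(sub.well)
        if len(wells) < need:
            raise ValueError(
                f"plate {plate} has {len(wells)} DMSO wells; "
                f"{need} are needed for the {n_train}/{n_val}/{n_test} assignment")
        wells = list(rng.permutation(wells))
        out[str(plate)] = {
            "train": sorted(wells[:n_train]),
            "val": sorted(wells[n_train:n_train + n_val]),
            "test": sorted(wells[n_train + n_val:need]),
        }
    return out


def make_splits(platemap: pd.DataFrame, n_splits: int = 5, seed: int = 0,
                dmso_counts: tuple[int, int, int] = (
                    DMSO_WELLS_TRAIN, DMSO_WELLS_VAL, DMSO_WELLS_TEST),
                test_frac: float = 0.2,
                ) -> SplitSet:
    """Build ``n_splits`` stratified compound-level splits.

    Per MoA with ``n`` compounds, the shuffled compound list is partitioned
    into ``k = round(1/test_frac)`` near-equal chunks (sizes ``n // k`` or
    one more, the remainder distributed round-robin); chunk ``s`` is the
    test set of split ``s``.  With ``n_splits == k`` (the default five at
    20%) the test sets are disjoint and exactly cover every compound.
    Non-test compounds are then shuffled per MoA and split 80/20 into
    train/validation (at least one validation compound per MoA whenever any
    remain).  Deterministic for a fixed seed.
    """
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    k = int(round(1.0 / test_frac))
    if n_splits > k:
        raise ValueError(f"n_splits={n_splits} exceeds 1/test_frac={k} "
                         "disjoint test sets")
    rng = np.random.default_rng([seed, 11])
    compounds = platemap[platemap.compound_id != DMSO_LABEL][
        ["compound_id", "moa_label"]].drop_duplicates()
    by_moa = {moa: sorted(sub.compound_id)
              for moa, sub in compounds.groupby("moa_label")}
    too_small = sorted(m for m, c in by_moa.items() if len(c) < k)
    if too_small:
        raise ValueError(
            f"MoA(s) {too_small} have fewer compounds than the {k} "
            "test chunks required")

    moa_order = list(rng.permutation(sorted(by_moa)))
    test_sets: list[list[tuple[str, str]]] = [[] for _ in range(k)]
    extra_cursor = 0
    for moa in moa_order:
        ids = list(rng.permutation(by_moa[moa]))
        n = len(ids)
        base, rem = divmod(n, k)
        sizes = [base] * k
        for _ in range(rem):
            sizes[extra_cursor % k] += 1
            extra_cursor += 1
        pos = 0
        for s in range(k):
            for cid in ids[pos:pos + sizes[s]]:
                test_sets[s].append((cid, moa))
            pos += sizes[s]

    dmso_wells = _dmso_assignment(platemap, rng, dmso_counts)

    assignments = []
    for s in range(n_splits):
        part: dict[str, str] = {}
        test_ids = {cid for cid, _ in test_sets[s]}
        for cid in test_ids:
            part[cid] = "test"
        for moa in sorted(by_moa):
            rest = [c for c in by_moa[moa] if c not in test_ids]
            rest = list(rng.permutation(rest))
            n_val = min(len(rest), max(1, int(round(0.2 * len(rest))))) \
                if rest else 0
            for cid in rest[:n_val]:
                part[cid] = "val"
            for cid in rest[n_val:]:
                part[cid] = "train"
        assignments.append(SplitAssignment(
            split_index=s + 1, compound_partition=part,
            dmso_wells=dmso_wells))
    return SplitSet(assignments=assignments, seed=seed)


def partition_sites(platemap_or_sites: pd.DataFrame,
                    assignment: SplitAssignment,
                    partition: str) -> pd.DataFrame:
    """Select the plate-map (or site-table) rows visible to one partition.

    Compound rows are selected by the compound assignment; DMSO rows by the
    fixed per-plate DMSO well lists.  This is the only gate through which
    training, validation and test data are drawn, which makes the
    no-leakage guarantee auditable at image level.
    """
    if partition not in PARTITIONS:
        raise ValueError(f"unknown partition {partition!r}")
    df = platemap_or_sites
    wanted = {c for c, p in assignment.compound_partition.items()
              if p == partition}
    is_cpd = df.compound_id.isin(wanted)
    dmso_mask = np.zeros(len(df), dtype=bool)
    dmso_rows = df.compound_id == DMSO_LABEL
    for plate, wells in assignment.dmso_wells.items():
        sel = dmso_rows & (df.plate_id == plate) & df.well.isin(wells[partition])
        dmso_mask |= sel.to_numpy()
    return df[is_cpd | dmso_mask].reset_index(drop=True)
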