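"""Profile-level analyses: grit, sphering, matching, batch diagnostics.

Site-level feature vectors (engineered features or CNN embeddings) are
mean-aggregated into well-level profiles.  On those profiles the module
computes:

* the **grit score** of a replicate profile — its mean correlation to the
  other replicates of the same perturbation, expressed as a z-statistic
  against its correlation distribution to control (DMSO) profiles.  High
  grit marks a strong, reproducible phenotype;
* the accuracy-versus-grit curve: samples sorted by grit and cut into ten
  equal-count bins, reporting each bin's mean grit and accuracy;
* a regularized **ZCA sphering** transform fitted on control profiles,
  ``W = (Sigma_c + lambda * (tr(Sigma_c)/d) * I)^(-1/2)``, which drives the
  control covariance toward identity and thereby suppresses plate effects;
* **mean average precision** for the biological matching task: every
  (non-control) well queries all other wells ranked by cosine similarity,
  a hit being a well sharing its MoA;
* cosine within/across MoA distributions and the plate-by-plate Pearson
  correlation matrix of control features, the two batch-effect diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import DMSO_LABEL

WELL_KEYS = ["plate_id", "well"]


def aggregate_sites_to_wells(features: pd.DataFrame,
                             feature_cols: list[str]) -> pd.DataFrame:
    """Arithmetic mean of site vectors per well, metadata carried along."""
    missing = [k for k in WELL_KEYS if k not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks well keys {missing}")
    meta_cols = [c for c in ("compound_id", "moa_label")
                 if c in features.columns]
    grouped = features.groupby(WELL_KEYS, as_index=False).agg(
        {**{c: "first" for c in meta_cols},
         **{c: "mean" for c in feature_cols}})
    return grouped


# ---------------------------------------------------------------------------
# Grit


@dataclass
class GritResult:
    scores: pd.DataFrame  # well keys + group + grit (NaN where undefined)
    control_label: str


def grit(profiles: pd.DataFrame, feature_cols: list[str],
         group_key: str = "compound_id", control_label: str = DMSO_LABEL,
         control_stats: str = "per_profile") -> GritResult:
    """Replicate-vs-control z-statistic per profile.

    For profile ``i`` of group ``c``: with ``R_i`` its Pearson correlations
    to the other replicates of ``c`` and ``C_i`` its correlations to all
    control profiles, ``grit_i = mean_r((r - mean(C_i)) / sd(C_i))``.

    ``control_stats`` selects where the control moments come from:
    ``"per_profile"`` (default) centers each profile's replicate
    correlations by that profile's own control-correlation distribution;
    ``"pooled"`` uses the moments of all treatment-to-control correlations
    pooled together.  The score is undefined (NaN, with a reason column)
    for singleton groups or zero control-correlation spread.
    """
    if control_stats not in ("per_profile", "pooled"):
        raise ValueError("control_stats must be 'per_profile' or 'pooled'")
    x = profiles[feature_cols].to_numpy(dtype=np.float64)
    # Row-standardize so the Gram matrix is the Pearson correlation matrix.
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xc, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("constant profile: Pearson correlation undefined")
    xn = xc / norms
    corr = xn @ xn.T

    groups = profiles[group_key].to_numpy()
    is_ctrl = groups == control_label
    if is_ctrl.sum() < 2:
        raise ValueError("need at least two control profiles")
    ctrl_idx = np.flatnonzero(is_ctrl)

    pooled_mu = pooled_sd = None
    if control_stats == "pooled":
        block = corr[~is_ctrl][:, ctrl_idx]
        pooled_mu, pooled_sd = float(block.mean()), float(block.std())

    rows = []
    for i in range(len(profiles)):
        rec = {k: profiles.iloc[i][k] for k in WELL_KEYS
               if k in profiles.columns}
        rec[group_key] = groups[i]
        if is_ctrl[i]:
            rec.update(grit=np.nan, reason="control")
            rows.append(rec)
            continue
        mates = np.flatnonzero((groups == groups[i]) & ~is_ctrl)
        mates = mates[mates != i]
        if len(mates) == 0:
            rec.update(grit=np.nan, reason="singleton group")
            rows.append(rec)
            continue
        c_i = corr[i, ctrl_idx]
        mu, sd = ((pooled_mu, pooled_sd) if control_stats == "pooled"
                  else (float(c_i.mean()), float(c_i.std())))
        if sd == 0:
            rec.update(grit=np.nan, reason="zero control spread")
            rows.append(rec)
            continue
        r_i = corr[i, mates]
        rec.update(grit=float(((r_i - mu) / sd).mean()), reason="")
        rows.append(rec)
    return GritResult(scores=pd.DataFrame(rows), control_label=control_label)


def bin_accuracy_by_grit(correct: np.ndarray, grits: np.ndarray,
                         n_bins: int = 10) -> pd.DataFrame:
    """Accuracy per equal-count grit bin.

    Samples are sorted by ascending grit and cut into ``n_bins`` contiguous
    bins of equal count, any remainder going to the lowest bins.  Returns
    one row per bin: ``bin, mean_grit, accuracy, n``.
    """
    correct = np.asarray(correct, dtype=float)
    grits = np.asarray(grits, dtype=float)
    if correct.shape != grits.shape:
        raise ValueError("correct and grits must align")
    n = len(grits)
    if n < n_bins:
        raise ValueError(f"{n} samples cannot fill {n_bins} bins")
    order = np.argsort(grits, kind="stable")
    base, rem = divmod(n, n_bins)
    sizes = [base + (1 if b < rem else 0) for b in range(n_bins)]
    rows, pos = [], 0
    for b, size in enumerate(sizes):
        idx = order[pos:pos + size]
        pos += size
        rows.append(dict(bin=b, mean_grit=float(grits[idx].mean()),
                         accuracy=float(correct[idx].mean()), n=size))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sphering


@dataclass
class SpheringTransform:
    """Regularized ZCA whitening fitted on control profiles."""

    center: np.ndarray
    whitening: np.ndarray
    lambda_reg: float

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        return (x - self.center) @ self.whitening

    def apply_frame(self, profiles: pd.DataFrame,
                    feature_cols: list[str]) -> pd.DataFrame:
        out = profiles.copy()
        out[feature_cols] = self(profiles[feature_cols].to_numpy())
        return out


def fit_sphering(control_profiles: np.ndarray,
                 lambda_reg: float) -> SpheringTransform:
    """Fit ``W = (Sigma_c + lambda * (tr(Sigma_c)/d) * I)^(-1/2)`` (ZCA).

    Small ``lambda_reg`` drives transformed control covariance to identity;
    large values shrink W toward a uniform rescaling of centered data.
    """
    x = np.asarray(control_profiles, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (n >= 2, d) control matrix")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite control features")
    if lambda_reg <= 0:
        raise ValueError("lambda must be > 0")
    center = x.mean(axis=0)
    sigma = np.cov(x - center, rowvar=False, ddof=1)
    sigma = np.atleast_2d(sigma)
    d = sigma.shape[0]
    ridge = lambda_reg * (np.trace(sigma) / d)
    evals, evecs = np.linalg.eigh(sigma + ridge * np.eye(d))
    w = (evecs * (1.0 / np.sqrt(evals))) @ evecs.T
    return SpheringTransform(center=center, whitening=w,
                             lambda_reg=lambda_reg)


# ---------------------------------------------------------------------------
# Matching


def _cosine_matrix(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero vector: cosine similarity undefined")
    xn = x / norms
    return xn @ xn.T


def average_precision_from_ranking(hits: np.ndarray) -> float:
    """AP of one ranked boolean hit list: mean of precision at each hit."""
    hits = np.asarray(hits, dtype=bool)
    positions = np.flatnonzero(hits) + 1
    if len(positions) == 0:
        return 0.0
    precisions = np.arange(1, len(positions) + 1) / positions
    return float(precisions.mean())


def mean_average_precision(profiles: pd.DataFrame, feature_cols: list[str],
                           label_key: str = "moa_label",
                           exclude_labels: tuple[str, ...] = (DMSO_LABEL,),
                           ) -> tuple[float, pd.DataFrame]:
    """mAP of retrieving same-MoA wells by cosine similarity.

    Each eligible well ranks all other eligible wells by descending cosine
    similarity (ties broken by stable well order); its AP averages the
    precision at every position holding a same-label well.  Labels in
    ``exclude_labels`` (the controls) and labels with a single well are
    excluded — the latter with a warning.  Returns the mAP and the
    per-well AP table.
    """
    keep = ~profiles[label_key].isin(exclude_labels)
    sub = profiles[keep].reset_index(drop=True)
    counts = sub[label_key].value_counts()
    single = sorted(counts[counts < 2].index)
    if single:
        import warnings
        warnings.warn(f"label(s) {single} have a single well; excluded",
                      stacklevel=2)
        sub = sub[~sub[label_key].isin(single)].reset_index(drop=True)
    if len(sub) < 2:
        raise ValueError("fewer than two eligible wells for matching")
    sim = _cosine_matrix(sub[feature_cols].to_numpy(dtype=np.float64))
    labels = sub[label_key].to_numpy()
    rows = []
    n = len(sub)
    for i in range(n):
        others = np.delete(np.arange(n), i)
        # Stable mergesort on -similarity keeps well order for ties.
        order = others[np.argsort(-sim[i, others], kind="stable")]
        ap = average_precision_from_ranking(labels[order] == labels[i])
        rec = {k: sub.iloc[i][k] for k in WELL_KEYS if k in sub.columns}
        rec.update({label_key: labels[i], "average_precision": ap})
        rows.append(rec)
    table = pd.DataFrame(rows)
    return float(table.average_precision.mean()), table


# ---------------------------------------------------------------------------
# Batch-effect diagnostics


@dataclass
class CosineSeparation:
    within: np.ndarray
    across: np.ndarray

    @property
    def separation(self) -> float:
        """Difference of means, the summary separation statistic."""
        return float(self.within.mean() - self.across.mean())


def cosine_within_across(features: np.ndarray,
                         labels: np.ndarray) -> CosineSeparation:
    """All pairwise cosine similarities, split by same vs different label."""
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any():
        raise ValueError("every class needs at least two samples")
    sim = _cosine_matrix(features)
    iu = np.triu_indices(len(labels), k=1)
    same = labels[iu[0]] == labels[iu[1]]
    return CosineSeparation(within=sim[iu][same], across=sim[iu][~same])


def plate_correlation_matrix(control_features: pd.DataFrame,
                             feature_cols: list[str]) -> pd.DataFrame:
    """Pearson correlation between per-plate mean control feature vectors.

    Control features from several splits may be pooled; the per-plate mean
    absorbs them.  Diagonal is 1; an entry involving a constant plate
    vector is NaN (flagged, not raised).
    """
    if control_features.empty:
        raise ValueError("no control features supplied")
    means = control_features.groupby("plate_id")[feature_cols].mean()
    x = means.to_numpy(dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=means.index, columns=means.index)
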