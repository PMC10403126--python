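"""Independent brute-force reference implementations.

Deliberately naive (loops, dictionaries, O(n^2) scans) so they share no
code path with the package; the metric tests compare the package against
these on randomized instances.
"""

from __future__ import annotations

import numpy as np


def per_class_f1_bf(y_true: list, y_pred: list, labels: list) -> dict:
    out = {}
    for lab in labels:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == lab and p == lab)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != lab and p == lab)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == lab and p != lab)
        denom = 2 * tp + fp + fn
        out[lab] = 2 * tp / denom if denom else 0.0
    return out


def macro_f1_bf(y_true: list, y_pred: list) -> float:
    labels = sorted(set(y_true) | set(y_pred))
    scores = per_class_f1_bf(y_true, y_pred, labels)
    return sum(scores.values()) / len(labels)


def confusion_bf(y_true: list, y_pred: list, labels: list,
                 normalize: bool) -> np.ndarray:
    m = np.zeros((len(labels), len(labels)))
    pos = {lab: i for i, lab in enumerate(labels)}
    for t, p in zip(y_true, y_pred):
        m[pos[t], pos[p]] += 1
    if normalize:
        for i in range(len(labels)):
            s = m[i].sum()
            if s:
                m[i] /= s
    return m


def compound_accuracy_bf(records: list[dict]) -> dict:
    by_cpd: dict[str, list[bool]] = {}
    for r in records:
        if r["compound_id"] == "DMSO":
            continue
        by_cpd.setdefault(r["compound_id"], []).append(
            r["moa_label"] == r["pred_label"])
    return {c: sum(v) / len(v) for c, v in by_cpd.items()}


def cosine_pairs_bf(vectors: np.ndarray, labels: list
                    ) -> tuple[list[float], list[float]]:
    within, across = [], []
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            c = float(np.dot(vectors[i], vectors[j])
                      / (np.linalg.norm(vectors[i])
                         * np.linalg.norm(vectors[j])))
            (within if labels[i] == labels[j] else across).append(c)
    return within, across


def average_precision_bf(ranked_hits: list[bool]) -> float:
    hits = 0
    precisions = []
    for k, h in enumerate(ranked_hits, start=1):
        if h:
            hits += 1
            precisions.append(hits / k)
    return sum(precisions) / len(precisions) if precisions else 0.0


def mean_ap_bf(vectors: np.ndarray, labels: list,
               ids: list) -> dict[int, float]:
    """AP per index, ranking by cosine with ties broken by stable id order."""
    n = len(labels)
    aps = {}
    for i in range(n):
        sims = []
        for j in range(n):
            if j == i:
                continue
            c = float(np.dot(vectors[i], vectors[j])
                      / (np.linalg.norm(vectors[i])
                         * np.linalg.norm(vectors[j])))
            sims.append((j, c))
        sims.sort(key=lambda t: (-t[1], ids[t[0]] if False else t[0]))
        aps[i] = average_precision_bf([labels[j] == labels[i]
                                       for j, _ in sims])
    return aps


def well_mean_bf(rows: list[dict], feature_keys: list[str]) -> dict:
    acc: dict[tuple, dict] = {}
    for r in rows:
        key = (r["plate_id"], r["well"])
        slot = acc.setdefault(key, {"n": 0, **{k: 0.0 for k in feature_keys}})
        slot["n"] += 1
        for k in feature_keys:
            slot[k] += r[k]
    return {key: {k: slot[k] / slot["n"] for k in feature_keys}
            for key, slot in acc.items()}


def pooled_sd_bf(pixel_lists: list[np.ndarray]) -> tuple[float, float]:
    allpix = np.concatenate([p.ravel() for p in pixel_lists])
    return float(allpix.mean()), float(allpix.std())
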