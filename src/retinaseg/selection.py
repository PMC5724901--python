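"""Mutual information and minimum-redundancy maximum-relevance (mRMR)
feature ranking.

Continuous features are discretized to equal-width bins (default 8) before
the plug-in mutual-information estimate; the greedy ranking maximizes the
difference criterion MI(f; label) - mean MI(f; selected) (the MID form),
with ties broken by feature-registry order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, TABLE_RANKING

__all__ = [
    "MrmrRanking",
    "discretize",
    "mutual_information",
    "mrmr_rank",
    "select_top",
]


@dataclass(frozen=True)
class MrmrRanking:
    """Ordered feature names with the per-step relevance, redundancy and
    criterion score recorded at the moment each feature was picked."""

    names: tuple
    relevance: tuple
    redundancy: tuple
    scores: tuple

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.names) + 1),
                "feature": self.names,
                "relevance": self.relevance,
                "redundancy": self.redundancy,
                "score": self.scores,
            }
        )


def discretize(values: np.ndarray, bins: int = 8) -> np.ndarray:
    """Equal-width binning over the observed range; constant input -> all 0."""
    values = np.asarray(values, float)
    lo, hi = float(values.min()), float(values.max())
    if hi - lo < 1e-12:
        return np.zeros(values.shape, dtype=np.intp)
    idx = np.floor((values - lo) / (hi - lo) * bins).astype(np.intp)
    return np.clip(idx, 0, bins - 1)


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in MI (nats) of two discrete sequences from their joint
    empirical distribution."""
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least two observations")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny) / x.size
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / (px @ py)[nz])).sum())


def mrmr_rank(
    table: pd.DataFrame, k: int, bins: int = 8, variant: str = "mid"
) -> MrmrRanking:
    """Greedy forward mRMR ranking of the feature columns against ``label``.

    The first pick maximizes relevance MI(f; label); each later pick
    maximizes relevance minus the mean MI with the already-selected set
    (MID) or their ratio (MIQ).  Deterministic: ties resolve to the earlier
    feature in registry order.  ``k`` larger than the feature count is
    clamped with a warning.
    """
    if "label" not in table.columns:
        raise ValueError("table has no 'label' column")
    if k < 1:
        raise ValueError("k must be >= 1")
    if variant not in ("mid", "miq"):
        raise ValueError("variant must be 'mid' or 'miq'")
    candidates = [c for c in FEATURE_NAMES if c in table.columns]
    if not candidates:
        raise ValueError("table contains no known feature columns")
    if k > len(candidates):
        import warnings

        warnings.warn(
            f"k={k} exceeds the {len(candidates)} available features; clamped",
            stacklevel=2,
        )
        k = len(candidates)

    label = np.asarray(table["label"])
    disc = {c: discretize(table[c].to_numpy(), bins) for c in candidates}
    relevance = {c: mutual_information(disc[c], label) for c in candidates}

    pair_cache: dict = {}

    def pair_mi(a: str, b: str) -> float:
        key = (a, b) if a < b else (b, a)
        if key not in pair_cache:
            pair_cache[key] = mutual_information(disc[key[0]], disc[key[1]])
        return pair_cache[key]

    selected: list = []
    rels, reds, scores = [], [], []
    remaining = list(candidates)
    for _ in range(k):
        best_name, best_score, best_red = None, -np.inf, 0.0
        for name in remaining:
            if selected:
                red = float(np.mean([pair_mi(name, s) for s in selected]))
            else:
                red = 0.0
            if variant == "mid":
                score = relevance[name] - red
            else:
                score = relevance[name] / (red + 1e-12)
            if score > best_score:
                best_name, best_score, best_red = name, score, red
        selected.append(best_name)
        remaining.remove(best_name)
        rels.append(relevance[best_name])
        reds.append(best_red)
        scores.append(best_score)
    return MrmrRanking(tuple(selected), tuple(rels), tuple(reds), tuple(scores))


def select_top(
    table: pd.DataFrame, ranking: MrmrRanking | None = None, k: int = 10
) -> pd.DataFrame:
    """Restrict the table to the first ``k`` ranked features.

    With no ranking given, the shipped incremental-combination ordering
    (:data:`retinaseg.features.TABLE_RANKING`, whose first ten features gave
    the best overall accuracy) is used.  Metadata columns
    (image_id/row/col/label) are preserved.
    """
    names = list(ranking.names) if ranking is not None else list(TABLE_RANKING)
    if k > len(names):
        raise ValueError(f"k={k} exceeds ranking length {len(names)}")
    chosen = names[:k]
    unknown = [n for n in chosen if n not in FEATURE_NAMES]
    if unknown:
        raise KeyError(f"unknown feature name(s): {unknown}")
    missing = [n for n in chosen if n not in table.columns]
    if missing:
        raise KeyError(f"feature(s) absent from table: {missing}")
    meta = [c for c in ("image_id", "row", "col") if c in table.columns]
    tail = ["label"] if "label" in table.columns else []
    return table[meta + chosen + tail]
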