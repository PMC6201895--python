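"""Qualitative factor labels and four-level quality assignment.

Given K = 4 clusters in the 3-dim feature space [W, H, E], each intrinsic
factor is ranked across clusters from its centroid:

* span (W): larger W means faster responding, so clusters are ranked by
  descending centroid W;
* stability (H): ranked by descending centroid H;
* distribution-shift (E): a *low* error rate is good, so clusters are
  ranked by ascending centroid E.

Rank 1..4 maps to the labels High, Moderate, Low, Bottom.  The overall
level is the rank-sum across the three factors: the cluster with the
smallest sum is Level 1 ("Excellent"), the largest Level 4 ("Unqualified"),
with ties broken by ascending centroid error rate.  Individual participants
can also be banded into the three-interval scheme an expert panel would use
(narrow/medium/wide span and so on), with cohort terciles as default cuts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import Partition
from .stats import ClusterStats, PairwiseClusterMetrics, graham_scan

__all__ = [
    "FactorLabels",
    "LevelAssignment",
    "rank_factor_labels",
    "assign_levels",
    "expert_threshold_labels",
    "build_report",
]

RANK_NAMES = ("High", "Moderate", "Low", "Bottom")
LEVEL_NAMES = {1: "Excellent", 2: "Good", 3: "Moderate", 4: "Unqualified"}

#: three-band vocabularies per factor, worst to best
BAND_NAMES = {
    "W": ("Narrow", "Medium", "Wide"),
    "H": ("Bad", "Medium", "Good"),
    "E": ("Slow & Inaccurate", "Medium", "Rapid & Exact"),
}


@dataclass
class FactorLabels:
    """Per-cluster qualitative labels for span, stability, distribution-shift.

    ``ranks`` holds the underlying 1..K ranks per factor; ``labels`` holds
    the High/Moderate/Low/Bottom names (only when K = 4).  ``ties`` flags
    any centroid ties that had to be broken by cluster index.
    """

    ranks: pd.DataFrame
    labels: pd.DataFrame | None
    ties: bool = False

    def table(self) -> pd.DataFrame:
        return self.labels if self.labels is not None else self.ranks


def _rank(values: np.ndarray, ascending: bool) -> np.ndarray:
    """1-based ranks; ties resolved by original (cluster) index."""
    key = values if ascending else -values
    order = np.lexsort((np.arange(len(key)), key))
    ranks = np.empty(len(key), dtype=int)
    ranks[order] = np.arange(1, len(key) + 1)
    return ranks


def rank_factor_labels(centroids) -> FactorLabels:
    """Rank the three intrinsic factors across clusters from 3-dim centroids."""
    C = np.asarray(centroids, dtype=float)
    if C.ndim != 2 or C.shape[1] != 3:
        raise ValueError("rank_factor_labels expects K x 3 centroids")
    K = len(C)
    ranks = pd.DataFrame(
        {
            "span": _rank(C[:, 0], ascending=False),
            "stability": _rank(C[:, 1], ascending=False),
            "distribution_shift": _rank(C[:, 2], ascending=True),
        },
        index=pd.Index(range(K), name="cluster"),
    )
    ties = any(
        len(np.unique(C[:, j])) < K for j in range(3)
    )
    if ties:
        warnings.warn("centroid ties broken by cluster index", stacklevel=2)
    labels = None
    if K == 4:
        labels = ranks.apply(lambda col: [RANK_NAMES[r - 1] for r in col])
    return FactorLabels(ranks=ranks, labels=labels, ties=ties)


@dataclass
class LevelAssignment:
    """Overall quality level per cluster (1 = Excellent .. 4 = Unqualified)."""

    scores: pd.Series
    levels: pd.Series
    names: pd.Series

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"score": self.scores, "level": self.levels, "name": self.names}
        )


def assign_levels(factor_labels: FactorLabels, centroids) -> LevelAssignment:
    """Rank-sum composite score to overall Level 1..K.

    The composite is the sum of the three factor ranks (1 best); ascending
    score maps to ascending level, with score ties broken by ascending
    centroid error rate so the more accurate cluster takes the better level.
    """
    C = np.asarray(centroids, dtype=float)
    scores = factor_labels.ranks.sum(axis=1)
    K = len(scores)
    order = np.lexsort((np.arange(K), C[:, 2], scores.to_numpy()))
    levels = np.empty(K, dtype=int)
    levels[order] = np.arange(1, K + 1)
    levels_s = pd.Series(levels, index=scores.index, name="level")
    names = levels_s.map(lambda l: LEVEL_NAMES.get(l, f"Level {l}"))
    return LevelAssignment(scores=scores.rename("score"), levels=levels_s,
                           names=names.rename("name"))


def expert_threshold_labels(features: pd.DataFrame,
                            thresholds: dict[str, tuple[float, float]] | None = None,
                            ) -> pd.DataFrame:
    """Per-participant three-band labels for each feature.

    ``thresholds`` maps a feature name to its two cut points; features
    without configured cuts use the cohort terciles.  For W and H larger is
    better; the error rate E is inverted (low E earns "Rapid & Exact").
    """
    thresholds = thresholds or {}
    out = {}
    for col in features.columns:
        if col not in BAND_NAMES:
            continue
        v = features[col].to_numpy(dtype=float)
        lo, hi = thresholds.get(col) or tuple(np.quantile(v, [1 / 3, 2 / 3]))
        if not lo <= hi:
            raise ValueError(f"non-monotone cut points for {col}: {(lo, hi)}")
        band = np.digitize(v, [lo, hi])  # 0, 1, 2
        if col == "E":
            band = 2 - band
        names = BAND_NAMES[col]
        out[col] = [names[b] for b in band]
    return pd.DataFrame(out, index=features.index)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="index"))
    if isinstance(obj, pd.Series):
        return json.loads(obj.to_json())
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def build_report(features: pd.DataFrame, partition: Partition,
                 stats: list[ClusterStats], metrics: PairwiseClusterMetrics,
                 factor_labels: FactorLabels | None = None,
                 levels: LevelAssignment | None = None,
                 config: dict | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """Assemble the full machine-readable assessment report.

    Returns a JSON-serializable dict mirroring the pipeline's tables
    (centroids, dispersion, covariance, correlation, eigen-structure, both
    ITM conventions, distance matrices, SSE, labels, levels and 2-dim hull
    vertices).  When ``out_dir`` is given, writes ``report.json`` plus CSV
    tables there.  Rerunning with identical inputs yields byte-identical
    JSON.
    """
    if len(features) != len(partition.assignments):
        raise ValueError("features and partition are inconsistent")
    K = partition.K
    if len(stats) != K:
        raise ValueError("stats do not cover every cluster")

    hulls = {}
    if features.shape[1] >= 2:
        pts2 = features.iloc[:, :2].to_numpy(dtype=float)
        for k in range(K):
            members = pts2[partition.assignments == k]
            if len(np.unique(members, axis=0)) >= 3:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    hulls[k] = graham_scan(members)
            else:
                hulls[k] = members

    report = {
        "config": _jsonable(config or {}),
        "n_participants": int(len(features)),
        "K": K,
        "feature_columns": list(features.columns),
        "clusters": {
            str(s.label): {
                "size": s.size,
                "centroid": _jsonable(s.centroid),
                "sigma": s.sigma,
                "sigma_per_dim": s.sigma_per_dim,
                "covariance": _jsonable(s.covariance),
                "correlation": _jsonable(s.correlation),
                "eigenvalues": _jsonable(s.eigenvalues),
                "eigenvectors": _jsonable(s.eigenvectors),
                "itm": {
                    "unnormalized": s.itm_unnormalized,
                    "per_dimension": s.itm_per_dimension,
                },
                "sse": s.sse,
            }
            for s in stats
        },
        "pairwise": {
            "euclidean": _jsonable(metrics.euclidean),
            "tld_divergence": _jsonable(metrics.tld_divergence),
            "tld_distance": _jsonable(metrics.tld_distance),
        },
        "sse_total": float(partition.sse_total),
        "hulls": {str(k): _jsonable(v) for k, v in hulls.items()},
        "assignments": {
            str(pid): int(lab)
            for pid, lab in zip(
                partition.participant_ids or range(len(features)),
                partition.assignments,
            )
        },
    }
    if factor_labels is not None:
        report["factor_ranks"] = _jsonable(factor_labels.ranks)
        if factor_labels.labels is not None:
            report["factor_labels"] = _jsonable(factor_labels.labels)
    if levels is not None:
        report["levels"] = _jsonable(levels.table())

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        features.to_csv(out / "features.csv")
        pd.DataFrame(
            {"participant_id": partition.participant_ids or range(len(features)),
             "cluster": partition.assignments}
        ).to_csv(out / "assignments.csv", index=False)
        centro = pd.DataFrame([s.centroid for s in stats],
                              columns=list(features.columns))
        centro.index.name = "cluster"
        centro.to_csv(out / "centroids.csv")
        if factor_labels is not None and factor_labels.labels is not None:
            factor_labels.labels.to_csv(out / "factor_labels.csv")
        if levels is not None:
            levels.table().to_csv(out / "levels.csv")
    return report
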