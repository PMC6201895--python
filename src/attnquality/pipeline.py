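"""End-to-end convenience: cohort -> features -> partition -> report."""

from __future__ import annotations

from pathlib import Path

from .cluster import kmeans
from .features import extract_features
from .hurst import RSConfig
from .io import Cohort
from .report import assign_levels, build_report, rank_factor_labels
from .stats import compute_cluster_stats

__all__ = ["assess_cohort"]


def assess_cohort(cohort: Cohort, dim: int = 3, k: int = 4, seed: int = 0,
                  restarts: int = 50, bounds_mode: str = "cohort",
                  rs_config: RSConfig | None = None, corrected: bool = True,
                  out_dir: str | Path | None = None) -> dict:
    """Run the full assessment on a cohort and return the report dict.

    Feature extraction, K-means partitioning, cluster statistics and — in
    the 3-dim case with K = 4 — factor labels and the four-level quality
    assignment.  ``out_dir`` additionally writes the JSON/CSV report.
    """
    features = extract_features(cohort, dim=dim, rs_config=rs_config,
                                bounds_mode=bounds_mode, corrected=corrected)
    partition = kmeans(features, k=k, seed=seed, restarts=restarts)
    stats, metrics = compute_cluster_stats(features, partition.assignments, K=k)

    factor_labels = levels = None
    if dim == 3 and k == 4:
        centroids = partition.centroids
        factor_labels = rank_factor_labels(centroids)
        levels = assign_levels(factor_labels, centroids)

    config = {
        "dim": dim, "k": k, "seed": seed, "restarts": restarts,
        "bounds_mode": bounds_mode, "corrected": corrected,
        "windows": list(rs_config.window_sizes) if rs_config and rs_config.window_sizes else "dyadic",
    }
    return build_report(features, partition, stats, metrics,
                        factor_labels=factor_labels, levels=levels,
                        config=config, out_dir=out_dir)
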