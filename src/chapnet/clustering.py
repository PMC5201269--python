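"""Developmental expression normalization, hierarchical clustering and MI classification.

Profiles are made comparable by per-gene z-scoring of log2 values;
clustering is agglomerative (correlation or Euclidean distance, average or
complete linkage) via scipy; the myogenesis-induced (MI) pattern — flat
early, strong step-up from the induction stage — is decided by an explicit
template classifier on the raw profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from chapnet.io import ExpressionMatrix

logger = logging.getLogger("chapnet")

_METRICS = {"correlation", "euclidean"}
_LINKAGES = {"average", "complete"}


@dataclass
class NormalizedProfile:
    gene_id: str
    z: np.ndarray
    constant: bool = False


@dataclass
class ClusterResult:
    labels: dict[str, int]
    linkage_matrix: np.ndarray
    params: dict


@dataclass(frozen=True)
class MiClassifierConfig:
    """Template parameters for the myogenesis-induced pattern.

    A gene is MI when its raw profile is flat before ``early_cutoff_minutes``
    (coefficient of variation at most ``max_early_cv``) and rises at least
    ``min_fold``-fold (linear scale) from the early mean to the maximum at or
    after ``induction_stage_minutes``.
    """

    early_cutoff_minutes: float = 200.0
    induction_stage_minutes: float = 290.0
    min_fold: float = 2.0
    max_early_cv: float = 0.5

    def __post_init__(self) -> None:
        if self.early_cutoff_minutes >= self.induction_stage_minutes:
            raise ValueError("early_cutoff must precede induction_stage")
        if self.min_fold <= 1:
            raise ValueError("min_fold must exceed 1")


def normalize_profiles(matrix: ExpressionMatrix) -> list[NormalizedProfile]:
    """Per-gene z-scores of log2 expression.

    Zeros are replaced by half the smallest positive value in the matrix
    (counted and logged); negative values are rejected. Constant rows give a
    zero vector with the constant flag set.
    """
    vals = np.array(matrix.values, dtype=float)
    if (vals < 0).any():
        raise ValueError("expression values must be non-negative")
    n_zero = int((vals == 0).sum())
    if n_zero:
        positive_min = vals[vals > 0].min()
        vals[vals == 0] = positive_min / 2
        logger.warning("replaced %d zero value(s) by half-minimum %.3g", n_zero, positive_min / 2)
    logged = np.log2(vals)
    out: list[NormalizedProfile] = []
    for gid, row in zip(matrix.gene_ids, logged):
        sd = row.std()  # population sd: z has unit sd exactly
        if sd == 0:
            out.append(NormalizedProfile(gid, np.zeros_like(row), constant=True))
        else:
            out.append(NormalizedProfile(gid, (row - row.mean()) / sd))
    return out


def hierarchical_cluster(
    profiles: list[NormalizedProfile],
    metric: str = "correlation",
    linkage_rule: str = "average",
    k: int = 2,
) -> ClusterResult:
    """Agglomerative clustering of normalized profiles, cut into k flat clusters."""
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}")
    if linkage_rule not in _LINKAGES:
        raise ValueError(f"linkage must be one of {sorted(_LINKAGES)}")
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds number of profiles {len(profiles)}")
    # constant profiles have undefined correlation to anything; nudge to avoid NaN
    data = np.vstack([p.z if not p.constant else p.z + 1e-12 * np.arange(p.z.size) for p in profiles])
    dists = pdist(data, metric=metric)
    dists = np.clip(dists, 0.0, None)
    lm = linkage(dists, method=linkage_rule)
    flat = fcluster(lm, t=k, criterion="maxclust")
    labels = {p.gene_id: int(c) for p, c in zip(profiles, flat)}
    return ClusterResult(
        labels, lm, {"metric": metric, "linkage": linkage_rule, "k": k}
    )


def classify_mi(
    profile_raw: np.ndarray,
    stage_minutes: list[float],
    config: MiClassifierConfig = MiClassifierConfig(),
) -> tuple[bool, dict]:
    """Decide the MI pattern on a raw (unstandardized) profile.

    Returns the boolean call plus diagnostics (early CV, induction fold).
    Invariant to positive rescaling of the profile.
    """
    profile = np.asarray(profile_raw, dtype=float)
    minutes = np.asarray(stage_minutes, dtype=float)
    if profile.shape != minutes.shape:
        raise ValueError("profile and stage_minutes lengths differ")
    early = profile[minutes < config.early_cutoff_minutes]
    late = profile[minutes >= config.induction_stage_minutes]
    if early.size == 0:
        raise ValueError("no stages before the early cutoff")
    if late.size == 0:
        raise ValueError("no stages at or after the induction stage")
    early_mean = early.mean()
    if early_mean <= 0:
        return False, {"early_cv": np.inf, "fold": 0.0}
    early_cv = early.std() / early_mean
    fold = late.max() / early_mean
    is_mi = early_cv <= config.max_early_cv and fold >= config.min_fold
    return bool(is_mi), {"early_cv": float(early_cv), "fold": float(fold)}


def mi_cluster_report(
    matrix: ExpressionMatrix,
    gene_subsets: dict[str, set[str]],
    config: MiClassifierConfig = MiClassifierConfig(),
    k: int = 2,
) -> dict:
    """Per-subset MI counts plus cluster co-membership of the MI genes."""
    calls = {
        gid: classify_mi(matrix.values[i], matrix.stage_minutes, config)[0]
        for i, gid in enumerate(matrix.gene_ids)
    }
    mi_genes = {g for g, c in calls.items() if c}

    profiles = normalize_profiles(matrix)
    cluster = hierarchical_cluster(profiles, k=k) if len(profiles) >= 2 else None

    subsets_out = {}
    matrix_genes = set(matrix.gene_ids)
    for name, subset in gene_subsets.items():
        present = set(subset) & matrix_genes
        if not present:
            logger.warning("subset %r shares no genes with the matrix", name)
        subsets_out[name] = {
            "n_present": len(present),
            "mi_count": len(present & mi_genes),
        }

    co_membership = None
    if cluster is not None and mi_genes:
        from collections import Counter

        label_counts = Counter(cluster.labels[g] for g in mi_genes)
        top_label, top_count = label_counts.most_common(1)[0]
        co_membership = {
            "dominant_cluster": int(top_label),
            "fraction_in_dominant": top_count / len(mi_genes),
        }

    return {
        "mi_genes": sorted(mi_genes),
        "mi_total": len(mi_genes),
        "per_gene": calls,
        "subsets": subsets_out,
        "cluster_co_membership": co_membership,
    }
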