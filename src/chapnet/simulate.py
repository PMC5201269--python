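"""Seeded generators for every input class, with machine-readable ground truth.

All draws flow through a single numpy Generator seeded from the config, in a
fixed order, so outputs are byte-identical across runs for fixed inputs.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from chapnet.io import (
    ChaperoneCatalog,
    CtRecord,
    CtTable,
    EvidenceSet,
    ExpressionMatrix,
)
from chapnet.io import normalize_gene_id as _norm_gene
from chapnet.motifs import EBOX_CONSENSUS, IUPAC

_FAMILY_CYCLE = ("Hsp70", "Hsp40/NEF", "sHsp", "Hsp90/cochaperone", "Hsp60/10", "other")

DEFAULT_STAGE_MINUTES = (5.0, 30.0, 60.0, 100.0, 140.0, 180.0, 240.0, 290.0, 360.0, 480.0)
DEFAULT_STAGE_LABELS = (
    "4cell", "Ecell", "AB4", "AB5", "AB6", "AB7", "preVE", "VE", "comma", "L1",
)


@dataclass
class SimulationConfig:
    seed: int = 0
    # catalog / evidence
    n_genes: int = 97
    occupancy_muscle_odds_ratio: float = 1.0
    n_occ: int = 62
    n_muscle: int = 53
    n_experiments_per_category: int = 3
    # time course
    n_timecourse_genes: int = 100
    mi_fraction: float = 0.2
    mi_fold: float = 8.0
    log2_noise_sd: float = 0.2
    stage_minutes: tuple = DEFAULT_STAGE_MINUTES
    stage_labels: tuple = DEFAULT_STAGE_LABELS
    # promoters
    promoter_length: int = 1000
    gc_content: float = 0.36
    planted_sites: tuple = ()  # (gene_id, tss_relative_position, word)
    n_promoters: int = 10
    # qPCR
    true_folds: dict = field(default_factory=lambda: {"geneA": 4.0})
    ct_noise_sd: float = 0.1
    n_replicates: int = 5
    reference_gene: str = "ref"
    mu_reference_ct: float = 20.0
    delta_ct_base: float = 2.0

    def __post_init__(self) -> None:
        if self.occupancy_muscle_odds_ratio <= 0:
            raise ValueError("odds ratio must be positive")
        if not 0 <= self.mi_fraction <= 1:
            raise ValueError("mi_fraction must lie in [0, 1]")
        if not 0 <= self.gc_content <= 1:
            raise ValueError("gc_content must lie in [0, 1]")
        if max(self.n_occ, self.n_muscle) > self.n_genes:
            raise ValueError("set sizes cannot exceed n_genes")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# Catalog + evidence
# ---------------------------------------------------------------------------


def _noncentral_overlap_pmf(n: int, K: int, N: int, theta: float) -> np.ndarray:
    """Fisher noncentral hypergeometric pmf of the overlap, over its support."""
    lo = max(0, n + K - N)
    hi = min(n, K)
    ks = np.arange(lo, hi + 1)
    logw = np.array(
        [
            (math.lgamma(K + 1) - math.lgamma(k + 1) - math.lgamma(K - k + 1))
            + (math.lgamma(N - K + 1) - math.lgamma(n - k + 1) - math.lgamma(N - K - n + k + 1))
            + k * math.log(theta)
            for k in ks
        ]
    )
    w = np.exp(logw - logw.max())
    return w / w.sum()


def simulate_catalog(
    config: SimulationConfig,
) -> tuple[ChaperoneCatalog, list[EvidenceSet], dict]:
    """Catalog + evidence sets with a tunable occupancy↔muscle association.

    The overlap between the occupancy and muscle sets is drawn from the
    Fisher noncentral hypergeometric distribution at odds ratio θ,
    conditioning on the requested margins; membership is then uniform given
    the overlap. Truth records the realized 2x2 table.
    """
    rng = np.random.default_rng(config.seed)
    N, n, K = config.n_genes, config.n_occ, config.n_muscle
    theta = config.occupancy_muscle_odds_ratio
    genes = _gene_ids(N)
    fams = [_FAMILY_CYCLE[i % len(_FAMILY_CYCLE)] for i in range(N)]
    catalog = ChaperoneCatalog(tuple(zip(genes, fams)))

    lo = max(0, n + K - N)
    pmf = _noncentral_overlap_pmf(n, K, N, theta)
    k = int(lo + rng.choice(len(pmf), p=pmf))

    occ_members = list(rng.choice(genes, size=n, replace=False))
    occ_lookup = set(occ_members)
    rest = [g for g in genes if g not in occ_lookup]
    overlap = list(rng.choice(occ_members, size=k, replace=False))
    muscle_members = overlap + list(rng.choice(rest, size=K - k, replace=False))

    m = config.n_experiments_per_category

    def _spread(members: list[str]) -> list[set[str]]:
        """Assign each member to a uniformly-sized random subset of m experiments."""
        sets: list[set[str]] = [set() for _ in range(m)]
        if not members:
            return sets
        r = rng.integers(1, m + 1, size=len(members))
        order = np.argsort(rng.random((len(members), m)), axis=1)
        for g, ri, row in zip(members, r, order):
            for idx in row[:ri]:
                sets[idx].add(g)
        return sets

    occ_sets = _spread(occ_members)

    routes = rng.choice(3, size=len(muscle_members), p=[0.55, 0.15, 0.30])
    enr_members = [g for g, rt in zip(muscle_members, routes) if rt in (0, 2)]
    req_members = [g for g, rt in zip(muscle_members, routes) if rt in (1, 2)]
    enr_sets = _spread(enr_members)
    req_sets = _spread(req_members)

    evidence = (
        [
            EvidenceSet(f"occupancy_{i+1}", "occupancy", frozenset(s), "simulated")
            for i, s in enumerate(occ_sets)
        ]
        + [
            EvidenceSet(f"enrichment_{i+1}", "enrichment", frozenset(s), "simulated")
            for i, s in enumerate(enr_sets)
        ]
        + [
            EvidenceSet(f"required_{i+1}", "required", frozenset(s), "simulated")
            for i, s in enumerate(req_sets)
        ]
    )
    truth = {
        "k": k,
        "n": n,
        "K": K,
        "N": N,
        "theta": theta,
        "occupancy_members": sorted(occ_members),
        "muscle_members": sorted(muscle_members),
    }
    return catalog, evidence, truth


# ---------------------------------------------------------------------------
# Time course
# ---------------------------------------------------------------------------


def simulate_timecourse(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, dict]:
    """10-stage time courses with a planted myogenesis-induced subset.

    Non-MI genes: constant log2 baseline plus Gaussian noise. MI genes:
    baseline before the induction stage (290 min), baseline + log2(mi_fold)
    at and after it. Values are returned on the linear scale.
    """
    minutes = list(config.stage_minutes)
    if not any(m < 200 for m in minutes) or not any(m >= 290 for m in minutes):
        raise ValueError("stage minutes must include stages < 200 and >= 290")
    rng = np.random.default_rng(config.seed)
    n = config.n_timecourse_genes
    genes = _gene_ids(n)
    n_mi = int(round(config.mi_fraction * n))
    mi_idx = rng.choice(n, size=n_mi, replace=False)
    is_mi = np.zeros(n, dtype=bool)
    is_mi[mi_idx] = True

    baselines = rng.uniform(3.0, 8.0, size=n)
    step = np.where(np.asarray(minutes) >= 290.0, math.log2(config.mi_fold), 0.0)
    log2_vals = baselines[:, None] + np.where(is_mi[:, None], step[None, :], 0.0)
    log2_vals = log2_vals + rng.normal(0.0, config.log2_noise_sd, size=log2_vals.shape)
    matrix = ExpressionMatrix(
        genes, list(config.stage_labels), minutes, np.exp2(log2_vals)
    )
    truth = {"mi_genes": sorted(np.array(genes)[is_mi].tolist())}
    return matrix, truth


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------


def _consensus_finditer(consensus: str, seq: str) -> list[int]:
    pat = re.compile("(?=(" + "".join(f"[{IUPAC[c]}]" for c in consensus) + "))")
    return [m.start() for m in pat.finditer(seq)]


def simulate_promoters(
    config: SimulationConfig,
) -> tuple[list[tuple[str, str]], dict]:
    """i.i.d.-background promoters with planted motif words.

    Truth records, per gene, the planted positions plus every consensus
    match present after planting (found by a regex oracle), as TSS-relative
    positions.
    """
    rng = np.random.default_rng(config.seed)
    L = config.promoter_length
    gc = config.gc_content
    base_probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    planted_by_gene: dict[str, list[tuple[int, str]]] = {}
    for gene, pos, word in config.planted_sites:
        if not (-L <= pos <= -len(word)):
            raise ValueError(f"planted site at {pos} does not fit in {L}-bp promoter")
        planted_by_gene.setdefault(gene, []).append((int(pos), word.upper()))

    gene_ids = list(planted_by_gene)
    extra = [g for g in _gene_ids(config.n_promoters) if g not in planted_by_gene]
    gene_ids += extra[: max(0, config.n_promoters - len(gene_ids))]

    records: list[tuple[str, str]] = []
    truth: dict[str, dict] = {}
    for gene in gene_ids:
        bases = rng.choice(np.array(list("ACGT")), size=L, p=base_probs)
        for pos, word in planted_by_gene.get(gene, []):
            i = L + pos
            bases[i : i + len(word)] = list(word)
        seq = "".join(bases)
        records.append((gene, seq))
        oracle_hits = [i - L for i in _consensus_finditer(EBOX_CONSENSUS, seq)]
        truth[gene] = {
            "planted": sorted(pos for pos, _ in planted_by_gene.get(gene, [])),
            "consensus_matches": sorted(oracle_hits),
        }
    return records, truth


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------


def _normalize(gene: str) -> str:
    return _norm_gene(gene)[0]


def simulate_qpcr(config: SimulationConfig) -> tuple[CtTable, dict]:
    """Replicate Ct values with known fold changes.

    Reference Ct ~ Normal(mu_ref, sd); target Ct = mu_ref + ΔCt_base
    - log2(true_fold) * 1(treated) + noise.
    """
    rng = np.random.default_rng(config.seed)
    sd = config.ct_noise_sd
    records: list[CtRecord] = []
    for condition in ("control", "treated"):
        for rep in range(1, config.n_replicates + 1):
            ct = config.mu_reference_ct + rng.normal(0.0, sd)
            records.append(CtRecord(config.reference_gene, condition, rep, float(ct)))
    for raw_gene, fold in config.true_folds.items():
        gene = _normalize(raw_gene)
        if fold <= 0:
            raise ValueError(f"true fold for {gene} must be positive")
        for condition in ("control", "treated"):
            shift = -math.log2(fold) if condition == "treated" else 0.0
            for rep in range(1, config.n_replicates + 1):
                ct = (
                    config.mu_reference_ct
                    + config.delta_ct_base
                    + shift
                    + rng.normal(0.0, sd)
                )
                records.append(CtRecord(gene, condition, rep, float(ct)))
    truth = {"true_folds": {_normalize(g): f for g, f in config.true_folds.items()}}
    return CtTable(records), truth
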