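"""Relative transcript quantification by the 2^-ΔΔCt method.

ΔCt = Ct_target - Ct_reference per matched replicate; ΔΔCt is the
difference of condition means; fold = 2^(-ΔΔCt), assuming amplification
efficiency 2. SEM is propagated over per-replicate folds against the
control mean, so each replicate contributes one fold, matching how
independent qPCR experiments are summarized.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from chapnet.io import CtTable
from chapnet.setstats import TestResult, mann_whitney

logger = logging.getLogger("chapnet")


@dataclass
class QpcrResult:
    gene_id: str
    treated: str
    control: str
    reference_gene: str
    delta_ct_treated: list[float]
    delta_ct_control: list[float]
    ddct: float
    fold: float
    replicate_folds: list[float]
    sem: float

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold must be positive")


def delta_ct(
    ct_target: dict[int, float], ct_reference: dict[int, float]
) -> list[float]:
    """ΔCt per replicate, pairing target and reference by replicate id.

    Replicates present in only one of the two series are dropped with a
    warning.
    """
    common = sorted(set(ct_target) & set(ct_reference))
    dropped = (set(ct_target) | set(ct_reference)) - set(common)
    if dropped:
        logger.warning("delta_ct: dropping unmatched replicate(s) %s", sorted(dropped))
    if not common:
        raise ValueError("no matched replicates between target and reference")
    return [ct_target[r] - ct_reference[r] for r in common]


def fold_change(
    dct_treated: list[float],
    dct_control: list[float],
    gene_id: str = "",
    treated: str = "treated",
    control: str = "control",
    reference_gene: str = "",
) -> QpcrResult:
    """2^-ΔΔCt fold change with SEM over per-replicate folds."""
    if not dct_treated or not dct_control:
        raise ValueError("both ΔCt lists must be non-empty")
    mean_c = sum(dct_control) / len(dct_control)
    mean_t = sum(dct_treated) / len(dct_treated)
    ddct = mean_t - mean_c
    fold = 2.0 ** (-ddct)
    rep_folds = [2.0 ** (-(d - mean_c)) for d in dct_treated]
    if len(rep_folds) > 1:
        mean_f = sum(rep_folds) / len(rep_folds)
        var = sum((f - mean_f) ** 2 for f in rep_folds) / (len(rep_folds) - 1)
        sem = math.sqrt(var / len(rep_folds))
    else:
        sem = float("nan")
    return QpcrResult(
        gene_id, treated, control, reference_gene,
        list(dct_treated), list(dct_control), ddct, fold, rep_folds, sem,
    )


def quantify(
    table: CtTable,
    gene_id: str,
    reference_gene: str,
    treated: str,
    control: str,
) -> QpcrResult:
    """End-to-end 2^-ΔΔCt for one gene from a Ct table."""
    dct_t = delta_ct(table.select(gene_id, treated), table.select(reference_gene, treated))
    dct_c = delta_ct(table.select(gene_id, control), table.select(reference_gene, control))
    return fold_change(dct_t, dct_c, gene_id, treated, control, reference_gene)


def compare_conditions(
    result_a: QpcrResult, result_b: QpcrResult
) -> tuple[TestResult, str]:
    """Mann-Whitney test between two results' per-replicate folds.

    Returns the test result and its significance stars (* p<0.05, ** p<0.01).
    """
    res = mann_whitney(result_a.replicate_folds, result_b.replicate_folds)
    return res, res.stars
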