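"""Promoter extraction and E-box motif scanning.

Two detectors are provided: a degenerate IUPAC consensus scanner (the
primary detector for CANNTG) and a PWM scanner with exact p-values from the
dynamic-programming null score distribution under an i.i.d. background (the
threshold-based scanner mode). Hit coordinates are TSS-relative negative integers,
-1 being the first base upstream of the TSS.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np

from chapnet.io import GeneModel

logger = logging.getLogger("chapnet")

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

EBOX_CONSENSUS = "CANNTG"
DEFAULT_SCORE_BIN = 1e-3


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PromoterSequence:
    gene_id: str
    sequence: str
    requested_length: int
    source_strand: str = "+"
    truncated: bool = False

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"promoter {self.gene_id}: non-DNA characters {sorted(bad)}")
        if len(self.sequence) != self.requested_length and not self.truncated:
            raise ValueError(
                f"promoter {self.gene_id}: length {len(self.sequence)} != requested "
                f"{self.requested_length} without truncation flag"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    tss_relative_position: int  # leftmost base of the match, negative
    strand: str  # '+', '-' or '±'
    score: float
    p_value: float

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value out of (0, 1]: {self.p_value}")


@dataclass
class MotifModel:
    """Degenerate consensus and/or PWM representation of a motif."""

    width: int
    consensus: str | None = None
    log_odds: np.ndarray | None = None  # shape (4, width), rows A,C,G,T
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (4,) or not math.isclose(
            self.background.sum(), 1.0, abs_tol=1e-9
        ):
            raise ValueError("background must be a distribution over A,C,G,T")
        if self.consensus is not None:
            if len(self.consensus) != self.width:
                raise ValueError("consensus length != width")
            bad = set(self.consensus.upper()) - set(IUPAC)
            if bad:
                raise ValueError(f"invalid IUPAC letters {sorted(bad)}")
        if self.log_odds is not None:
            self.log_odds = np.asarray(self.log_odds, dtype=float)
            if self.log_odds.shape != (4, self.width):
                raise ValueError("log_odds must have shape (4, width)")
            if not np.isfinite(self.log_odds).all():
                raise ValueError("log_odds must be finite")

    def is_palindromic(self) -> bool:
        """True when the motif equals its own reverse complement."""
        if self.log_odds is not None:
            flipped = self.log_odds[::-1, ::-1]  # complement rows, reverse columns
            return bool(np.allclose(flipped, self.log_odds, atol=1e-12))
        assert self.consensus is not None
        cons = self.consensus.upper()
        return revcomp(cons) == cons


# ---------------------------------------------------------------------------
# Promoter extraction
# ---------------------------------------------------------------------------


def extract_promoter(
    genome: dict[str, str], gene_model: GeneModel, length: int = 1000
) -> PromoterSequence:
    """Extract the upstream promoter of a gene model from a genome.

    For + genes the bases [TSS-L, TSS) on the + strand; for - genes the
    reverse complement of (TSS, TSS+L]. Promoters truncated at a contig end
    are flagged.
    """
    if gene_model.seqid not in genome:
        raise KeyError(f"contig {gene_model.seqid!r} missing from genome")
    contig = genome[gene_model.seqid].upper()
    tss0 = gene_model.tss - 1  # 0-based index of the TSS base
    if gene_model.strand == "+":
        start = max(0, tss0 - length)
        seq = contig[start:tss0]
    else:
        end = min(len(contig), tss0 + 1 + length)
        seq = revcomp(contig[tss0 + 1 : end])
    truncated = len(seq) < length
    if truncated:
        logger.warning(
            "promoter of %s truncated at contig boundary: %d < %d bp",
            gene_model.gene_id, len(seq), length,
        )
    return PromoterSequence(
        gene_model.gene_id, seq, length, gene_model.strand, truncated
    )


# ---------------------------------------------------------------------------
# Consensus scanning
# ---------------------------------------------------------------------------


def _consensus_regex(consensus: str) -> re.Pattern:
    return re.compile("".join(f"[{IUPAC[c]}]" for c in consensus.upper()))


def scan_consensus(
    seq: str, consensus: str = EBOX_CONSENSUS, gene_id: str = ""
) -> list[MotifHit]:
    """All matches of an IUPAC consensus on both strands of a promoter.

    Positions are TSS-relative (the sequence ends at the TSS). When the
    consensus is its own reverse complement as a pattern class (CANNTG),
    the + and - hit sets coincide and each is reported once with strand ±.
    """
    seq = seq.upper()
    w = len(consensus)
    L = len(seq)
    fwd = _consensus_regex(consensus)
    rc_cons = revcomp(consensus.upper())
    palindromic = rc_cons == consensus.upper()
    hits: list[MotifHit] = []
    plus_positions = {m.start() for m in _finditer_overlapping(fwd, seq)}
    if palindromic:
        for i in sorted(plus_positions):
            hits.append(MotifHit(gene_id, i - L, "±", 1.0, 1.0))
        return hits
    minus_positions = {
        m.start() for m in _finditer_overlapping(_consensus_regex(rc_cons), seq)
    }
    for i in sorted(plus_positions):
        hits.append(MotifHit(gene_id, i - L, "+", 1.0, 1.0))
    for i in sorted(minus_positions):
        hits.append(MotifHit(gene_id, i - L, "-", 1.0, 1.0))
    return hits


def _finditer_overlapping(pattern: re.Pattern, seq: str):
    pos = 0
    while True:
        m = pattern.search(seq, pos)
        if m is None:
            return
        yield m
        pos = m.start() + 1


# ---------------------------------------------------------------------------
# PWM construction and exact null distribution
# ---------------------------------------------------------------------------


def consensus_to_pwm(
    consensus: str,
    pseudocount: float = 0.01,
    background: np.ndarray | None = None,
) -> MotifModel:
    """Build a log-odds PWM from an IUPAC consensus.

    Each column puts probability ``pseudocount`` on every disallowed letter
    and shares the remainder uniformly over the allowed letters; log-odds
    (base 2) are taken against the background.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-9) or (bg <= 0).any():
        raise ValueError("background must be a strictly positive distribution")
    cons = consensus.upper()
    bad = set(cons) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC letters {sorted(bad)}")
    w = len(cons)
    probs = np.empty((4, w))
    for j, letter in enumerate(cons):
        allowed = IUPAC[letter]
        n_dis = 4 - len(allowed)
        share = (1.0 - pseudocount * n_dis) / len(allowed)
        for b, bi in _BASE_INDEX.items():
            probs[bi, j] = share if b in allowed else pseudocount
    log_odds = np.log2(probs / bg[:, None])
    return MotifModel(
        width=w,
        consensus=cons,
        log_odds=log_odds,
        background=bg,
        pseudocount=pseudocount,
    )


@dataclass
class NullDistribution:
    """Exact discretized PWM score null under an i.i.d. background.

    Scores are binned on a fixed grid; ``tail(s)`` returns P(score >= s)
    evaluated at the bin of s.
    """

    bin_width: float
    bins: np.ndarray  # sorted ascending integer bin indices
    tail_probs: np.ndarray  # P(score >= bins[i] * bin_width)

    def tail(self, score: float) -> float:
        b = int(round(score / self.bin_width))
        idx = np.searchsorted(self.bins, b, side="left")
        if idx >= len(self.bins):
            return float(self.tail_probs[-1]) if b <= self.bins[-1] else 0.0
        return float(self.tail_probs[idx])

    @property
    def max_score(self) -> float:
        return float(self.bins[-1] * self.bin_width)


def pwm_null_distribution(
    model: MotifModel, bin_width: float = DEFAULT_SCORE_BIN
) -> NullDistribution:
    """Exact score distribution over all words under the i.i.d. background.

    Dynamic programming: convolve the per-column (score, probability) pairs,
    with scores discretized to the grid. Total mass 1 within 1e-9.
    """
    if model.log_odds is None:
        raise ValueError("model has no PWM")
    dist: dict[int, float] = {0: 1.0}
    for j in range(model.width):
        nxt: dict[int, float] = {}
        for b in range(4):
            inc = int(round(model.log_odds[b, j] / bin_width))
            p = model.background[b]
            for s, m in dist.items():
                key = s + inc
                nxt[key] = nxt.get(key, 0.0) + m * p
        dist = nxt
    total = sum(dist.values())
    if abs(total - 1.0) > 1e-9:
        raise AssertionError(f"null distribution mass {total} != 1")
    bins = np.array(sorted(dist), dtype=np.int64)
    masses = np.array([dist[b] for b in bins])
    # tail_probs[i] = P(score >= bins[i])
    tail = masses[::-1].cumsum()[::-1]
    return NullDistribution(bin_width, bins, tail)


def scan_pwm(
    seq: str,
    model: MotifModel,
    p_threshold: float = 0.001,
    gene_id: str = "",
    null: NullDistribution | None = None,
) -> list[MotifHit]:
    """Windows on both strands with null p-value at or below the threshold.

    Windows containing N are skipped. For palindromic PWMs the two strands
    score identically and each position is reported once with strand ±.
    """
    if model.log_odds is None:
        raise ValueError("model has no PWM")
    seq = seq.upper()
    w = model.width
    L = len(seq)
    if L < w:
        logger.warning("sequence shorter than motif width; no windows")
        return []
    if null is None:
        null = pwm_null_distribution(model)
    palindromic = model.is_palindromic()
    hits: list[MotifHit] = []
    for i in range(L - w + 1):
        window = seq[i : i + w]
        if "N" in window:
            continue
        fwd_score = _score_window(window, model)
        entries: list[tuple[str, float]] = []
        if palindromic:
            entries.append(("±", fwd_score))
        else:
            entries.append(("+", fwd_score))
            entries.append(("-", _score_window(revcomp(window), model)))
        for strand, score in entries:
            p = null.tail(score)
            if 0.0 < p <= p_threshold:
                hits.append(MotifHit(gene_id, i - L, strand, round(score, 9), p))
    return hits


def _score_window(window: str, model: MotifModel) -> float:
    return float(
        sum(model.log_odds[_BASE_INDEX[b], j] for j, b in enumerate(window))
    )


# ---------------------------------------------------------------------------
# Mutation effects
# ---------------------------------------------------------------------------


def mutation_effect(
    seq: str,
    tss_relative_position: int,
    replacement: str,
    model: MotifModel,
    p_threshold: float = 0.001,
    use_pwm: bool = False,
    gene_id: str = "",
) -> tuple[list[MotifHit], list[MotifHit]]:
    """Re-scan a promoter after substituting a window in place.

    ``tss_relative_position`` is the (negative) leftmost base of the excised
    window; the replacement must have the same length. Returns the hit lists
    before and after the edit.
    """
    L = len(seq)
    i = L + tss_relative_position
    if not (0 <= i and i + len(replacement) <= L):
        raise ValueError(
            f"edit at {tss_relative_position} with length {len(replacement)} "
            f"falls outside the {L}-bp promoter"
        )
    mutated = seq[:i] + replacement.upper() + seq[i + len(replacement) :]

    def _scan(s: str) -> list[MotifHit]:
        if use_pwm:
            return scan_pwm(s, model, p_threshold, gene_id=gene_id)
        assert model.consensus is not None
        return scan_consensus(s, model.consensus, gene_id=gene_id)

    return _scan(seq), _scan(mutated)
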