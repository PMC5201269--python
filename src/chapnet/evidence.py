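"""Per-gene evidence ranks, the muscle-associated union and the four regulatory groups.

Each gene in the catalog receives three integer ranks — the number of
occupancy, muscle-enrichment and muscle-required evidence sets containing
it, with equal weight per experiment — a muscle-associated flag (enriched
or required), and a group label:

  group 1: occupancy evidence and muscle-associated
  group 2: occupancy evidence, not muscle-associated
  group 3: no occupancy evidence, muscle-associated
  group 4: neither
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from chapnet.io import ChaperoneCatalog, EvidenceSet

logger = logging.getLogger("chapnet")


@dataclass(frozen=True)
class GeneRank:
    gene_id: str
    family: str
    r_occ: int
    r_enr: int
    r_req: int

    @property
    def muscle_associated(self) -> bool:
        return self.r_enr >= 1 or self.r_req >= 1

    @property
    def group(self) -> int:
        if self.r_occ >= 1:
            return 1 if self.muscle_associated else 2
        return 3 if self.muscle_associated else 4


@dataclass
class RankTable:
    """Evidence ranks for every gene in a catalog."""

    catalog: ChaperoneCatalog
    rows: list[GeneRank]

    def __post_init__(self) -> None:
        if {r.gene_id for r in self.rows} != set(self.catalog.gene_ids):
            raise ValueError("rank table rows must cover the catalog exactly")

    def __getitem__(self, gene_id: str) -> GeneRank:
        for r in self.rows:
            if r.gene_id == gene_id:
                return r
        raise KeyError(gene_id)

    def genes_with(self, predicate) -> set[str]:
        return {r.gene_id for r in self.rows if predicate(r)}

    def group_sizes(self) -> dict[int, int]:
        sizes = {1: 0, 2: 0, 3: 0, 4: 0}
        for r in self.rows:
            sizes[r.group] += 1
        return sizes

    def sorted_rows(self) -> list[GeneRank]:
        """Display order: occupancy rank desc, then enrichment, required, gene id."""
        return sorted(
            self.rows, key=lambda r: (-r.r_occ, -r.r_enr, -r.r_req, r.gene_id)
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "gene_id\tfamily\tr_occ\tr_enr\tr_req\tmuscle_associated\tgroup\n"
            )
            for r in self.sorted_rows():
                fh.write(
                    f"{r.gene_id}\t{r.family}\t{r.r_occ}\t{r.r_enr}\t{r.r_req}\t"
                    f"{int(r.muscle_associated)}\t{r.group}\n"
                )


def rank_evidence(
    catalog: ChaperoneCatalog,
    evidence_sets: list[EvidenceSet],
    strict: bool = False,
) -> RankTable:
    """Count, per gene and per category, the evidence sets containing it.

    Evidence genes outside the catalog are dropped with a warning (or
    rejected under strict mode). A category with no sets yields all-zero
    ranks with a warning.
    """
    validated = [s.validated_against(catalog, strict=strict) for s in evidence_sets]
    by_cat: dict[str, list[EvidenceSet]] = {"occupancy": [], "enrichment": [], "required": []}
    for s in validated:
        by_cat[s.category].append(s)
    for cat, sets in by_cat.items():
        if not sets:
            logger.warning("no %s evidence sets; ranks in this category are 0", cat)
    fams = catalog.families
    rows = [
        GeneRank(
            g,
            fams[g],
            sum(g in s.genes for s in by_cat["occupancy"]),
            sum(g in s.genes for s in by_cat["enrichment"]),
            sum(g in s.genes for s in by_cat["required"]),
        )
        for g in catalog.gene_ids
    ]
    return RankTable(catalog, rows)


def assign_groups(rank_table: RankTable) -> dict[str, int]:
    """Gene id -> group label. Groups are a pure function of the ranks."""
    return {r.gene_id: r.group for r in rank_table.rows}


def set_summary(rank_table: RankTable) -> dict[str, set[str]]:
    """Named gene sets derived from the ranks.

    occupancy_set (r_occ >= 1), enriched_set (r_enr >= 1), required_set
    (r_req >= 1), and muscle_set = enriched ∪ required.
    """
    occ = rank_table.genes_with(lambda r: r.r_occ >= 1)
    enr = rank_table.genes_with(lambda r: r.r_enr >= 1)
    req = rank_table.genes_with(lambda r: r.r_req >= 1)
    return {
        "occupancy_set": occ,
        "enriched_set": enr,
        "required_set": req,
        "muscle_set": enr | req,
    }
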