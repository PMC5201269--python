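"""Access to the packaged 97-gene catalog and evidence tables.

The packaged tables mirror the structure of the curated evidence workbook
this analysis consumes: three occupancy call sets, three muscle-enrichment
datasets and three literature-curation criteria over a 97-gene universe.
"""

from __future__ import annotations

from importlib import resources as _ir

from chapnet.io import ChaperoneCatalog, EvidenceSet, read_catalog, read_evidence_table

_DATA = _ir.files("chapnet") / "data"


def packaged_catalog() -> ChaperoneCatalog:
    with _ir.as_file(_DATA / "catalog.tsv") as p:
        return read_catalog(p)


def packaged_evidence() -> list[EvidenceSet]:
    out: list[EvidenceSet] = []
    for fname, category in [
        ("evidence_occupancy.tsv", "occupancy"),
        ("evidence_enrichment.tsv", "enrichment"),
        ("evidence_required.tsv", "required"),
    ]:
        with _ir.as_file(_DATA / fname) as p:
            out.extend(read_evidence_table(p, category))
    return out
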