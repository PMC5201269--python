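"""Readers, writers and validation for every external artifact the pipeline touches.

Formats handled: delimited evidence tables (wide-binary or long gene-list),
expression matrices with stage metadata, FASTA, GFF3, qPCR Ct tables (CSV)
and JSON reports. All readers validate and reject rather than silently
coerce; every dropped record is counted and reported.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("chapnet")

VALID_FAMILIES = frozenset(
    {"Hsp60/10", "Hsp70", "Hsp40/NEF", "Hsp90/cochaperone", "sHsp", "other"}
)
EVIDENCE_CATEGORIES = ("occupancy", "enrichment", "required")

_ITALIC_MARKERS = re.compile(r"[*_]")
_FAMILY_TAG = re.compile(r"\(([^()]*)\)\s*$")


class ParseError(ValueError):
    """Malformed input file."""


class ValidationError(ValueError):
    """Structurally parseable input violating a contract."""


def normalize_gene_id(raw: str) -> tuple[str, str | None]:
    """Normalize a gene identifier to canonical lower-case form.

    Strips italic markers (``*daf-21*`` styles) and a trailing
    parenthesized family tag (``daf-21(Hsp90)``), which is returned
    separately.

    Returns
    -------
    (gene_id, family_tag)
        ``family_tag`` is None when no parenthesized tag was present.
    """
    s = _ITALIC_MARKERS.sub("", raw).strip()
    tag = None
    m = _FAMILY_TAG.search(s)
    if m:
        tag = m.group(1).strip()
        s = s[: m.start()].strip()
    return s.lower(), tag


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChaperoneCatalog:
    """The gene universe anchoring every set operation."""

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        ids = [g for g, _ in self.entries]
        if len(ids) != len(set(ids)):
            dupes = sorted({g for g in ids if ids.count(g) > 1})
            raise ValidationError(f"duplicate gene ids in catalog: {dupes}")
        if any(not g for g in ids):
            raise ValidationError("empty gene id in catalog")
        for g, fam in self.entries:
            if fam not in VALID_FAMILIES:
                raise ValidationError(f"unknown family {fam!r} for gene {g!r}")

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.entries)

    @property
    def families(self) -> dict[str, str]:
        return {g: fam for g, fam in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in set(self.gene_ids)


@dataclass
class EvidenceSet:
    """One named experiment's binary gene membership."""

    name: str
    category: str
    genes: frozenset[str]
    source_note: str = ""

    def __post_init__(self) -> None:
        if self.category not in EVIDENCE_CATEGORIES:
            raise ValidationError(
                f"category must be one of {EVIDENCE_CATEGORIES}, got {self.category!r}"
            )
        self.genes = frozenset(self.genes)

    def validated_against(
        self, catalog: ChaperoneCatalog, strict: bool = False
    ) -> "EvidenceSet":
        """Drop (or, under strict mode, reject) genes outside the catalog."""
        known = set(catalog.gene_ids)
        unknown = sorted(self.genes - known)
        if unknown:
            if strict:
                raise ValidationError(
                    f"evidence set {self.name!r} contains genes outside the "
                    f"catalog: {unknown}"
                )
            logger.warning(
                "evidence set %r: dropping %d unknown gene(s): %s",
                self.name,
                len(unknown),
                unknown,
            )
        return EvidenceSet(
            self.name, self.category, self.genes & known, self.source_note
        )


@dataclass
class ExpressionMatrix:
    """Genes x developmental stages, with stage-time metadata in minutes."""

    gene_ids: list[str]
    stage_labels: list[str]
    stage_minutes: list[float]
    values: "np.ndarray"

    def __post_init__(self) -> None:
        import numpy as np

        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.stage_labels)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.stage_labels)} stages"
            )
        if len(self.stage_labels) != len(self.stage_minutes):
            raise ValidationError("stage_labels and stage_minutes length mismatch")
        if len(self.stage_labels) < 2:
            raise ValidationError("need at least 2 stages")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene_id in expression matrix")
        mins = list(self.stage_minutes)
        if any(b <= a for a, b in zip(mins, mins[1:])):
            raise ValidationError("stage_minutes must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, gene_id: str) -> "np.ndarray":
        return self.values[self.gene_ids.index(gene_id)]


@dataclass(frozen=True)
class CtRecord:
    gene_id: str
    condition: str
    replicate: int
    ct: float


@dataclass
class CtTable:
    records: list[CtRecord]

    def __post_init__(self) -> None:
        import math

        keys = [(r.gene_id, r.condition, r.replicate) for r in self.records]
        if len(keys) != len(set(keys)):
            raise ValidationError("duplicate (gene_id, condition, replicate) in Ct table")
        for r in self.records:
            if not math.isfinite(r.ct) or not (0 <= r.ct <= 45):
                raise ValidationError(
                    f"Ct out of range [0, 45] for {r.gene_id}/{r.condition}/{r.replicate}: {r.ct}"
                )

    def select(self, gene_id: str, condition: str) -> dict[int, float]:
        """Replicate -> Ct for one gene in one condition."""
        return {
            r.replicate: r.ct
            for r in self.records
            if r.gene_id == gene_id and r.condition == condition
        }

    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.gene_id, None)
        return list(seen)

    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.condition, None)
        return list(seen)


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene model: contig, 1-based inclusive span, strand."""

    gene_id: str
    seqid: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"strand must be + or -, got {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"invalid 1-based coordinates for {self.gene_id}: {self.start}-{self.end}"
            )

    @property
    def tss(self) -> int:
        """1-based transcription start: start on +, end on -."""
        return self.start if self.strand == "+" else self.end


# ---------------------------------------------------------------------------
# Catalog / evidence readers
# ---------------------------------------------------------------------------


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_catalog(path: str | Path) -> ChaperoneCatalog:
    """Read a catalog table with columns gene_id, family."""
    path = Path(path)
    entries: list[tuple[str, str]] = []
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ParseError(f"{path}: empty catalog")
    delim = _sniff_delimiter(lines[0])
    header = [c.strip().lower() for c in lines[0].split(delim)]
    if header[:2] != ["gene_id", "family"]:
        raise ParseError(f"{path}: expected header gene_id{delim}family, got {lines[0]!r}")
    for i, ln in enumerate(lines[1:], start=2):
        cells = ln.split(delim)
        if len(cells) < 2:
            raise ParseError(f"{path}: line {i}: expected 2 columns")
        gid, tag = normalize_gene_id(cells[0])
        fam = cells[1].strip()
        entries.append((gid, fam))
    return ChaperoneCatalog(tuple(entries))


def read_evidence_table(path: str | Path, category: str) -> list[EvidenceSet]:
    """Read evidence sets from a delimited file.

    Two layouts are auto-detected by header sniffing:

    * wide-binary — first column is ``gene_id``, remaining columns are
      experiment names with cells in {0, 1};
    * long gene-list — two columns ``set_name`` (or ``set``) and
      ``gene_id``, one gene per row per named set.

    Duplicate genes within a set collapse to single membership.
    """
    path = Path(path)
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        logger.warning("%s: empty evidence table; zero sets", path)
        return []
    delim = _sniff_delimiter(lines[0])
    header = [c.strip() for c in lines[0].split(delim)]
    if len(header) < 2:
        raise ParseError(f"{path}: line 1: evidence header needs >= 2 columns")
    lowered = [h.lower() for h in header]

    if lowered[0] in {"set_name", "set"} and lowered[1] == "gene_id":
        # long layout
        members: dict[str, set[str]] = {}
        for i, ln in enumerate(lines[1:], start=2):
            cells = ln.split(delim)
            if len(cells) < 2:
                raise ParseError(f"{path}: line {i}: expected 2 columns")
            gid, _ = normalize_gene_id(cells[1])
            members.setdefault(cells[0].strip(), set()).add(gid)
        return [
            EvidenceSet(name, category, frozenset(genes), source_note=str(path))
            for name, genes in members.items()
        ]

    if lowered[0] != "gene_id":
        raise ParseError(
            f"{path}: line 1: expected first column 'gene_id' or long layout "
            f"'set_name{delim}gene_id', got {header[0]!r}"
        )
    # wide-binary layout
    set_names = header[1:]
    members = {name: set() for name in set_names}
    if not lines[1:]:
        logger.warning("%s: empty evidence body; zero-member sets", path)
    for i, ln in enumerate(lines[1:], start=2):
        cells = ln.split(delim)
        if len(cells) != len(header):
            raise ParseError(
                f"{path}: line {i}: expected {len(header)} columns, got {len(cells)}"
            )
        gid, _ = normalize_gene_id(cells[0])
        for name, cell in zip(set_names, cells[1:]):
            cell = cell.strip()
            if cell not in {"0", "1"}:
                raise ValidationError(
                    f"{path}: line {i}: non-binary cell {cell!r} in column {name!r}"
                )
            if cell == "1":
                members[name].add(gid)
    return [
        EvidenceSet(name, category, frozenset(members[name]), source_note=str(path))
        for name in set_names
    ]


def write_evidence_table(
    sets: Sequence[EvidenceSet], gene_ids: Sequence[str], path: str | Path
) -> None:
    """Write evidence sets in wide-binary layout over the given gene order."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene_id\t" + "\t".join(s.name for s in sets) + "\n")
        for g in gene_ids:
            flags = "\t".join("1" if g in s.genes else "0" for s in sets)
            fh.write(f"{g}\t{flags}\n")


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes x stages table.

    Layout: optional comment line ``#minutes<delim>m1<delim>m2...`` carrying
    stage times; header row ``gene_id`` followed by stage labels (labels of
    the form ``name:minutes`` also supply times); one row per gene. Rows
    containing any non-numeric cell are dropped and counted.
    """
    import numpy as np

    path = Path(path)
    minutes_line: str | None = None
    lines: list[str] = []
    with path.open() as fh:
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln.strip():
                continue
            if ln.startswith("#minutes"):
                minutes_line = ln
            elif ln.startswith("#"):
                continue
            else:
                lines.append(ln)
    if not lines:
        raise ParseError(f"{path}: empty expression matrix")
    delim = _sniff_delimiter(lines[0])
    header = [c.strip() for c in lines[0].split(delim)]
    if header[0].lower() != "gene_id":
        raise ParseError(f"{path}: first header column must be gene_id")
    labels = header[1:]
    if len(labels) < 2:
        raise ParseError(f"{path}: need at least 2 stages, got {len(labels)}")

    minutes: list[float]
    if minutes_line is not None:
        cells = minutes_line.split(delim)[1:]
        if len(cells) != len(labels):
            raise ParseError(
                f"{path}: #minutes line has {len(cells)} values for {len(labels)} stages"
            )
        minutes = [float(c) for c in cells]
    elif all(":" in lab for lab in labels):
        minutes = [float(lab.rsplit(":", 1)[1]) for lab in labels]
        labels = [lab.rsplit(":", 1)[0] for lab in labels]
    else:
        raise ParseError(
            f"{path}: stage minutes missing (no #minutes line, labels not name:minutes)"
        )

    gene_ids: list[str] = []
    rows: list[list[float]] = []
    n_dropped = 0
    for i, ln in enumerate(lines[1:], start=2):
        cells = ln.split(delim)
        if len(cells) != len(labels) + 1:
            raise ParseError(f"{path}: line {i}: expected {len(labels)+1} columns")
        gid, _ = normalize_gene_id(cells[0])
        try:
            vals = [float(c) for c in cells[1:]]
        except ValueError:
            n_dropped += 1
            continue
        if not all(np.isfinite(vals)):
            n_dropped += 1
            continue
        gene_ids.append(gid)
        rows.append(vals)
    if n_dropped:
        logger.warning("%s: dropped %d row(s) with non-numeric cells", path, n_dropped)
    if len(set(gene_ids)) != len(gene_ids):
        raise ValidationError(f"{path}: duplicate gene_id")
    return ExpressionMatrix(gene_ids, labels, minutes, np.array(rows, dtype=float))


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("#minutes\t" + "\t".join(_fmt_num(m) for m in matrix.stage_minutes) + "\n")
        fh.write("gene_id\t" + "\t".join(matrix.stage_labels) + "\n")
        for gid, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


# ---------------------------------------------------------------------------
# FASTA / GFF3
# ---------------------------------------------------------------------------

_DNA_OK = frozenset("ACGTN")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records, uppercasing sequences; strict DNA alphabet."""
    out: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _DNA_OK
        if bad:
            raise ValidationError(
                f"{path}: record {rec.id!r} has non-DNA characters: {sorted(bad)}"
            )
        out.append((rec.id, seq))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


_GFF_ID = re.compile(r"ID=([^;]+)")
_GFF_NAME = re.compile(r"Name=([^;]+)")


def read_gff3(path: str | Path, feature_types: frozenset[str] = frozenset({"gene"})) -> list[GeneModel]:
    """Read gene models from GFF3 (1-based inclusive coordinates kept as-is)."""
    path = Path(path)
    models: list[GeneModel] = []
    with path.open() as fh:
        for i, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln or ln.startswith("#"):
                continue
            cells = ln.split("\t")
            if len(cells) != 9:
                raise ParseError(f"{path}: line {i}: expected 9 GFF3 columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = cells
            if ftype not in feature_types:
                continue
            m = _GFF_NAME.search(attrs) or _GFF_ID.search(attrs)
            if m is None:
                raise ParseError(f"{path}: line {i}: feature lacks ID/Name attribute")
            gid, _ = normalize_gene_id(m.group(1))
            models.append(GeneModel(gid, seqid, int(start), int(end), strand))
    return models


# ---------------------------------------------------------------------------
# Ct tables
# ---------------------------------------------------------------------------


def read_ct_table(path: str | Path) -> CtTable:
    """Read a Ct CSV with columns gene_id, condition, replicate, ct."""
    path = Path(path)
    records: list[CtRecord] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"gene_id", "condition", "replicate", "ct"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ParseError(
                f"{path}: Ct table must have columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):
            gid, _ = normalize_gene_id(row["gene_id"])
            try:
                rep = int(row["replicate"])
                ct = float(row["ct"])
            except ValueError as exc:
                raise ParseError(f"{path}: line {i}: {exc}") from exc
            records.append(CtRecord(gid, row["condition"].strip(), rep, ct))
    return CtTable(records)


def write_ct_table(table: CtTable, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["gene_id", "condition", "replicate", "ct"])
        for r in table.records:
            w.writerow([r.gene_id, r.condition, r.replicate, repr(r.ct)])


# ---------------------------------------------------------------------------
# JSON reports
# ---------------------------------------------------------------------------


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable config mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_report(results: dict, path: str | Path, config: dict | None = None) -> dict:
    """Write a pipeline report as JSON; returns the full document written."""
    from chapnet import __version__

    doc = {
        "version": __version__,
        "config": config or {},
        "config_hash": config_hash(config or {}),
        "results": results,
    }
    with Path(path).open("w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return doc


def read_report(path: str | Path) -> dict:
    with Path(path).open() as fh:
        return json.load(fh)
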