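"""Pipeline orchestration: rank → overlap → cluster → scan → qpcr from one config.

Stages communicate only via files; a stage with missing inputs is skipped
with a recorded reason. The JSON report echoes the config and its hash so a
re-run reproduces it bit-for-bit for deterministic stages.
"""

from __future__ import annotations

import logging
from pathlib import Path

from chapnet import io as cio
from chapnet import resources
from chapnet.clustering import MiClassifierConfig, mi_cluster_report
from chapnet.evidence import rank_evidence, set_summary
from chapnet.motifs import EBOX_CONSENSUS, scan_consensus
from chapnet.qpcr import quantify
from chapnet.setstats import fisher_overlap, venn_counts

logger = logging.getLogger("chapnet")

STAGE_ORDER = ("rank", "overlap", "cluster", "scan", "qpcr")


def _load_catalog_and_evidence(config: dict):
    paths = config.get("inputs", {})
    if "catalog" in paths:
        catalog = cio.read_catalog(paths["catalog"])
        evidence = []
        for cat in ("occupancy", "enrichment", "required"):
            key = f"evidence_{cat}"
            if key in paths:
                evidence.extend(cio.read_evidence_table(paths[key], cat))
    else:
        catalog = resources.packaged_catalog()
        evidence = resources.packaged_evidence()
    return catalog, evidence


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run the enabled stages in dependency order; return the report document.

    ``config['stages']`` lists the enabled stage names. Unknown stages are
    rejected; stages whose inputs are absent are skipped with a reason.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    enabled = list(config.get("stages", []))
    unknown = [s for s in enabled if s not in STAGE_ORDER]
    if unknown:
        raise ValueError(f"unknown stage(s): {unknown}")
    if not enabled:
        logger.warning("no stages enabled; writing empty report")

    results: dict = {}
    warnings: list[str] = []
    outputs: list[str] = []
    rank_table = None

    for stage in STAGE_ORDER:
        if stage not in enabled:
            continue
        try:
            if stage == "rank":
                catalog, evidence = _load_catalog_and_evidence(config)
                rank_table = rank_evidence(catalog, evidence)
                path = out_dir / "rank_table.tsv"
                rank_table.to_tsv(path)
                outputs.append(str(path))
                summary = set_summary(rank_table)
                results["rank"] = {
                    "n_genes": len(catalog),
                    "set_sizes": {k: len(v) for k, v in summary.items()},
                    "group_sizes": {str(g): c for g, c in rank_table.group_sizes().items()},
                }
            elif stage == "overlap":
                if rank_table is None:
                    catalog, evidence = _load_catalog_and_evidence(config)
                    rank_table = rank_evidence(catalog, evidence)
                summary = set_summary(rank_table)
                universe = set(rank_table.catalog.gene_ids)
                occ = summary["occupancy_set"]
                tests = {}
                for name, (a, b) in {
                    "required_vs_enriched": (summary["required_set"], summary["enriched_set"]),
                    "occupancy_vs_muscle": (occ, summary["muscle_set"]),
                    "no_occupancy_vs_muscle": (universe - occ, summary["muscle_set"]),
                }.items():
                    table, res = fisher_overlap(a, b, universe)
                    tests[name] = {
                        "k": table.k, "n": table.n, "K": table.K, "N": table.N,
                        "p_value": res.p_value,
                    }
                regions = venn_counts(
                    {"enriched": summary["enriched_set"], "required": summary["required_set"]},
                    universe,
                )
                results["overlap"] = {
                    "tests": tests,
                    "venn_enriched_required": {
                        "/".join(k) or "outside": v for k, v in regions.items()
                    },
                }
            elif stage == "cluster":
                path = config.get("inputs", {}).get("expression")
                if path is None:
                    warnings.append("cluster skipped: no expression matrix configured")
                    continue
                matrix = cio.read_expression_matrix(path)
                mi_cfg = MiClassifierConfig(**config.get("mi_classifier", {}))
                subsets: dict[str, set[str]] = {}
                if rank_table is not None:
                    subsets = {
                        k: v for k, v in set_summary(rank_table).items()
                    }
                report = mi_cluster_report(
                    matrix, subsets, mi_cfg, k=int(config.get("cluster_k", 2))
                )
                mi_path = out_dir / "mi_classification.tsv"
                with mi_path.open("w") as fh:
                    fh.write("gene_id\tis_mi\n")
                    for g, call in report["per_gene"].items():
                        fh.write(f"{g}\t{int(call)}\n")
                outputs.append(str(mi_path))
                results["cluster"] = {
                    "n_genes": len(matrix.gene_ids),
                    "mi_total": report["mi_total"],
                    "subsets": report["subsets"],
                }
            elif stage == "scan":
                path = config.get("inputs", {}).get("promoters")
                if path is None:
                    warnings.append("scan skipped: no promoter FASTA configured")
                    continue
                records = cio.read_fasta(path)
                consensus = config.get("motif", {}).get("consensus", EBOX_CONSENSUS)
                per_gene = {}
                hits_path = out_dir / "motif_hits.tsv"
                with hits_path.open("w") as fh:
                    fh.write("gene_id\ttss_relative_position\tstrand\n")
                    for gid, seq in records:
                        hits = scan_consensus(seq, consensus, gene_id=gid)
                        per_gene[gid] = len(hits)
                        for h in hits:
                            fh.write(f"{gid}\t{h.tss_relative_position}\t{h.strand}\n")
                outputs.append(str(hits_path))
                results["scan"] = {
                    "consensus": consensus,
                    "n_promoters": len(records),
                    "genes_with_motif": sum(1 for c in per_gene.values() if c),
                    "hit_counts": per_gene,
                }
            elif stage == "qpcr":
                qc = config.get("qpcr")
                path = config.get("inputs", {}).get("ct_table")
                if path is None or qc is None:
                    warnings.append("qpcr skipped: no Ct table or qpcr block configured")
                    continue
                table = cio.read_ct_table(path)
                ref = qc["reference_gene"]
                treated, control = qc.get("treated", "treated"), qc.get("control", "control")
                folds = {}
                for gene in table.genes():
                    if gene == ref:
                        continue
                    res = quantify(table, gene, ref, treated, control)
                    folds[gene] = {"fold": res.fold, "sem": res.sem}
                results["qpcr"] = {"reference_gene": ref, "folds": folds}
        except FileNotFoundError as exc:
            warnings.append(f"{stage} skipped: missing input ({exc})")

    results["warnings"] = warnings
    results["outputs"] = outputs
    report_path = out_dir / "report.json"
    doc = cio.write_report(results, report_path, config=config)
    logger.info("report written to %s (config hash %s)", report_path, doc["config_hash"])
    return doc
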