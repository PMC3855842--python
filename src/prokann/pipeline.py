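"""The integration pipeline: raw per-tool evidence in, one annotation out.

Stage order is fixed: RNA mask -> consensus merge -> RNA/CDS overlap
resolution -> product assignment -> taxonomy vote -> summaries ->
writers.  Each stage logs its input/output counts and everything lands
in one run directory with fixed file names plus a machine-readable
``run_summary.json``.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import formats_io
from .config import consensus_params, product_params
from .consensus import build_mask, merge_gene_calls, resolve_rna_overlap
from .model import GeneCall, HierarchyNode
from .products import assign_product, tally_products
from .summaries import build_hierarchy, completeness, pathway_counts
from .taxonomy import assign_gbt, gbt_table

log = logging.getLogger(__name__)

__all__ = ["run_integrate"]

OUTPUT_FILES = (
    "consensus.gff3",
    "products.tsv",
    "annotation.tbl",
    "warehouse.xml",
    "run_summary.json",
)


class StageError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_integrate(
    predictor_paths: dict[str, str | Path],
    rna_path: str | Path | None,
    homology_paths: dict[str, str | Path],
    domains_path: str | Path | None,
    outdir: str | Path,
    config: dict,
    organism_name: str = "organism",
) -> dict:
    """Run the full integration and write all outputs under ``outdir``.

    Degrades gracefully: with no homology tables every product is
    "hypothetical protein" and no taxonomy report is written (both
    logged as warnings).  Returns the run summary dictionary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root_logger = logging.getLogger("prokann")
    root_logger.addHandler(handler)
    summary: dict = {"stages": {}, "parameters": {k: config[k] for k in sorted(config)}}

    def stage(name: str):
        log.info("stage %s", name)
        return name

    try:
        current = stage("read_inputs")
        calls_by_predictor = {
            name: formats_io.read_features(path, "gff3")
            for name, path in sorted(predictor_paths.items())
        }
        rna_calls: list[GeneCall] = (
            formats_io.read_features(rna_path, "gff3") if rna_path else []
        )
        summary["stages"]["read_inputs"] = {
            "predictor_calls": {k: len(v) for k, v in calls_by_predictor.items()},
            "rna_calls": len(rna_calls),
        }

        current = stage("build_mask")
        mask = build_mask(rna_calls)
        summary["stages"]["build_mask"] = {
            "mask_intervals": sum(len(v) for v in mask.intervals.values())
        }

        current = stage("merge_gene_calls")
        cparams = consensus_params(config)
        consensus = merge_gene_calls(calls_by_predictor, cparams)
        summary["stages"]["merge_gene_calls"] = {"consensus_cds": len(consensus)}

        current = stage("resolve_rna_overlap")
        consensus = resolve_rna_overlap(consensus, mask, cparams.max_rna_overlap)
        summary["stages"]["resolve_rna_overlap"] = {"cds_after_mask": len(consensus)}
        all_calls = sorted(
            consensus + rna_calls, key=lambda c: (c.contig_id, c.start, c.end)
        )

        current = stage("assign_product")
        pparams = product_params(config)
        hits_by_db_gene: dict[str, dict[str, list]] = {}
        for db, path in sorted(homology_paths.items()):
            hits_by_db_gene[db] = formats_io.read_homology(path, db)
        if not hits_by_db_gene:
            log.warning("no homology tables supplied; all products will be hypothetical")
        domains = formats_io.read_domains(domains_path) if domains_path else []
        assignments = []
        for call in consensus:
            per_db = {
                db: hits.get(call.gene_id, [])
                for db, hits in hits_by_db_gene.items()
                if hits.get(call.gene_id)
            }
            assignments.append(
                assign_product(call.gene_id, per_db, domains, pparams)
            )
        tallies = tally_products(assignments)
        summary["stages"]["assign_product"] = tallies

        current = stage("assign_gbt")
        gbt_db = config.get("gbt", {}).get("db", "nr")
        gbt_results = []
        if gbt_db in hits_by_db_gene:
            gene_to_contig = {c.gene_id: c.contig_id for c in consensus}
            gbt_results = assign_gbt(
                hits_by_db_gene[gbt_db],
                gene_to_contig,
                scope=config.get("gbt", {}).get("scope", "per_contig"),
                binomial=config.get("gbt", {}).get("binomial", False),
            )
            summary["stages"]["assign_gbt"] = {
                r.scope_id: r.winner for r in gbt_results
            }
        else:
            log.warning("taxonomy vote skipped: no %r homology table", gbt_db)

        current = stage("summaries")
        status_paths = {
            a.gene_id: [["CDS", a.status]] for a in assignments
        }
        for call in rna_calls:
            status_paths[call.gene_id] = [[call.feature_type]]
        feature_tree = build_hierarchy(status_paths, root_name=organism_name)
        lineage_map = config.get("summaries", {}).get("lineage_map", {}) or {}
        gbt_tree = None
        if gbt_results:
            tax_paths = {}
            for r in gbt_results:
                for sp, votes, _aln in r.ranking:
                    lineage = list(lineage_map.get(sp, [])) + [sp]
                    for i in range(votes):
                        tax_paths[f"{r.scope_id}:{sp}:{i}"] = [lineage]
            gbt_tree = build_hierarchy(tax_paths, root_name=organism_name)

        current = stage("writers")
        (outdir / "consensus.gff3").write_text(formats_io.write_gff3(all_calls))
        (outdir / "products.tsv").write_text(
            "gene_id\tproduct\tsource\tstatus\n"
            + "".join(
                f"{a.gene_id}\t{a.product}\t{a.source}\t{a.status}\n" for a in assignments
            )
        )
        (outdir / "annotation.tbl").write_text(
            formats_io.write_feature_table(all_calls, assignments)
        )
        hits_for_xml: dict[str, list] = {}
        if gbt_db in hits_by_db_gene:
            hits_for_xml = hits_by_db_gene[gbt_db]
        (outdir / "warehouse.xml").write_text(
            formats_io.write_warehouse_xml(
                all_calls,
                assignments,
                hits_for_xml,
                domains,
                organism_name=organism_name,
            )
        )
        (outdir / "hierarchy_features.txt").write_text(
            formats_io.write_hierarchy_text(feature_tree)
        )
        if gbt_results:
            (outdir / "gbt.tsv").write_text(gbt_table(gbt_results))
            if gbt_tree is not None:
                (outdir / "hierarchy_gbt.txt").write_text(
                    formats_io.write_hierarchy_text(gbt_tree)
                )
        sconf = config.get("summaries", {})
        ko_map = sconf.get("ko_to_pathways") or {}
        if ko_map:
            gene_to_kos = sconf.get("gene_to_kos") or {}
            rows = pathway_counts(gene_to_kos, {k: [tuple(p) for p in v] for k, v in ko_map.items()})
            (outdir / "pathways.tsv").write_text(
                "# naive KO-membership pathway counts (no parsimony pruning)\n"
                "pathway_id\tpathway_name\tgenes\n"
                + "".join(f"{pid}\t{name}\t{n}\n" for pid, name, n in rows)
            )
        core = sconf.get("core_cogs_bacteria") or []
        observed = sconf.get("observed_cogs")
        if core and observed is not None:
            rep = completeness(set(observed), list(core), "bacteria")
            (outdir / "completeness.tsv").write_text(
                "domain\tcore_total\tcore_observed\tcompleteness_pct\n"
                f"{rep.domain_label}\t{rep.core_total}\t{rep.core_observed}\t{rep.completeness_pct:.2f}\n"
            )
        summary["outputs"] = sorted(
            p.name for p in outdir.iterdir() if p.name != "run.log"
        )
        (outdir / "run_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    except Exception as exc:  # noqa: BLE001 - rewrap with the failing stage name
        raise StageError(current, exc) from exc
    finally:
        root_logger.removeHandler(handler)
        handler.close()
    return summary
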