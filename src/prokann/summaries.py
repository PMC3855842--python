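"""Hierarchical annotation summaries, completeness, pathways, enrichment.

Covers four reporting tasks downstream of annotation: (1) rolling
per-gene lineage paths (COG categories, GO slims, taxonomy, domain
families) into a counted tree for Krona-style display; (2) genome
completeness as the fraction of a core-COG list observed; (3) naive
KO -> pathway membership tallies with canonical KEGG highlight URLs;
(4) hypergeometric enrichment of terms in a gene list against a
background, with Bonferroni or Benjamini-Hochberg correction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .model import HierarchyNode

__all__ = [
    "EnrichmentResult",
    "CompletenessReport",
    "build_hierarchy",
    "completeness",
    "pathway_counts",
    "kegg_highlight_url",
    "enrich",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (the reporting convention here)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# hierarchy


def build_hierarchy(
    assignments: dict[str, list[list[str]]], root_name: str = "root"
) -> HierarchyNode:
    """Aggregate per-gene lineage paths into a counted tree.

    ``assignments`` maps a gene id to one or more root-first paths (the
    root itself is implicit).  A node's count is the number of *distinct*
    genes in its subtree: a gene annotated to several paths through one
    node is counted once there.  Children are sorted by name.
    """
    gene_sets: dict[tuple[str, ...], set[str]] = {(): set()}
    for gene, paths in assignments.items():
        for path in paths:
            if not path:
                raise ValueError(f"gene {gene} has an empty lineage path")
            prefix: tuple[str, ...] = ()
            gene_sets[prefix].add(gene)
            for level in path:
                prefix = prefix + (level,)
                gene_sets.setdefault(prefix, set()).add(gene)

    def make(prefix: tuple[str, ...], name: str) -> HierarchyNode:
        depth = len(prefix)
        child_names = sorted(
            {p[depth] for p in gene_sets if len(p) == depth + 1 and p[:depth] == prefix}
        )
        return HierarchyNode(
            name=name,
            count=len(gene_sets[prefix]),
            children=[make(prefix + (c,), c) for c in child_names],
        )

    return make((), root_name)


# ---------------------------------------------------------------------------
# completeness


@dataclass
class CompletenessReport:
    """Observed fraction of a core single-copy COG list."""

    domain_label: str  # "archaea" or "bacteria"
    core_total: int
    core_observed: int
    completeness_pct: float


def completeness(
    observed_cogs: set[str], core_list: list[str], domain_label: str
) -> CompletenessReport:
    """Fraction of the domain's core COGs observed in the genome.

    Meaningful only relative to the supplied core list; the percentage is
    rounded to 2 decimals, ties away from zero.
    """
    if not core_list:
        raise ValueError("core COG list must be non-empty")
    if len(set(core_list)) != len(core_list):
        raise ValueError("core COG list has duplicates")
    core = set(core_list)
    observed = len(observed_cogs & core)
    return CompletenessReport(
        domain_label=domain_label,
        core_total=len(core),
        core_observed=observed,
        completeness_pct=round_half_away(100.0 * observed / len(core)),
    )


# ---------------------------------------------------------------------------
# pathways


def pathway_counts(
    gene_to_kos: dict[str, list[str]],
    ko_to_pathways: dict[str, list[tuple[str, str]]],
) -> list[tuple[str, str, int]]:
    """Count genes per pathway via their KO assignments.

    A gene counts once per pathway regardless of how many of its KOs map
    there (naive membership counting — no parsimony-based pathway
    pruning).  Output is sorted by (count desc, pathway name asc); a
    top-N view is a slice of this list.
    """
    genes_per_pathway: dict[tuple[str, str], set[str]] = {}
    for gene, kos in gene_to_kos.items():
        for ko in kos:
            for pathway in ko_to_pathways.get(ko, []):
                genes_per_pathway.setdefault(tuple(pathway), set()).add(gene)
    rows = [(pid, pname, len(genes)) for (pid, pname), genes in genes_per_pathway.items()]
    rows.sort(key=lambda r: (-r[2], r[1], r[0]))
    return rows


_PATHWAY_ID_RE = re.compile(r"^(map|ko)\d{5}$")
KEGG_SHOW_PATHWAY = "https://www.kegg.jp/kegg-bin/show_pathway"


def kegg_highlight_url(pathway_id: str, kos: list[str]) -> str:
    """Canonical KEGG URL displaying a pathway map with KOs highlighted.

    KOs are deduplicated and sorted so equal gene sets yield equal URLs;
    an empty KO list gives the plain pathway URL.
    """
    if not _PATHWAY_ID_RE.match(pathway_id):
        raise ValueError(f"malformed pathway id {pathway_id!r}")
    parts = [pathway_id] + sorted(set(kos))
    return f"{KEGG_SHOW_PATHWAY}?{'+'.join(parts)}"


# ---------------------------------------------------------------------------
# enrichment


@dataclass
class EnrichmentResult:
    """Hypergeometric over-representation of one term in a gene list."""

    term: str
    k: int  # list genes with the term
    n: int  # list size
    K: int  # background genes with the term
    N: int  # background size
    p_value: float
    p_adjusted: float
    method: str


def enrich(
    list_terms: dict[str, set[str]],
    background_terms: dict[str, set[str]],
    method: str = "bh",
) -> list[EnrichmentResult]:
    """Term enrichment of a gene list against a background.

    For each term seen in the list, the p-value is the upper-tail
    hypergeometric probability P[X >= k] of drawing k of the background's
    K term-carrying genes in n draws from N.  Adjustment (``bonferroni``
    or ``bh``) is applied across all tested terms; terms absent from the
    list (k = 0) are not tested.  Results are sorted by p-value.
    """
    if method not in ("bonferroni", "bh"):
        raise ValueError(f"bad correction method {method!r}")
    missing = set(list_terms) - set(background_terms)
    if missing:
        raise ValueError(f"list genes absent from background: {sorted(missing)[:5]}")
    if not list_terms:
        return []

    N = len(background_terms)
    n = len(list_terms)
    k_counts: dict[str, int] = {}
    for terms in list_terms.values():
        for t in terms:
            k_counts[t] = k_counts.get(t, 0) + 1
    K_counts: dict[str, int] = {}
    for terms in background_terms.values():
        for t in terms:
            K_counts[t] = K_counts.get(t, 0) + 1

    terms = sorted(k_counts)
    pvals = [float(hypergeom.sf(k_counts[t] - 1, N, K_counts[t], n)) for t in terms]
    if method == "bonferroni":
        adjusted = [min(1.0, p * len(pvals)) for p in pvals]
    else:
        adjusted = list(multipletests(pvals, method="fdr_bh")[1])

    results = [
        EnrichmentResult(
            term=t,
            k=k_counts[t],
            n=n,
            K=K_counts[t],
            N=N,
            p_value=p,
            p_adjusted=min(1.0, adj),
            method=method,
        )
        for t, p, adj in zip(terms, pvals, adjusted)
    ]
    results.sort(key=lambda r: (r.p_value, r.term))
    return results
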