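"""Product-name assignment from multi-database homology and domain evidence.

The goal is to minimise uninformative ("hypothetical") product names:
databases are scanned in a configured precedence order for the best hit
whose name actually conveys a function, falling back to a protein-domain
derived name, then to the best hit's name even if hypothetical, and
finally to the literal "hypothetical protein".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .model import DomainHit, HomologyHit, ProductAssignment

__all__ = [
    "ProductParams",
    "DEFAULT_HYPOTHETICAL_PATTERNS",
    "DEFAULT_NAME_CLEANUP_RULES",
    "is_hypothetical",
    "clean_name",
    "assign_product",
    "tally_products",
]

# Case-insensitive substrings marking a product name as uninformative.
DEFAULT_HYPOTHETICAL_PATTERNS: tuple[str, ...] = (
    "hypothetical",
    "uncharacterized",
    "uncharacterised",
    "unknown function",
    "predicted protein",
    "duf",
)

# Ordered (pattern, replacement) rewrites stripping database formatting
# artifacts from subject descriptions before the hypothetical test.
DEFAULT_NAME_CLEANUP_RULES: tuple[tuple[str, str], ...] = (
    (r"^MULTISPECIES:\s*", ""),
    (r"^RecName: Full=", ""),
    (r";\s*(AltName|Short|Flags).*$", ""),
    (r"\s*\[[^\[\]]*\]\s*$", ""),  # trailing organism bracket
    (r"\s+", " "),
)


@dataclass
class ProductParams:
    """Thresholds and rules for product assignment.

    Hits must pass ``max_evalue`` (default 1e-5), ``min_identity``
    (percent, default 30) and ``min_query_cov`` (fraction, default 0.5;
    only enforced when coverage is known).  ``db_precedence`` orders the
    databases scanned for a functional name.
    """

    db_precedence: tuple[str, ...] = ("uniprot", "nr", "kegg", "cdd")
    max_evalue: float = 1e-5
    min_identity: float = 30.0
    min_query_cov: float = 0.5
    hypothetical_patterns: tuple[str, ...] = DEFAULT_HYPOTHETICAL_PATTERNS
    name_cleanup_rules: tuple[tuple[str, str], ...] = DEFAULT_NAME_CLEANUP_RULES

    def __post_init__(self) -> None:
        if self.max_evalue < 0:
            raise ValueError("max_evalue must be >= 0")
        if not 0 <= self.min_identity <= 100:
            raise ValueError("min_identity must be in [0, 100]")
        if not 0 <= self.min_query_cov <= 1:
            raise ValueError("min_query_cov must be in [0, 1]")
        if not self.hypothetical_patterns:
            raise ValueError("hypothetical pattern list must be non-empty")


def is_hypothetical(name: str, patterns: tuple[str, ...] = DEFAULT_HYPOTHETICAL_PATTERNS) -> bool:
    """True iff the name conveys no function (any pattern matches, case-insensitively)."""
    if not name.strip():
        return True
    low = name.lower()
    return any(p.lower() in low for p in patterns)


def clean_name(
    name: str, rules: tuple[tuple[str, str], ...] = DEFAULT_NAME_CLEANUP_RULES
) -> str:
    for pattern, repl in rules:
        name = re.sub(pattern, repl, name)
    return name.strip()


def _passes(hit: HomologyHit, params: ProductParams) -> bool:
    if hit.evalue > params.max_evalue:
        return False
    if hit.pct_identity < params.min_identity:
        return False
    if hit.query_cov is not None and hit.query_cov < params.min_query_cov:
        return False
    return True


def assign_product(
    gene_id: str,
    hits_by_db: dict[str, list[HomologyHit]],
    domains: list[DomainHit],
    params: ProductParams | None = None,
) -> ProductAssignment:
    """Choose one product name for a gene.

    Scan databases in precedence order; within each, take the best-ranked
    hit passing the thresholds whose cleaned name is non-hypothetical.
    Failing that, derive a name from the best InterPro-integrated domain
    (``"<description>-family protein"``); failing that, use the best
    passing hit's name even if hypothetical; the floor is "hypothetical
    protein" with source "none".  The status is always recomputed from
    the final name.
    """
    params = params or ProductParams()

    def finish(product: str, source: str) -> ProductAssignment:
        status = "hypothetical" if is_hypothetical(product, params.hypothetical_patterns) else "functional"
        return ProductAssignment(gene_id=gene_id, product=product, source=source, status=status)

    ordered_dbs = [db for db in params.db_precedence if db in hits_by_db]
    ordered_dbs += sorted(db for db in hits_by_db if db not in params.db_precedence)

    best_passing: tuple[str, str] | None = None  # (cleaned name, db)
    for db in ordered_dbs:
        for hit in hits_by_db[db]:
            if hit.query_id != gene_id or not _passes(hit, params):
                continue
            name = clean_name(hit.subject_desc, params.name_cleanup_rules)
            if not name:
                continue
            if best_passing is None:
                best_passing = (name, db)
            if not is_hypothetical(name, params.hypothetical_patterns):
                return finish(name, db)

    candidates = [
        d for d in domains if d.query_id == gene_id and d.ipr_acc and d.signature_desc
    ]
    if candidates:
        best = min(
            candidates,
            key=lambda d: (d.evalue if d.evalue is not None else float("inf"), d.signature_acc),
        )
        name = clean_name(best.signature_desc, params.name_cleanup_rules)
        if name and not is_hypothetical(name, params.hypothetical_patterns):
            return finish(f"{name}-family protein", "domain")

    if best_passing is not None:
        return finish(*best_passing)
    return finish("hypothetical protein", "none")


def tally_products(assignments: list[ProductAssignment]) -> dict[str, int]:
    """Count functional vs orphan (hypothetical) genes."""
    functional = sum(1 for a in assignments if a.status == "functional")
    return {"functional": functional, "orphan": len(assignments) - functional}
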