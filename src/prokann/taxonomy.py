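"""Contig-level taxonomy assignment by top-hit voting.

Each gene casts one vote: the species of its top-ranked homology hit.
The species with the most votes over a scope (a contig, or the whole
genome) is that scope's globally best taxonomy.  Vote ties are broken by
the total alignment length accumulated by each tied species over *all*
hits of the scope's genes, then lexicographically so the result is
always deterministic.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass

from .model import HomologyHit

log = logging.getLogger(__name__)

__all__ = ["GbtResult", "extract_species", "assign_gbt"]

_BRACKET_RE = re.compile(r"\[([^\[\]]+)\]")


@dataclass
class GbtResult:
    """Taxonomy vote for one scope (contig id or "genome")."""

    scope_id: str
    ranking: list[tuple[str, int, int]]  # (species, top-hit votes, total aln length)
    winner: str | None
    n_genes_with_hits: int


def extract_species(subject_desc: str, species_field: str | None = None, binomial: bool = False) -> str | None:
    """Pull a species name from a hit.

    An explicit species field wins; otherwise the last bracketed
    ``[...]`` substring of the subject description is used (the NCBI
    defline convention).  With ``binomial=True`` the name is truncated to
    two tokens — three when the first token is "Candidatus".
    """
    name = species_field
    if not name:
        matches = _BRACKET_RE.findall(subject_desc or "")
        name = matches[-1].strip() if matches else None
    if not name:
        return None
    if binomial:
        tokens = name.split()
        keep = 3 if tokens and tokens[0] == "Candidatus" else 2
        name = " ".join(tokens[:keep])
    return name or None


def assign_gbt(
    hits_by_gene: dict[str, list[HomologyHit]],
    gene_to_contig: dict[str, str] | None = None,
    scope: str = "per_contig",
    binomial: bool = False,
) -> list[GbtResult]:
    """Vote a globally best taxonomy per contig (or genome-wide).

    Hit lists must be ranked (bitscore desc, e-value asc, subject asc).
    Each gene contributes one vote — the species of its top-ranked
    species-resolvable hit list head; genes whose top hit has no
    extractable species are skipped (logged).  The tie-break sums
    alignment lengths over all of a species' hits among the scope's
    genes, not only top hits.
    """
    if scope not in ("per_contig", "genome"):
        raise ValueError(f"bad scope {scope!r}")
    if scope == "per_contig" and gene_to_contig is None:
        raise ValueError("per-contig scope needs a gene -> contig mapping")

    groups: dict[str, list[str]] = {}
    for gene in hits_by_gene:
        key = "genome" if scope == "genome" else gene_to_contig.get(gene)
        if key is None:
            log.warning("gene %s has no contig mapping; skipped", gene)
            continue
        groups.setdefault(key, []).append(gene)

    results: list[GbtResult] = []
    for scope_id in sorted(groups):
        votes: Counter[str] = Counter()
        aln_totals: Counter[str] = Counter()
        n_voting = 0
        for gene in groups[scope_id]:
            hits = hits_by_gene[gene]
            if not hits:
                continue
            top_species = extract_species(hits[0].subject_desc, hits[0].species, binomial)
            if top_species is None:
                log.warning("gene %s: top hit has no extractable species", gene)
            else:
                votes[top_species] += 1
                n_voting += 1
            for h in hits:
                sp = extract_species(h.subject_desc, h.species, binomial)
                if sp is not None:
                    aln_totals[sp] += h.aln_length
        ranking = sorted(
            ((sp, n, aln_totals[sp]) for sp, n in votes.items()),
            key=lambda t: (-t[1], -t[2], t[0]),
        )
        results.append(
            GbtResult(
                scope_id=scope_id,
                ranking=ranking,
                winner=ranking[0][0] if ranking else None,
                n_genes_with_hits=n_voting,
            )
        )
    return results


def gbt_table(results: list[GbtResult]) -> str:
    """Render GBT results as a TSV report."""
    lines = ["scope\twinner\tvotes\ttotal_aln_length\tn_genes_with_hits"]
    for r in results:
        if r.winner is None:
            lines.append(f"{r.scope_id}\t-\t0\t0\t{r.n_genes_with_hits}")
        else:
            _, v, a = r.ranking[0]
            lines.append(f"{r.scope_id}\t{r.winner}\t{v}\t{a}\t{r.n_genes_with_hits}")
    return "\n".join(lines) + "\n"
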