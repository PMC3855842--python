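"""Merge CDS calls from multiple ab initio predictors into one gene set.

The merge clusters calls that share a stop coordinate — the 3' end, which
is the coordinate prokaryotic gene callers agree on — and votes on the
start.  RNA genes (rRNA/tRNA from dedicated finders) take absolute
precedence: the genome is masked for RNA first and protein calls that
overlap the mask beyond a tolerance are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .model import GeneCall, GenomicInterval, RNA_TYPES

log = logging.getLogger(__name__)

__all__ = ["MaskSet", "ConsensusParams", "build_mask", "merge_gene_calls", "resolve_rna_overlap"]


@dataclass
class MaskSet:
    """Per-contig sorted, disjoint, strandless intervals covering RNA genes."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def overlap(self, interval: GenomicInterval) -> int:
        """Largest overlap (nt) of ``interval`` with any single mask interval."""
        best = 0
        for s, e in self.intervals.get(interval.contig_id, []):
            if s > interval.end:
                break
            best = max(best, min(e, interval.end) - max(s, interval.start) + 1)
        return best


@dataclass
class ConsensusParams:
    """Tunables of the merge.

    min_cds_len
        Minimum consensus CDS length in nt (default 90 nt = 30 aa, a
        conventional small-ORF floor for prokaryotes).
    start_vote
        ``"majority"`` (default): each predictor votes for its start, ties
        resolved toward the longest ORF; ``"longest"``: always take the
        longest ORF.
    orphan_policy
        What to do with clusters supported by a single predictor:
        ``"keep"`` (default) or ``"drop"``.
    max_rna_overlap
        Tolerated overlap (nt) between a CDS and the RNA mask; 0 by
        default, i.e. any overlap removes the CDS.
    predictor_priority
        Order used as a last-resort tie-break.
    """

    min_cds_len: int = 90
    start_vote: str = "majority"
    orphan_policy: str = "keep"
    max_rna_overlap: int = 0
    predictor_priority: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.min_cds_len < 3:
            raise ValueError("min_cds_len must be >= 3")
        if self.max_rna_overlap < 0:
            raise ValueError("max_rna_overlap must be >= 0")
        if self.start_vote not in ("majority", "longest"):
            raise ValueError(f"bad start_vote {self.start_vote!r}")
        if self.orphan_policy not in ("keep", "drop"):
            raise ValueError(f"bad orphan_policy {self.orphan_policy!r}")


def build_mask(rna_calls: list[GeneCall]) -> MaskSet:
    """Union the intervals of RNA gene calls into a per-contig mask.

    Overlapping or abutting intervals are merged.  Raises if any call is
    not an rRNA/tRNA.
    """
    per_contig: dict[str, list[tuple[int, int]]] = {}
    for call in rna_calls:
        if call.feature_type not in RNA_TYPES:
            raise ValueError(f"build_mask given non-RNA call {call.gene_id} ({call.feature_type})")
        per_contig.setdefault(call.contig_id, []).append((call.start, call.end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for contig, ivals in per_contig.items():
        ivals.sort()
        out: list[tuple[int, int]] = []
        for s, e in ivals:
            if out and s <= out[-1][1] + 1:  # overlap or abut
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[contig] = out
    return MaskSet(merged)


def _stop_coord(call: GeneCall) -> int:
    """Genomic coordinate of the 3' (stop) end: end on '+', start on '-'."""
    return call.end if call.strand == "+" else call.start


def _start_coord(call: GeneCall) -> int:
    """Genomic coordinate of the 5' (start) end: start on '+', end on '-'."""
    return call.start if call.strand == "+" else call.end


def merge_gene_calls(
    calls_by_predictor: dict[str, list[GeneCall]],
    params: ConsensusParams | None = None,
) -> list[GeneCall]:
    """Build the consensus CDS set from per-predictor call lists.

    Calls are clustered by (contig, strand, stop coordinate); each cluster
    yields at most one consensus gene.  The start is chosen by majority
    vote over predictors, ties resolved toward the longest ORF, then by
    predictor priority.  Single-predictor clusters are kept or dropped per
    ``orphan_policy``; consensus genes shorter than ``min_cds_len`` are
    dropped unless flagged partial.  Output is sorted by (contig, start)
    and independent of input ordering.
    """
    params = params or ConsensusParams()
    if not calls_by_predictor:
        raise ValueError("merge_gene_calls needs at least one predictor")
    priority = {name: i for i, name in enumerate(params.predictor_priority)}

    clusters: dict[tuple[str, str, int], list[tuple[str, GeneCall]]] = {}
    for predictor in sorted(calls_by_predictor):
        for call in calls_by_predictor[predictor]:
            if call.feature_type != "CDS":
                raise ValueError(f"merge_gene_calls given non-CDS call {call.gene_id}")
            key = (call.contig_id, call.strand, _stop_coord(call))
            clusters.setdefault(key, []).append((predictor, call))

    consensus: list[GeneCall] = []
    for (contig, strand, stop), members in clusters.items():
        predictors = {p for p, _ in members}
        if len(predictors) == 1 and params.orphan_policy == "drop":
            log.info("dropping orphan cluster at %s:%s:%d", contig, strand, stop)
            continue
        # one vote per (predictor, start) pair
        votes: dict[int, set[str]] = {}
        for predictor, call in members:
            votes.setdefault(_start_coord(call), set()).add(predictor)

        def rank(start: int) -> tuple:
            length = (stop - start + 1) if strand == "+" else (start - stop + 1)
            n_votes = 0 if params.start_vote == "longest" else len(votes[start])
            best_prio = min(
                (priority.get(p, len(priority)) for p in votes[start]), default=len(priority)
            )
            return (-n_votes, -length, best_prio, start)

        start = min(votes, key=rank)
        lo, hi = (min(start, stop), max(start, stop))
        partial = any(c.partial for _, c in members)
        if hi - lo + 1 < params.min_cds_len and not partial:
            log.info("dropping short consensus CDS %s:%d-%d", contig, lo, hi)
            continue
        consensus.append(
            GeneCall(
                gene_id="pending",
                interval=GenomicInterval(contig, lo, hi, strand),
                feature_type="CDS",
                source="consensus",
                partial=partial,
            )
        )
    consensus.sort(key=lambda c: (c.contig_id, c.start, c.end, c.strand))
    width = max(4, len(str(len(consensus))))
    return [c.with_id(f"cds_{i + 1:0{width}d}") for i, c in enumerate(consensus)]


def resolve_rna_overlap(
    cds: list[GeneCall], mask: MaskSet, max_rna_overlap: int = 0
) -> list[GeneCall]:
    """Drop CDS whose overlap with the RNA mask exceeds the tolerance.

    RNA genes always win a conflict; removals are logged with the overlap
    length.  Idempotent.
    """
    kept: list[GeneCall] = []
    for call in cds:
        ov = mask.overlap(call.interval)
        if ov > max_rna_overlap:
            log.info("removing CDS %s: %d nt overlap with RNA mask", call.gene_id, ov)
        else:
            kept.append(call)
    return kept
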