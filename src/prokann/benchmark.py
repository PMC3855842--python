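"""Gene-call benchmarking against a reference annotation.

Every reference gene falls into exactly one of three categories:
*identical* (test gene with the same start and stop), *similar* (start or
stop within a configurable offset, 50 bp by default, of a co-located
test gene), or *not detected*.  Matching is one-to-one; identical pairs
are fixed first, then the similar phase finds a maximum set of
one-to-one pairs among the remainder.  Reference genes left unmatched
are false negatives; test genes left unmatched are false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .model import GeneCall
from .summaries import round_half_away

__all__ = ["MatchResult", "ComparisonReport", "match_gene_calls", "comparison_report"]

IDENTICAL = "identical"
SIMILAR = "similar"
NOT_DETECTED = "not_detected"


@dataclass
class MatchResult:
    """Per-reference-gene categories plus the unmatched test genes."""

    # (reference gene, category, matched test gene or None), in ref input order
    per_reference: list[tuple[GeneCall, str, GeneCall | None]]
    false_positive_genes: list[GeneCall]
    n_test: int
    n_reference: int


def _similar_eligible(ref: GeneCall, test: GeneCall, offset: int) -> bool:
    """Same contig/strand/type, >=1 nt overlap, and one coordinate within offset."""
    if (
        ref.contig_id != test.contig_id
        or ref.strand != test.strand
        or ref.feature_type != test.feature_type
    ):
        return False
    if ref.interval.overlap(test.interval) < 1:
        return False
    return abs(ref.start - test.start) <= offset or abs(ref.end - test.end) <= offset


def match_gene_calls(
    test: list[GeneCall], ref: list[GeneCall], offset: int = 50
) -> MatchResult:
    """Match test gene calls one-to-one against reference gene calls.

    Identical pairs (exact start and stop, same contig/strand/type) are
    matched first.  The remaining reference genes are matched to
    remaining similar-eligible test genes by maximum-cardinality
    assignment, preferring pairs with the smallest total coordinate
    displacement among equally large matchings.  Unmatched reference
    genes are not detected; unmatched test genes are false positives.
    """
    if offset < 0:
        raise ValueError("offset must be >= 0")

    test_used = [False] * len(test)
    matched: dict[int, tuple[str, int]] = {}  # ref index -> (category, test index)

    # phase 1: identical matches, first-come one-to-one
    exact: dict[tuple, list[int]] = {}
    for j, t in enumerate(test):
        key = (t.contig_id, t.strand, t.feature_type, t.start, t.end)
        exact.setdefault(key, []).append(j)
    for i, r in enumerate(ref):
        key = (r.contig_id, r.strand, r.feature_type, r.start, r.end)
        for j in exact.get(key, []):
            if not test_used[j]:
                test_used[j] = True
                matched[i] = (IDENTICAL, j)
                break

    # phase 2: similar matches by min-cost maximum-cardinality assignment
    rem_ref = [i for i in range(len(ref)) if i not in matched]
    rem_test = [j for j in range(len(test)) if not test_used[j]]
    if rem_ref and rem_test:
        costs = np.full((len(rem_ref), len(rem_test)), -1.0)
        finite_total = 0.0
        for a, i in enumerate(rem_ref):
            for b, j in enumerate(rem_test):
                if _similar_eligible(ref[i], test[j], offset):
                    c = abs(ref[i].start - test[j].start) + abs(ref[i].end - test[j].end)
                    costs[a, b] = c
                    finite_total += c
        # a forbidden pair costs more than every real pair combined, so the
        # solver maximises the number of real pairs before minimising cost
        big = finite_total + 1.0
        costs[costs < 0] = big
        rows, cols = linear_sum_assignment(costs)
        for a, b in zip(rows, cols):
            if costs[a, b] < big:
                i, j = rem_ref[a], rem_test[b]
                matched[i] = (SIMILAR, j)
                test_used[j] = True

    per_reference = [
        (r, *(
            (matched[i][0], test[matched[i][1]]) if i in matched else (NOT_DETECTED, None)
        ))
        for i, r in enumerate(ref)
    ]
    false_positives = [t for j, t in enumerate(test) if not test_used[j]]
    return MatchResult(
        per_reference=per_reference,
        false_positive_genes=false_positives,
        n_test=len(test),
        n_reference=len(ref),
    )


@dataclass
class ComparisonReport:
    """Category counts and percentages of a test-vs-reference comparison.

    Percentages are of the reference total, rounded to 2 decimals with
    ties away from zero; they are ``None`` for an empty reference.
    ``false_negatives`` equals ``not_detected`` (reference genes with no
    matching test gene); ``false_positives`` counts test genes matching
    no reference gene.
    """

    identical: int
    similar: int
    not_detected: int
    n_reference: int
    n_test: int
    false_positives: int = 0
    pct_identical: float | None = None
    pct_similar: float | None = None
    pct_not_detected: float | None = None
    per_type: dict[str, dict[str, int]] = field(default_factory=dict)
    functional_test: int | None = None
    orphan_test: int | None = None

    @property
    def false_negatives(self) -> int:
        return self.not_detected

    @classmethod
    def from_counts(
        cls,
        identical: int,
        similar: int,
        not_detected: int,
        n_test: int | None = None,
        false_positives: int = 0,
    ) -> "ComparisonReport":
        """Build a report from category counts alone.

        The reference total is the sum of the three categories (they
        partition the reference set by construction).
        """
        total = identical + similar + not_detected
        report = cls(
            identical=identical,
            similar=similar,
            not_detected=not_detected,
            n_reference=total,
            n_test=n_test if n_test is not None else identical + similar + false_positives,
            false_positives=false_positives,
        )
        if total > 0:
            report.pct_identical = round_half_away(100.0 * identical / total)
            report.pct_similar = round_half_away(100.0 * similar / total)
            report.pct_not_detected = round_half_away(100.0 * not_detected / total)
        return report

    def to_tsv(self) -> str:
        """Fixed-column TSV rendering (one row per feature type plus total)."""
        header = (
            "feature_type\tn_test\tn_reference\tidentical\tsimilar\tnot_detected\t"
            "false_negatives\tfalse_positives\tpct_identical\tpct_similar\tpct_not_detected"
        )
        lines = [header]

        def fmt(p: float | None) -> str:
            return "-" if p is None else f"{p:.2f}"

        for ftype in sorted(self.per_type):
            c = self.per_type[ftype]
            total = c["n_reference"]
            lines.append(
                "\t".join(
                    [
                        ftype,
                        str(c["n_test"]),
                        str(total),
                        str(c["identical"]),
                        str(c["similar"]),
                        str(c["not_detected"]),
                        str(c["not_detected"]),
                        str(c["false_positives"]),
                        fmt(round_half_away(100 * c["identical"] / total) if total else None),
                        fmt(round_half_away(100 * c["similar"] / total) if total else None),
                        fmt(round_half_away(100 * c["not_detected"] / total) if total else None),
                    ]
                )
            )
        lines.append(
            "\t".join(
                [
                    "total",
                    str(self.n_test),
                    str(self.n_reference),
                    str(self.identical),
                    str(self.similar),
                    str(self.not_detected),
                    str(self.false_negatives),
                    str(self.false_positives),
                    fmt(self.pct_identical),
                    fmt(self.pct_similar),
                    fmt(self.pct_not_detected),
                ]
            )
        )
        if self.functional_test is not None:
            lines.append(f"# functional_test\t{self.functional_test}")
            lines.append(f"# orphan_test\t{self.orphan_test}")
        return "\n".join(lines) + "\n"


def comparison_report(
    matching: MatchResult,
    test_products: list | None = None,
) -> ComparisonReport:
    """Summarise a match result into category counts and percentages.

    When product assignments for the test set are supplied, functional
    and orphan tallies are included.
    """
    counts = {IDENTICAL: 0, SIMILAR: 0, NOT_DETECTED: 0}
    per_type: dict[str, dict[str, int]] = {}

    def bucket(ftype: str) -> dict[str, int]:
        return per_type.setdefault(
            ftype,
            {
                "n_test": 0,
                "n_reference": 0,
                "identical": 0,
                "similar": 0,
                "not_detected": 0,
                "false_positives": 0,
            },
        )

    for r, category, _t in matching.per_reference:
        counts[category] += 1
        b = bucket(r.feature_type)
        b["n_reference"] += 1
        b[category] += 1
    for t in matching.false_positive_genes:
        bucket(t.feature_type)["false_positives"] += 1
    # per-type test totals = matched + unmatched test genes of that type
    for r, category, t in matching.per_reference:
        if t is not None:
            bucket(t.feature_type)["n_test"] += 1
    for t in matching.false_positive_genes:
        bucket(t.feature_type)["n_test"] += 1

    report = ComparisonReport.from_counts(
        identical=counts[IDENTICAL],
        similar=counts[SIMILAR],
        not_detected=counts[NOT_DETECTED],
        n_test=matching.n_test,
        false_positives=len(matching.false_positive_genes),
    )
    report.per_type = per_type
    if test_products is not None:
        functional = sum(1 for p in test_products if p.status == "functional")
        report.functional_test = functional
        report.orphan_test = len(test_products) - functional
    return report
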