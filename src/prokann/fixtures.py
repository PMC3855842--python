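"""Deterministic synthetic genomes and evidence with planted structure.

Everything the pipeline consumes can be generated here from a single
seeded specification: contig sequences, a true annotation, perturbed
predictor outputs and a perturbed "test" annotation with known expected
benchmark categories, homology tables with a planted majority species,
and a sprinkling of domain hits.  Generators are pure functions of the
spec — regenerating with the same seed is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from io import StringIO
from pathlib import Path

import numpy as np
from Bio.Seq import Seq
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from .formats_io import write_gff3
from .model import GeneCall, GenomicInterval

__all__ = [
    "Perturbation",
    "FixtureSpec",
    "simulate_annotated_genome",
    "perturb_annotation",
    "simulate_homology_hits",
    "simulate_domain_hits",
    "predictor_call_sets",
    "write_fixture_dir",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

FUNCTIONAL_NAME_POOL = (
    "chaperonin GroEL",
    "DNA gyrase subunit A",
    "ABC transporter ATP-binding protein",
    "elongation factor Tu",
    "50S ribosomal protein L2",
    "DNA-directed RNA polymerase subunit beta",
    "glyceraldehyde-3-phosphate dehydrogenase",
    "ATP synthase subunit alpha",
    "cell division protein FtsZ",
    "two-component sensor histidine kinase",
    "phosphoenolpyruvate carboxykinase",
    "signal recognition particle protein",
)

HYPOTHETICAL_NAME_POOL = (
    "hypothetical protein",
    "uncharacterized protein",
    "DUF1234 domain-containing protein",
)

DOMAIN_POOL = (
    ("PF00005", "ABC transporter", "IPR003439"),
    ("PF00072", "Response regulator receiver", "IPR001789"),
    ("PF00115", "Cytochrome C oxidase subunit I", "IPR000883"),
    ("PF01926", "50S ribosome-binding GTPase", "IPR002917"),
)


@dataclass(frozen=True)
class Perturbation:
    """How the test annotation deviates from the truth.

    ``k_shift`` genes get a start shift of at most ``max_shift`` nt
    (frame-preserving, overlap-preserving), ``m_drop`` genes are removed
    and ``j_add`` spurious genes are inserted into intergenic space.
    """

    k_shift: int = 5
    max_shift: int = 50
    m_drop: int = 3
    j_add: int = 4

    def __post_init__(self) -> None:
        if min(self.k_shift, self.m_drop, self.j_add) < 0:
            raise ValueError("perturbation counts must be >= 0")
        if self.k_shift > 0 and self.max_shift < 3:
            raise ValueError("max_shift must be >= 3 to allow a frame-preserving shift")


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic genome.

    Defaults describe a small draft genome: 50 genes (4 of them RNA) on
    2 contigs, gene lengths 300-1500 nt, and a test annotation carrying
    5 sub-offset start shifts, 3 deletions and 4 insertions.  The
    homology tables plant a 70/30 two-species mixture so the majority
    species is the expected taxonomy vote.
    """

    seed: int = 0
    n_contigs: int = 2
    n_genes: int = 50
    gene_len_range: tuple[int, int] = (300, 1500)
    intergenic_range: tuple[int, int] = (50, 200)
    rna_genes: int = 4
    perturbation: Perturbation = field(default_factory=Perturbation)
    species_mix: tuple[tuple[str, float], ...] = (
        ("Salinisphaera shabanensis", 0.7),
        ("Haloplasma contractile", 0.3),
    )
    hypothetical_fraction: float = 0.3

    def __post_init__(self) -> None:
        if self.n_contigs < 1 or self.n_genes < 0:
            raise ValueError("need >= 1 contig and >= 0 genes")
        if self.rna_genes > self.n_genes:
            raise ValueError("rna_genes exceeds n_genes")
        if self.gene_len_range[0] < 90 or self.gene_len_range[0] > self.gene_len_range[1]:
            raise ValueError("bad gene length range")
        if abs(sum(f for _, f in self.species_mix) - 1.0) > 1e-9:
            raise ValueError("species fractions must sum to 1")
        if not 0 <= self.hypothetical_fraction <= 1:
            raise ValueError("hypothetical_fraction must be in [0, 1]")
        n_cds = self.n_genes - self.rna_genes
        if self.perturbation.k_shift + self.perturbation.m_drop > n_cds:
            raise ValueError("k_shift + m_drop exceeds the number of CDS genes")


def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([stream, spec.seed])


def simulate_annotated_genome(spec: FixtureSpec) -> tuple[dict[str, str], list[GeneCall]]:
    """Generate contig sequences and the true annotation.

    Genes are non-overlapping (on either strand), separated by intergenic
    gaps drawn from the spec's range; CDS lengths are multiples of 3 with
    planted start/stop codons.
    """
    rng = _rng(spec, 0)
    per_contig = [spec.n_genes // spec.n_contigs] * spec.n_contigs
    for i in range(spec.n_genes % spec.n_contigs):
        per_contig[i] += 1
    rna_idx = set(
        rng.choice(spec.n_genes, size=spec.rna_genes, replace=False).tolist()
        if spec.rna_genes
        else []
    )

    contigs: dict[str, str] = {}
    truth: list[GeneCall] = []
    gene_no = 0
    lo, hi = spec.gene_len_range
    glo, ghi = spec.intergenic_range
    n_rrna_seen = 0
    for ci in range(spec.n_contigs):
        contig_id = f"contig{ci + 1}"
        pos = 0  # last used base (0 = none)
        placements: list[tuple[int, int, str, str, str | None]] = []
        for _ in range(per_contig[ci]):
            gap = int(rng.integers(glo, ghi + 1))
            start = pos + gap + 1
            if gene_no in rna_idx:
                length = int(rng.integers(lo, hi + 1))
                if n_rrna_seen % 2 == 0:
                    ftype, subtype = "rRNA", "16S ribosomal RNA"
                else:
                    ftype, subtype = "tRNA", "tRNA-Ala"
                n_rrna_seen += 1
            else:
                length = 3 * int(rng.integers(lo // 3, hi // 3 + 1))
                ftype, subtype = "CDS", None
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            placements.append((start, start + length - 1, strand, ftype, subtype))
            pos = start + length - 1
            gene_no += 1
        tail = int(rng.integers(glo, ghi + 1))
        seq_len = pos + tail
        seq = rng.choice(list("ACGT"), size=max(seq_len, 1))
        for start, end, strand, ftype, _ in placements:
            if ftype != "CDS":
                continue
            if strand == "+":
                seq[start - 1 : start + 2] = list("ATG")
                seq[end - 3 : end] = list("TAA")
            else:
                seq[start - 1 : start + 2] = list("TTA")  # revcomp(TAA)
                seq[end - 3 : end] = list("CAT")  # revcomp(ATG)
        contigs[contig_id] = "".join(seq)
        for start, end, strand, ftype, subtype in placements:
            truth.append(
                GeneCall(
                    gene_id="pending",
                    interval=GenomicInterval(contig_id, start, end, strand),
                    feature_type=ftype,
                    source="truth",
                    rna_subtype=subtype,
                )
            )
    # id scheme mirrors the consensus merge (cds_NNNN in genomic order), so
    # fixture evidence tables join against a consensus built from the truth
    n_cds = sum(1 for c in truth if c.feature_type == "CDS")
    cw = max(4, len(str(n_cds)))
    rw = max(4, len(str(len(truth) - n_cds)))
    ci = ri = 0
    named: list[GeneCall] = []
    for c in truth:
        if c.feature_type == "CDS":
            ci += 1
            named.append(c.with_id(f"cds_{ci:0{cw}d}"))
        else:
            ri += 1
            named.append(c.with_id(f"rna_{ri:0{rw}d}"))
    return contigs, named


def perturb_annotation(
    truth: list[GeneCall], spec: FixtureSpec
) -> tuple[list[GeneCall], dict[str, int]]:
    """Derive a test annotation with known benchmark categories.

    Shifts move the 5' start inward by a multiple of 3 no larger than
    ``max_shift`` (so the gene stays in frame, keeps its stop and still
    overlaps the original); drops remove genes; additions place small
    spurious ORFs in intergenic gaps where they overlap nothing.  The
    returned expected counts are exact by construction.
    """
    p = spec.perturbation
    rng = _rng(spec, 1)
    cds_idx = [i for i, c in enumerate(truth) if c.feature_type == "CDS"]
    if p.k_shift + p.m_drop > len(cds_idx):
        raise ValueError("not enough CDS genes to shift and drop")
    order = rng.permutation(len(cds_idx))
    shift_set = {cds_idx[order[i]] for i in range(p.k_shift)}
    drop_set = {cds_idx[order[p.k_shift + i]] for i in range(p.m_drop)}

    test: list[GeneCall] = []
    for i, call in enumerate(truth):
        if i in drop_set:
            continue
        if i in shift_set:
            max_units = max(1, min(p.max_shift // 3, (call.length - 90) // 3))
            delta = 3 * int(rng.integers(1, max_units + 1))
            iv = call.interval
            if call.strand == "+":
                iv = GenomicInterval(iv.contig_id, iv.start + delta, iv.end, "+")
            else:
                iv = GenomicInterval(iv.contig_id, iv.start, iv.end - delta, "-")
            call = replace(call, interval=iv)
        test.append(call)

    # spurious additions go into intergenic gaps, overlapping no true gene
    by_contig: dict[str, list[GeneCall]] = {}
    for c in truth:
        by_contig.setdefault(c.contig_id, []).append(c)
    gaps: list[tuple[str, int, int]] = []
    for contig, calls in sorted(by_contig.items()):
        calls = sorted(calls, key=lambda c: c.start)
        prev_end = 0
        for c in calls:
            if c.start - prev_end - 1 >= 94:
                gaps.append((contig, prev_end + 1, c.start - 1))
            prev_end = max(prev_end, c.end)
    added = 0
    for contig, lo, hi in gaps:
        if added == p.j_add:
            break
        max_len = min(150, hi - lo + 1 - 4)
        length = 90 + 3 * int(rng.integers(0, (max_len - 90) // 3 + 1))
        start = lo + 2
        test.append(
            GeneCall(
                gene_id="pending",
                interval=GenomicInterval(contig, start, start + length - 1, "+"),
                feature_type="CDS",
                source="spurious",
            )
        )
        added += 1
    if added < p.j_add:
        raise ValueError("not enough intergenic room for spurious additions")

    test.sort(key=lambda c: (c.contig_id, c.start, c.end))
    width = max(4, len(str(len(test))))
    test = [c.with_id(f"t{i + 1:0{width}d}") for i, c in enumerate(test)]
    expected = {
        "identical": len(truth) - p.k_shift - p.m_drop,
        "similar": p.k_shift,
        "not_detected": p.m_drop,
        "false_positives": p.j_add,
    }
    return test, expected


def simulate_homology_hits(truth: list[GeneCall], spec: FixtureSpec) -> str:
    """Emit a 14-column homology table with a planted species mixture.

    Every CDS gene gets 1-5 hits.  Top-hit species are allotted per
    contig by largest-remainder apportionment of the spec's mixture and
    then shuffled, so a mixture fraction above 0.5 is a guaranteed
    per-contig majority, not just an expectation.  Lower-rank species
    are drawn freely from the mixture; bitscores decrease with rank; each
    hit's product name is drawn hypothetical with the configured
    probability.
    """
    rng = _rng(spec, 2)
    species = [s for s, _ in spec.species_mix]
    probs = [f for _, f in spec.species_mix]

    # deterministic per-contig apportionment of top-hit species
    cds_by_contig: dict[str, list[str]] = {}
    for call in truth:
        if call.feature_type == "CDS":
            cds_by_contig.setdefault(call.contig_id, []).append(call.gene_id)
    top_species: dict[str, str] = {}
    for contig in sorted(cds_by_contig):
        genes = cds_by_contig[contig]
        k = len(genes)
        quotas = [(f * k) for f in probs]
        counts = [int(q) for q in quotas]
        leftover = k - sum(counts)
        by_remainder = sorted(
            range(len(species)), key=lambda i: (-(quotas[i] - counts[i]), -probs[i], species[i])
        )
        for i in range(leftover):
            counts[by_remainder[i % len(species)]] += 1
        pool = [sp for sp, c in zip(species, counts) for _ in range(c)]
        for gene, idx in zip(genes, rng.permutation(k)):
            top_species[gene] = pool[idx]

    rows: list[str] = []
    subj_no = 0
    for call in truth:
        if call.feature_type != "CDS":
            continue
        n_hits = int(rng.integers(1, 6))
        bitscore = float(rng.uniform(200, 400))
        aa_len = call.length // 3
        for _rank in range(n_hits):
            if _rank == 0:
                sp = top_species[call.gene_id]
            else:
                sp = species[int(rng.choice(len(species), p=probs))]
            hypo = rng.random() < spec.hypothetical_fraction
            pool = HYPOTHETICAL_NAME_POOL if hypo else FUNCTIONAL_NAME_POOL
            name = pool[int(rng.integers(0, len(pool)))]
            aln = max(30, int(aa_len * rng.uniform(0.6, 1.0)))
            pct_id = float(rng.uniform(35, 98))
            evalue = 10.0 ** (-min(bitscore / 2.5, 180.0))
            subj_no += 1
            rows.append(
                "\t".join(
                    [
                        call.gene_id,
                        f"WP_{subj_no:09d}.1",
                        f"{pct_id:.1f}",
                        str(aln),
                        str(int(aln * (100 - pct_id) / 100)),
                        "0",
                        "1",
                        str(aln),
                        "1",
                        str(aln),
                        f"{evalue:.2e}",
                        f"{bitscore:.1f}",
                        f"{name} [{sp}]",
                        sp,
                    ]
                )
            )
            bitscore -= float(rng.uniform(5, 30))
            bitscore = max(bitscore, 25.0)
    return "\n".join(rows) + ("\n" if rows else "")


def simulate_domain_hits(truth: list[GeneCall], spec: FixtureSpec) -> str:
    """Emit an InterProScan-style TSV giving ~25% of CDS genes one domain."""
    rng = _rng(spec, 3)
    rows: list[str] = []
    for call in truth:
        if call.feature_type != "CDS" or rng.random() >= 0.25:
            continue
        acc, desc, ipr = DOMAIN_POOL[int(rng.integers(0, len(DOMAIN_POOL)))]
        aa_len = call.length // 3
        go = "GO:0005524|GO:0016887" if rng.random() < 0.5 else "-"
        rows.append(
            "\t".join(
                [
                    call.gene_id,
                    "0" * 32,
                    str(aa_len),
                    "Pfam",
                    acc,
                    desc,
                    "5",
                    str(max(6, aa_len - 5)),
                    "1.0e-20",
                    "T",
                    "01-01-2020",
                    ipr,
                    desc,
                    go,
                ]
            )
        )
    return "\n".join(rows) + ("\n" if rows else "")


def predictor_call_sets(truth: list[GeneCall], spec: FixtureSpec) -> dict[str, list[GeneCall]]:
    """Derive three imperfect ab initio predictor outputs from the truth.

    predA reproduces every CDS exactly; predB shifts ~20% of starts
    inward by 3 nt; predC misses ~10% of genes.  A shared-stop majority
    vote over the three therefore recovers the true gene set exactly.
    """
    rng = _rng(spec, 4)
    cds = [c for c in truth if c.feature_type == "CDS"]
    out: dict[str, list[GeneCall]] = {"predA": [], "predB": [], "predC": []}
    for call in cds:
        out["predA"].append(replace(call, source="predA"))
        b = replace(call, source="predB")
        if rng.random() < 0.2 and call.length >= 99:
            iv = call.interval
            if call.strand == "+":
                iv = GenomicInterval(iv.contig_id, iv.start + 3, iv.end, "+")
            else:
                iv = GenomicInterval(iv.contig_id, iv.start, iv.end - 3, "-")
            b = replace(b, interval=iv)
        out["predB"].append(b)
        if rng.random() >= 0.1:
            out["predC"].append(replace(call, source="predC"))
    return out


def write_fixture_dir(spec: FixtureSpec, outdir: str | Path) -> dict:
    """Materialise a full fixture directory and return its manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs, truth = simulate_annotated_genome(spec)
    test, expected = perturb_annotation(truth, spec)

    records = [
        SeqRecord(Seq(seq), id=cid, description="synthetic contig") for cid, seq in contigs.items()
    ]
    buf = StringIO()
    seqio_write(records, buf, "fasta")
    (outdir / "genome.fasta").write_text(buf.getvalue())

    (outdir / "truth.gff3").write_text(write_gff3(truth))
    (outdir / "test.gff3").write_text(write_gff3(test))
    rna = [c for c in truth if c.feature_type in ("rRNA", "tRNA")]
    (outdir / "rna.gff3").write_text(write_gff3(rna))
    for name, calls in predictor_call_sets(truth, spec).items():
        (outdir / f"{name}.gff3").write_text(write_gff3(calls))
    (outdir / "homology_nr.tsv").write_text(simulate_homology_hits(truth, spec))
    (outdir / "domains.tsv").write_text(simulate_domain_hits(truth, spec))

    manifest = {
        "seed": spec.seed,
        "n_genes": spec.n_genes,
        "n_cds": sum(1 for c in truth if c.feature_type == "CDS"),
        "n_rna": len(rna),
        "expected_benchmark": expected,
        "planted_majority_species": max(spec.species_mix, key=lambda sf: sf[1])[0],
    }
    (outdir / "expected.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
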