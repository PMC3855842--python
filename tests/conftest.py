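"""Shared test helpers: tiny random annotation generators and file writers."""

from __future__ import annotations

import numpy as np
import pytest

from prokann.model import GeneCall, GenomicInterval


def make_call(
    contig="c1",
    start=100,
    end=400,
    strand="+",
    ftype="CDS",
    gene_id="g1",
    source="test",
    **kw,
):
    return GeneCall(
        gene_id=gene_id,
        interval=GenomicInterval(contig, start, end, strand),
        feature_type=ftype,
        source=source,
        **kw,
    )


def random_annotation(rng: np.random.Generator, n: int | None = None) -> list[GeneCall]:
    """A random (possibly overlapping) mixed-type annotation for round trips."""
    n = int(rng.integers(1, 20)) if n is None else n
    calls = []
    for i in range(n):
        start = int(rng.integers(1, 5000))
        length = int(rng.integers(60, 2000))
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        ftype = ["CDS", "CDS", "CDS", "rRNA", "tRNA"][int(rng.integers(0, 5))]
        calls.append(
            make_call(
                contig=f"c{int(rng.integers(1, 4))}",
                start=start,
                end=start + length - 1,
                strand=strand,
                ftype=ftype,
                gene_id=f"g{i + 1:03d}",
                source="randgen",
                rna_subtype="tRNA-Ala" if ftype == "tRNA" else None,
            )
        )
    return calls


@pytest.fixture
def tiny_gff3(tmp_path):
    path = tmp_path / "tiny.gff3"
    path.write_text(
        "##gff-version 3\n"
        "c1\tprodigal\tCDS\t100\t400\t.\t+\t.\tID=g1\n"
    )
    return path
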