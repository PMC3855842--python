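"""Readers and writers for every on-disk format the pipeline touches.

Formats handled here: GFF3 and NCBI feature-table (TBL) gene calls,
12(+2)-column tab-separated homology tables, InterProScan TSV domain
scans, the Krona text import format, and a schema-validated warehouse
XML.  Coordinates are normalised to 1-based inclusive on read; the TBL
reader/writer own the minus-strand coordinate reversal that format uses.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

from lxml import etree

from .model import (
    DomainHit,
    FEATURE_TYPES,
    GeneCall,
    GenomicInterval,
    HierarchyNode,
    HomologyHit,
    ProductAssignment,
    hit_rank_key,
)

log = logging.getLogger(__name__)

__all__ = [
    "read_features",
    "write_gff3",
    "write_feature_table",
    "read_homology",
    "read_domains",
    "write_warehouse_xml",
    "validate_warehouse_xml",
    "write_hierarchy_text",
    "DEFAULT_XML_MODEL",
]


# ---------------------------------------------------------------------------
# gene calls: GFF3 and TBL


def read_features(path: str | Path, dialect: str = "gff3") -> list[GeneCall]:
    """Read gene calls from a GFF3 or NCBI feature-table (TBL) file.

    Records of types other than CDS/rRNA/tRNA (and, for TBL, their paired
    ``gene`` lines) are skipped with a warning.  Minus-strand TBL records,
    written with reversed coordinates on disk, come back normalised to
    ``start <= end`` with strand ``-``.  Input order is preserved.
    """
    path = Path(path)
    if dialect == "gff3":
        return _read_gff3(path)
    if dialect == "tbl":
        return _read_tbl(path)
    raise ValueError(f"unsupported dialect {dialect!r}")


def _parse_gff3_attrs(field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in field.strip().split(";"):
        part = part.strip()
        if not part or part == ".":
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def _read_gff3(path: Path) -> list[GeneCall]:
    calls: list[GeneCall] = []
    auto = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):  # trailing FASTA section
                break
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(
                    f"{path}:{lineno}: malformed GFF3 line "
                    f"(expected 9 tab-separated columns, got {len(cols)})"
                )
            seqid, source, ftype, start_s, end_s, score_s, strand, _phase, attr_s = cols
            if ftype not in FEATURE_TYPES:
                log.warning("%s:%d: skipping feature of type %r", path, lineno, ftype)
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            score = None if score_s in (".", "") else float(score_s)
            attrs = _parse_gff3_attrs(attr_s)
            gene_id = attrs.get("ID")
            if gene_id is None:
                auto += 1
                gene_id = f"{seqid}_f{auto}"
            try:
                interval = GenomicInterval(seqid, start, end, strand)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            calls.append(
                GeneCall(
                    gene_id=gene_id,
                    interval=interval,
                    feature_type=ftype,
                    source=source if source != "." else "unknown",
                    rna_subtype=attrs.get("rna_subtype") or None,
                    score=score,
                    partial=attrs.get("partial") == "true",
                )
            )
    return calls


def write_gff3(calls: list[GeneCall]) -> str:
    """Render gene calls as GFF3 text (one feature line per call)."""
    lines = ["##gff-version 3"]
    for c in calls:
        attrs = [f"ID={c.gene_id}"]
        if c.rna_subtype:
            attrs.append(f"rna_subtype={c.rna_subtype}")
        if c.partial:
            attrs.append("partial=true")
        score = "." if c.score is None else format(c.score, "g")
        lines.append(
            "\t".join(
                [
                    c.contig_id,
                    c.source,
                    c.feature_type,
                    str(c.start),
                    str(c.end),
                    score,
                    c.strand,
                    ".",
                    ";".join(attrs),
                ]
            )
        )
    return "\n".join(lines) + "\n"


_TBL_TYPES = FEATURE_TYPES + ("gene",)


def _read_tbl(path: Path) -> list[GeneCall]:
    calls: list[GeneCall] = []
    contig: str | None = None
    # pending ``gene`` record waiting for its typed partner line
    pending: tuple[GenomicInterval, dict[str, str]] | None = None
    current: GeneCall | None = None  # typed record accepting qualifiers
    auto = 0

    def flush_pending() -> None:
        nonlocal pending, auto
        if pending is None:
            return
        interval, quals = pending
        auto += 1
        calls.append(
            GeneCall(
                gene_id=quals.get("locus_tag", f"{interval.contig_id}_f{auto}"),
                interval=interval,
                feature_type="CDS",
                source="tbl",
            )
        )
        pending = None

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">Feature"):
                flush_pending()
                current = None
                parts = line.split()
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: feature header without contig id")
                contig = parts[1]
                continue
            cols = line.split("\t")
            if cols[0] == "" and len(cols) >= 5:
                # qualifier continuation line: \t\t\tkey\tvalue
                key, value = cols[3], cols[4]
                if pending is not None:
                    pending[1][key] = value
                elif current is not None:
                    if key == "locus_tag":
                        calls[-1] = calls[-1].with_id(value)
                        current = calls[-1]
                    elif key == "product" and current.feature_type in ("rRNA", "tRNA"):
                        from dataclasses import replace

                        calls[-1] = replace(calls[-1], rna_subtype=value)
                        current = calls[-1]
                continue
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: malformed TBL line")
            if contig is None:
                raise ValueError(f"{path}:{lineno}: record before any >Feature header")
            raw_start_s, raw_end_s, ftype = cols[0], cols[1], cols[2]
            try:
                raw_start, raw_end = int(raw_start_s.lstrip("<>")), int(raw_end_s.lstrip("<>"))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            partial = raw_start_s[0] in "<>" or raw_end_s[0] in "<>"
            if raw_start <= raw_end:
                interval = GenomicInterval(contig, raw_start, raw_end, "+")
            else:  # minus strand is written reversed in TBL
                interval = GenomicInterval(contig, raw_end, raw_start, "-")
            if ftype == "gene":
                flush_pending()
                current = None
                pending = (interval, {})
            elif ftype in FEATURE_TYPES:
                if pending is not None and pending[0] == interval:
                    gene_id = pending[1].get("locus_tag")
                    pending = None
                else:
                    flush_pending()
                    gene_id = None
                if gene_id is None:
                    auto += 1
                    gene_id = f"{contig}_f{auto}"
                current = GeneCall(
                    gene_id=gene_id,
                    interval=interval,
                    feature_type=ftype,
                    source="tbl",
                    partial=partial,
                )
                calls.append(current)
            else:
                flush_pending()
                current = None
                log.warning("%s:%d: skipping TBL record of type %r", path, lineno, ftype)
    flush_pending()
    return calls


def write_feature_table(
    calls: list[GeneCall], products: list[ProductAssignment] | None = None
) -> str:
    """Render gene calls as an NCBI feature table (TBL).

    Every CDS must carry a product assignment (``"hypothetical protein"``
    at minimum).  Minus-strand records are written with reversed
    coordinates, per the TBL convention.
    """
    by_gene = {p.gene_id: p for p in (products or [])}
    lines: list[str] = []
    contig: str | None = None
    for c in calls:
        if c.feature_type == "CDS" and c.gene_id not in by_gene:
            raise ValueError(f"CDS {c.gene_id} has no product assignment")
        if c.contig_id != contig:
            contig = c.contig_id
            lines.append(f">Feature {contig}")
        a, b = (c.start, c.end) if c.strand == "+" else (c.end, c.start)
        lines.append(f"{a}\t{b}\tgene")
        lines.append(f"\t\t\tlocus_tag\t{c.gene_id}")
        lines.append(f"{a}\t{b}\t{c.feature_type}")
        if c.feature_type == "CDS":
            lines.append(f"\t\t\tproduct\t{by_gene[c.gene_id].product}")
        elif c.rna_subtype:
            lines.append(f"\t\t\tproduct\t{c.rna_subtype}")
    return "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# homology tables (12-column tabular + optional description/species columns)


def read_homology(
    path: str | Path,
    db: str,
    query_lengths: dict[str, int] | None = None,
) -> dict[str, list[HomologyHit]]:
    """Read a 12(+2)-column tab-separated homology table.

    Columns: query, subject, %identity, alignment length, mismatches,
    gap opens, qstart, qend, sstart, send, e-value, bitscore, then an
    optional subject description (13) and species (14).  Hits come back
    grouped per query and ranked by (bitscore desc, e-value asc,
    subject asc).  ``query_cov`` is filled in only when ``query_lengths``
    supplies the query's length.
    """
    path = Path(path)
    hits: dict[str, list[HomologyHit]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 12 tab-separated columns, got {len(cols)}"
                )
            try:
                pct_id = float(cols[2])
                aln_len = int(cols[3])
                qstart, qend = int(cols[6]), int(cols[7])
                evalue = float(cols[10])
                bitscore = float(cols[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric numeric field") from exc
            query = cols[0]
            cov = None
            if query_lengths and query in query_lengths:
                cov = (qend - qstart + 1) / query_lengths[query]
            desc = cols[12] if len(cols) > 12 else ""
            species = cols[13] if len(cols) > 13 and cols[13] not in ("", "-") else None
            hits.setdefault(query, []).append(
                HomologyHit(
                    query_id=query,
                    db=db,
                    subject_id=cols[1],
                    pct_identity=pct_id,
                    aln_length=aln_len,
                    evalue=evalue,
                    bitscore=bitscore,
                    subject_desc=desc,
                    species=species,
                    query_cov=cov,
                )
            )
    for query in hits:
        hits[query].sort(key=hit_rank_key)
    return hits


# ---------------------------------------------------------------------------
# InterProScan TSV

_GO_RE = re.compile(r"GO:\d{7}")


def read_domains(path: str | Path) -> list[DomainHit]:
    """Read an InterProScan-style TSV of protein signature hits.

    Standard column layout (query, md5, length, analysis, signature
    accession, signature description, start, stop, e-value, status, date,
    InterPro accession, InterPro description, GO terms); GO terms may be
    pipe- or comma-separated and are deduplicated per row.  ``-`` marks a
    missing value throughout.
    """
    path = Path(path)
    out: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 9 tab-separated columns, got {len(cols)}"
                )
            ev_s = cols[8]
            if ev_s in ("-", ""):
                evalue = None
            else:
                try:
                    evalue = float(ev_s)
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: non-numeric e-value") from exc
            ipr = cols[11] if len(cols) > 11 and cols[11] not in ("-", "") else None
            go_field = cols[13] if len(cols) > 13 else ""
            gos: list[str] = []
            for term in _GO_RE.findall(go_field):
                if term not in gos:
                    gos.append(term)
            out.append(
                DomainHit(
                    query_id=cols[0],
                    analysis=cols[3],
                    signature_acc=cols[4],
                    signature_desc=cols[5] if cols[5] != "-" else "",
                    ipr_acc=ipr,
                    go_terms=tuple(gos),
                    evalue=evalue,
                )
            )
    return out


# ---------------------------------------------------------------------------
# warehouse XML

# Minimal explicit schema for the warehouse export: entity name -> allowed
# attribute names.  Functional annotations are emitted as identifier
# references only; the warehouse resolves names against its own ontology
# and pathway sources.
DEFAULT_XML_MODEL: dict[str, set[str]] = {
    "organism": {"name"},
    "contig": {"id"},
    "gene": {"id", "contig", "start", "end", "strand", "featureType"},
    "protein": {"gene", "product", "source", "status"},
    "goTermRef": {"id"},
    "pathwayRef": {"id"},
    "domainRef": {"id"},
    "homologyRef": {"db", "subject"},
}


def write_warehouse_xml(
    calls: list[GeneCall],
    products: list[ProductAssignment] | None = None,
    hits: dict[str, list[HomologyHit]] | None = None,
    domains: list[DomainHit] | None = None,
    model: dict[str, set[str]] | None = None,
    organism_name: str = "organism",
) -> str:
    """Serialise an annotation set to schema-validated warehouse XML.

    Every element and attribute must exist in ``model``; a violation is an
    error, never a warning.  Cross-references (GO terms, pathways,
    domains, homology subjects) carry identifiers only.
    """
    model = model if model is not None else DEFAULT_XML_MODEL
    by_gene = {p.gene_id: p for p in (products or [])}
    dom_by_gene: dict[str, list[DomainHit]] = {}
    for d in domains or []:
        dom_by_gene.setdefault(d.query_id, []).append(d)

    root = etree.Element("organism", name=organism_name)
    contig_elems: dict[str, etree._Element] = {}
    for c in calls:
        if c.contig_id not in contig_elems:
            contig_elems[c.contig_id] = etree.SubElement(root, "contig", id=c.contig_id)
        gene = etree.SubElement(
            root,
            "gene",
            id=c.gene_id,
            contig=c.contig_id,
            start=str(c.start),
            end=str(c.end),
            strand=c.strand,
            featureType=c.feature_type,
        )
        prod = by_gene.get(c.gene_id)
        if prod is not None:
            protein = etree.SubElement(
                gene,
                "protein",
                gene=c.gene_id,
                product=prod.product,
                source=prod.source,
                status=prod.status,
            )
            seen_go: set[str] = set()
            for d in dom_by_gene.get(c.gene_id, []):
                if d.ipr_acc:
                    etree.SubElement(protein, "domainRef", id=d.ipr_acc)
                for go in d.go_terms:
                    if go not in seen_go:
                        seen_go.add(go)
                        etree.SubElement(protein, "goTermRef", id=go)
            for h in (hits or {}).get(c.gene_id, [])[:1]:
                etree.SubElement(protein, "homologyRef", db=h.db, subject=h.subject_id)
    text = etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode("utf-8")
    validate_warehouse_xml(text, model)
    return text


def validate_warehouse_xml(xml_text: str, model: dict[str, set[str]]) -> None:
    """Check every element/attribute of ``xml_text`` against ``model``.

    Raises ``ValueError`` naming the offending entity and attribute.
    """
    root = etree.fromstring(xml_text.encode("utf-8"))
    for elem in root.iter():
        if elem.tag not in model:
            raise ValueError(f"entity {elem.tag!r} not in warehouse model")
        allowed = model[elem.tag]
        for attr in elem.attrib:
            if attr not in allowed:
                raise ValueError(
                    f"attribute {attr!r} not allowed on entity {elem.tag!r}"
                )


# ---------------------------------------------------------------------------
# Krona text


def write_hierarchy_text(root: HierarchyNode) -> str:
    """Render a summary tree in the Krona text-import format.

    One row per leaf: ``count<TAB>level1<TAB>level2...`` (path from the
    root down), rows sorted lexicographically by path.  A childless root
    with zero count renders as empty output.
    """
    rows: list[tuple[tuple[str, ...], int]] = []

    def walk(node: HierarchyNode, path: tuple[str, ...]) -> None:
        if node.count < 0:
            raise ValueError(f"negative count at node {node.name!r}")
        path = path + (node.name,)
        if not node.children:
            rows.append((path, node.count))
        else:
            for child in node.children:
                walk(child, path)

    if not root.children and root.count == 0:
        return ""
    walk(root, ())
    rows.sort(key=lambda r: r[0])
    return "".join(f"{count}\t" + "\t".join(path) + "\n" for path, count in rows)
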