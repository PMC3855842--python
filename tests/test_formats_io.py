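"""I/O contracts: GFF3/TBL parsing and writing, homology and domain
tables, warehouse XML validation, Krona text."""

import numpy as np
import pytest

from conftest import make_call, random_annotation
from prokann import formats_io
from prokann.model import HierarchyNode, ProductAssignment


# ---------------------------------------------------------------------------
# GFF3


class TestGff3:
    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.gff3"
        p.write_text("")
        assert formats_io.read_features(p, "gff3") == []

    def test_single_record_field_mapping(self, tiny_gff3):
        (call,) = formats_io.read_features(tiny_gff3, "gff3")
        assert (call.contig_id, call.start, call.end, call.strand) == ("c1", 100, 400, "+")
        assert call.feature_type == "CDS"
        assert call.gene_id == "g1"
        assert call.source == "prodigal"

    def test_malformed_line_error_names_line_number(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text("c1\tx\tCDS\t100\t400\t.\t+\t.\tID=g1\nc1\tx\tCDS\t100\n")
        with pytest.raises(ValueError, match=":2"):
            formats_io.read_features(p, "gff3")

    def test_unknown_feature_type_skipped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "mixed.gff3"
        p.write_text(
            "c1\tx\tregion\t1\t999\t.\t+\t.\tID=r\n"
            "c1\tx\tCDS\t100\t400\t.\t+\t.\tID=g1\n"
        )
        with caplog.at_level("WARNING"):
            calls = formats_io.read_features(p, "gff3")
        assert len(calls) == 1
        assert "region" in caplog.text

    def test_unsupported_dialect_rejected(self, tiny_gff3):
        with pytest.raises(ValueError, match="dialect"):
            formats_io.read_features(tiny_gff3, "genbank")


# ---------------------------------------------------------------------------
# TBL


class TestTbl:
    def test_minus_strand_coordinates_normalised(self, tmp_path):
        p = tmp_path / "t.tbl"
        p.write_text(">Feature c1\n400\t100\tgene\n")
        (call,) = formats_io.read_features(p, "tbl")
        assert (call.start, call.end, call.strand) == (100, 400, "-")

    def test_writer_plus_strand_layout(self):
        call = make_call(start=100, end=400, strand="+")
        text = formats_io.write_feature_table(
            [call], [ProductAssignment("g1", "chaperonin GroEL", "nr", "functional")]
        )
        assert "100\t400\tgene" in text
        assert "\t\t\tproduct\tchaperonin GroEL" in text

    def test_writer_minus_strand_reverses_coordinates(self):
        call = make_call(start=100, end=400, strand="-")
        text = formats_io.write_feature_table(
            [call], [ProductAssignment("g1", "hypothetical protein", "none", "hypothetical")]
        )
        assert "400\t100\tgene" in text

    def test_cds_without_product_is_an_error(self):
        with pytest.raises(ValueError, match="g1"):
            formats_io.write_feature_table([make_call()], [])

    def test_round_trip_recovers_calls(self, tmp_path):
        rng = np.random.default_rng(7)
        calls = random_annotation(rng, 12)
        products = [
            ProductAssignment(c.gene_id, "hypothetical protein", "none", "hypothetical")
            for c in calls
            if c.feature_type == "CDS"
        ]
        p = tmp_path / "rt.tbl"
        p.write_text(formats_io.write_feature_table(calls, products))
        back = formats_io.read_features(p, "tbl")
        assert [(c.gene_id, c.contig_id, c.start, c.end, c.strand, c.feature_type) for c in back] \
            == [(c.gene_id, c.contig_id, c.start, c.end, c.strand, c.feature_type) for c in calls]


# ---------------------------------------------------------------------------
# homology tables


def _homology_line(q, s, bits, evalue, aln=100, pct=80.0):
    return "\t".join(
        [q, s, f"{pct}", str(aln), "5", "0", "1", str(aln), "1", str(aln), f"{evalue}", f"{bits}"]
    )


class TestHomology:
    def test_empty_file(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("")
        assert formats_io.read_homology(p, "nr") == {}

    def test_ranked_by_bitscore_desc(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(
            _homology_line("g1", "s1", 200, 1e-40) + "\n" + _homology_line("g1", "s2", 250, 1e-60) + "\n"
        )
        hits = formats_io.read_homology(p, "nr")["g1"]
        assert [h.bitscore for h in hits] == [250.0, 200.0]

    def test_equal_bitscore_tie_broken_by_evalue(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(
            _homology_line("g1", "worse", 200, 1e-40) + "\n" + _homology_line("g1", "better", 200, 1e-50) + "\n"
        )
        hits = formats_io.read_homology(p, "nr")["g1"]
        assert [h.subject_id for h in hits] == ["better", "worse"]

    def test_ranking_invariant_under_row_permutation(self, tmp_path):
        rng = np.random.default_rng(3)
        lines = [
            _homology_line(f"g{rng.integers(1, 4)}", f"s{i}", float(rng.integers(50, 300)),
                           10.0 ** -float(rng.integers(5, 80)))
            for i in range(30)
        ]
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        p1.write_text("\n".join(lines) + "\n")
        shuffled = list(lines)
        rng.shuffle(shuffled)
        p2.write_text("\n".join(shuffled) + "\n")
        h1 = formats_io.read_homology(p1, "nr")
        h2 = formats_io.read_homology(p2, "nr")
        assert h1 == h2

    def test_optional_description_and_species_columns(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(
            _homology_line("g1", "s1", 200, 1e-40)
            + "\tchaperonin GroEL [Escherichia coli]\tEscherichia coli\n"
        )
        (hit,) = formats_io.read_homology(p, "nr")["g1"]
        assert hit.subject_desc == "chaperonin GroEL [Escherichia coli]"
        assert hit.species == "Escherichia coli"

    def test_query_coverage_computed_only_when_length_known(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(_homology_line("g1", "s1", 200, 1e-40, aln=50) + "\n")
        (hit,) = formats_io.read_homology(p, "nr", query_lengths={"g1": 100})["g1"]
        assert hit.query_cov == pytest.approx(0.5)
        (hit,) = formats_io.read_homology(p, "nr")["g1"]
        assert hit.query_cov is None

    def test_non_numeric_field_error_names_line(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(_homology_line("g1", "s1", 200, 1e-40) + "\n"
                     + "g2\ts2\tabc\t100\t5\t0\t1\t100\t1\t100\t1e-5\t50\n")
        with pytest.raises(ValueError, match=":2"):
            formats_io.read_homology(p, "nr")


# ---------------------------------------------------------------------------
# InterProScan TSV


def _ipr_line(q, go="GO:0003677|GO:0005524", ipr="IPR003439"):
    return "\t".join(
        [q, "0" * 32, "300", "Pfam", "PF00005", "ABC transporter", "5", "295",
         "1.0e-20", "T", "01-01-2020", ipr, "ABC transporter", go]
    )


class TestDomains:
    def test_go_terms_split(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text(_ipr_line("g1") + "\n")
        (d,) = formats_io.read_domains(p)
        assert set(d.go_terms) == {"GO:0003677", "GO:0005524"}

    def test_empty_go_field(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text(_ipr_line("g1", go="-") + "\n")
        (d,) = formats_io.read_domains(p)
        assert d.go_terms == ()

    def test_duplicate_go_deduplicated(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text(_ipr_line("g1", go="GO:0005524|GO:0005524") + "\n")
        (d,) = formats_io.read_domains(p)
        assert d.go_terms == ("GO:0005524",)


# ---------------------------------------------------------------------------
# warehouse XML


class TestWarehouseXml:
    def test_empty_annotation_gives_organism_envelope(self):
        text = formats_io.write_warehouse_xml([], organism_name="Salinisphaera shabanensis")
        assert "<organism" in text
        assert "<gene" not in text

    def test_go_reference_is_identifier_only(self, tmp_path):
        call = make_call()
        prod = ProductAssignment("g1", "ABC transporter", "nr", "functional")
        p = tmp_path / "d.tsv"
        p.write_text(_ipr_line("g1", go="GO:0005524") + "\n")
        domains = formats_io.read_domains(p)
        text = formats_io.write_warehouse_xml([call], [prod], {}, domains)
        assert "GO:0005524" in text
        # reference carries the identifier but never a term name/description
        assert 'goTermRef id="GO:0005524"' in text.replace("  ", " ")
        assert "ATP binding" not in text

    def test_attribute_outside_model_is_an_error(self):
        restricted = {k: set(v) for k, v in formats_io.DEFAULT_XML_MODEL.items()}
        restricted["gene"] = {"id"}  # forbid coordinates
        with pytest.raises(ValueError, match="gene"):
            formats_io.write_warehouse_xml([make_call()], model=restricted)

    def test_output_revalidates_against_its_model(self):
        calls = random_annotation(np.random.default_rng(5), 8)
        prods = [
            ProductAssignment(c.gene_id, "hypothetical protein", "none", "hypothetical")
            for c in calls
        ]
        text = formats_io.write_warehouse_xml(calls, prods)
        formats_io.validate_warehouse_xml(text, formats_io.DEFAULT_XML_MODEL)


# ---------------------------------------------------------------------------
# Krona text


class TestHierarchyText:
    def test_single_leaf(self):
        root = HierarchyNode("Bacteria", 12, [HierarchyNode("Proteobacteria", 12)])
        assert formats_io.write_hierarchy_text(root) == "12\tBacteria\tProteobacteria\n"

    def test_empty_tree(self):
        assert formats_io.write_hierarchy_text(HierarchyNode("root", 0)) == ""

    def test_two_leaves_repeat_parent(self):
        root = HierarchyNode(
            "Bacteria", 5, [HierarchyNode("Bacilli", 2), HierarchyNode("Clostridia", 3)]
        )
        text = formats_io.write_hierarchy_text(root)
        assert text == "2\tBacteria\tBacilli\n3\tBacteria\tClostridia\n"

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            formats_io.write_hierarchy_text(HierarchyNode("r", -1))


# ---------------------------------------------------------------------------
# GFF3 round trip (property over random annotations)


@pytest.mark.parametrize("seed", range(10))
def test_gff3_round_trip_identity(tmp_path, seed):
    rng = np.random.default_rng(seed)
    calls = random_annotation(rng)
    p = tmp_path / "rt.gff3"
    text = formats_io.write_gff3(calls)
    p.write_text(text)
    back = formats_io.read_features(p, "gff3")
    assert back == calls
    # writing again is byte-identical
    assert formats_io.write_gff3(back) == text
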