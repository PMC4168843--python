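import pytest
from hypothesis import given, settings, strategies as st

from mitobarcode import seqio
from mitobarcode.errors import (
    AlignmentShapeError,
    BoundsError,
    FormatError,
    LabelParseError,
    SerializationError,
)
from mitobarcode.seqio import (
    RegionAnnotation,
    TreeNode,
    newick_string,
    parse_taxon_label,
    read_fasta,
    read_nexus_alignment,
    read_regions,
    write_fasta,
    write_nexus,
)


class TestFasta:
    def test_parses_records_in_order(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nACGT\n>b\nAC-T\n")
        aln = read_fasta(p)
        assert aln.labels == ["a", "b"]
        assert aln.length == 4
        assert aln[1].sequence == "AC-T"

    def test_normalizes_case_and_rna(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nacgu\n>b\nACGT\n")
        assert read_fasta(p)[0].sequence == "ACGT"

    def test_unequal_lengths_name_offender(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nACGT\n>b\nACG\n")
        with pytest.raises(AlignmentShapeError, match="b"):
            read_fasta(p)

    def test_empty_file_is_format_error(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("")
        with pytest.raises(FormatError):
            read_fasta(p)

    def test_roundtrip(self, tmp_path, tiny_alignment):
        p = tmp_path / "rt.fasta"
        write_fasta(tiny_alignment, p)
        back = read_fasta(p)
        assert back.labels == tiny_alignment.labels
        assert [r.sequence for r in back] == [r.sequence for r in tiny_alignment]


class TestNexus:
    def test_sequential(self, tmp_path):
        p = tmp_path / "a.nex"
        p.write_text(
            "#NEXUS\nBEGIN DATA;\nDIMENSIONS NTAX=2 NCHAR=8;\n"
            "FORMAT DATATYPE=DNA MISSING=? GAP=-;\nMATRIX\n"
            "taxA ACGTACGT\ntaxB ACGTAC-T\n;\nEND;\n"
        )
        aln = read_nexus_alignment(p)
        assert aln.labels == ["taxA", "taxB"]
        assert aln.length == 8

    def test_interleaved_matches_independent_parser(self, tmp_path):
        import dendropy

        p = tmp_path / "i.nex"
        p.write_text(
            "#NEXUS\nBEGIN DATA;\nDIMENSIONS NTAX=3 NCHAR=8;\n"
            "FORMAT DATATYPE=DNA INTERLEAVE=YES MISSING=? GAP=-;\nMATRIX\n"
            "taxA ACGT\ntaxB ACGA\ntaxC AC-T\n\n"
            "taxA TTTT\ntaxB TTTA\ntaxC TT-T\n;\nEND;\n"
        )
        aln = read_nexus_alignment(p)
        ref = dendropy.DnaCharacterMatrix.get(path=str(p), schema="nexus")
        assert aln.length == 8
        for taxon in ref.taxon_namespace:
            mine = next(r for r in aln if r.label == taxon.label)
            assert mine.sequence == str(ref[taxon]).upper()

    def test_quoted_label_preserved(self, tmp_path):
        p = tmp_path / "q.nex"
        p.write_text(
            "#NEXUS\nBEGIN DATA;\nDIMENSIONS NTAX=2 NCHAR=4;\n"
            "FORMAT DATATYPE=DNA;\nMATRIX\n"
            "'Agaricia fragilis' ACGT\ntaxB ACGA\n;\nEND;\n"
        )
        assert "Agaricia fragilis" in read_nexus_alignment(p).labels

    def test_missing_matrix_block(self, tmp_path):
        p = tmp_path / "bad.nex"
        p.write_text("#NEXUS\nBEGIN TREES;\nEND;\n")
        with pytest.raises(FormatError):
            read_nexus_alignment(p)

    def test_write_read_roundtrip(self, tmp_path, tiny_alignment):
        p = tmp_path / "rt.nex"
        write_nexus(tiny_alignment, p)
        back = read_nexus_alignment(p)
        assert back.labels == tiny_alignment.labels
        assert [r.sequence for r in back] == [r.sequence for r in tiny_alignment]


class TestTaxonLabels:
    @pytest.mark.parametrize(
        "label, genus, epithet, qualifier",
        [
            ("Agaricia_fragilis_KM051016", "Agaricia", "fragilis", "none"),
            ("Agaricia fragilis", "Agaricia", "fragilis", "none"),
            ("Discosoma sp.", "Discosoma", None, "sp"),
            ("Discosoma_sp", "Discosoma", None, "sp"),
            ("Pavona_cf._varians", "Pavona", "varians", "cf"),
            ("Pavona aff. varians AB12345", "Pavona", "varians", "aff"),
            ("Leptoseris_sp._JX123456", "Leptoseris", None, "sp"),
            ("Montastraea", "Montastraea", None, "none"),
        ],
    )
    def test_parse(self, label, genus, epithet, qualifier):
        name = parse_taxon_label(label)
        assert (name.genus, name.epithet, name.qualifier) == (genus, epithet, qualifier)
        assert name.raw_label == label

    def test_no_alphabetic_token_fails(self):
        with pytest.raises(LabelParseError):
            parse_taxon_label("12345_678")
        with pytest.raises(LabelParseError):
            parse_taxon_label("   ")

    @given(st.text(alphabet="ABCabc_ .0123456789", min_size=1, max_size=30))
    @settings(max_examples=200, deadline=None)
    def test_total_and_deterministic_on_alphabetic_labels(self, label):
        try:
            first = parse_taxon_label(label)
        except LabelParseError:
            assert not any(
                t.rstrip(".").isalpha() for t in label.replace("_", " ").split()
            )
            return
        assert parse_taxon_label(label) == first
        assert first.genus


class TestRegions:
    def test_bed_halfopen(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("chrM\t100\t600\tCYB\nchrM\t700\t900\trnl\tribosomal\n")
        regions = read_regions(p)
        assert (regions[0].start, regions[0].end) == (100, 600)
        assert regions[0].category == "coding"
        assert regions[1].category == "ribosomal"

    def test_gff_converts_coordinates(self, tmp_path):
        p = tmp_path / "r.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chrM\tx\tCDS\t101\t600\t.\t+\t0\tID=CYB\n"
            "chrM\tx\trRNA\t701\t900\t.\t+\t.\tName=rnl\n"
        )
        regions = read_regions(p)
        assert (regions[0].start, regions[0].end) == (100, 600)
        assert regions[0].category == "coding"
        assert (regions[1].name, regions[1].category) == ("rnl", "ribosomal")

    def test_empty_interval_rejected(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("chrM\t100\t100\tX\n")
        with pytest.raises(BoundsError):
            read_regions(p)

    def test_bounds_checked_against_length(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("chrM\t100\t600\tCYB\n")
        with pytest.raises(BoundsError):
            read_regions(p, seq_length=500)

    def test_bed_roundtrip_involutive(self, tmp_path):
        regions = [
            RegionAnnotation("CYB", 100, 600, "coding"),
            RegionAnnotation("rnl", 700, 900, "ribosomal"),
        ]
        p = tmp_path / "rt.bed"
        seqio.write_regions_bed(regions, p)
        assert read_regions(p) == regions


class TestNewick:
    def test_three_tip_star(self):
        tree = TreeNode(children=[
            (TreeNode(label="a"), 1.0),
            (TreeNode(label="b"), 2.0),
            (TreeNode(label="c"), 3.0),
        ])
        assert newick_string(tree) == "(a:1,b:2,c:3);"

    def test_roundtrip_through_dendropy(self, tmp_path):
        import dendropy

        tree = TreeNode(children=[
            (TreeNode(label="a"), 0.1),
            (TreeNode(children=[(TreeNode(label="b"), 0.25),
                                (TreeNode(label="c"), 0.3)]), 0.05),
            (TreeNode(label="Discosoma sp."), 0.7),
        ])
        p = tmp_path / "t.nwk"
        seqio.write_newick(tree, p)
        parsed = dendropy.Tree.get(path=str(p), schema="newick",
                                   preserve_underscores=True)
        assert sorted(l.taxon.label for l in parsed.leaf_node_iter()) == [
            "Discosoma sp.", "a", "b", "c",
        ]
        lengths = sorted(e.length for e in parsed.edges() if e.length is not None)
        assert lengths == [0.05, 0.1, 0.25, 0.3, 0.7]

    def test_label_with_space_quoted(self):
        tree = TreeNode(children=[
            (TreeNode(label="Discosoma sp."), 1.0),
            (TreeNode(label="b"), 1.0),
            (TreeNode(label="c"), 1.0),
        ])
        assert "'Discosoma sp.'" in newick_string(tree)

    def test_duplicate_tips_rejected(self):
        tree = TreeNode(children=[
            (TreeNode(label="a"), 1.0),
            (TreeNode(label="a"), 1.0),
            (TreeNode(label="c"), 1.0),
        ])
        with pytest.raises(SerializationError):
            newick_string(tree)
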