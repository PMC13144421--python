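"""Format boundary behaviour: GFF3/FASTA/RepeatMasker/TSV readers and writers."""

import pandas as pd
import pytest

from diploscan.genome_io import (
    GeneModel,
    GenomeIOError,
    read_family_table,
    read_fasta,
    read_gff3,
    read_repeatmasker_out,
    read_feature_matrix,
    write_feature_matrix,
    write_gff3,
)
from diploscan.simulate import write_simulation

GFF_SINGLE = """##gff-version 3
chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1
chr1\tsrc\tmRNA\t101\t200\t.\t+\t.\tID=g1.t1;Parent=g1
chr1\tsrc\texon\t101\t200\t.\t+\t.\tID=g1.t1.e1;Parent=g1.t1
chr1\tsrc\tCDS\t101\t200\t.\t+\t0\tID=g1.t1.c1;Parent=g1.t1
"""

GFF_MINUS = """##gff-version 3
chr1\tsrc\tgene\t1001\t2000\t.\t-\t.\tID=g2
chr1\tsrc\tmRNA\t1001\t2000\t.\t-\t.\tID=g2.t1;Parent=g2
chr1\tsrc\texon\t1001\t1100\t.\t-\t.\tID=e1;Parent=g2.t1
chr1\tsrc\texon\t1301\t1400\t.\t-\t.\tID=e2;Parent=g2.t1
chr1\tsrc\texon\t1901\t2000\t.\t-\t.\tID=e3;Parent=g2.t1
"""


class TestGFF3:
    def test_one_based_closed_to_half_open(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF_SINGLE)
        genes = read_gff3(p)
        assert len(genes) == 1
        assert genes[0].exons == [(100, 200)]
        assert genes[0].cds == [(100, 200)]
        assert genes[0].strand == "+"

    def test_minus_strand_exons_in_genomic_order(self, tmp_path):
        p = tmp_path / "b.gff3"
        p.write_text(GFF_MINUS)
        (g,) = read_gff3(p)
        assert g.strand == "-"
        assert g.exons == [(1000, 1100), (1300, 1400), (1900, 2000)]

    def test_exon_without_parent_errors_with_line(self, tmp_path):
        p = tmp_path / "c.gff3"
        p.write_text("chr1\ts\texon\t1\t10\t.\t+\t.\tID=orphan\n")
        with pytest.raises(GenomeIOError, match="line 1"):
            read_gff3(p)

    def test_undefined_parent_errors(self, tmp_path):
        p = tmp_path / "d.gff3"
        p.write_text(
            "chr1\ts\tmRNA\t1\t10\t.\t+\t.\tID=t1;Parent=nope\n"
        )
        with pytest.raises(GenomeIOError, match="nope"):
            read_gff3(p)

    def test_cds_outside_exons_rejected(self, tmp_path):
        p = tmp_path / "e.gff3"
        p.write_text(
            "chr1\ts\tgene\t1\t100\t.\t+\t.\tID=g\n"
            "chr1\ts\tmRNA\t1\t100\t.\t+\t.\tID=t;Parent=g\n"
            "chr1\ts\texon\t1\t50\t.\t+\t.\tID=e;Parent=t\n"
            "chr1\ts\tCDS\t40\t80\t.\t+\t0\tID=c;Parent=t\n"
        )
        with pytest.raises(GenomeIOError, match="outside exons"):
            read_gff3(p)

    def test_roundtrip_bit_exact(self, tmp_path, rich_sim):
        _, bundles, _ = rich_sim
        focal = bundles["focal"]
        p1 = tmp_path / "one.gff3"
        write_gff3(focal.genes, p1)
        genes = read_gff3(p1)
        p2 = tmp_path / "two.gff3"
        write_gff3(genes, p2)
        assert p1.read_text() == p2.read_text()
        by_id = {g.gene_id: g for g in genes}
        for g in focal.genes:
            r = by_id[g.gene_id]
            assert (r.chromosome, r.strand, r.exons, r.cds) == (
                g.chromosome, g.strand, g.exons, g.cds,
            )

    def test_total_exonic_length_matches_printed_spans(self, tmp_path):
        p = tmp_path / "f.gff3"
        p.write_text(GFF_MINUS)
        (g,) = read_gff3(p)
        printed = (1100 - 1001 + 1) + (1400 - 1301 + 1) + (2000 - 1901 + 1)
        assert g.exonic_length == printed


RM_OUT = """   SW  perc perc perc  query      position in query    matching repeat
score  div. del. ins.  sequence    begin     end    (left)    repeat  class/family  begin  end (left)   ID

  225   5.2 0.0 0.0  chr1 1001 2000 (0) + TE_1 LTR/Gypsy 1 1000 (0) 1
  310  12.0 0.0 0.0  chr1 3001 3300 (0) + TE_2 LINE/L1 1 300 (0) 2
  100  27.5 0.0 0.0  chr2 11 210 (0) + TE_3 DNA/hAT 1 200 (0) 3
"""


class TestRepeatMasker:
    def test_row_parsing(self, tmp_path):
        p = tmp_path / "r.out"
        p.write_text(RM_OUT)
        feats = read_repeatmasker_out(p)
        assert feats[0].start == 1000 and feats[0].end == 2000
        assert feats[0].class_label == "LTR/Gypsy"
        assert feats[0].divergence_pct == 5.2

    def test_header_only_yields_nothing(self, tmp_path):
        p = tmp_path / "h.out"
        p.write_text(RM_OUT.split("\n\n")[0] + "\n\n")
        assert read_repeatmasker_out(p) == []

    def test_total_span_matches_hand_sum(self, tmp_path):
        p = tmp_path / "r.out"
        p.write_text(RM_OUT)
        feats = read_repeatmasker_out(p)
        assert len(feats) == 3
        assert sum(f.length for f in feats) == 1000 + 300 + 200

    def test_non_numeric_coordinates_error(self, tmp_path):
        p = tmp_path / "bad.out"
        p.write_text("  225 5.2 0.0 0.0  chr1 xx 2000 (0) + TE LTR/Gypsy 1 1000 (0) 1\n")
        with pytest.raises(GenomeIOError, match="line 1"):
            read_repeatmasker_out(p)


FAM_TSV = "family_id\tspecies_or_group\tgene_id\nf1\tsp1\tg1\nf1\tsp1\tg2\nf1\tsp2\tg3\nf2\tsp1\tg4\nf2\tsp2\tg5\nf2\tsp2\tg6\n"


class TestFamilyTable:
    def test_two_families(self, tmp_path):
        p = tmp_path / "fam.tsv"
        p.write_text(FAM_TSV)
        fams = read_family_table(p)
        assert len(fams) == 2
        assert fams["f1"]["sp1"] == {"g1", "g2"}

    def test_duplicate_row_idempotent(self, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        p1.write_text(FAM_TSV)
        p2.write_text(FAM_TSV + "f1\tsp1\tg1\n")
        assert read_family_table(p1) == read_family_table(p2)

    def test_gene_in_two_families_errors(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text(FAM_TSV + "f2\tsp1\tg1\n")
        with pytest.raises(GenomeIOError, match="g1"):
            read_family_table(p)


class TestFeatureMatrix:
    def _records(self):
        from diploscan.pseudogenes import PseudogeneCall

        return [
            PseudogeneCall("c1", 500, 900, "p2", 0.4, 92.0, 0, 1, False, "FRAG", False),
            PseudogeneCall("c1", 100, 400, "p1", 0.9, 97.5, 1, 0, False, "DUP", True, "g1"),
        ]

    def test_roundtrip(self, tmp_path):
        p = tmp_path / "m.tsv"
        write_feature_matrix(self._records(), p)
        df = read_feature_matrix(p)
        assert list(df.columns)[0] == "chromosome"
        assert list(df.start) == [100, 500]  # deterministic row sort
        assert list(df.pg_class) == ["DUP", "FRAG"]

    def test_one_record_two_lines(self, tmp_path):
        p = tmp_path / "one.tsv"
        write_feature_matrix(self._records()[:1], p)
        assert len(p.read_text().strip().split("\n")) == 2

    def test_empty(self, tmp_path):
        p = tmp_path / "empty.tsv"
        write_feature_matrix([], p)
        assert read_feature_matrix(p).empty


def test_simulation_files_read_back_consistently(tmp_path, rich_sim):
    """Emitted FASTA/GFF3/.out/TSV are accepted by the readers and reproduce
    the in-memory bundle."""
    _, bundles, truth = rich_sim
    paths = write_simulation(tmp_path, bundles, truth)
    seqs = read_fasta(paths["genome"])
    assert seqs == bundles["focal"].sequences
    genes = read_gff3(paths["genes"])
    assert len(genes) == len(bundles["focal"].genes)
    feats = read_repeatmasker_out(paths["repeats"])
    assert len(feats) == len(bundles["focal"].repeats)
    fams = read_family_table(paths["families"])
    assert set(fams) == set(bundles["focal"].families) | set(bundles["outgroup"].families)
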