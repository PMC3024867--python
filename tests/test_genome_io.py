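"""I/O round-trips and format-contract checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ptsevo import genome_io
from ptsevo.records import Alignment, ParseError, reverse_complement

SEQ = st.text(alphabet="ACGT", min_size=1, max_size=120)
IDS = st.from_regex(r"[A-Za-z][A-Za-z0-9_]{0,10}", fullmatch=True)


def test_fasta_case_normalized(tmp_path):
    p = tmp_path / "x.fa"
    p.write_text(">g1\nacGT\n")
    assert genome_io.read_fasta(p) == {"g1": "ACGT"}


def test_fasta_duplicate_header_rejected(tmp_path):
    p = tmp_path / "x.fa"
    p.write_text(">g1\nAC\n>g1\nGT\n")
    with pytest.raises(ParseError, match="g1"):
        genome_io.read_fasta(p)


def test_fasta_malformed_header_names_line(tmp_path):
    p = tmp_path / "x.fa"
    p.write_text("ACGT\n>g1\nAC\n")
    with pytest.raises(ParseError, match="line 1"):
        genome_io.read_fasta(p)


def test_fasta_empty_file_warns(tmp_path, caplog):
    p = tmp_path / "x.fa"
    p.write_text("")
    with caplog.at_level("WARNING"):
        assert genome_io.read_fasta(p) == {}
    assert "empty" in caplog.text


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.dictionaries(IDS, SEQ, min_size=1, max_size=6))
def test_fasta_round_trip(tmp_path_factory, seqs):
    p = tmp_path_factory.mktemp("fa") / "rt.fa"
    genome_io.write_fasta(seqs, p)
    assert genome_io.read_fasta(p) == seqs


def test_gff3_minus_strand_reverse_complement(tmp_path):
    contig = "AAAAAAAAAACATAAA"
    gff = tmp_path / "g.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "c1\tsrc\tCDS\t11\t13\t.\t-\t0\tID=x;locus_tag=g1;product=p\n")
    recs = genome_io.read_gene_table(gff, "gff3", contigs={"c1": contig})
    assert len(recs) == 1 and recs[0].nt_seq == "ATG"


def test_gff3_without_cds_is_empty(tmp_path, caplog):
    gff = tmp_path / "g.gff3"
    gff.write_text("##gff-version 3\nc1\tsrc\tgene\t1\t9\t.\t+\t.\tID=g\n")
    with caplog.at_level("WARNING"):
        assert genome_io.read_gene_table(gff, "gff3") == []
    assert "no CDS" in caplog.text


def test_gff3_cds_without_locus_tag_skipped(tmp_path, caplog):
    gff = tmp_path / "g.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "c1\tsrc\tCDS\t1\t6\t.\t+\t0\tID=a\n"
        "c1\tsrc\tCDS\t10\t15\t.\t+\t0\tID=b;locus_tag=g2\n")
    with caplog.at_level("WARNING"):
        recs = genome_io.read_gene_table(gff, "gff3")
    assert [r.gene_id for r in recs] == ["g2"]
    assert "locus_tag" in caplog.text


def test_tsv_gene_table_sorted(tmp_path):
    p = tmp_path / "g.tsv"
    p.write_text("gene_id\tcontig\tstart\tend\tstrand\tproduct\n"
                 "g3\tc2\t5\t10\t+\tx\n"
                 "g2\tc1\t100\t120\t-\ty\n"
                 "g1\tc1\t1\t9\t+\tz\n")
    recs = genome_io.read_gene_table(p, "tsv")
    assert [r.gene_id for r in recs] == ["g1", "g2", "g3"]
    assert recs[0].start <= recs[1].start


def test_gene_table_start_after_end_rejected(tmp_path):
    p = tmp_path / "g.tsv"
    p.write_text("gene_id\tcontig\tstart\tend\tstrand\tproduct\n"
                 "g1\tc1\t10\t5\t+\tx\n")
    with pytest.raises(ParseError, match="start"):
        genome_io.read_gene_table(p, "tsv")


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_minus_strand_extraction_is_reverse_complement(tmp_path_factory, seed):
    rng = np.random.default_rng(seed)
    contig = "".join(rng.choice(list("ACGT"), size=60))
    start, end = 11, 31
    p = tmp_path_factory.mktemp("gff") / "g.tsv"
    p.write_text("gene_id\tcontig\tstart\tend\tstrand\tproduct\n"
                 f"g1\tc1\t{start}\t{end}\t-\tx\n")
    rec = genome_io.read_gene_table(p, "tsv", contigs={"c1": contig})[0]
    assert rec.nt_seq == reverse_complement(contig[start - 1:end])


def test_domain_tsv_evalue_threshold(tmp_path, vocab):
    p = tmp_path / "d.tsv"
    p.write_text("g1\tPF03830\tIIB\t1\t100\t1e-4\n"
                 "g2\tPF03830\tIIB\t1\t100\t1e-8\n")
    hits = genome_io.read_domain_tsv(p, vocab, evalue_max=1e-5)
    assert [h.gene_id for h in hits] == ["g2"]
    assert hits[0].signature_label == "PTS_IIB_FRU_MAN_SOR"
    assert all(h.evalue <= 1e-5 for h in hits)


def test_domain_tsv_unmapped_is_other_and_empty_ok(tmp_path, vocab):
    p = tmp_path / "d.tsv"
    p.write_text("g1\tPF99999\tmystery\t1\t50\t1e-20\n")
    assert genome_io.read_domain_tsv(p, vocab)[0].signature_label == "OTHER"
    (tmp_path / "e.tsv").write_text("")
    assert genome_io.read_domain_tsv(tmp_path / "e.tsv", vocab) == []


def test_domain_tsv_non_numeric_evalue(tmp_path, vocab):
    p = tmp_path / "d.tsv"
    p.write_text("g1\tPF03830\tIIB\t1\t100\toops\n")
    with pytest.raises(ParseError, match="e-value"):
        genome_io.read_domain_tsv(p, vocab)


def test_domain_tsv_interproscan_dialect(tmp_path, vocab):
    cols = ["g1", "md5", "300", "Pfam", "PF03613", "EIID", "10", "250",
            "2.2e-40", "T", "2020-01-01"]
    p = tmp_path / "d.tsv"
    p.write_text("\t".join(cols) + "\n")
    hits = genome_io.read_domain_tsv(p, vocab)
    assert hits[0].signature_label == "PTS_IID_FRU_MAN_SOR"
    assert (hits[0].aa_start, hits[0].aa_end) == (10, 250)


def test_newick_round_trip(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text("((A:1,B:1)95:0.5,C:2);\n")
    t = genome_io.read_newick(p)
    assert {x.name for x in t.tips()} == {"A", "B", "C"}
    internal = [n for n in t.non_tips() if not n.is_root()]
    assert internal[0].support == 95.0
    out = tmp_path / "o.nwk"
    genome_io.write_newick(t, out)
    t2 = genome_io.read_newick(out)
    assert {x.name for x in t2.tips()} == {"A", "B", "C"}
    assert [n.support for n in t2.non_tips() if not n.is_root()] == [95.0]
    a = t.find("A")
    assert abs(a.length - 1.0) < 1e-9


def test_newick_single_leaf_and_unbalanced(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text("(A);\n")
    t = genome_io.read_newick(p)
    assert [x.name for x in t.tips()] == ["A"]
    p.write_text("((A,B);\n")
    with pytest.raises(Exception):
        genome_io.read_newick(p)


def test_alignment_ragged_names_offenders(tmp_path):
    p = tmp_path / "a.fa"
    p.write_text(">s1\nAC-G\n>s2\nACG\n")
    with pytest.raises(ParseError, match="s2"):
        genome_io.read_alignment(p, "fasta")


def test_alignment_clustal_round_trip(tmp_path):
    aln = Alignment(["s1", "s2"], ["AC-GT", "ACAGT"])
    p = tmp_path / "a.aln"
    genome_io.write_alignment(aln, p, "clustal")
    back = genome_io.read_alignment(p, "clustal")
    assert back.labels == aln.labels and back.rows == aln.rows
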