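"""Subunit calling, set assembly and family classification."""

import numpy as np
import pytest

from ptsevo.pts_catalog import (assemble_sets, assign_subunits, catalog_summary,
                                classify_family, find_general_pts_genes)
from ptsevo.records import DomainHit, GeneRecord


def hit(gene, sig, a0, a1, ev=1e-30):
    return DomainHit(gene, sig, "", a0, a1, ev)


def gene(gid, start, end, strand="+", contig="c1", product=""):
    return GeneRecord(gid, "g", contig, start, end, strand, product=product)


def test_fused_subunits_follow_domain_order(vocab):
    calls = assign_subunits(
        [hit("g1", "PF03830", 150, 300), hit("g1", "PF03610", 1, 140)], vocab)
    assert len(calls) == 1
    c = calls[0]
    assert c.subunits == ["IIA", "IIB"] and c.fused and c.token == "IIAB"
    assert c.family == "FRU_MAN_SOR"


def test_triple_fusion_token(vocab):
    calls = assign_subunits(
        [hit("g1", "PF00359", 1, 140), hit("g1", "PF02302", 150, 250),
         hit("g1", "PF02366", 260, 500)], vocab)
    assert calls[0].subunits == ["IIA", "IIB", "IIC"]
    assert calls[0].token == "IIABC" and calls[0].family == "FRU_MANNITOL"


def test_non_pts_domains_get_no_call(vocab):
    assert assign_subunits([hit("g1", "PF01380", 1, 100)], vocab) == []
    assert assign_subunits([hit("g1", "PFxxxx", 1, 100)], vocab) == []


def test_family_tie_yields_unknown(vocab, caplog):
    with caplog.at_level("WARNING"):
        calls = assign_subunits(
            [hit("g1", "PF03610", 1, 100), hit("g1", "PF02302", 120, 200)], vocab)
    assert calls[0].family == "UNKNOWN"


def _run_genes(vocab):
    """IIC IID IIB [hyp] IIA run with small gaps, plus distant orphan IIB."""
    sigs = {"IIA": "PF03610", "IIB": "PF03830", "IIC": "PF03609",
            "IID": "PF03613"}
    layout = [("m1", "IIC"), ("m2", "IID"), ("m3", "IIB"), ("x1", None),
              ("m4", "IIA")]
    genes, domains = [], []
    pos = 1000
    for gid, sub in layout:
        genes.append(gene(gid, pos, pos + 899))
        if sub:
            domains.append(hit(gid, sigs[sub], 1, 250))
        pos += 1000  # 100 bp intergenic gaps
    genes.append(gene("orp", 20000, 20899))
    domains.append(hit("orp", sigs["IIB"], 1, 250))
    return genes, assign_subunits(domains, vocab)


def test_assemble_tolerates_one_inserted_gene(vocab):
    genes, calls = _run_genes(vocab)
    sets = assemble_sets(genes, calls)
    assert len(sets) == 2
    s = next(s for s in sets if len(s.members) > 1)
    assert s.members == ["m1", "m2", "m3", "m4"]
    assert s.inserted_genes == ["x1"]
    assert s.architecture_string == "IIC/IID/IIB/IIA"
    assert s.complete and not s.orphan


def test_isolated_subunit_is_orphan(vocab):
    genes, calls = _run_genes(vocab)
    sets = assemble_sets(genes, calls)
    orp = next(s for s in sets if s.members == ["orp"])
    assert orp.orphan and not orp.complete and len(orp.members) == 1


def test_distant_sets_never_merge(vocab):
    sig = "PF03830"
    genes = [gene("a", 100, 999), gene("b", 50_000, 50_899)]
    calls = assign_subunits([hit("a", sig, 1, 100), hit("b", sig, 1, 100)], vocab)
    assert len(assemble_sets(genes, calls)) == 2


def test_gap_rule_splits_runs(vocab):
    genes = [gene("a", 100, 999), gene("b", 1500, 2399)]  # 500 bp gap
    calls = assign_subunits([hit("a", "PF03830", 1, 100),
                             hit("b", "PF03610", 1, 100)], vocab)
    assert len(assemble_sets(genes, calls, max_gap_bp=300)) == 2
    assert len(assemble_sets(genes, calls, max_gap_bp=600)) == 1


def test_two_consecutive_inserted_genes_break_run(vocab):
    genes = [gene("a", 100, 999), gene("x1", 1100, 1999),
             gene("x2", 2100, 2999), gene("b", 3100, 3999)]
    calls = assign_subunits([hit("a", "PF03830", 1, 100),
                             hit("b", "PF03610", 1, 100)], vocab)
    sets = assemble_sets(genes, calls, max_inserted=1)
    assert sorted(len(s.members) for s in sets) == [1, 1]
    sets2 = assemble_sets(genes, calls, max_inserted=2)
    assert [s.members for s in sets2] == [["a", "b"]]


def test_assembly_partitions_called_genes_and_ignores_order(vocab):
    genes, calls = _run_genes(vocab)
    rng = np.random.default_rng(0)
    shuffled = list(genes)
    rng.shuffle(shuffled)
    sets_a = assemble_sets(genes, calls)
    sets_b = assemble_sets(shuffled, calls)
    assert [s.members for s in sets_a] == [s.members for s in sets_b]
    called = {c.gene_id for c in calls}
    in_sets = [g for s in sets_a for g in s.members]
    assert sorted(in_sets) == sorted(called)  # partition: once each


def test_classify_family_rules():
    assert classify_family({"IIA", "IIB", "IIC", "IID"}, "FRU_MAN_SOR") == \
        ("FRU_MAN_SOR", True)
    assert classify_family({"IIA", "IIB", "IIC"}, "FRU_MANNITOL") == \
        ("FRU_MANNITOL", True)
    assert classify_family({"IIA", "IIB", "IIC"}, "FRU_MAN_SOR") == \
        ("FRU_MAN_SOR", False)
    assert classify_family({"IIB"}, "FRU_MAN_SOR")[1] is False
    # IID forces the fructose/mannose/sorbose family
    fam, complete = classify_family({"IIA", "IIB", "IIC", "IID"}, "GLUCOSE")
    assert fam == "FRU_MAN_SOR" and complete


def test_catalog_summary_counts_and_position(vocab):
    genes, calls = _run_genes(vocab)
    sets = assemble_sets(genes, calls)
    summary = catalog_summary({"g": sets}, {"g": 100_000})
    counts = summary["counts"]
    row = counts[counts.genome_id == "g"].iloc[0]
    assert row.total_sets == 2 and row.complete_sets == 1 and row.orphans == 1
    per_set = summary["per_set"]
    big = per_set[per_set.n_members == 4].iloc[0]
    assert big.pos_strand_in_first_half  # '+' strand, midpoint ~3.5 kb / 100 kb
    assert abs(big.position_frac - 0.029) < 0.01


def test_general_pts_keyword_flags():
    genes = [gene("e1", 1, 9, product="phosphoenolpyruvate-protein phosphotransferase"),
             gene("h1", 20, 29, product="phosphocarrier protein HPr"),
             gene("x1", 40, 49, product="hypothetical protein")]
    df = find_general_pts_genes(genes)
    assert set(df.kind) == {"enzyme_I", "hpr"}
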