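"""Alignment, distances, NJ, RF, bootstrap and duplicate detection.

Independent oracles: exhaustive alignment enumeration, the path metric
of randomly generated additive trees, scikit-bio's NJ, and dendropy's
bipartition-based RF distance.
"""

import io
import math

import dendropy
import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from ptsevo import evaluation, phylo
from ptsevo.pts_catalog import PTSGeneSet, SubunitCall
from ptsevo.records import Alignment
from ptsevo.synthetic_data import sim_sequences

# ------------------------------------------------------------- alignment


def test_identical_sequences_align_perfectly():
    r = phylo.nw_align("MKVLITG", "MKVLITG")
    assert r.identity == 100.0 and r.positives == 100.0
    assert "-" not in r.alignment.rows[0]


def test_single_substitution_identity():
    r = phylo.nw_align("ACDEFG", "ACDEFH")
    assert math.isclose(r.identity, 100 * 5 / 6)


def test_alignment_score_matches_exhaustive_enumeration():
    rng = np.random.default_rng(12)
    for _ in range(30):
        la, lb = rng.integers(1, 7, size=2)
        a = "".join(rng.choice(list(evaluation.AA20), size=la))
        b = "".join(rng.choice(list(evaluation.AA20), size=lb))
        assert phylo.nw_align(a, b).score == pytest.approx(
            evaluation.brute_force_alignment_score(a, b))


def test_alignment_score_symmetric():
    rng = np.random.default_rng(3)
    for _ in range(10):
        a = "".join(rng.choice(list(evaluation.AA20), size=20))
        b = "".join(rng.choice(list(evaluation.AA20), size=15))
        assert phylo.nw_align(a, b).score == pytest.approx(
            phylo.nw_align(b, a).score)


def test_empty_sequence_rejected():
    with pytest.raises(ValueError):
        phylo.nw_align("", "ACD")


# ------------------------------------------------------------- distances

def test_pdistance_cases():
    assert phylo.pdistance("AAAA", "AAAA") == 0.0
    assert phylo.pdistance("AAAA", "AAAT") == 0.25
    assert phylo.pdistance("A-CT", "AG-T") == 0.0  # gapped columns skipped
    with pytest.raises(ValueError, match="comparable"):
        phylo.pdistance("A---", "-AAA")


def test_poisson_distance():
    assert phylo.poisson_distance(0.0) == 0.0
    assert math.isclose(phylo.poisson_distance(0.5), math.log(2))
    ps = np.linspace(0, 0.95, 20)
    ds = [phylo.poisson_distance(p) for p in ps]
    assert all(x < y for x, y in zip(ds, ds[1:]))  # monotone
    assert phylo.poisson_distance(1.0) == phylo.SATURATION_CEILING


# -------------------------------------------------------------------- NJ

def test_nj_two_taxa_single_edge():
    t = phylo.nj(DistanceMatrix([[0, 0.4], [0.4, 0]], ["A", "B"]))
    dm = t.tip_tip_distances()
    assert dm["A", "B"] == pytest.approx(0.4)


def test_nj_three_taxa_closed_form():
    d = DistanceMatrix([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]],
                       ["A", "B", "C"])
    t = phylo.nj(d)
    la = (0.3 + 0.5 - 0.6) / 2
    assert t.find("A").length == pytest.approx(la)
    dm = t.tip_tip_distances()
    assert dm["A", "B"] == pytest.approx(0.3)
    assert dm["B", "C"] == pytest.approx(0.6)


def test_nj_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        phylo.nj(DistanceMatrix([[0.0]], ["A"]))


def test_nj_recovers_random_additive_trees_exactly():
    report = evaluation.nj_recovery_study(n_trials=40, seed=9, max_taxa=12)
    assert report["topology_recovery"] == 1.0
    assert report["max_length_error"] < 1e-9


def test_nj_topology_agrees_with_scikit_bio():
    rng = np.random.default_rng(17)
    for _ in range(5):
        _, dm = evaluation.random_additive_case(8, rng)
        ours = phylo.nj(dm)
        theirs = skbio_nj(dm)
        assert phylo.rf_distance(ours, theirs) == 0


# -------------------------------------------------------------------- RF

def _random_tree(n, rng):
    return evaluation.random_additive_case(n, rng)[0]


def _dendropy_rf(t1: TreeNode, t2: TreeNode) -> int:
    tns = dendropy.TaxonNamespace()
    d1 = dendropy.Tree.get(data=str(t1), schema="newick",
                           taxon_namespace=tns)
    d2 = dendropy.Tree.get(data=str(t2), schema="newick",
                           taxon_namespace=tns)
    d1.encode_bipartitions()
    d2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(d1, d2)


def test_rf_identical_topologies_zero():
    t = TreeNode.read(io.StringIO("((A:1,B:1):1,(C:1,D:1):1);"))
    t2 = TreeNode.read(io.StringIO("((C:2,D:1):1,(B:1,A:3):1);"))
    assert phylo.rf_distance(t, t2) == 0


def test_rf_requires_same_leaves():
    t1 = TreeNode.read(io.StringIO("((A,B),(C,D));"))
    t2 = TreeNode.read(io.StringIO("((A,B),(C,E));"))
    with pytest.raises(ValueError):
        phylo.rf_distance(t1, t2)


def test_rf_matches_dendropy_and_is_a_metric():
    rng = np.random.default_rng(23)
    trees = [_random_tree(7, rng) for _ in range(6)]
    for t in trees:
        assert phylo.rf_distance(t, t) == 0
    for a in trees:
        for b in trees:
            rf = phylo.rf_distance(a, b)
            assert rf == phylo.rf_distance(b, a) == _dendropy_rf(a, b)
            assert 0 <= rf <= 2 * (7 - 3)
    for a in trees[:3]:
        for b in trees[:3]:
            for c in trees[:3]:
                assert phylo.rf_distance(a, c) <= \
                    phylo.rf_distance(a, b) + phylo.rf_distance(b, c)


# --------------------------------------------------------------- bootstrap

def test_bootstrap_deterministic_given_seed():
    rng = np.random.default_rng(4)
    tree = TreeNode.read(io.StringIO("((A:.1,B:.1):.4,(C:.1,D:.1):.4);"))
    seqs = sim_sequences(tree, "".join(rng.choice(list(evaluation.AA20), 200)),
                         model="poisson", rate=1.0, rng=rng)
    msa = Alignment(sorted(seqs), [seqs[k] for k in sorted(seqs)])
    _, s1 = phylo.bootstrap(msa, B=50, seed=7)
    _, s2 = phylo.bootstrap(msa, B=50, seed=7)
    assert s1 == s2
    assert all(0 <= v <= 100 for v in s1.values())


def test_bootstrap_zero_replicates_gives_plain_tree():
    msa = Alignment(["A", "B", "C", "D"],
                    ["MKVL", "MKVI", "MRVL", "MRVI"])
    tree, supports = phylo.bootstrap(msa, B=0)
    assert supports == {}
    assert {t.name for t in tree.tips()} == {"A", "B", "C", "D"}


# --------------------------------------------------------- progressive MSA

def test_msa_of_two_reduces_to_pairwise():
    seqs = {"x": "MKVLITGAA", "y": "MKVITGAA"}
    msa = phylo.progressive_msa(seqs)
    pair = phylo.nw_align(seqs["x"], seqs["y"], "x", "y").alignment
    assert msa.rows == pair.rows


def test_msa_identical_sequences_gap_free():
    msa = phylo.progressive_msa({f"s{i}": "MKVLITGAWQ" for i in range(4)})
    assert all("-" not in r for r in msa.rows)
    assert msa.n_cols == 10


def test_msa_recovers_ungapped_homology_columns():
    rng = np.random.default_rng(8)
    tree = TreeNode.read(io.StringIO(
        "(((A:.05,B:.05):.2,(C:.05,D:.05):.2):.2,(E:.05,F:.05):.4);"))
    root = "".join(rng.choice(list(evaluation.AA20), size=120))
    seqs = sim_sequences(tree, root, model="poisson", rate=0.5, rng=rng)
    msa = phylo.progressive_msa(seqs)
    # indel-free evolution: true homology is the ungapped column matching
    assert msa.n_cols == 120
    assert all("-" not in r for r in msa.rows)
    for label in seqs:
        assert msa.row(label) == seqs[label]


# ------------------------------------------------------------- duplicates

def _mk_set(name, genome, iib_gene, arch, strand="+"):
    calls = {iib_gene: SubunitCall(iib_gene, ["IIB"], "FRU_MAN_SOR")}
    return PTSGeneSet(name, genome, [iib_gene], calls, [], "FRU_MAN_SOR",
                      True, False, arch, "c1", 1, 900, strand)


def test_detect_duplicates_thresholds():
    rng = np.random.default_rng(5)
    base = "".join(rng.choice(list(evaluation.AA20), size=200))

    def mutated(frac):
        s = list(base)
        for i in rng.choice(200, size=int(200 * frac), replace=False):
            s[i] = [a for a in evaluation.AA20 if a != s[i]][
                int(rng.integers(19))]
        return "".join(s)

    proteins = {"p0": base, "p95": mutated(0.05), "p75": mutated(0.25)}
    sets = [_mk_set("s0", "g", "p0", "IID/IIC/IIB/IIA"),
            _mk_set("s95", "g", "p95", "IID/IIC/IIB/IIA"),
            _mk_set("s75", "g", "p75", "IID/IIC/IIB/IIA")]
    recs = phylo.detect_duplicates(sets, proteins, identity_min=90)
    rel = {frozenset((r.set_a, r.set_b)): r.relation for r in recs}
    assert rel[frozenset(("s0", "s95"))] == "duplicate"
    assert rel[frozenset(("s0", "s75"))] == "paralog"
    ident = {frozenset((r.set_a, r.set_b)): r.identity for r in recs}
    assert ident[frozenset(("s0", "s95"))] == pytest.approx(95.0, abs=1.0)


def test_identical_sets_detected_at_full_identity():
    proteins = {"a": "MKVLITGAWQMKVLITGAWQ", "b": "MKVLITGAWQMKVLITGAWQ"}
    sets = [_mk_set("sa", "g", "a", "IIB"), _mk_set("sb", "g", "b", "IIB")]
    recs = phylo.detect_duplicates(sets, proteins)
    assert recs[0].relation == "duplicate" and recs[0].identity == 100.0
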