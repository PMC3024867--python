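"""Validation studies with independent oracles.

Each study checks a pipeline component against a route that does not
share code with it: Neighbor-Joining against the path metric of random
additive trees; the Gotoh aligner against exhaustive enumeration of all
global alignments; the 1-D GC grouping against brute-force enumeration
of contiguous partitions; the end-to-end pipeline against the
simulator's ground-truth manifest; and bootstrap supports against the
known topology of a well-separated simulated family.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from skbio import DistanceMatrix, TreeNode

from . import gc_profile, hgt_model, phylo, pipeline, synthetic_data
from .pipeline import PipelineConfig
from .vocab import Vocabulary

AA20 = "ACDEFGHIKLMNPQRSTVWY"


# ----------------------------------------------------- random additive trees

def random_additive_case(n: int, rng: np.random.Generator,
                         length_range: tuple[float, float] = (0.1, 1.0),
                         ) -> tuple[TreeNode, DistanceMatrix]:
    """Random binary unrooted tree with U(0.1,1) branch lengths, plus its
    exact leaf path-metric (the additive matrix NJ must invert)."""
    labels = [f"L{i:02d}" for i in range(n)]
    nodes = [TreeNode(name=l) for l in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        a.length = float(rng.uniform(*length_range))
        b.length = float(rng.uniform(*length_range))
        parent = TreeNode(children=[b, a])
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [parent]
    for node in nodes:
        node.length = float(rng.uniform(*length_range))
    tree = TreeNode(children=nodes) if len(nodes) > 1 else nodes[0]
    dm = tree.tip_tip_distances()
    dm = DistanceMatrix(dm.filter(sorted(dm.ids)).data, sorted(dm.ids))
    return tree, dm


def nj_recovery_study(n_trials: int = 200, seed: int = 0,
                      max_taxa: int = 16) -> dict:
    """Fraction of random additive matrices for which NJ returns RF=0 and
    reproduces the generating path metric to 1e-9."""
    rng = np.random.default_rng(seed)
    topo_ok = length_ok = 0
    worst = 0.0
    for _ in range(n_trials):
        n = int(rng.integers(4, max_taxa + 1))
        true_tree, dm = random_additive_case(n, rng)
        est = phylo.nj(dm)
        if phylo.rf_distance(true_tree, est) == 0:
            topo_ok += 1
        est_dm = est.tip_tip_distances()
        est_dm = est_dm.filter(sorted(est_dm.ids))
        err = float(np.abs(est_dm.data - dm.data).max())
        worst = max(worst, err)
        if err <= 1e-9:
            length_ok += 1
    return {"n_trials": n_trials, "topology_recovery": topo_ok / n_trials,
            "length_recovery": length_ok / n_trials, "max_length_error": worst}


# ------------------------------------------------ exhaustive alignment oracle

def brute_force_alignment_score(a: str, b: str) -> float:
    """Best global alignment score by exhaustive enumeration of all
    monotone alignments, with the same affine gap accounting as the
    aligner (existence 11, extension 1) but none of its code."""
    go, ge = phylo.GAP_OPEN, phylo.GAP_EXTEND
    best = -float("inf")

    def rec(i: int, j: int, score: float, last: str) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1,
                score + phylo.substitution_score(a[i], b[j]), "d")
        if j < len(b):
            cost = ge if last == "a" else go + ge
            rec(i, j + 1, score - cost, "a")  # gap in a
        if i < len(a):
            cost = ge if last == "b" else go + ge
            rec(i + 1, j, score - cost, "b")  # gap in b
    rec(0, 0, 0.0, "")
    return best


def alignment_oracle_study(n_pairs: int = 100, seed: int = 0,
                           max_len: int = 8) -> dict:
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_pairs):
        la, lb = rng.integers(2, max_len + 1, size=2)
        a = "".join(rng.choice(list(AA20), size=la))
        b = "".join(rng.choice(list(AA20), size=lb))
        expected = brute_force_alignment_score(a, b)
        got = phylo.nw_align(a, b).score
        agree += abs(got - expected) < 1e-9
    return {"n_pairs": n_pairs, "agreement": agree / n_pairs}


# -------------------------------------------------- brute-force 1-D grouping

def brute_force_partition_ss(values: list[float], k: int) -> float:
    """Minimum within-group SS over all contiguous k-partitions of the
    sorted values, by enumeration."""
    sv = sorted(values)
    n = len(sv)

    def ss(seg: list[float]) -> float:
        m = sum(seg) / len(seg)
        return sum((x - m) ** 2 for x in seg)

    best = float("inf")
    for cuts in combinations(range(1, n), k - 1):
        edges = [0, *cuts, n]
        best = min(best, sum(ss(sv[a:b]) for a, b in zip(edges, edges[1:])))
    return best


def grouping_oracle_study(n_trials: int = 200, seed: int = 0,
                          max_n: int = 12, max_k: int = 4) -> dict:
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_trials):
        n = int(rng.integers(2, max_n + 1))
        k = int(rng.integers(1, min(max_k, n) + 1))
        values = list(np.round(rng.uniform(25, 60, size=n), 2))
        got = gc_profile.group_gc(values, k).within_ss
        expected = brute_force_partition_ss(values, k)
        agree += abs(got - expected) < 1e-9
    return {"n_trials": n_trials, "agreement": agree / n_trials}


# Published GC% values of the nine complete fructose/mannose/sorbose PTS II
# gene sets of C. beijerinckii NCIMB 8052 (the four-gene set carrying an
# inserted hypothetical gene taken at its inserted-inclusive value, 33.1).
REFERENCE_SET_GC = [37.5, 31.8, 31.9, 33.1, 32.4, 32.0, 35.1, 30.3, 35.1]
REFERENCE_PARTITION = (
    [30.3, 31.8, 31.9, 32.0, 32.4, 33.1], [35.1, 35.1], [37.5])


def reference_grouping_matches() -> bool:
    """Does k=3 grouping of the published set GC values reproduce the
    published three-group split?"""
    got = gc_profile.group_gc(REFERENCE_SET_GC, 3).groups()
    return [sorted(g) for g in got] == [list(g) for g in REFERENCE_PARTITION]


# -------------------------------------------------------- pipeline recovery

@dataclass
class RecoveryReport:
    n_sets_true: int
    n_sets_found: int
    boundary_exact: int          # sets recovered with exact member+inserted lists
    architecture_exact: int
    synteny_exact: int
    duplicates_expected: int
    duplicates_found: int
    hgt_strong_tp: int
    hgt_true: int
    strong_false_positives: int

    @property
    def all_recovered(self) -> bool:
        return (self.boundary_exact == self.architecture_exact ==
                self.synteny_exact == self.n_sets_true)


def end_to_end_recovery(seed: int, cfg: PipelineConfig | None = None,
                        spec=None) -> RecoveryReport:
    """Run simulate -> full pipeline; compare to the manifest."""
    spec = spec or synthetic_data.default_simspec(seed)
    cfg = cfg or PipelineConfig(seed=seed)
    sim = synthetic_data.sim_genome(spec)
    result = pipeline.run_all(sim.bundles, Vocabulary.default(),
                              sim.species_tree, cfg)
    found = {tuple(s.members): s for s in result.all_sets()}
    ctx = result.contexts
    hgt_by_set = {r.set_id: r for r in result.hgt.itertuples()} \
        if result.hgt is not None else {}

    boundary = architecture = syn = 0
    hgt_tp = 0
    true_hgt_sets = 0
    matched_ids = {}
    for ts in sim.truth.sets:
        s = found.get(tuple(ts.members))
        if s is None or sorted(s.inserted_genes) != sorted(ts.inserted):
            continue
        boundary += 1
        matched_ids[ts.name] = s.set_id
        if s.architecture_string == ts.architecture and s.family == ts.family \
                and s.complete == ts.complete and s.orphan == ts.orphan:
            architecture += 1
        c = ctx.get(s.set_id)
        if c is not None and c.synteny_class == ts.synteny_class \
                and c.flanked_by_is == ts.flanked_by_is:
            syn += 1
        if ts.hgt:
            true_hgt_sets += 1
            call = hgt_by_set.get(s.set_id)
            if call is not None and call.verdict == "STRONG":
                hgt_tp += 1

    true_ids = set(matched_ids.values())
    strong_fp = sum(
        1 for r in hgt_by_set.values()
        if r.verdict == "STRONG" and r.set_id not in {
            matched_ids[ts.name] for ts in sim.truth.sets
            if ts.hgt and ts.name in matched_ids})

    dup_expected = sum(1 for ts in sim.truth.sets if ts.duplicate_of)
    dup_found = 0
    for ts in sim.truth.sets:
        if not ts.duplicate_of:
            continue
        a = matched_ids.get(ts.name)
        b = matched_ids.get(ts.duplicate_of)
        for d in result.duplicates:
            if d.relation == "duplicate" and {d.set_a, d.set_b} == {a, b}:
                dup_found += 1
                break
    return RecoveryReport(len(sim.truth.sets), len(found), boundary,
                          architecture, syn, dup_expected, dup_found,
                          hgt_tp, true_hgt_sets, strong_fp)


def hgt_rate_study(seed: int = 0, min_sets: int = 200) -> dict:
    """Sensitivity / false-positive rate of the HGT verdict over
    replicated default simulations (GC + IS evidence; trees are
    exercised separately).  A positive is verdict STRONG or CANDIDATE."""
    rng = np.random.SeedSequence(seed)
    tp = fn = fp = tn = 0
    n_sets = 0
    vocab = Vocabulary.default()
    cfg = PipelineConfig(seed=seed)
    rep = 0
    while n_sets < min_sets:
        child_seed = int(np.random.default_rng(rng.spawn(1)[0]).integers(2 ** 31))
        spec = synthetic_data.default_simspec(child_seed)
        sim = synthetic_data.sim_genome(spec, vocab)
        sets_by_genome, _ = pipeline.run_catalog(sim.bundles, vocab, cfg)
        gc_df = pipeline.run_gc(sim.bundles, sets_by_genome, cfg)
        syn_df, _ = pipeline.run_synteny(sim.bundles, sets_by_genome, vocab, cfg)
        hgt_df, _ = pipeline.run_hgt(sim.bundles, sets_by_genome, gc_df,
                                     syn_df, {}, None, cfg)
        truth_by_members = {tuple(ts.members): ts for ts in sim.truth.sets}
        set_by_id = {s.set_id: s for sets in sets_by_genome.values() for s in sets}
        for row in hgt_df.itertuples():
            ts = truth_by_members.get(tuple(set_by_id[row.set_id].members))
            if ts is None:
                continue
            positive = row.verdict in {"STRONG", "CANDIDATE"}
            if ts.hgt:
                tp += positive
                fn += not positive
            else:
                fp += positive
                tn += not positive
            n_sets += 1
        rep += 1
    return {"n_sets": n_sets, "n_replicates": rep,
            "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
            "fpr": fp / (fp + tn) if fp + tn else float("nan")}


# ------------------------------------------------------------- bootstrap

def bootstrap_support_study(seed: int = 0, n_sites: int = 1000,
                            B: int = 500) -> dict:
    """Bootstrap supports on a 6-taxon caterpillar with long internal
    branches: every true internal edge should be strongly supported."""
    rng = np.random.default_rng(seed)
    newick = ("((A:0.1,B:0.1):0.5,(C:0.1,D:0.1):0.5,"
              "(E:0.1,F:0.1):0.5);")
    import io
    tree = TreeNode.read(io.StringIO(newick))
    root_seq = "".join(rng.choice(list(AA20), size=n_sites))
    leaves = synthetic_data.sim_sequences(tree, root_seq, model="poisson",
                                          rate=1.0, rng=rng)
    from .records import Alignment
    msa = Alignment(sorted(leaves), [leaves[l] for l in sorted(leaves)])
    est, supports = phylo.bootstrap(msa, B=B, seed=seed)
    true_bips = phylo.bipartitions(tree)
    est_bips = phylo.bipartitions(est)
    min_support = min((supports.get(bp, 0.0) for bp in true_bips), default=0.0)
    return {"n_true_edges": len(true_bips),
            "recovered_edges": len(true_bips & est_bips),
            "min_true_edge_support": min_support}
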