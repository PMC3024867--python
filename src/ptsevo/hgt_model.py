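"""Composite horizontal-gene-transfer screen for PTS gene sets.

Three lines of evidence are combined per set:

1. GC anomaly — the set's GC z-score against the host genome's
   per-gene GC distribution, with direction relative to whole-genome GC;
2. gene-tree / species-tree incongruence — the set's gene-tree leaf
   sitting in a clade mixing the two taxon groups (high-GC donor clade
   vs low-GC recipient clade);
3. IS flanking — insertion-sequence evidence on both flanks.

Verdict: STRONG with >= 2 evidence lines, CANDIDATE with exactly 1,
NONE otherwise.  A donor group is inferred only when the set's GC is
elevated above the host genome (the direction the underlying
high-GC-to-low-GC transfer model predicts).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from skbio import TreeNode

from .gc_profile import GCBaseline
from .records import GenomeBundle

HIGH_GC = "HIGH_GC_DONOR_CLADE"
LOW_GC = "LOW_GC_RECIPIENT_CLADE"

DEFAULT_Z_MIN = 2.0


def classify_taxa(species_tree: TreeNode, genome_gc: dict[str, float],
                  labels: dict[str, str] | None = None) -> dict[str, str]:
    """Two-group taxon classification.

    Defaults to the deepest bipartition of the species tree (first root
    child vs the rest); the group with the higher mean genome GC becomes
    the donor clade.  An explicit ``labels`` map overrides the tree.
    """
    if labels is not None:
        bad = set(labels.values()) - {HIGH_GC, LOW_GC}
        if bad:
            raise ValueError(f"unknown group labels: {bad}")
        return dict(labels)
    tips = [t.name for t in species_tree.tips()]
    if len(tips) < 2:
        raise ValueError("species tree needs >= 2 taxa")
    side_a = {t.name for t in species_tree.children[0].tips()} \
        if not species_tree.children[0].is_tip() else {species_tree.children[0].name}
    side_b = set(tips) - side_a
    if not side_b:
        raise ValueError("degenerate species-tree bipartition")

    def mean_gc(side):
        vals = [genome_gc[t] for t in side if t in genome_gc]
        return sum(vals) / len(vals) if vals else -math.inf

    if mean_gc(side_a) >= mean_gc(side_b):
        high, low = side_a, side_b
    else:
        high, low = side_b, side_a
    return {**{t: HIGH_GC for t in high}, **{t: LOW_GC for t in low}}


def mixed_clade_test(gene_tree: TreeNode, taxon_of_leaf: dict[str, str],
                     groups: dict[str, str]) -> tuple[dict[str, bool], int]:
    """Per-leaf incongruence flags plus a tree-level mixing count.

    A leaf is "mixed" when its smallest non-trivial surrounding clade
    (its parent's clade) contains leaves from both taxon groups.  The
    count is the number of non-trivial bipartitions with both groups on
    both sides (0 for any tree congruent with the two-group split).
    """
    def group_of(leaf: str) -> str:
        if leaf not in taxon_of_leaf:
            raise ValueError(f"gene-tree leaf {leaf!r} has no taxon mapping")
        taxon = taxon_of_leaf[leaf]
        if taxon not in groups:
            raise ValueError(f"taxon {taxon!r} has no group classification")
        return groups[taxon]

    leaves = [t.name for t in gene_tree.tips()]
    flags: dict[str, bool] = {}
    for tip in gene_tree.tips():
        node = tip.parent if tip.parent is not None else tip
        clade_groups = {group_of(t.name) for t in node.tips()}
        flags[tip.name] = len(clade_groups) > 1

    n = len(leaves)
    count = 0
    for node in gene_tree.non_tips():
        if node.is_root():
            continue
        clade = [t.name for t in node.tips()]
        if not 1 < len(clade) < n - 1:
            continue
        inside = {group_of(l) for l in clade}
        outside = {group_of(l) for l in set(leaves) - set(clade)}
        if len(inside) > 1 and len(outside) > 1:
            count += 1
    return flags, count


@dataclass
class HGTCall:
    set_id: str
    gc_z: float
    gc_direction: str
    mixed_clade: bool
    flanked_by_is: bool
    verdict: str  # STRONG | CANDIDATE | NONE
    inferred_donor_group: str | None = None
    rf_norm: float | None = None


def hgt_verdict(set_id: str, gc_z: float, gc_direction: str,
                mixed_flag: bool, is_flag: bool,
                z_min: float = DEFAULT_Z_MIN,
                rf_norm: float | None = None) -> HGTCall:
    """Two-of-three evidence rule.

    Evidence lines: elevated GC (z >= z_min and direction "above"),
    mixed clade, IS flanking.  STRONG iff >= 2 lines, CANDIDATE iff 1.
    """
    if z_min <= 0:
        raise ValueError("z_min must be positive")
    gc_line = (not math.isnan(gc_z)) and gc_z >= z_min and gc_direction == "above"
    evidence = int(gc_line) + int(mixed_flag) + int(is_flag)
    verdict = "STRONG" if evidence >= 2 else "CANDIDATE" if evidence == 1 else "NONE"
    donor = HIGH_GC if (gc_direction == "above" and verdict != "NONE") else None
    return HGTCall(set_id, gc_z, gc_direction, mixed_flag, is_flag,
                   verdict, donor, rf_norm)


def normalized_rf(rf: int, n_leaves: int) -> float:
    """RF / 2(n-3), the fraction of possible conflicting bipartitions."""
    denom = 2 * (n_leaves - 3)
    return rf / denom if denom > 0 else 0.0


def gc_gradient_report(bundles: list[GenomeBundle],
                       sets_by_genome: dict[str, list],
                       set_gc_values: dict[str, float],
                       family: str = "FRU_MAN_SOR",
                       baselines: dict[str, GCBaseline] | None = None,
                       ) -> pd.DataFrame:
    """Per-genome GC gradient table for one family, sorted by genome GC
    descending: genome GC, min/max/mean of the family's set GC values,
    and the difference (set mean - genome GC)."""
    rows = []
    for bundle in bundles:
        fam_sets = [s for s in sets_by_genome.get(bundle.genome_id, [])
                    if s.family == family]
        gcs = [set_gc_values[s.set_id] for s in fam_sets if s.set_id in set_gc_values]
        genome_gc = (baselines[bundle.genome_id].genome_gc
                     if baselines else bundle.genome_gc)
        row = {"genome_id": bundle.genome_id, "genome_gc": genome_gc,
               "n_sets": len(gcs)}
        if gcs:
            mean = sum(gcs) / len(gcs)
            row.update(set_gc_min=min(gcs), set_gc_max=max(gcs),
                       set_gc_mean=mean, diff=mean - genome_gc)
        else:
            row.update(set_gc_min=math.nan, set_gc_max=math.nan,
                       set_gc_mean=math.nan, diff=math.nan)
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values("genome_gc", ascending=False).reset_index(drop=True)
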