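"""Neighborhood (synteny) analysis of PTS gene sets.

For each set, the up-to-``window`` flanking genes on each side of the
set on its contig are collected and scanned for regulatory/mobility
markers: sigma-54 factor (rpoN), sugar isomerase (SIS) domain proteins,
and IS-element transposases.  Domain-label evidence outranks the
product-text regex fallback.  The sigma-54/SIS presence pattern yields
a synteny class (BOTH / SIGMA54_ONLY / NEITHER / OTHER); IS evidence is
tracked separately, with "flanked_by_IS" requiring matches on both
flanks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .records import DomainHit, GeneRecord
from .pts_catalog import PTSGeneSet
from .vocab import Vocabulary

DEFAULT_WINDOW = 4


@dataclass
class SyntenyContext:
    set_id: str
    upstream: list[GeneRecord] = field(default_factory=list)    # lower coordinates
    downstream: list[GeneRecord] = field(default_factory=list)  # higher coordinates
    marker_genes: dict[str, list[str]] = field(default_factory=dict)
    sigma54: bool = False
    sis: bool = False
    is_adjacent: bool = False
    flanked_by_is: bool = False
    synteny_class: str = "NEITHER"


def classify_markers(sigma54: bool, sis: bool) -> str:
    """Pure flag -> class mapping."""
    if sigma54 and sis:
        return "BOTH"
    if sigma54:
        return "SIGMA54_ONLY"
    if sis:
        return "OTHER"
    return "NEITHER"


def extract_context(pts_set: PTSGeneSet, genes: list[GeneRecord],
                    window: int = DEFAULT_WINDOW) -> SyntenyContext:
    """Up to ``window`` genes on each flank of the set on its contig.

    The set's own members and inserted genes are never neighbors;
    flanks truncate silently at contig ends.
    """
    own = set(pts_set.members) | set(pts_set.inserted_genes)
    contig_genes = sorted((g for g in genes if g.contig_id == pts_set.contig_id),
                          key=lambda g: g.start)
    others = [g for g in contig_genes if g.gene_id not in own]
    upstream = [g for g in others if g.end < pts_set.start][-window:]
    downstream = [g for g in others if g.start > pts_set.end][:window]
    return SyntenyContext(pts_set.set_id, upstream, downstream)


def _gene_matches_marker(gene: GeneRecord, marker: str,
                         domains_by_gene: dict[str, list[DomainHit]],
                         vocab: Vocabulary) -> bool:
    for hit in domains_by_gene.get(gene.gene_id, []):
        if vocab.marker_of_label(hit.signature_label) == marker:
            return True
    return vocab.product_matches(marker, gene.product)


def detect_markers(context: SyntenyContext,
                   domains_by_gene: dict[str, list[DomainHit]],
                   vocab: Vocabulary) -> SyntenyContext:
    """Fill marker flags and the synteny class in-place (and return it)."""
    hits: dict[str, list[str]] = {"sigma54": [], "sis": [], "is_element": []}
    is_up = is_down = False
    for side, flank in (("up", context.upstream), ("down", context.downstream)):
        for gene in flank:
            for marker in hits:
                if _gene_matches_marker(gene, marker, domains_by_gene, vocab):
                    hits[marker].append(gene.gene_id)
                    if marker == "is_element":
                        is_up |= side == "up"
                        is_down |= side == "down"
    context.marker_genes = {m: g for m, g in hits.items() if g}
    context.sigma54 = bool(hits["sigma54"])
    context.sis = bool(hits["sis"])
    context.is_adjacent = bool(hits["is_element"])
    context.flanked_by_is = is_up and is_down
    context.synteny_class = classify_markers(context.sigma54, context.sis)
    return context


def analyze_set(pts_set: PTSGeneSet, genes: list[GeneRecord],
                domains_by_gene: dict[str, list[DomainHit]],
                vocab: Vocabulary, window: int = DEFAULT_WINDOW) -> SyntenyContext:
    return detect_markers(extract_context(pts_set, genes, window),
                          domains_by_gene, vocab)


@dataclass
class ArchitectureComparison:
    architecture_match: bool
    class_match: bool
    markers_match: bool


def shared_architecture(set_a: PTSGeneSet, set_b: PTSGeneSet,
                        context_a: SyntenyContext | None = None,
                        context_b: SyntenyContext | None = None,
                        ) -> ArchitectureComparison:
    """Compare genomic organization of two sets.

    Architectures match when their token lists are equal, or equal after
    reversal when the sets sit on opposite strands (reading the cluster
    from its own 5' end).
    """
    ta = set_a.architecture_string.split("/")
    tb = set_b.architecture_string.split("/")
    if set_a.strand == set_b.strand:
        arch = ta == tb
    else:
        arch = ta == tb[::-1]
    class_match = markers_match = False
    if context_a is not None and context_b is not None:
        class_match = context_a.synteny_class == context_b.synteny_class
        markers_match = (
            class_match
            and context_a.is_adjacent == context_b.is_adjacent
            and context_a.flanked_by_is == context_b.flanked_by_is
        )
    return ArchitectureComparison(arch, class_match, markers_match)
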