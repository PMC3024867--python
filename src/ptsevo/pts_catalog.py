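"""Classify genes into PTS enzyme II subunits/families from their domain
architecture and assemble them into operon-like gene sets.

A gene's subunit composition is read off its PTS domain hits in N->C
order (e.g. IIA+IIB on one peptide => fused "IIAB").  Sets are maximal
coordinate-contiguous runs of same-family PTS genes on one contig,
tolerating short intergenic gaps and up to a configurable number of
consecutive inserted non-PTS genes.  The fructose/mannose/sorbose
family is the only one requiring a IID subunit for completeness; all
other families require IIA+IIB+IIC.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .records import DomainHit, GeneRecord, GenomeBundle
from .vocab import SUBUNITS, Vocabulary

logger = logging.getLogger(__name__)

DEFAULT_MAX_GAP_BP = 300
DEFAULT_MAX_INSERTED = 1

REQUIRED_SUBUNITS = {"FRU_MAN_SOR": {"IIA", "IIB", "IIC", "IID"}}
_DEFAULT_REQUIRED = {"IIA", "IIB", "IIC"}


def required_subunits(family: str) -> set[str]:
    return REQUIRED_SUBUNITS.get(family, set(_DEFAULT_REQUIRED))


@dataclass
class SubunitCall:
    gene_id: str
    subunits: list[str]       # N->C order, drawn from IIA/IIB/IIC/IID
    family: str               # majority family over the gene's PTS domains

    @property
    def fused(self) -> bool:
        return len(self.subunits) >= 2

    @property
    def token(self) -> str:
        """Architecture token, e.g. [IIA, IIB] -> 'IIAB'."""
        return "II" + "".join(s[-1] for s in self.subunits)


@dataclass
class PTSGeneSet:
    set_id: str
    genome_id: str
    members: list[str]
    calls: dict[str, SubunitCall]
    inserted_genes: list[str] = field(default_factory=list)
    family: str = "UNKNOWN"
    complete: bool = False
    orphan: bool = False
    architecture_string: str = ""
    contig_id: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"

    @property
    def subunit_union(self) -> set[str]:
        return {s for c in self.calls.values() for s in c.subunits}

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


def assign_subunits(domains: list[DomainHit], vocab: Vocabulary) -> list[SubunitCall]:
    """Per-gene subunit calls from PTS domain hits.

    Subunit tokens are ordered by aa_start (duplicate hits for one
    subunit collapse to its first occurrence); family is the majority
    family token, with ties yielding UNKNOWN.  Genes with no PTS domain
    get no call.
    """
    by_gene: dict[str, list[DomainHit]] = {}
    for h in domains:
        if vocab.lookup(h.signature_id).kind == "pts":
            by_gene.setdefault(h.gene_id, []).append(h)
    calls = []
    for gene_id, hits in by_gene.items():
        hits.sort(key=lambda h: (h.aa_start, h.aa_end))
        subunits: list[str] = []
        families: list[str] = []
        for h in hits:
            info = vocab.lookup(h.signature_id)
            if info.subunit not in subunits:
                subunits.append(info.subunit)
            families.append(info.family)
        counts = Counter(families).most_common()
        if len(counts) > 1 and counts[0][1] == counts[1][1]:
            logger.warning("%s: no majority family among %s; set to UNKNOWN",
                           gene_id, families)
            family = "UNKNOWN"
        else:
            family = counts[0][0]
        subunits.sort(key=SUBUNITS.index)  # stable canonical order inside token
        subunits_nc = sorted(subunits, key=lambda s: min(
            h.aa_start for h in hits if vocab.lookup(h.signature_id).subunit == s))
        calls.append(SubunitCall(gene_id, subunits_nc, family))
    return calls


def _families_compatible(a: str, b: str) -> bool:
    return a == b or "UNKNOWN" in (a, b)


def assemble_sets(genes: list[GeneRecord], calls: list[SubunitCall],
                  max_gap_bp: int = DEFAULT_MAX_GAP_BP,
                  max_inserted: int = DEFAULT_MAX_INSERTED) -> list[PTSGeneSet]:
    """Group PTS-called genes into maximal contiguous same-family runs.

    A run extends over an intervening non-PTS gene only while at most
    ``max_inserted`` consecutive such genes separate two PTS members and
    every intergenic gap between consecutive run genes is <= ``max_gap_bp``.
    """
    call_by_gene = {c.gene_id: c for c in calls}
    genes = sorted(genes, key=lambda g: (g.contig_id, g.start))
    sets: list[PTSGeneSet] = []

    members: list[GeneRecord] = []
    inserted: list[GeneRecord] = []
    pending: list[GeneRecord] = []
    family = "UNKNOWN"
    last: GeneRecord | None = None

    def close() -> None:
        nonlocal members, inserted, pending, family, last
        if members:
            sets.append(_finalize_set(members, inserted, call_by_gene))
        members, inserted, pending = [], [], []
        family = "UNKNOWN"
        last = None

    for g in genes:
        call = call_by_gene.get(g.gene_id)
        if last is not None and (g.contig_id != last.contig_id
                                 or g.start - last.end - 1 > max_gap_bp):
            close()
        if call is None:
            if members:
                pending.append(g)
                if len(pending) > max_inserted:
                    close()
                else:
                    last = g
            continue
        if members and not _families_compatible(family, call.family):
            close()
        if not members:
            members, inserted, pending = [g], [], []
        else:
            inserted.extend(pending)
            pending = []
            members.append(g)
        if call.family != "UNKNOWN":
            family = call.family
        last = g
    close()
    return sets


def classify_family(subunit_union: set[str], family: str) -> tuple[str, bool]:
    """Resolve a set's family and completeness from its subunit union.

    A IID subunit forces the fructose/mannose/sorbose family (it is the
    only family carrying IID); completeness requires the family's full
    subunit complement.
    """
    if "IID" in subunit_union and family != "FRU_MAN_SOR":
        logger.warning("set with IID labelled %s; reclassified FRU_MAN_SOR", family)
        family = "FRU_MAN_SOR"
    complete = subunit_union >= required_subunits(family)
    return family, complete


def _finalize_set(members: list[GeneRecord], inserted: list[GeneRecord],
                  call_by_gene: dict[str, SubunitCall]) -> PTSGeneSet:
    members = sorted(members, key=lambda g: g.start)
    calls = {g.gene_id: call_by_gene[g.gene_id] for g in members}
    fams = [c.family for c in calls.values() if c.family != "UNKNOWN"]
    family = Counter(fams).most_common(1)[0][0] if fams else "UNKNOWN"
    union = {s for c in calls.values() for s in c.subunits}
    family, complete = classify_family(union, family)
    strands = Counter(g.strand for g in members)
    if len(strands) > 1:
        logger.warning("mixed-strand set starting at %s", members[0].gene_id)
    strand = strands.most_common(1)[0][0]
    everything = members + inserted
    return PTSGeneSet(
        set_id=f"set:{members[0].gene_id}",
        genome_id=members[0].genome_id,
        members=[g.gene_id for g in members],
        calls=calls,
        inserted_genes=[g.gene_id for g in sorted(inserted, key=lambda g: g.start)],
        family=family,
        complete=complete,
        orphan=len(members) == 1 and not complete,
        architecture_string="/".join(calls[g.gene_id].token for g in members),
        contig_id=members[0].contig_id,
        start=min(g.start for g in everything),
        end=max(g.end for g in everything),
        strand=strand,
    )


def catalog_genome(bundle: GenomeBundle, vocab: Vocabulary,
                   max_gap_bp: int = DEFAULT_MAX_GAP_BP,
                   max_inserted: int = DEFAULT_MAX_INSERTED) -> list[PTSGeneSet]:
    """Subunit assignment + set assembly for one genome."""
    calls = assign_subunits(bundle.domains, vocab)
    return assemble_sets(bundle.genes, calls, max_gap_bp, max_inserted)


def catalog_summary(sets_by_genome: dict[str, list[PTSGeneSet]],
                    genome_lengths: dict[str, int]) -> dict[str, pd.DataFrame]:
    """Per-set table plus per-genome x family count table.

    The per-set table records strand and fractional genomic position
    (midpoint / genome length) with a convenience flag
    ``pos_strand_in_first_half``.
    """
    set_rows = []
    for genome_id, sets in sets_by_genome.items():
        length = genome_lengths[genome_id]
        for s in sets:
            frac = s.midpoint / length
            set_rows.append({
                "genome_id": genome_id, "set_id": s.set_id, "family": s.family,
                "architecture": s.architecture_string, "n_members": len(s.members),
                "complete": s.complete, "orphan": s.orphan,
                "n_inserted": len(s.inserted_genes), "strand": s.strand,
                "position_frac": frac,
                "pos_strand_in_first_half": s.strand == "+" and frac < 0.5,
            })
        if not sets:
            set_rows.append({"genome_id": genome_id, "set_id": None,
                             "family": None, "architecture": None,
                             "n_members": 0, "complete": False, "orphan": False,
                             "n_inserted": 0, "strand": None,
                             "position_frac": None,
                             "pos_strand_in_first_half": False})
    per_set = pd.DataFrame(set_rows)
    real = per_set.dropna(subset=["set_id"])
    counts = (real.groupby(["genome_id", "family"])
              .agg(total_sets=("set_id", "count"),
                   complete_sets=("complete", "sum"),
                   orphans=("orphan", "sum"))
              .reset_index())
    return {"per_set": per_set, "counts": counts}


_GENERAL_PTS_KEYWORDS = {
    "enzyme_I": ("phosphoenolpyruvate-protein phosphotransferase", "enzyme i "),
    "hpr": ("phosphocarrier", "hpr"),
}


def find_general_pts_genes(genes: list[GeneRecord]) -> pd.DataFrame:
    """Convenience flag for enzyme I / Hpr by product-text keyword."""
    rows = []
    for g in genes:
        text = (g.product or "").lower()
        for kind, keys in _GENERAL_PTS_KEYWORDS.items():
            if any(k in text for k in keys):
                rows.append({"gene_id": g.gene_id, "kind": kind, "product": g.product})
    return pd.DataFrame(rows, columns=["gene_id", "kind", "product"])
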