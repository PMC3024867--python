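"""Core in-memory containers shared by every stage of the pipeline.

Coordinates are 1-based inclusive throughout (GFF3 convention).  Locus
tags (``gene_id``) are the universal join key between the gene table,
the protein FASTA and the domain table.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ParseError(ValueError):
    """An input file violated its format contract."""


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneRecord:
    """One annotated CDS."""

    gene_id: str
    genome_id: str
    contig_id: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive, start <= end
    strand: str  # "+" or "-"
    nt_seq: str = ""
    aa_seq: str = ""
    product: str = ""

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.start > self.end:
            raise ParseError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.nt_seq and len(self.nt_seq) != self.end - self.start + 1:
            raise ValueError(
                f"{self.gene_id}: nt_seq length {len(self.nt_seq)} does not match "
                f"span {self.end - self.start + 1}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class DomainHit:
    """One protein domain match (InterProScan-style)."""

    gene_id: str
    signature_id: str
    signature_label: str  # normalized vocabulary token; "OTHER" if unmapped
    aa_start: int
    aa_end: int
    evalue: float

    def __post_init__(self) -> None:
        if self.aa_start > self.aa_end:
            raise ParseError(f"{self.gene_id}/{self.signature_id}: aa_start > aa_end")
        if self.evalue < 0:
            raise ParseError(f"{self.gene_id}/{self.signature_id}: negative e-value")


@dataclass
class GenomeBundle:
    """Everything the pipeline knows about one genome."""

    genome_id: str
    contigs: dict[str, str]
    genes: list[GeneRecord] = field(default_factory=list)
    domains: list[DomainHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes.sort(key=lambda g: (g.contig_id, g.start))
        for g in self.genes:
            if g.contig_id not in self.contigs:
                raise ValueError(f"{g.gene_id}: unknown contig {g.contig_id!r}")
            if g.end > len(self.contigs[g.contig_id]):
                raise ValueError(f"{g.gene_id}: coordinates exceed contig length")

    @property
    def genome_gc(self) -> float:
        """Whole-genome GC% over concatenated contigs."""
        n = gc = 0
        for seq in self.contigs.values():
            s = seq.upper()
            gc += s.count("G") + s.count("C")
            n += len(s)
        if n == 0:
            raise ValueError(f"{self.genome_id}: no sequence")
        return 100.0 * gc / n

    def domains_by_gene(self) -> dict[str, list[DomainHit]]:
        out: dict[str, list[DomainHit]] = {}
        for h in self.domains:
            out.setdefault(h.gene_id, []).append(h)
        for hits in out.values():
            hits.sort(key=lambda h: h.aa_start)
        return out

    def genes_by_id(self) -> dict[str, GeneRecord]:
        return {g.gene_id: g for g in self.genes}


@dataclass
class Alignment:
    """A gapped multiple (or pairwise) sequence alignment."""

    labels: list[str]
    rows: list[str]
    alphabet: str = "protein"  # or "dna"

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in number")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            ragged = [l for l, r in zip(self.labels, self.rows)
                      if len(r) != len(self.rows[0])]
            raise ParseError(f"ragged alignment rows for: {', '.join(ragged)}")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, label: str) -> str:
        return self.rows[self.labels.index(label)]
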