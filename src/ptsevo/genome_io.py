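"""Readers/writers for the external formats the pipeline touches.

FASTA, GFF3 gene tables (plus a plain TSV dialect), InterProScan-style
domain TSVs, Newick trees (with internal-node supports) and
FASTA/Clustal alignments.  Coordinates stay 1-based inclusive; strand
"-" genes get reverse-complemented nucleotide sequences.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import gffutils
import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

from .records import Alignment, DomainHit, GeneRecord, ParseError, reverse_complement
from .vocab import Vocabulary

logger = logging.getLogger(__name__)

DEFAULT_EVALUE_MAX = 1e-5


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered ``{id: uppercase sequence}`` map."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        logger.warning("empty FASTA file: %s", path)
        return {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise ParseError(f"{path}: line {lineno}: expected '>' header, got {line[:30]!r}")
            break
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ParseError(f"{path}: duplicate FASTA id {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")  # 60-column wrap


# ----------------------------------------------------------- gene table

_TSV_COLUMNS = ["gene_id", "contig", "start", "end", "strand", "product"]


def read_gene_table(path: str | Path, dialect: str = "gff3", *,
                    contigs: dict[str, str] | None = None,
                    proteins: dict[str, str] | None = None,
                    genome_id: str = "genome") -> list[GeneRecord]:
    """Read CDS features into GeneRecords sorted by (contig, start).

    ``dialect="gff3"`` consumes CDS features carrying a ``locus_tag``
    attribute; ``dialect="tsv"`` consumes a table with columns
    gene_id/contig/start/end/strand/product.  When ``contigs`` is given,
    nucleotide sequences are sliced out (reverse-complemented on "-").
    """
    if dialect == "gff3":
        rows = _read_gff3_rows(Path(path))
    elif dialect == "tsv":
        rows = _read_tsv_rows(Path(path))
    else:
        raise ValueError(f"unknown gene-table dialect {dialect!r}")

    records = []
    for gene_id, contig, start, end, strand, product in rows:
        if start > end:
            raise ParseError(f"{path}: {gene_id}: start {start} > end {end}")
        nt = ""
        if contigs is not None:
            if contig not in contigs:
                raise ParseError(f"{path}: {gene_id}: contig {contig!r} not in FASTA")
            nt = contigs[contig][start - 1:end]
            if strand == "-":
                nt = reverse_complement(nt)
        aa = (proteins or {}).get(gene_id, "")
        if proteins is not None and gene_id not in proteins:
            logger.warning("%s: no protein for locus tag %s", path, gene_id)
        records.append(GeneRecord(gene_id, genome_id, contig, start, end,
                                  strand, nt, aa, product))
    records.sort(key=lambda g: (g.contig_id, g.start))
    return records


def _read_gff3_rows(path: Path):
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    rows = []
    n_cds = 0
    for feat in db.features_of_type("CDS"):
        n_cds += 1
        tags = feat.attributes.get("locus_tag")
        if not tags:
            logger.warning("%s: CDS at %s:%d-%d lacks locus_tag; skipped",
                           path, feat.seqid, feat.start, feat.end)
            continue
        product = (feat.attributes.get("product") or [""])[0]
        strand = feat.strand if feat.strand in {"+", "-"} else "+"
        rows.append((tags[0], feat.seqid, feat.start, feat.end, strand, product))
    if n_cds == 0:
        logger.warning("%s: no CDS features found", path)
    return rows


def _read_tsv_rows(path: Path):
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "contig": str})
    missing = [c for c in _TSV_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if "product" not in df.columns:
        df["product"] = ""
    df["product"] = df["product"].fillna("")
    return [(r.gene_id, r.contig, int(r.start), int(r.end), r.strand, r.product)
            for r in df.itertuples()]


def write_gene_table(genes: list[GeneRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(g.gene_id, g.contig_id, g.start, g.end, g.strand, g.product) for g in genes],
        columns=_TSV_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------- domain TSV

def read_domain_tsv(path: str | Path, vocab: Vocabulary,
                    evalue_max: float = DEFAULT_EVALUE_MAX) -> list[DomainHit]:
    """Read an InterProScan-style TSV into DomainHits.

    Accepts the full 11+-column InterProScan layout (protein, md5, length,
    analysis, signature, description, start, stop, e-value, ...) or a
    minimal 6-column layout (gene_id, signature, description, start, end,
    e-value).  Hits with e-value above ``evalue_max`` are dropped.
    """
    path = Path(path)
    if not path.read_text().strip():
        return []
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] >= 11:
        cols = [0, 4, 6, 7, 8]
    elif df.shape[1] == 6:
        cols = [0, 1, 3, 4, 5]
    else:
        raise ParseError(f"{path}: expected 6 or >=11 columns, got {df.shape[1]}")
    hits = []
    for _, row in df.iterrows():
        gene_id, sig, start, end, ev = (row[c] for c in cols)
        try:
            evalue = float(ev)
        except (TypeError, ValueError):
            raise ParseError(f"{path}: non-numeric e-value {ev!r} for {gene_id}") from None
        if not math.isfinite(evalue) or evalue > evalue_max:
            continue
        hits.append(DomainHit(str(gene_id), str(sig), vocab.label(str(sig)),
                              int(start), int(end), evalue))
    return hits


def write_domain_tsv(hits: list[DomainHit], path: str | Path) -> None:
    """Write hits in the minimal 6-column dialect."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.gene_id}\t{h.signature_id}\t{h.signature_label}\t"
                     f"{h.aa_start}\t{h.aa_end}\t{h.evalue:g}\n")


# --------------------------------------------------------------- Newick

def read_newick(path: str | Path) -> TreeNode:
    """Read a Newick tree; numeric internal-node labels become supports."""
    tree = TreeNode.read(str(path), format="newick")
    tree.assign_supports()  # numeric internal labels -> node.support
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Write Newick; internal-node supports are emitted as labels."""
    tree.write(str(path), format="newick")


# ------------------------------------------------------------ alignment

def read_alignment(path: str | Path, format: str = "fasta",
                   alphabet: str = "protein") -> Alignment:
    """Read an aligned FASTA or Clustal file; gaps normalized to '-'."""
    if format not in {"fasta", "clustal"}:
        raise ValueError(f"unknown alignment format {format!r}")
    if format == "fasta":
        seqs = read_fasta(path)
        labels, rows = list(seqs), list(seqs.values())
    else:
        aln = AlignIO.read(str(path), "clustal")
        labels = [r.id for r in aln]
        rows = [str(r.seq).upper() for r in aln]
    rows = [r.replace(".", "-") for r in rows]
    return Alignment(labels, rows, alphabet)


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    if format == "fasta":
        write_fasta(dict(zip(aln.labels, aln.rows)), path)
    elif format == "clustal":
        bio = AlignIO.MultipleSeqAlignment(
            [SeqRecord(Seq(r), id=l, description="") for l, r in zip(aln.labels, aln.rows)]
        )
        AlignIO.write(bio, str(path), "clustal")
    else:
        raise ValueError(f"unknown alignment format {format!r}")
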