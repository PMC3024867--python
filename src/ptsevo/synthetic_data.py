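"""Synthetic genomes, trees and sequences with known ground truth.

The generator emulates the structures the analysis stages look for:
genomes with a controlled background GC; planted multi-gene PTS sets
whose GC is offset from the background (realized by biasing codon
third positions, so proteins stay comparable across GC regimes);
fused-subunit variants; inserted hypothetical genes inside sets;
orphan subunits; sigma-54 / SIS / IS marker genes in set
neighborhoods; near-identical duplicated sets; and HGT-style sets
whose GC matches a donor regime, planted into a recipient genome along
a known species tree.  Every planted entity is recorded in a
ground-truth manifest.

Simulated CDS carry no reading-frame biology beyond stop-codon
avoidance (third bases of would-be stops are redrawn from the
GC-neutral conditional distribution); there are no indels, so the true
alignment of any simulated protein family is the ungapped homology.
All randomness flows from one seed through named per-stage substreams.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable
from skbio import TreeNode

from . import genome_io
from .records import DomainHit, GeneRecord, GenomeBundle, reverse_complement
from .synteny import classify_markers
from .pts_catalog import required_subunits
from .vocab import Vocabulary

_BASES = np.array(["G", "C", "A", "T"])

_table = CodonTable.unambiguous_dna_by_id[11]
AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in _table.forward_table.items():
    AA_TO_CODONS.setdefault(aa, []).append(codon)
CODON_TO_AA = dict(_table.forward_table)
STOP_CODONS = set(_table.stop_codons)


# ------------------------------------------------------------ spec types

@dataclass
class GeneGrid:
    """Gene layout of one genome: counts, lengths (codons) and gaps (bp)."""
    n_genes: int = 200
    codon_min: int = 150
    codon_max: int = 400
    gap_min: int = 50
    gap_max: int = 250
    set_gap_min: int = 20
    set_gap_max: int = 120


@dataclass
class OperonTemplate:
    """One planted PTS gene set."""
    name: str
    genome: str
    architecture: str          # e.g. "IID/IIC/IIB/IIA", "IIAB/IIC/IID", "IIABC"
    family: str
    gc_offset: float = 0.0     # GC points above the host background
    markers: tuple[str, ...] = ()       # subset of {"sigma54", "sis"}
    inserted_after: int | None = None   # insert a hypothetical gene after this member
    is_flanked: bool = False            # IS elements on both flanks
    hgt_donor: str | None = None        # donor taxon id for HGT plants
    duplicate_of: str | None = None     # name of an earlier template to copy
    duplicate_identity: float = 95.0    # target protein identity of the copy


@dataclass
class SimSpec:
    seed: int
    taxa: dict[str, float]              # taxon id -> background GC%
    templates: list[OperonTemplate] = field(default_factory=list)
    grid: GeneGrid = field(default_factory=GeneGrid)
    birth_rate: float = 1.0

    def __post_init__(self) -> None:
        for t, gc in self.taxa.items():
            if not 0 < gc < 100:
                raise ValueError(f"{t}: GC target must be in (0,100)")
        names = [t.name for t in self.templates]
        if len(set(names)) != len(names):
            raise ValueError("duplicate template names")


def parse_architecture(arch: str) -> list[list[str]]:
    """'IIAB/IIC' -> [['IIA','IIB'], ['IIC']]."""
    genes = []
    for token in arch.split("/"):
        if not token.startswith("II") or not token[2:]:
            raise ValueError(f"bad architecture token {token!r}")
        genes.append(["II" + ch for ch in token[2:]])
    return genes


def default_simspec(seed: int) -> SimSpec:
    """The study conditions used throughout: three genomes on a GC
    gradient (50/43/30%), ~200 genes each, six planted sets — one with
    an inserted hypothetical gene, one orphan subunit, one 95%-identity
    duplicated pair, and two IS-flanked HGT plants at +6 GC points."""
    return SimSpec(
        seed=seed,
        taxa={"G_high": 50.0, "G_mid": 43.0, "G_low": 30.0},
        templates=[
            OperonTemplate("t_insert", "G_low", "IIC/IID/IIB/IIA",
                           "FRU_MAN_SOR", gc_offset=2.0, inserted_after=2),
            OperonTemplate("t_orphan", "G_low", "IIB", "FRU_MAN_SOR",
                           gc_offset=1.0),
            OperonTemplate("t_dup_a", "G_low", "IID/IIC/IIB/IIA",
                           "FRU_MAN_SOR", gc_offset=2.0, markers=("sigma54",)),
            OperonTemplate("t_dup_b", "G_low", "IID/IIC/IIB/IIA",
                           "FRU_MAN_SOR", gc_offset=2.0, markers=("sigma54",),
                           duplicate_of="t_dup_a", duplicate_identity=95.0),
            OperonTemplate("t_hgt_low", "G_low", "IIA/IIB/IIC/IID",
                           "FRU_MAN_SOR", gc_offset=6.0,
                           markers=("sigma54", "sis"), is_flanked=True,
                           hgt_donor="G_high"),
            OperonTemplate("t_hgt_mid", "G_mid", "IIABC", "FRU_MANNITOL",
                           gc_offset=6.0, is_flanked=True, hgt_donor="G_high"),
        ],
    )


# ----------------------------------------------------------- ground truth

@dataclass
class TrueSet:
    name: str
    genome: str
    members: list[str]
    inserted: list[str]
    architecture: str
    family: str
    complete: bool
    orphan: bool
    markers: tuple[str, ...]
    synteny_class: str
    flanked_by_is: bool
    gc_offset: float
    hgt: bool
    donor: str | None
    duplicate_of: str | None


@dataclass
class GroundTruth:
    seed: int
    sets: list[TrueSet] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"seed": self.seed, "sets": [asdict(s) for s in self.sets]}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        return cls(raw["seed"], [TrueSet(**{**s, "markers": tuple(s["markers"])})
                                 for s in raw["sets"]])


# ------------------------------------------------------------ species tree

def sim_species_tree(names: list[str], birth_rate: float,
                     rng: np.random.Generator) -> TreeNode:
    """Ultrametric Yule tree over the given taxa (deterministic per rng)."""
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    n = len(names)
    if n == 1:
        return TreeNode(name=names[0])
    root = TreeNode()
    c1, c2 = TreeNode(), TreeNode()
    root.extend([c1, c2])
    active: list[tuple[TreeNode, float]] = [(c1, 0.0), (c2, 0.0)]
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        node, born = active.pop(int(rng.integers(len(active))))
        node.length = t - born
        k1, k2 = TreeNode(), TreeNode()
        node.extend([k1, k2])
        active.extend([(k1, t), (k2, t)])
    t_end = t + rng.exponential(1.0 / (birth_rate * n))
    for node, born in active:
        node.length = t_end - born
    order = rng.permutation(n)
    tips = list(root.tips())
    for idx, tip in zip(order, tips):
        tip.name = names[int(idx)]
    return root


# ------------------------------------------------------- sequence evolution

def sim_sequences(tree: TreeNode, root_seq: str, model: str = "jc69",
                  rate: float = 1.0, seed: int | None = None,
                  rng: np.random.Generator | None = None) -> dict[str, str]:
    """Evolve a root sequence down a tree; returns leaf sequences.

    DNA (``jc69``): per branch of length L each site substitutes with
    probability 3/4 (1 - exp(-4/3 rate L)), uniform target base.
    Protein (``poisson``): probability 1 - exp(-rate L), uniform target
    residue.  No indels, so leaf sequences stay column-homologous.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if model == "jc69":
        alphabet = np.array(list("ACGT"))
        def p_sub(L): return 0.75 * (1.0 - np.exp(-4.0 / 3.0 * rate * L))
    elif model == "poisson":
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        def p_sub(L): return 1.0 - np.exp(-rate * L)
    else:
        raise ValueError(f"unknown model {model!r}")
    idx_of = {c: i for i, c in enumerate(alphabet)}
    K = len(alphabet)

    def evolve(seq_idx: np.ndarray, node: TreeNode, out: dict[str, str]) -> None:
        if node.length:
            hit = rng.random(seq_idx.size) < p_sub(node.length)
            if hit.any():
                seq_idx = seq_idx.copy()
                # uniform over the K-1 other symbols
                shift = rng.integers(1, K, size=int(hit.sum()))
                seq_idx[hit] = (seq_idx[hit] + shift) % K
        if node.is_tip():
            out[node.name] = "".join(alphabet[seq_idx])
        else:
            for child in node.children:
                evolve(seq_idx, child, out)

    root_idx = np.array([idx_of[c] for c in root_seq.upper()])
    out: dict[str, str] = {}
    for child in (tree.children or [tree]):
        evolve(root_idx, child, out)
    if tree.is_tip():
        out[tree.name] = root_seq.upper()
    return out


# ------------------------------------------------------------- CDS synthesis

def _draw_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = gc / 100.0
    return rng.choice(_BASES, size=n, p=[p / 2, p / 2, (1 - p) / 2, (1 - p) / 2])


def random_cds(rng: np.random.Generator, n_codons: int, gc_target: float,
               gc_background: float | None = None) -> str:
    """Random coding sequence at a target GC.

    When ``gc_background`` is given, codon positions 1+2 follow the
    background composition and position 3 is biased so the overall GC
    hits ``gc_target``.  Stop codons are removed by redrawing the third
    base from the (GC-neutral) non-stop conditional distribution.
    """
    if gc_background is None:
        codons = _draw_bases(rng, 3 * n_codons, gc_target).reshape(n_codons, 3)
        p3 = gc_target / 100.0
    else:
        p12 = _draw_bases(rng, 2 * n_codons, gc_background).reshape(n_codons, 2)
        q = 3.0 * gc_target - 2.0 * gc_background  # third-position GC%
        q = min(max(q, 2.0), 98.0)
        p3 = q / 100.0
        third = _draw_bases(rng, n_codons, q)
        codons = np.column_stack([p12, third])
    # stop removal: TA? -> {C,T} keeping P(GC)=p3; TGA -> {C,G,T} renormalized
    for i in range(n_codons):
        c = "".join(codons[i])
        if c not in STOP_CODONS:
            continue
        if c.startswith("TA"):
            codons[i, 2] = "C" if rng.random() < p3 else "T"
        else:  # TGA
            w = np.array([p3 / 2, p3 / 2, (1 - p3) / 2])
            codons[i, 2] = rng.choice(np.array(["C", "G", "T"]), p=w / w.sum())
    return "".join(codons.ravel())


def translate_cds(nt: str) -> str:
    return "".join(CODON_TO_AA[nt[i:i + 3]] for i in range(0, len(nt), 3))


def mutate_cds_to_identity(nt: str, target_identity: float,
                           rng: np.random.Generator) -> str:
    """Copy a CDS, substituting codons so the protein identity hits the
    target (each touched codon is recoded to a different amino acid)."""
    n = len(nt) // 3
    k = int(round((1.0 - target_identity / 100.0) * n))
    positions = rng.choice(n, size=k, replace=False)
    codons = [nt[3 * i:3 * i + 3] for i in range(n)]
    aas = sorted(AA_TO_CODONS)
    for i in positions:
        current = CODON_TO_AA[codons[i]]
        choices = [a for a in aas if a != current]
        new_aa = choices[int(rng.integers(len(choices)))]
        opts = AA_TO_CODONS[new_aa]
        codons[i] = opts[int(rng.integers(len(opts)))]
    return "".join(codons)


# ------------------------------------------------------------- genome build

@dataclass
class SimResult:
    spec: SimSpec
    bundles: dict[str, GenomeBundle]
    species_tree: TreeNode
    truth: GroundTruth


def _plan_genome(spec: SimSpec, genome: str) -> list[dict]:
    """Slot plan: which grid positions hold set members/markers."""
    grid = spec.grid
    plan = [{"role": "bg"} for _ in range(grid.n_genes)]
    templates = [t for t in spec.templates if t.genome == genome]
    for idx, tpl in enumerate(templates):
        genes = parse_architecture(tpl.architecture)
        block: list[dict] = []
        if tpl.is_flanked:
            block.append({"role": "marker", "marker": "is_element", "tpl": tpl})
        if "sigma54" in tpl.markers:
            block.append({"role": "marker", "marker": "sigma54", "tpl": tpl})
        for m, subunits in enumerate(genes):
            block.append({"role": "member", "tpl": tpl, "subunits": subunits,
                          "member_index": m})
            if tpl.inserted_after == m:
                block.append({"role": "inserted", "tpl": tpl})
        if "sis" in tpl.markers:
            block.append({"role": "marker", "marker": "sis", "tpl": tpl})
        if tpl.is_flanked:
            block.append({"role": "marker", "marker": "is_element", "tpl": tpl})
        start = (idx + 1) * grid.n_genes // (len(templates) + 1)
        if start + len(block) > grid.n_genes:
            raise ValueError(f"{genome}: grid too small for planted sets")
        for off, entry in enumerate(block):
            plan[start + off] = entry
    return plan


_MARKER_PRODUCTS = {
    "sigma54": "RNA polymerase sigma-54 factor RpoN",
    "sis": "sugar isomerase (SIS) domain protein",
    "is_element": "transposase, insertion sequence IS elem",
}


def sim_genome(spec: SimSpec, vocab: Vocabulary | None = None) -> SimResult:
    """Generate all genomes of a SimSpec plus the species tree and the
    ground-truth manifest.  Byte-deterministic given the spec."""
    vocab = vocab or Vocabulary.default()
    ss = np.random.SeedSequence(spec.seed)
    streams = ss.spawn(1 + len(spec.taxa))
    tree_rng = np.random.default_rng(streams[0])
    taxa = list(spec.taxa)
    species_tree = sim_species_tree(taxa, spec.birth_rate, tree_rng)

    truth = GroundTruth(spec.seed)
    bundles: dict[str, GenomeBundle] = {}
    member_nts: dict[str, list[str]] = {}  # template name -> member CDSs

    for stream, genome in zip(streams[1:], taxa):
        rng = np.random.default_rng(stream)
        bg_gc = spec.taxa[genome]
        grid = spec.grid
        plan = _plan_genome(spec, genome)

        genes_nt: list[str] = []
        tpl_members: dict[str, list[int]] = {}
        for slot, entry in enumerate(plan):
            n_codons = int(rng.integers(grid.codon_min, grid.codon_max + 1))
            if entry["role"] == "member":
                tpl = entry["tpl"]
                if tpl.duplicate_of is not None:
                    src = member_nts[tpl.duplicate_of][entry["member_index"]]
                    nt = mutate_cds_to_identity(src, tpl.duplicate_identity, rng)
                else:
                    nt = random_cds(rng, n_codons, bg_gc + tpl.gc_offset, bg_gc)
                member_nts.setdefault(tpl.name, [])
                assert len(member_nts[tpl.name]) == entry["member_index"]
                member_nts[tpl.name].append(nt)
                tpl_members.setdefault(tpl.name, []).append(slot)
            elif entry["role"] == "marker":
                nt = random_cds(rng, 200, bg_gc)
            else:  # bg / inserted
                nt = random_cds(rng, n_codons, bg_gc)
            genes_nt.append(nt)

        # strands: one per template (members share it; a duplicated block
        # keeps its source's orientation), random elsewhere
        tpl_strand: dict[str, str] = {}
        for t in spec.templates:
            if t.genome != genome:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            tpl_strand[t.name] = tpl_strand.get(t.duplicate_of, strand)
        contig_parts: list[str] = []
        pos = 0
        records: list[GeneRecord] = []
        domains: list[DomainHit] = []

        def in_block(i: int) -> bool:
            return plan[i]["role"] in {"member", "inserted"}

        for slot, (entry, nt) in enumerate(zip(plan, genes_nt)):
            tight = slot > 0 and in_block(slot) and in_block(slot - 1)
            lo, hi = ((grid.set_gap_min, grid.set_gap_max) if tight
                      else (grid.gap_min, grid.gap_max))
            gap = int(rng.integers(lo, hi + 1))
            contig_parts.append("".join(_draw_bases(rng, gap, bg_gc)))
            pos += gap
            start, end = pos + 1, pos + len(nt)
            tpl = entry.get("tpl")
            if entry["role"] in {"member", "inserted"} and tpl is not None:
                strand = tpl_strand[tpl.name]
            else:
                strand = "+" if rng.random() < 0.5 else "-"
            contig_parts.append(nt if strand == "+" else reverse_complement(nt))
            pos += len(nt)
            gene_id = f"{genome}_{slot:04d}"
            aa = translate_cds(nt)
            if entry["role"] == "member":
                product = (f"PTS system, {tpl.family} family, "
                           f"{'/'.join(entry['subunits'])} component")
                n_sub = len(entry["subunits"])
                span = len(aa) // n_sub
                for si, sub in enumerate(entry["subunits"]):
                    sig = vocab.pts_signature(sub, tpl.family)
                    a0 = si * span + 1
                    a1 = len(aa) if si == n_sub - 1 else (si + 1) * span
                    domains.append(DomainHit(gene_id, sig, vocab.label(sig),
                                             a0, a1, 1e-40))
            elif entry["role"] == "marker":
                product = _MARKER_PRODUCTS[entry["marker"]]
                sig = vocab.marker_signature(entry["marker"])
                domains.append(DomainHit(gene_id, sig, vocab.label(sig),
                                         1, len(aa), 1e-30))
            else:
                product = "hypothetical protein"
            records.append(GeneRecord(gene_id, genome, f"{genome}_c1",
                                      start, end, strand, nt, aa, product))
        contig_parts.append("".join(_draw_bases(
            rng, int(rng.integers(grid.gap_min, grid.gap_max + 1)), bg_gc)))
        contig = "".join(contig_parts)
        bundles[genome] = GenomeBundle(genome, {f"{genome}_c1": contig},
                                       records, domains)

        for tpl in (t for t in spec.templates if t.genome == genome):
            member_ids = [f"{genome}_{s:04d}" for s in tpl_members[tpl.name]]
            inserted_ids = [f"{genome}_{s:04d}" for s, e in enumerate(plan)
                            if e["role"] == "inserted" and e["tpl"] is tpl]
            union = {s for g in parse_architecture(tpl.architecture) for s in g}
            complete = union >= required_subunits(tpl.family)
            truth.sets.append(TrueSet(
                name=tpl.name, genome=genome, members=member_ids,
                inserted=inserted_ids, architecture=tpl.architecture,
                family=tpl.family, complete=complete,
                orphan=len(member_ids) == 1 and not complete,
                markers=tpl.markers,
                synteny_class=classify_markers("sigma54" in tpl.markers,
                                               "sis" in tpl.markers),
                flanked_by_is=tpl.is_flanked, gc_offset=tpl.gc_offset,
                hgt=tpl.hgt_donor is not None, donor=tpl.hgt_donor,
                duplicate_of=tpl.duplicate_of))

    return SimResult(spec, bundles, species_tree, truth)


# ------------------------------------------------------------------- I/O

def write_simulation(result: SimResult, outdir: str | Path) -> None:
    """Write the exact formats genome_io reads, plus the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome_io.write_newick(result.species_tree, outdir / "species_tree.nwk")
    result.truth.to_json(outdir / "manifest.json")
    for genome, bundle in result.bundles.items():
        gdir = outdir / "genomes" / genome
        gdir.mkdir(parents=True, exist_ok=True)
        genome_io.write_fasta(bundle.contigs, gdir / "contigs.fna")
        genome_io.write_gene_table(bundle.genes, gdir / "genes.tsv")
        genome_io.write_fasta({g.gene_id: g.aa_seq for g in bundle.genes},
                              gdir / "proteins.faa")
        genome_io.write_domain_tsv(bundle.domains, gdir / "domains.tsv")


def load_simulation(indir: str | Path,
                    vocab: Vocabulary | None = None,
                    evalue_max: float = genome_io.DEFAULT_EVALUE_MAX,
                    ) -> tuple[dict[str, GenomeBundle], TreeNode, GroundTruth | None]:
    """Read a simulation directory (or any directory in its layout)."""
    vocab = vocab or Vocabulary.default()
    indir = Path(indir)
    bundles = {}
    for gdir in sorted((indir / "genomes").iterdir()):
        genome = gdir.name
        contigs = genome_io.read_fasta(gdir / "contigs.fna")
        proteins = genome_io.read_fasta(gdir / "proteins.faa")
        genes = genome_io.read_gene_table(gdir / "genes.tsv", "tsv",
                                          contigs=contigs, proteins=proteins,
                                          genome_id=genome)
        domains = genome_io.read_domain_tsv(gdir / "domains.tsv", vocab, evalue_max)
        bundles[genome] = GenomeBundle(genome, contigs, genes, domains)
    tree_path = indir / "species_tree.nwk"
    tree = genome_io.read_newick(tree_path) if tree_path.exists() else None
    manifest = indir / "manifest.json"
    truth = GroundTruth.from_json(manifest) if manifest.exists() else None
    return bundles, tree, truth
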