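"""Stage orchestration: catalog -> GC -> synteny -> trees -> HGT.

Each ``run_*`` function is pure (bundles in, tables out); ``run_all``
chains them and ``write_reports`` serializes every stage to TSV/JSON
in one output directory.  Stages cross-reference by ``set_id``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from skbio import TreeNode

from . import gc_profile, genome_io, hgt_model, phylo, pts_catalog, synteny
from .records import GenomeBundle
from .vocab import Vocabulary

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    evalue_max: float = 1e-5
    max_gap_bp: int = 300
    max_inserted: int = 1
    k_groups: int = 3
    window: int = 4
    identity_min: float = 90.0
    z_min: float = 2.0
    bootstrap: int = 500
    seed: int = 0
    include_inserted: bool = True   # count inserted genes in set GC
    exclude_orphans: bool = True    # keep orphans out of GC grouping
    min_tree_leaves: int = 4        # smallest family tree worth building
    distance: str = "poisson"       # or "p"

    def __post_init__(self) -> None:
        positives = {"evalue_max": self.evalue_max, "max_gap_bp": self.max_gap_bp,
                     "k_groups": self.k_groups, "window": self.window,
                     "identity_min": self.identity_min, "z_min": self.z_min}
        for name, value in positives.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.max_inserted < 0 or self.bootstrap < 0:
            raise ValueError("max_inserted and bootstrap must be >= 0")
        if self.distance not in {"poisson", "p"}:
            raise ValueError(f"unknown distance {self.distance!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


@dataclass
class PipelineResult:
    config: PipelineConfig
    sets_by_genome: dict[str, list] = field(default_factory=dict)
    catalog: dict[str, pd.DataFrame] = field(default_factory=dict)
    gc: pd.DataFrame | None = None
    synteny: pd.DataFrame | None = None
    contexts: dict[str, synteny.SyntenyContext] = field(default_factory=dict)
    trees: dict[str, dict] = field(default_factory=dict)
    duplicates: list = field(default_factory=list)
    hgt: pd.DataFrame | None = None
    gradient: pd.DataFrame | None = None

    def all_sets(self) -> list:
        return [s for sets in self.sets_by_genome.values() for s in sets]


def run_catalog(bundles: dict[str, GenomeBundle], vocab: Vocabulary,
                cfg: PipelineConfig) -> tuple[dict[str, list], dict[str, pd.DataFrame]]:
    sets_by_genome = {
        gid: pts_catalog.catalog_genome(b, vocab, cfg.max_gap_bp, cfg.max_inserted)
        for gid, b in bundles.items()
    }
    lengths = {gid: sum(len(c) for c in b.contigs.values())
               for gid, b in bundles.items()}
    summary = pts_catalog.catalog_summary(sets_by_genome, lengths)
    return sets_by_genome, summary


def run_gc(bundles: dict[str, GenomeBundle], sets_by_genome: dict[str, list],
           cfg: PipelineConfig) -> pd.DataFrame:
    rows = []
    for gid, sets in sets_by_genome.items():
        bundle = bundles[gid]
        baseline = gc_profile.genome_baseline(bundle)
        genes = bundle.genes_by_id()
        values, ids = [], []
        for s in sets:
            gc = gc_profile.set_gc(s, genes, include_inserted=cfg.include_inserted)
            z, direction = gc_profile.gc_anomaly(gc, baseline)
            rows.append({"set_id": s.set_id, "genome_id": gid, "family": s.family,
                         "length_bp": s.end - s.start + 1, "gc_percent": gc,
                         "genome_gc": baseline.genome_gc,
                         "baseline_mean": baseline.gene_mean,
                         "baseline_sd": baseline.gene_sd,
                         "z": z, "direction": direction, "gc_group": None})
            if not (cfg.exclude_orphans and s.orphan):
                values.append(gc)
                ids.append(s.set_id)
        if values:
            k = min(cfg.k_groups, len(values))
            grouping = gc_profile.group_gc(values, k, ids)
            for row in rows:
                if row["set_id"] in grouping.assignment:
                    row["gc_group"] = grouping.assignment[row["set_id"]]
    return pd.DataFrame(rows)


def run_synteny(bundles: dict[str, GenomeBundle], sets_by_genome: dict[str, list],
                vocab: Vocabulary, cfg: PipelineConfig,
                ) -> tuple[pd.DataFrame, dict[str, synteny.SyntenyContext]]:
    rows, contexts = [], {}
    for gid, sets in sets_by_genome.items():
        bundle = bundles[gid]
        domains = bundle.domains_by_gene()
        for s in sets:
            ctx = synteny.analyze_set(s, bundle.genes, domains, vocab, cfg.window)
            contexts[s.set_id] = ctx
            rows.append({"set_id": s.set_id, "genome_id": gid,
                         "synteny_class": ctx.synteny_class,
                         "sigma54": ctx.sigma54, "sis": ctx.sis,
                         "is_adjacent": ctx.is_adjacent,
                         "flanked_by_is": ctx.flanked_by_is,
                         "marker_genes": ";".join(
                             f"{m}:{','.join(g)}" for m, g in ctx.marker_genes.items()),
                         "architecture": s.architecture_string})
    return pd.DataFrame(rows), contexts


def run_tree(bundles: dict[str, GenomeBundle], sets_by_genome: dict[str, list],
             cfg: PipelineConfig,
             contexts: dict[str, synteny.SyntenyContext] | None = None,
             ) -> tuple[dict[str, dict], list]:
    """Per-family IIB trees (substrate specificity lives on IIB) plus
    duplicate-set detection."""
    proteins = {g.gene_id: g.aa_seq for b in bundles.values() for g in b.genes}
    all_sets = [s for sets in sets_by_genome.values() for s in sets]

    by_family: dict[str, dict[str, str]] = {}
    leaf_sets: dict[str, dict[str, str]] = {}
    for s in all_sets:
        gid = phylo._iib_gene(s)
        if gid and proteins.get(gid):
            by_family.setdefault(s.family, {})[gid] = proteins[gid]
            leaf_sets.setdefault(s.family, {})[gid] = s.set_id

    trees: dict[str, dict] = {}
    for family, seqs in by_family.items():
        if len(seqs) < cfg.min_tree_leaves:
            logger.info("family %s: only %d IIB genes; no tree", family, len(seqs))
            continue
        msa = phylo.progressive_msa(seqs)
        tree, supports = phylo.bootstrap(msa, B=cfg.bootstrap, seed=cfg.seed,
                                         correction=cfg.distance)
        trees[family] = {"msa": msa, "tree": tree, "supports": supports,
                         "leaf_set": leaf_sets[family]}
    duplicates = phylo.detect_duplicates(all_sets, proteins,
                                         identity_min=cfg.identity_min,
                                         contexts=contexts or {})
    return trees, duplicates


def run_hgt(bundles: dict[str, GenomeBundle], sets_by_genome: dict[str, list],
            gc_df: pd.DataFrame, synteny_df: pd.DataFrame,
            trees: dict[str, dict], species_tree: TreeNode | None,
            cfg: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    genome_gc = {gid: b.genome_gc for gid, b in bundles.items()}
    groups = None
    if species_tree is not None and len(genome_gc) >= 2:
        groups = hgt_model.classify_taxa(species_tree, genome_gc)

    mixed: dict[str, bool] = {}
    if groups is not None:
        gene_genome = {g.gene_id: gid for gid, b in bundles.items() for g in b.genes}
        for family, info in trees.items():
            flags, _ = hgt_model.mixed_clade_test(info["tree"], gene_genome, groups)
            for leaf, flag in flags.items():
                mixed[info["leaf_set"][leaf]] = flag

    is_flags = dict(zip(synteny_df["set_id"], synteny_df["flanked_by_is"])) \
        if len(synteny_df) else {}
    calls = []
    for row in gc_df.itertuples():
        call = hgt_model.hgt_verdict(
            row.set_id, row.z, row.direction,
            mixed.get(row.set_id, False), bool(is_flags.get(row.set_id, False)),
            z_min=cfg.z_min)
        calls.append({**asdict(call), "genome_id": row.genome_id,
                      "family": row.family})
    hgt_df = pd.DataFrame(calls)

    set_gc_values = dict(zip(gc_df["set_id"], gc_df["gc_percent"]))
    families = sorted({s.family for sets in sets_by_genome.values() for s in sets})
    gradients = [hgt_model.gc_gradient_report(list(bundles.values()),
                                              sets_by_genome, set_gc_values, fam)
                 .assign(family=fam) for fam in families]
    gradient = pd.concat(gradients, ignore_index=True) if gradients \
        else pd.DataFrame()
    return hgt_df, gradient


def run_all(bundles: dict[str, GenomeBundle], vocab: Vocabulary | None = None,
            species_tree: TreeNode | None = None,
            cfg: PipelineConfig | None = None) -> PipelineResult:
    vocab = vocab or Vocabulary.default()
    cfg = cfg or PipelineConfig()
    logger.info("pipeline thresholds: %s", asdict(cfg))
    result = PipelineResult(cfg)
    result.sets_by_genome, result.catalog = run_catalog(bundles, vocab, cfg)
    result.gc = run_gc(bundles, result.sets_by_genome, cfg)
    result.synteny, result.contexts = run_synteny(bundles, result.sets_by_genome,
                                                  vocab, cfg)
    result.trees, result.duplicates = run_tree(bundles, result.sets_by_genome,
                                               cfg, result.contexts)
    result.hgt, result.gradient = run_hgt(bundles, result.sets_by_genome,
                                          result.gc, result.synteny,
                                          result.trees, species_tree, cfg)
    return result


def write_reports(result: PipelineResult, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def save(df: pd.DataFrame | None, name: str) -> None:
        if df is not None:
            path = outdir / name
            df.to_csv(path, sep="\t", index=False, float_format="%.6g")
            written.append(path)

    sets_rows = []
    catalog_json: dict[str, list] = {}
    for gid, sets in result.sets_by_genome.items():
        catalog_json[gid] = []
        for s in sets:
            rec = {"set_id": s.set_id, "members": s.members,
                   "inserted": s.inserted_genes, "family": s.family,
                   "architecture": s.architecture_string, "complete": s.complete,
                   "orphan": s.orphan, "contig": s.contig_id,
                   "start": s.start, "end": s.end, "strand": s.strand}
            catalog_json[gid].append(rec)
            sets_rows.append({"genome_id": gid, **rec,
                              "members": ",".join(s.members),
                              "inserted": ",".join(s.inserted_genes)})
    save(pd.DataFrame(sets_rows), "sets.tsv")
    (outdir / "catalog.json").write_text(json.dumps(catalog_json, indent=1))
    written.append(outdir / "catalog.json")

    save(result.catalog.get("counts"), "catalog_counts.tsv")
    save(result.gc, "gc.tsv")
    save(result.synteny, "synteny.tsv")
    if result.duplicates:
        save(pd.DataFrame([asdict(d) for d in result.duplicates]), "duplicates.tsv")
    else:
        save(pd.DataFrame(columns=["set_a", "set_b", "gene_a", "gene_b",
                                   "identity", "architecture_match", "relation"]),
             "duplicates.tsv")
    save(result.hgt, "hgt_calls.tsv")
    save(result.gradient, "gradient.tsv")
    for family, info in result.trees.items():
        tdir = outdir / "trees"
        tdir.mkdir(exist_ok=True)
        genome_io.write_newick(info["tree"], tdir / f"{family}.nwk")
        genome_io.write_alignment(info["msa"], tdir / f"{family}.afa")
        written.append(tdir / f"{family}.nwk")
    return written
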