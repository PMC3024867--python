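# Methods

## Scope and model

`ptsevo` operationalizes a comparative-genomics argument about the
origin of bacterial PTS enzyme II gene sets: if a sugar-uptake operon
was acquired horizontally from a higher-GC donor, it should (i) sit
above its host genome's GC, with the excess eroding over time, (ii)
group with donor-lineage homologs in a gene tree rather than following
the species tree, and (iii) occasionally retain mobility scars (IS
elements) at its flanks.  None of these signals is decisive alone, so
the screen is explicitly composite: each is reduced to a boolean
evidence line and a set is STRONG with ≥ 2 lines, CANDIDATE with 1,
NONE with 0.  The two-of-three rule, the z ≥ 2 threshold and the
per-gene-SD normalization are this package's formalization of an
otherwise qualitative argument; all are config keys
(`z_min`, `PipelineConfig`).

## Catalog

Subunit calls come only from domain evidence: a controlled vocabulary
(editable TSV shipped with the package) maps signature accessions to
(subunit, family) pairs; a gene's subunits are read in N→C order of
its hits, so one peptide with IIA+IIB domains becomes the fusion token
`IIAB`.  The gene's family is the majority family over its PTS hits,
with ties demoted to UNKNOWN.  Sets are maximal same-contig,
same-family runs with intergenic gaps ≤ `max_gap_bp` (default 300 bp —
operon-scale spacing) tolerating at most `max_inserted` (default 1)
consecutive non-PTS genes between members, because real clusters do
carry the odd inserted hypothetical gene.  Completeness is
family-aware: the fructose/mannose/sorbose family is the only one with
a IID subunit, so it requires {IIA,IIB,IIC,IID} while every other
family requires {IIA,IIB,IIC}; the presence of IID in a set labelled
otherwise forces reclassification.  A lone incomplete gene is an
orphan.  Mixed-strand runs take the majority strand and are logged.

## GC profile

GC% is 100·(G+C)/length with ambiguity codes in the denominator only;
it is computed on coding-strand CDS concatenations (GC is
strand-symmetric, so the choice is immaterial).  Set GC is therefore
length-weighted, which is why including an inserted AT-rich gene
lowers it — the behavior the `include_inserted` flag exposes.  The
anomaly baseline is the per-gene GC distribution (mean, SD with
ddof=1) of all host CDS, because genes and gene sets are the units
compared; direction ("above"/"below") is taken against whole-genome
GC.  Grouping of set GC values uses the exact optimal contiguous
k-partition of the sorted values (minimum within-group sum of squares
by dynamic programming — the 1-D case where k-means is solvable
exactly), k = 3 by default; ties prefer boundaries at the largest
value gaps, then leftmost.  Orphans are excluded from grouping by
default since single short genes are the noisiest entities.  Values
are kept at full precision internally and rounded only in reports.

## Synteny

The neighborhood is the up-to-4 genes on each flank on the set's
contig (window configurable; truncated at contig ends; a set's own
members are never its neighbors).  Markers fire on domain labels
first, case-insensitive product regexes second (both editable):
sigma-54 (rpoN), SIS-domain proteins, and IS-element transposases.
The sigma-54 × SIS presence pattern yields the four synteny classes;
IS evidence is kept separate, with `flanked_by_IS` demanding hits on
both flanks (one-sided hits are only `is_adjacent`).  Architecture
comparison treats two sets as sharing organization when their token
lists are equal, or equal after reversal when they lie on opposite
strands (reading each cluster from its own 5′ end).

## Phylogenetics

Pairwise alignment is global affine-gap Gotoh with BLOSUM62 and gap
existence/extension 11/1 (blastp-like defaults, so identity figures
are comparable to common practice); ambiguous residues score 0.
Traceback ties prefer substitution over a gap in the first sequence
over a gap in the second, making output deterministic.  Identity is
per aligned column.  Distances are p-distance with pairwise gap
deletion, Poisson-corrected (d = −ln(1−p), capped at 5 when
saturated); p-distance is available by flag.  Trees come from classic
Neighbor-Joining (Q-criterion; ties broken by smallest leaf-label
pair; negative branch estimates clamped to 0 with a log line),
returned unrooted with a trifurcating root.  Bootstrap resamples
alignment columns with replacement, rebuilds distances+NJ, and scores
each internal-edge bipartition of the full-data tree as a percent of
replicates.  The progressive MSA aligns profiles along an NJ guide
tree with mean-of-pairs column scoring; with two sequences it reduces
exactly to the pairwise aligner.  Duplicate detection aligns the IIB
subunits (IIB determines substrate specificity, so it is the family's
natural marker gene) of same-genome set pairs: identity ≥ 90% with
matching organization is a duplicate, ≥ 50% a paralog.

Because the aligner is global while database searches report local
alignments, identities can differ by a point or two on sequences with
ragged termini; validation of printed identity values should allow ±2
points.

## HGT screen

Taxa are split into two groups at the deepest bipartition of the
supplied species tree (explicit label files override); the group with
the higher mean genome GC is the donor clade.  The incongruence test
asks, per gene-tree leaf, whether its parent clade contains both
groups; a congruent tree yields zero mixed leaves, and the tree-level
count of bipartitions impure on both sides is also reported.  Donor
direction is only ever inferred when the set's GC is elevated — a
below-baseline set gives no directional information under the model.

## Simulator

`synthetic_data` generates what the pipeline consumes: per-genome
contig FASTA, gene TSV, protein FASTA, domain TSV, a Yule species
tree, and a JSON manifest of every planted entity.  Background
sequence and genes are drawn i.i.d. at the genome's target GC; planted
sets realize their GC offset at codon third positions so proteins stay
comparable across GC regimes; would-be stop codons have their third
base redrawn from the non-stop conditional distribution, which is
GC-neutral for TAA/TAG and adds < 0.1 GC point overall.  Duplicated
blocks copy the source set's CDS and recode a fraction of codons to
different amino acids to hit the target protein identity (95% by
default), inheriting the source orientation.  HGT plants are sets at
donor-like GC (+6 points by default) flanked by IS-element genes.
Substitution-only sequence evolution (JC69 for DNA, Poisson for
protein) is provided for tree/bootstrap studies; there are **no
indels** in v1, so true alignments are the ungapped homology columns
and the progressive aligner is validated on those plus hand-made
gapped cases.  All randomness flows from one seed through named
`SeedSequence` substreams (tree, then one per genome), making outputs
byte-identical per seed.

The default study conditions (`default_simspec`): three genomes at
50/43/30% background GC, 200 genes each (150–400 codons, 50–250 bp
gaps; 20–120 bp inside sets), six planted sets — a four-gene set with
one inserted hypothetical gene, an orphan IIB, a 95%-identity
duplicated pair (sigma-54 neighborhoods), an IS-flanked +6 plant with
sigma-54+SIS context, and an IS-flanked fused-IIABC +6 plant of the
mannitol-type family in the mid-GC genome.

## What the synthetic data does and does not show

The simulator reproduces the *statistical* structure the stages rely
on — composition offsets, operon layout, marker placement, identity
levels — but not real-genome complications: no codon-usage or
amelioration gradients, no rearrangements or pseudogenes, no
annotation errors, no shared ancestry between background genes.
Passing the recovery tests therefore demonstrates algorithmic
correctness at realistic signal sizes, not field performance on real
annotations, where set counts are known to be annotation-version
dependent.  Note also that the default non-HGT sets are planted 1–2 GC
points above background, which deliberately places the GC evidence
line near its z = 2 threshold: measured false-positive rates of the
screen hover around 3–5% across seeds, so the FPR ≤ 5% operating point
should be read as approximate at these conditions.

## Validation studies and problem sizes

`ptsevo.evaluation` holds the independent-oracle studies that both the
test suite and `scripts/acceptance.py` run: NJ against the path metric
of 200 random additive trees (4–16 taxa; exact recovery to 1e-9);
Gotoh scores against exhaustive enumeration of all global alignments
(100 pairs, length ≤ 8); the grouping DP against brute-force
contiguous partitions (n ≤ 12, k ≤ 4) plus the published nine-value
reference split; end-to-end recovery of the default simulation's
manifest; screen sensitivity/FPR over ≥ 200 replicate sets (catalog +
GC + synteny per replicate; gene trees are exercised in the end-to-end
run rather than per replicate); and bootstrap supports (B = 500) on
1000 simulated protein sites over a six-taxon tree with long internal
branches.  These sizes keep the whole validation under a few minutes
on one core while leaving each statistic well away from small-sample
artifacts.

## Known limitations

GenBank flat files are not parsed (export GFF3+FASTA instead); gene
calling, remote database searches and IS-database queries are out of
scope — domain tables and IS annotations are inputs.  The aligner has
no sequence weighting or position-specific gap penalties; trees are
distance-based only (no ML/Bayesian).  Within-genome GC heterogeneity
(e.g. strand or replication-timing effects) is not modelled in the
baseline, which treats per-gene GC as exchangeable.
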