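"""GC content of genes, gene sets and genomes; optimal 1-D grouping;
GC-anomaly scoring.

GC% is 100·(G+C)/length with ambiguity codes (N, ...) counting in the
denominator only.  Set GC is computed over the concatenated coding
sequences of the members, i.e. length-weighted.  The anomaly baseline is
the per-gene GC distribution of the host genome, because genes/sets are
the units being compared.  Grouping of set GC values is the exact
optimal contiguous k-partition of the sorted values (minimum
within-group sum of squares, dynamic programming), which is the 1-D
analogue of k-means with a global optimum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .records import GeneRecord, GenomeBundle

logger = logging.getLogger(__name__)

_TIE_EPS = 1e-9


def gc_percent(seq: str) -> float:
    """GC% of a nucleotide string; N etc. count in the denominator."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def set_gc(pts_set, genes_by_id: dict[str, GeneRecord],
           include_inserted: bool = False) -> float:
    """Length-weighted GC% of a gene set's concatenated CDS."""
    ids = list(pts_set.members)
    if include_inserted:
        ids += list(pts_set.inserted_genes)
    parts = []
    for gid in ids:
        gene = genes_by_id.get(gid)
        if gene is None or not gene.nt_seq:
            raise ValueError(f"missing nucleotide sequence for member {gid}")
        parts.append(gene.nt_seq)
    return gc_percent("".join(parts))


@dataclass
class GCBaseline:
    genome_id: str
    genome_gc: float      # whole-genome GC% over concatenated contigs
    gene_mean: float      # mean of per-CDS GC%
    gene_sd: float        # SD (ddof=1) of per-CDS GC%
    n_genes: int


def genome_baseline(bundle: GenomeBundle) -> GCBaseline:
    """Whole-genome GC plus the per-gene GC distribution of all CDS."""
    vals = np.array([gc_percent(g.nt_seq) for g in bundle.genes if g.nt_seq])
    if vals.size == 0:
        raise ValueError(f"{bundle.genome_id}: no gene sequences")
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    if sd == 0.0:
        logger.warning("%s: degenerate per-gene GC distribution (SD=0); "
                       "z-scores undefined", bundle.genome_id)
    return GCBaseline(bundle.genome_id, bundle.genome_gc,
                      float(vals.mean()), sd, int(vals.size))


@dataclass
class GCProfile:
    entity_id: str
    length_bp: int
    gc_percent: float
    baseline_mean: float
    baseline_sd: float

    @property
    def z(self) -> float:
        if self.baseline_sd == 0.0:
            return math.nan
        return (self.gc_percent - self.baseline_mean) / self.baseline_sd


def gc_anomaly(set_gc_value: float, baseline: GCBaseline) -> tuple[float, str]:
    """(z, direction) of a set's GC against the host baseline.

    z is relative to the per-gene distribution; direction compares to the
    whole-genome GC ("above" iff strictly greater).
    """
    z = math.nan if baseline.gene_sd == 0.0 else \
        (set_gc_value - baseline.gene_mean) / baseline.gene_sd
    direction = "above" if set_gc_value > baseline.genome_gc else "below"
    return z, direction


# ------------------------------------------------------- 1-D grouping

@dataclass
class GCGrouping:
    k: int
    sorted_values: list[float]
    sorted_ids: list[str]
    assignment: dict[str, int] = field(default_factory=dict)
    boundaries: list[int] = field(default_factory=list)  # start index of each group
    within_ss: float = 0.0

    def groups(self) -> list[list[float]]:
        edges = self.boundaries + [len(self.sorted_values)]
        return [self.sorted_values[a:b] for a, b in zip(edges, edges[1:])]


def _segment_ss(prefix: np.ndarray, prefix2: np.ndarray, i: int, j: int) -> float:
    """Within-SS of sorted values[i:j]."""
    n = j - i
    s = prefix[j] - prefix[i]
    s2 = prefix2[j] - prefix2[i]
    return max(0.0, s2 - s * s / n)


def group_gc(values: list[float], k: int,
             ids: list[str] | None = None) -> GCGrouping:
    """Exact optimal contiguous k-partition of sorted values (min within-SS).

    Deterministic tie-break among equally optimal partitions: prefer
    boundaries falling at the largest gaps between consecutive sorted
    values, then the leftmost boundary.
    """
    n = len(values)
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    if ids is None:
        ids = [str(i) for i in range(n)]
    order = sorted(range(n), key=lambda i: (values[i], ids[i]))
    sv = [values[i] for i in order]
    sids = [ids[i] for i in order]
    arr = np.asarray(sv, dtype=float)
    prefix = np.concatenate([[0.0], np.cumsum(arr)])
    prefix2 = np.concatenate([[0.0], np.cumsum(arr * arr)])

    # D[m][j] = min within-SS of splitting sv[:j] into m groups
    D = np.full((k + 1, n + 1), np.inf)
    D[0][0] = 0.0
    for m in range(1, k + 1):
        for j in range(m, n + 1):
            best = np.inf
            for i in range(m - 1, j):
                c = D[m - 1][i] + _segment_ss(prefix, prefix2, i, j)
                if c < best:
                    best = c
            D[m][j] = best

    # backtrack, breaking ties by gap size then leftmost boundary
    boundaries: list[int] = []
    j = n
    for m in range(k, 0, -1):
        candidates = []
        for i in range(m - 1, j):
            c = D[m - 1][i] + _segment_ss(prefix, prefix2, i, j)
            if c <= D[m][j] + _TIE_EPS:
                gap = sv[i] - sv[i - 1] if 0 < i < n else math.inf
                candidates.append((-gap, i))
        candidates.sort()
        i = candidates[0][1]
        boundaries.append(i)
        j = i
    boundaries.reverse()

    grouping = GCGrouping(k, sv, sids, boundaries=boundaries,
                          within_ss=float(D[k][n]))
    edges = boundaries + [n]
    for g, (a, b) in enumerate(zip(edges, edges[1:])):
        for idx in range(a, b):
            grouping.assignment[sids[idx]] = g
    return grouping
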