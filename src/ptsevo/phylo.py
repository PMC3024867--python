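"""From-scratch phylogenetics: global pairwise alignment with affine
gaps (Gotoh), distance estimation, progressive multiple alignment,
Neighbor-Joining with bootstrap supports, Robinson-Foulds comparison,
and duplicate-set detection.

Trees are ``skbio.TreeNode`` objects (unrooted, represented with a
trifurcating root for n >= 3); distances are ``skbio.DistanceMatrix``.
Scoring mirrors blastp defaults (BLOSUM62, gap existence 11, extension
1), so a gap of length L costs 11 + L.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix, TreeNode

from .records import Alignment
from .synteny import SyntenyContext, shared_architecture

logger = logging.getLogger(__name__)

GAP_OPEN = 11.0
GAP_EXTEND = 1.0
SATURATION_CEILING = 5.0

_TIE_EPS = 1e-12


def _blosum62() -> dict[tuple[str, str], float]:
    m = substitution_matrices.load("BLOSUM62")
    scores: dict[tuple[str, str], float] = {}
    for a in m.alphabet:
        for b in m.alphabet:
            scores[(a, b)] = float(m[a, b])
    # ambiguous residues score 0 against everything
    for a in m.alphabet:
        scores[(a, "X")] = scores[("X", a)] = 0.0
    scores[("X", "X")] = 0.0
    return scores


_B62 = _blosum62()


def substitution_score(a: str, b: str) -> float:
    return _B62.get((a, b), 0.0)


# ------------------------------------------------------------- Gotoh core

_DIAG, _GAP_A, _GAP_B = 0, 1, 2  # gap_a: gap in sequence/profile A (consumes B)


def _gotoh(na: int, nb: int, score):
    """Affine-gap global alignment over abstract columns.

    ``score(i, j)`` scores pairing column i of A (0-based) with column j
    of B.  Returns (best_score, moves) where moves is a list of _DIAG /
    _GAP_A / _GAP_B.  Traceback tie-break: diagonal, then gap-in-A, then
    gap-in-B.
    """
    NEG = -math.inf
    go, ge = GAP_OPEN, GAP_EXTEND
    M = [[NEG] * (nb + 1) for _ in range(na + 1)]
    GA = [[NEG] * (nb + 1) for _ in range(na + 1)]  # gap in A: consumed extra B col
    GB = [[NEG] * (nb + 1) for _ in range(na + 1)]  # gap in B: consumed extra A col
    M[0][0] = 0.0
    for j in range(1, nb + 1):
        GA[0][j] = -(go + ge * j)
    for i in range(1, na + 1):
        GB[i][0] = -(go + ge * i)
    for i in range(1, na + 1):
        Mi, Mi1 = M[i], M[i - 1]
        GAi, GAi1 = GA[i], GA[i - 1]
        GBi, GBi1 = GB[i], GB[i - 1]
        for j in range(1, nb + 1):
            s = score(i - 1, j - 1)
            Mi[j] = max(Mi1[j - 1], GAi1[j - 1], GBi1[j - 1]) + s
            open_a = max(Mi[j - 1], GBi[j - 1]) - (go + ge)
            GAi[j] = max(open_a, GAi[j - 1] - ge)
            open_b = max(Mi1[j], GAi1[j]) - (go + ge)
            GBi[j] = max(open_b, GBi1[j] - ge)

    i, j = na, nb
    finals = (M[i][j], GA[i][j], GB[i][j])
    best = max(finals)
    state = min(k for k in (_DIAG, _GAP_A, _GAP_B)
                if finals[k] >= best - _TIE_EPS)
    moves: list[int] = []
    while i > 0 or j > 0:
        if state == _DIAG:
            prevs = (M[i - 1][j - 1], GA[i - 1][j - 1], GB[i - 1][j - 1])
            target = M[i][j] - score(i - 1, j - 1)
            state = min(k for k in (_DIAG, _GAP_A, _GAP_B)
                        if prevs[k] >= target - _TIE_EPS)
            moves.append(_DIAG)
            i, j = i - 1, j - 1
        elif state == _GAP_A:
            if i == 0:
                moves.append(_GAP_A)
                j -= 1
                continue
            if M[i][j - 1] >= GA[i][j] + (GAP_OPEN + GAP_EXTEND) - _TIE_EPS:
                state = _DIAG
            elif GA[i][j - 1] - GAP_EXTEND >= GA[i][j] - _TIE_EPS:
                state = _GAP_A
            else:
                state = _GAP_B
            moves.append(_GAP_A)
            j -= 1
        else:
            if j == 0:
                moves.append(_GAP_B)
                i -= 1
                continue
            if M[i - 1][j] >= GB[i][j] + (GAP_OPEN + GAP_EXTEND) - _TIE_EPS:
                state = _DIAG
            elif GB[i - 1][j] - GAP_EXTEND >= GB[i][j] - _TIE_EPS:
                state = _GAP_B
            else:
                state = _GAP_A
            moves.append(_GAP_B)
            i -= 1
    moves.reverse()
    return best, moves


@dataclass
class PairwiseResult:
    alignment: Alignment
    score: float
    identity: float   # percent over aligned columns
    positives: float  # percent of columns with positive substitution score


def nw_align(a: str, b: str, label_a: str = "a", label_b: str = "b") -> PairwiseResult:
    """Global protein alignment (Gotoh affine gaps, BLOSUM62 11/1).

    Identity = 100 * identical columns / aligned columns; positives =
    100 * columns with substitution score > 0 / aligned columns.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    a, b = a.upper(), b.upper()
    best, moves = _gotoh(len(a), len(b), lambda i, j: substitution_score(a[i], b[j]))
    row_a = []
    row_b = []
    i = j = 0
    for mv in moves:
        if mv == _DIAG:
            row_a.append(a[i]); row_b.append(b[j]); i += 1; j += 1
        elif mv == _GAP_A:
            row_a.append("-"); row_b.append(b[j]); j += 1
        else:
            row_a.append(a[i]); row_b.append("-"); i += 1
    ra, rb = "".join(row_a), "".join(row_b)
    ncols = len(ra)
    ident = sum(x == y and x != "-" for x, y in zip(ra, rb))
    pos = sum(x != "-" and y != "-" and substitution_score(x, y) > 0
              for x, y in zip(ra, rb))
    return PairwiseResult(Alignment([label_a, label_b], [ra, rb]), best,
                          100.0 * ident / ncols, 100.0 * pos / ncols)


# -------------------------------------------------------------- distances

def pdistance(row_i: str, row_j: str) -> float:
    """Observed proportion of differences, pairwise deletion of gaps."""
    pairs = [(x, y) for x, y in zip(row_i, row_j) if x != "-" and y != "-"]
    if not pairs:
        raise ValueError("no comparable columns (all-gap overlap)")
    return sum(x != y for x, y in pairs) / len(pairs)


def poisson_distance(p: float, ceiling: float = SATURATION_CEILING) -> float:
    """Poisson multiple-hit correction d = -ln(1 - p); saturates at p >= 1."""
    if p < 0:
        raise ValueError("p must be >= 0")
    if p >= 1:
        logger.warning("saturated distance (p=%.3f); capped at %.1f", p, ceiling)
        return ceiling
    return min(-math.log(1.0 - p), ceiling)


def alignment_distance_matrix(msa: Alignment, correction: str = "poisson",
                              columns: np.ndarray | None = None) -> DistanceMatrix:
    """Pairwise distances over alignment rows (optionally a column resample)."""
    arr = np.array([list(r) for r in msa.rows])
    if columns is not None:
        arr = arr[:, columns]
    n = len(msa.labels)
    d = np.zeros((n, n))
    gaps = arr == "-"
    for i, j in combinations(range(n), 2):
        ok = ~(gaps[i] | gaps[j])
        m = int(ok.sum())
        if m == 0:
            raise ValueError(f"no comparable columns between "
                             f"{msa.labels[i]} and {msa.labels[j]}")
        p = float((arr[i, ok] != arr[j, ok]).sum()) / m
        dij = p if correction == "p" else poisson_distance(p)
        d[i, j] = d[j, i] = dij
    return DistanceMatrix(d, msa.labels)


# ------------------------------------------------------------------- NJ

def nj(dm: DistanceMatrix) -> TreeNode:
    """Classic Neighbor-Joining.

    Joins the pair minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j; ties go
    to the lexicographically smallest pair of node keys (a node's key is
    its smallest leaf label).  Negative branch-length estimates are
    clamped to zero with a log message.  Returns an unrooted tree
    (trifurcating root for n >= 3).
    """
    labels = list(dm.ids)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    D = np.array(dm.data, dtype=float)
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix is not symmetric")
    nodes = [TreeNode(name=l) for l in labels]
    keys = list(labels)

    def clamp(x: float, what: str) -> float:
        if x < 0:
            if x < -1e-9:
                logger.info("negative NJ branch length %.3g (%s); clamped", x, what)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cands = [(tuple(sorted((keys[i], keys[j]))), i, j)
                 for i in range(m) for j in range(i + 1, m)
                 if Q[i, j] <= qmin + _TIE_EPS * max(1.0, abs(qmin))]
        _, i, j = min(cands)
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        li, lj = clamp(li, keys[i]), clamp(lj, keys[j])
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = li, lj
        new = TreeNode(children=[child_i, child_j])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([np.hstack([D[np.ix_(keep, keep)],
                                  dnew[keep][:, None]]),
                       np.hstack([dnew[keep], [0.0]])])
        nodes = [nodes[k] for k in keep] + [new]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    if len(nodes) == 2:
        d = D[0, 1]
        for node in nodes:
            node.length = d / 2.0
        return TreeNode(children=nodes)
    # three remaining: unique unrooted resolution
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    la = clamp((dab + dac - dbc) / 2.0, keys[0])
    lb = clamp((dab + dbc - dac) / 2.0, keys[1])
    lc = clamp((dac + dbc - dab) / 2.0, keys[2])
    for node, l in zip(nodes, (la, lb, lc)):
        node.length = l
    return TreeNode(children=nodes)


# --------------------------------------------------- bipartitions / RF

def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial leaf bipartitions, canonicalized to the side not
    containing the lexicographically smallest leaf."""
    leaves = frozenset(t.name for t in tree.tips())
    ref = min(leaves)
    out = set()
    for node in tree.non_tips():
        if node.is_root():
            continue
        clade = frozenset(t.name for t in node.tips())
        side = leaves - clade if ref in clade else clade
        if 1 < len(side) < len(leaves) - 1:
            out.add(side)
    return out


def rf_distance(t1: TreeNode, t2: TreeNode) -> int:
    """Robinson-Foulds: size of the symmetric difference of the two
    trees' non-trivial bipartition sets."""
    l1 = {t.name for t in t1.tips()}
    l2 = {t.name for t in t2.tips()}
    if l1 != l2:
        raise ValueError("trees have different leaf sets")
    return len(bipartitions(t1) ^ bipartitions(t2))


# ------------------------------------------------------------- bootstrap

def bootstrap(msa: Alignment, B: int = 500, seed: int | None = None,
              correction: str = "poisson") -> tuple[TreeNode, dict[frozenset, float]]:
    """Column-resampling bootstrap of the NJ tree.

    Returns the full-data NJ tree with ``support`` (percent of
    replicates reproducing each internal-edge bipartition) attached to
    its internal nodes, plus the bipartition -> support map.
    """
    base_tree = nj(alignment_distance_matrix(msa, correction))
    if B <= 0:
        return base_tree, {}
    rng = np.random.default_rng(seed)
    L = msa.n_cols
    counts: dict[frozenset, int] = {bp: 0 for bp in bipartitions(base_tree)}
    for _ in range(B):
        cols = rng.integers(0, L, size=L)
        rep = nj(alignment_distance_matrix(msa, correction, columns=cols))
        for bp in bipartitions(rep):
            if bp in counts:
                counts[bp] += 1
    supports = {bp: 100.0 * c / B for bp, c in counts.items()}
    leaves = frozenset(t.name for t in base_tree.tips())
    ref = min(leaves)
    for node in base_tree.non_tips():
        if node.is_root():
            continue
        clade = frozenset(t.name for t in node.tips())
        side = leaves - clade if ref in clade else clade
        if side in supports:
            node.support = supports[side]
    return base_tree, supports


# -------------------------------------------------------- progressive MSA

def _profile_align(a: Alignment, b: Alignment) -> Alignment:
    cols_a = [tuple(r[k] for r in a.rows) for k in range(a.n_cols)]
    cols_b = [tuple(r[k] for r in b.rows) for k in range(b.n_cols)]
    na, nb = len(a.rows), len(b.rows)
    norm = float(na * nb)

    def score(i: int, j: int) -> float:
        s = 0.0
        for x in cols_a[i]:
            if x == "-":
                continue
            for y in cols_b[j]:
                if y != "-":
                    s += substitution_score(x, y)
        return s / norm

    _, moves = _gotoh(len(cols_a), len(cols_b), score)
    rows_a = [[] for _ in range(na)]
    rows_b = [[] for _ in range(nb)]
    i = j = 0
    for mv in moves:
        if mv == _DIAG:
            for k in range(na):
                rows_a[k].append(a.rows[k][i])
            for k in range(nb):
                rows_b[k].append(b.rows[k][j])
            i += 1; j += 1
        elif mv == _GAP_A:
            for k in range(na):
                rows_a[k].append("-")
            for k in range(nb):
                rows_b[k].append(b.rows[k][j])
            j += 1
        else:
            for k in range(na):
                rows_a[k].append(a.rows[k][i])
            for k in range(nb):
                rows_b[k].append("-")
            i += 1
    return Alignment(a.labels + b.labels,
                     ["".join(r) for r in rows_a] + ["".join(r) for r in rows_b],
                     a.alphabet)


def progressive_msa(seqs: dict[str, str]) -> Alignment:
    """Progressive multiple alignment.

    Guide tree = NJ on pairwise Gotoh p-distances; profiles are merged
    by profile-profile Gotoh with mean-of-pairs column scoring.  Column
    order is deterministic given input order and the traceback
    tie-breaks.
    """
    labels = list(seqs)
    if not labels:
        raise ValueError("no sequences")
    if len(labels) == 1:
        return Alignment(labels, [seqs[labels[0]]])
    if len(labels) == 2:
        res = nw_align(seqs[labels[0]], seqs[labels[1]], *labels)
        return res.alignment
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        res = nw_align(seqs[labels[i]], seqs[labels[j]])
        d[i, j] = d[j, i] = pdistance(*res.alignment.rows)
    guide = nj(DistanceMatrix(d, labels))

    def align_node(node: TreeNode) -> Alignment:
        if node.is_tip():
            return Alignment([node.name], [seqs[node.name]])
        parts = [align_node(c) for c in node.children]
        prof = parts[0]
        for p in parts[1:]:
            prof = _profile_align(prof, p)
        return prof

    merged = align_node(guide)
    # restore input label order
    order = [merged.labels.index(l) for l in labels]
    return Alignment(labels, [merged.rows[k] for k in order], merged.alphabet)


# --------------------------------------------------- duplicate detection

@dataclass
class DuplicateRecord:
    set_a: str
    set_b: str
    gene_a: str
    gene_b: str
    identity: float
    architecture_match: bool
    relation: str  # "duplicate" | "paralog"


def _iib_gene(pts_set) -> str | None:
    for gid in pts_set.members:
        if "IIB" in pts_set.calls[gid].subunits:
            return gid
    return None


def detect_duplicates(sets, proteins: dict[str, str],
                      identity_min: float = 90.0,
                      require_architecture_match: bool = True,
                      paralog_min: float = 50.0,
                      contexts: dict[str, SyntenyContext] | None = None,
                      ) -> list[DuplicateRecord]:
    """Same-genome set pairs whose IIB proteins align at high identity.

    Pairs at ``identity >= identity_min`` (and, by default, matching
    architectures) are duplicates; pairs at ``paralog_min <= identity <
    identity_min`` are reported as paralogs.
    """
    records = []
    by_genome: dict[str, list] = {}
    for s in sets:
        by_genome.setdefault(s.genome_id, []).append(s)
    for genome_sets in by_genome.values():
        for sa, sb in combinations(genome_sets, 2):
            ga, gb = _iib_gene(sa), _iib_gene(sb)
            if ga is None or gb is None:
                continue
            pa, pb = proteins.get(ga), proteins.get(gb)
            if not pa or not pb:
                continue
            res = nw_align(pa, pb, ga, gb)
            cmp = shared_architecture(
                sa, sb,
                (contexts or {}).get(sa.set_id), (contexts or {}).get(sb.set_id))
            if res.identity >= identity_min and (
                    cmp.architecture_match or not require_architecture_match):
                relation = "duplicate"
            elif res.identity >= paralog_min:
                relation = "paralog"
            else:
                continue
            records.append(DuplicateRecord(sa.set_id, sb.set_id, ga, gb,
                                           res.identity, cmp.architecture_match,
                                           relation))
    return records
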