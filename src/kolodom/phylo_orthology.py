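"""Protein phylogenetics and synteny-verified ortholog clustering.

Distances are maximum-likelihood estimates under the empirical JTT
amino-acid model with gamma-distributed rate variation across sites
(default shape 1, four discrete categories), computed on alignment columns
passing a 60% site-coverage filter.  Trees are classic Saitou-Nei
neighbour joining with a deterministic lexicographic tie-break, and edge
support comes from column-resampling bootstrap.

Ortholog clusters are the tree clades expected for genes domesticated
before the diploid/allotetraploid split: one diploid gene (or a tandem
pair) together with tetraploid genes on the corresponding L/S homeologous
chromosomes, verified by shared orthologous neighbour genes in the gene
models (synteny).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .seq_core import GeneModel, Interval

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
_AA_IDX = {a: i for i, a in enumerate(AA_ORDER)}

# Jones-Taylor-Thornton (1992) empirical exchangeabilities, lower triangle
# in the order above, with the companion equilibrium frequencies — the
# standard published constants used by every JTT implementation.
_JTT_LOWER = [
    58, 54, 81, 56, 57, 105, 179, 27, 36, 30, 35, 54, 15, 194, 378, 475, 9,
    11, 298, 45, 16, 113, 310, 29, 137, 328, 22, 38, 646, 44, 5, 74, 101, 64,
    126, 20, 17, 528, 34, 86, 58, 81, 391, 47, 12, 263, 30, 10, 15, 503, 232,
    8, 70, 16, 10, 49, 767, 130, 112, 11, 7, 26, 15, 4, 15, 59, 38, 4, 46,
    31, 9, 5, 59, 69, 17, 23, 7, 31, 78, 14, 223, 42, 115, 209, 62, 323, 26,
    597, 9, 72, 292, 43, 4, 164, 53, 51, 18, 24, 20, 119, 26, 12, 9, 181, 18,
    5, 18, 30, 32, 10, 7, 45, 23, 6, 6, 27, 14, 5, 24, 201, 33, 55, 8, 47,
    16, 56, 45, 33, 40, 115, 73, 46, 8, 573, 11, 229, 21, 479, 89, 10, 40,
    245, 9, 32, 961, 14, 388, 248, 102, 59, 25, 52, 24, 180, 65, 4, 21, 47,
    103, 10, 8, 14, 43, 16, 29, 226, 24, 18, 323, 17, 92, 12, 53, 536, 62,
    285, 118, 6, 10, 23, 477, 35, 63, 38, 12, 21, 112, 71, 25, 16,
]
JTT_FREQS = np.array([
    0.07674792, 0.05169095, 0.04264496, 0.05154395, 0.01980298, 0.04075196,
    0.06182994, 0.07315193, 0.02294398, 0.05376095, 0.09190391, 0.05867594,
    0.02382598, 0.04012596, 0.05090095, 0.06876493, 0.05856494, 0.01426099,
    0.03210197, 0.06600493,
])
JTT_FREQS = JTT_FREQS / JTT_FREQS.sum()

SATURATION_T = 10.0


def _jtt_rate_matrix() -> np.ndarray:
    S = np.zeros((20, 20))
    k = 0
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = _JTT_LOWER[k]
            k += 1
    Q = S * JTT_FREQS[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    # scale to one expected substitution per unit time
    rate = -(JTT_FREQS * np.diag(Q)).sum()
    return Q / rate


_JTT_Q = _jtt_rate_matrix()
# eigendecomposition through the pi-symmetrized form (numerically stable)
_sq = np.sqrt(JTT_FREQS)
_B = (_sq[:, None] * _JTT_Q) / _sq[None, :]
_EVALS, _U = np.linalg.eigh((_B + _B.T) / 2.0)
_LEFT = _U / _sq[:, None]          # D^{-1/2} U
_RIGHT = _U.T * _sq[None, :]       # U^T D^{1/2}


def jtt_transition_matrix(t: float) -> np.ndarray:
    """P(t) = exp(Qt) under the scaled JTT model."""
    P = (_LEFT * np.exp(_EVALS * t)) @ _RIGHT
    return np.clip(P, 1e-300, None)


def discrete_gamma_rates(shape: float, ncat: int = 4) -> np.ndarray:
    """Mean rates of ``ncat`` equal-probability gamma(shape, mean 1) bins."""
    edges = gamma_dist.ppf(np.linspace(0, 1, ncat + 1), a=shape, scale=1 / shape)
    upper = gammainc(shape + 1, edges[1:] * shape)
    lower = gammainc(shape + 1, edges[:-1] * shape)
    return ncat * (upper - lower)


class SaturatedDistance(RuntimeError):
    pass


def _pair_count_matrix(a: str, b: str) -> np.ndarray:
    C = np.zeros((20, 20))
    for x, y in zip(a, b):
        i = _AA_IDX.get(x)
        j = _AA_IDX.get(y)
        if i is not None and j is not None:
            C[i, j] += 1
    return C


def _ml_distance_from_counts(C: np.ndarray, gamma_shape: float) -> tuple[float, bool]:
    n = C.sum()
    if n < 10:
        raise ValueError(f"only {int(n)} comparable columns (< 10)")
    if C.sum() - np.trace(C) == 0:
        return 0.0, False
    rates = discrete_gamma_rates(gamma_shape)

    def negloglik(t: float) -> float:
        mix = np.zeros((20, 20))
        for r in rates:
            mix += jtt_transition_matrix(t * r)
        mix /= len(rates)
        joint = JTT_FREQS[:, None] * mix
        return -(C * np.log(joint)).sum()

    res = minimize_scalar(negloglik, bounds=(1e-8, SATURATION_T * 2),
                          method="bounded", options={"xatol": 1e-8})
    t = float(res.x)
    saturated = t >= SATURATION_T
    return (SATURATION_T if saturated else t), saturated


def pairwise_distance(aligned_a: str, aligned_b: str, gamma_shape: float = 1.0
                      ) -> float:
    """ML JTT(+gamma) distance between two rows of one alignment.

    Columns gapped in either sequence are ignored; fewer than 10 comparable
    columns is an error; saturation raises :class:`SaturatedDistance`.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("sequences must come from one alignment")
    d, saturated = _ml_distance_from_counts(
        _pair_count_matrix(aligned_a, aligned_b), gamma_shape)
    if saturated:
        raise SaturatedDistance(f"distance at saturation bound {d}")
    return d


def poisson_distance(aligned_a: str, aligned_b: str) -> float:
    """Poisson-corrected p-distance cross-check (-ln(1 - p))."""
    pairs = [(x, y) for x, y in zip(aligned_a, aligned_b)
             if x != "-" and y != "-"]
    if len(pairs) < 10:
        raise ValueError("fewer than 10 comparable columns")
    p = sum(1 for x, y in pairs if x != y) / len(pairs)
    if p >= 1.0:
        raise SaturatedDistance("p-distance 1.0")
    return -math.log(1.0 - p)


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray
    saturated: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape disagrees with labels")
        if not np.allclose(m, m.T):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(m < 0):
            raise ValueError("negative distances")
        self.matrix = m
        if self.saturated is None:
            self.saturated = np.zeros_like(m, dtype=bool)


def filter_columns(msa: dict[str, str], min_site_coverage: float = 0.60
                   ) -> dict[str, str]:
    """Drop alignment columns with less than the required site coverage
    (fraction of non-gap residues)."""
    rows = list(msa.values())
    L = len(rows[0])
    if any(len(r) != L for r in rows):
        raise ValueError("ragged alignment")
    keep = [c for c in range(L)
            if sum(r[c] != "-" for r in rows) / len(rows) >= min_site_coverage]
    return {n: "".join(r[c] for c in keep) for n, r in msa.items()}


def distance_matrix(msa: dict[str, str], gamma_shape: float = 1.0,
                    min_site_coverage: float = 0.60) -> DistanceMatrix:
    """All-pairs JTT(+gamma) ML distances after the coverage filter.

    Saturated pairs are clamped to the saturation bound and flagged rather
    than raised, so tree building can proceed.
    """
    filtered = filter_columns(msa, min_site_coverage)
    labels = list(filtered)
    n = len(labels)
    m = np.zeros((n, n))
    sat = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            d, s = _ml_distance_from_counts(
                _pair_count_matrix(filtered[labels[i]], filtered[labels[j]]),
                gamma_shape)
            m[i, j] = m[j, i] = d
            sat[i, j] = sat[j, i] = s
    return DistanceMatrix(labels, m, sat)


# ---------------------------------------------------------------------------
# Neighbour joining

def nj_tree(d: DistanceMatrix) -> dendropy.Tree:
    """Classic neighbour joining with deterministic tie-breaks.

    Ties in the Q criterion resolve by the lexicographically smallest pair
    of cluster labels (a cluster is labelled by its smallest leaf).
    Negative branch lengths are clamped to zero.
    """
    n = len(d.labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    active: dict[str, str] = {lbl: lbl for lbl in d.labels}  # label -> newick
    dist: dict[tuple[str, str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            a, b = sorted((d.labels[i], d.labels[j]))
            dist[(a, b)] = d.matrix[i, j]

    def D(a: str, b: str) -> float:
        return dist[tuple(sorted((a, b)))]

    while len(active) > 3:
        labels = sorted(active)
        r = {a: sum(D(a, b) for b in labels if b != a) for a in labels}
        best = None
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                q = (len(labels) - 2) * D(a, b) - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        dab = D(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (len(labels) - 2))
        lb = dab - la
        la, lb = max(0.0, la), max(0.0, lb)
        merged_label = min(a, b)
        newick = f"({active[a]}:{la:.10f},{active[b]}:{lb:.10f})"
        for c in labels:
            if c in (a, b):
                continue
            dc = 0.5 * (D(a, c) + D(b, c) - dab)
            dist[tuple(sorted((merged_label, c)))] = max(0.0, dc)
        del active[a if merged_label == b else b]
        active[merged_label] = newick

    a, b, c = sorted(active)
    la = max(0.0, 0.5 * (D(a, b) + D(a, c) - D(b, c)))
    lb = max(0.0, 0.5 * (D(a, b) + D(b, c) - D(a, c)))
    lc = max(0.0, 0.5 * (D(a, c) + D(b, c) - D(a, b)))
    newick = (f"({active[a]}:{la:.10f},{active[b]}:{lb:.10f},"
              f"{active[c]}:{lc:.10f});")
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    return tree


def bipartition_sets(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Nontrivial bipartitions as canonical frozensets of leaf labels (the
    side not containing the alphabetically first leaf)."""
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    anchor = min(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = {lf.taxon.label for lf in node.leaf_iter()}
        if anchor in side:
            side = leaves - side
        if 1 < len(side) < len(leaves) - 1:
            out.add(frozenset(side))
    return out


def clades(tree: dendropy.Tree) -> list[frozenset[str]]:
    """Candidate clades of an unrooted tree: every bipartition side."""
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    out: list[frozenset[str]] = []
    seen: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        for cand in (side, leaves - side):
            if 1 < len(cand) < len(leaves) and cand not in seen:
                seen.add(cand)
                out.append(cand)
    return out


def bootstrap_support(msa: dict[str, str], n_reps: int = 500, seed: int = 0,
                      gamma_shape: float = 1.0,
                      min_site_coverage: float = 0.60
                      ) -> tuple[dendropy.Tree, dict[frozenset[str], float]]:
    """Column-resampling bootstrap for the NJ tree of an alignment.

    Returns the reference tree plus support (fraction of replicates
    containing each bipartition); supports are also annotated on internal
    nodes of the returned tree as ``node.label`` percentages.
    """
    filtered = filter_columns(msa, min_site_coverage)
    labels = list(filtered)
    codes = np.array([[_AA_IDX.get(ch, -1) for ch in filtered[lbl]]
                      for lbl in labels])
    L = codes.shape[1]
    rng = np.random.default_rng(seed)

    def tree_from_weights(w: np.ndarray) -> dendropy.Tree:
        n = len(labels)
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                ok = (codes[i] >= 0) & (codes[j] >= 0) & (w > 0)
                C = np.zeros((20, 20))
                np.add.at(C, (codes[i][ok], codes[j][ok]), w[ok])
                dd, _ = _ml_distance_from_counts(C, gamma_shape)
                m[i, j] = m[j, i] = dd
        return nj_tree(DistanceMatrix(labels, m))

    ref = tree_from_weights(np.ones(L))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in bipartition_sets(ref)}
    for _ in range(n_reps):
        w = np.bincount(rng.integers(0, L, size=L), minlength=L).astype(float)
        for bp in bipartition_sets(tree_from_weights(w)):
            if bp in counts:
                counts[bp] += 1
    support = {bp: c / n_reps for bp, c in counts.items()}
    leaves = {lf.taxon.label for lf in ref.leaf_node_iter()}
    anchor = min(leaves)
    for node in ref.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = {lf.taxon.label for lf in node.leaf_iter()}
        if anchor in side:
            side = leaves - side
        bp = frozenset(side)
        if bp in support:
            node.label = f"{100 * support[bp]:.0f}"
    return ref, support


# ---------------------------------------------------------------------------
# Ortholog clusters

@dataclass
class OrthologCluster:
    id: str
    members: list[str]
    shape: str  # triplet | doublet
    synteny_ok: bool
    evidence: list[str] = field(default_factory=list)
    notes: str = ""


def _neighbor_base_names(models: list[GeneModel], locus: Interval,
                         window_genes: int) -> set[str]:
    same = sorted((g for g in models if g.interval.contig == locus.contig),
                  key=lambda g: g.interval.start)
    before = [g for g in same if g.interval.end <= locus.start]
    after = [g for g in same if g.interval.start >= locus.end]
    chosen = before[-window_genes:] + after[:window_genes]
    return {strip_homeolog_suffix(g.name) for g in chosen}


def strip_homeolog_suffix(name: str) -> str:
    """L/S homeolog naming convention: trailing '.L'/'.S' marks the
    subgenome copy of a shared base gene symbol."""
    if name.endswith((".L", ".S")):
        return name[:-2]
    return name


def find_ortholog_clusters(tree: dendropy.Tree, loci: dict[str, Interval],
                           species_of: dict[str, str],
                           homeology_map: dict[str, list[str]],
                           gene_models: dict[str, list[GeneModel]],
                           tandem_window: int = 50_000,
                           min_shared_neighbors: int = 2,
                           neighbor_window_genes: int = 10
                           ) -> list[OrthologCluster]:
    """Tree-derived triplet/doublet ortholog clusters with synteny verdicts.

    ``species_of`` maps each leaf to 'diploid' or 'tetraploid';
    ``gene_models`` maps those two keys to gene-model lists.  A candidate
    clade holds exactly one diploid gene (or a tandem pair within
    ``tandem_window``) plus tetraploid genes on the homeologous L/S pair of
    the diploid gene's chromosome; maximal candidates become clusters,
    labelled serially in tree order.  Synteny holds when every tetraploid
    member shares at least ``min_shared_neighbors`` neighbour gene symbols
    with the diploid member within ``neighbor_window_genes`` genes.
    """
    candidates: list[tuple[frozenset[str], str]] = []
    for clade in clades(tree):
        dips = sorted(g for g in clade if species_of[g] == "diploid")
        tets = sorted(g for g in clade if species_of[g] == "tetraploid")
        if not tets or not dips or len(dips) > 2:
            continue
        if len(dips) == 2:
            a, b = (loci[dips[0]], loci[dips[1]])
            if a.contig != b.contig or a.gap_to(b) > tandem_window:
                continue
        note = ""
        dip_contigs = {loci[g].contig for g in dips}
        allowed: set[str] | None = set()
        for c in dip_contigs:
            if c in homeology_map:
                allowed.update(homeology_map[c])
            else:
                allowed = None  # unplaced scaffold: chromosome test skipped
                note = f"chromosomal location of {'/'.join(dips)} uncertain"
                break
        if allowed is not None:
            if not all(loci[g].contig in allowed for g in tets):
                continue
        candidates.append((clade, note))

    def synteny(clade: frozenset[str]) -> tuple[bool, list[str]]:
        dips = sorted(g for g in clade if species_of[g] == "diploid")
        tets = sorted(g for g in clade if species_of[g] == "tetraploid")
        dip_neighbors: set[str] = set()
        for g in dips:
            dip_neighbors |= _neighbor_base_names(gene_models["diploid"],
                                                  loci[g], neighbor_window_genes)
        ok = True
        evidence: set[str] = set()
        for g in tets:
            shared = dip_neighbors & _neighbor_base_names(
                gene_models["tetraploid"], loci[g], neighbor_window_genes)
            evidence |= shared
            if len(shared) < min_shared_neighbors:
                ok = False
        return ok, sorted(evidence)

    evaluated = [(clade, note, *synteny(clade)) for clade, note in candidates]
    # keep maximal clades, preferring synteny-verified ones: a candidate is
    # dropped when a strictly larger candidate of at-least-equal synteny
    # standing contains it (a gene that groups with non-syntenic extras
    # stays with its syntenic core rather than the bigger mixed clade)
    kept = []
    for c in evaluated:
        dominated = False
        for other in evaluated:
            if c[0] < other[0] and (other[2] or not c[2]):
                dominated = True
                break
        if not dominated:
            kept.append(c)
    # a kept clade may still overlap a kept superset (syntenic core inside a
    # larger non-syntenic clade): report the syntenic core, not the mixture
    kept = [c for c in kept
            if c[2] or not any(o[2] and o[0] < c[0] for o in kept)]
    # serial order: first appearance of any member in a stable traversal
    order = {lf.taxon.label: i for i, lf in enumerate(tree.leaf_node_iter())}
    kept.sort(key=lambda c: min(order[g] for g in c[0]))
    clusters: list[OrthologCluster] = []
    for idx, (clade, note, ok, evidence) in enumerate(kept, start=1):
        dips = sorted(g for g in clade if species_of[g] == "diploid")
        tets = sorted(g for g in clade if species_of[g] == "tetraploid")
        tet_classes = set()
        for g in tets:
            contig = loci[g].contig
            for dip, pair in homeology_map.items():
                if contig == pair[0]:
                    tet_classes.add("L")
                elif len(pair) > 1 and contig == pair[1]:
                    tet_classes.add("S")
        shape = "triplet" if {"L", "S"} <= tet_classes else "doublet"
        clusters.append(OrthologCluster(f"D{idx}", dips + tets, shape, ok,
                                        evidence, note))
    return clusters
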