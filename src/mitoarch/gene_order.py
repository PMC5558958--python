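"""Gene-order conservation, DCJ rearrangement distance and branch-specific rates.

Gene order conservation (GOC) between two genomes is the fraction of shared
orthologues whose circular-order adjacencies are preserved:

    GOC = N_orthologues,contiguous / N_orthologues,      GOL = 1 - GOC.

Pairwise GOL values over all leaf pairs of a phylogeny are apportioned to
branches by least squares: with b_ij = 1 when branch j lies on the path
between the leaves of pair i, the branch-specific GOL vector x minimizes

    L = sum_i ( sum_j b_ij x_j - GOL_i )^2,    x_j >= 0,

and the per-branch rearrangement rate is x_j divided by the branch length.
For a binary unrooted tree on n leaves the design matrix is C(n,2) x (2n-3).

Rearrangement distances between syntenic-block orders use the double-cut-and-
join (DCJ) model: d = N - C where N is the marker count and C the number of
cycles in the adjacency graph of the two genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "GeneOrder",
    "GOCMatrix",
    "BranchRateSolution",
    "goc",
    "goc_matrix",
    "dcj_distance",
    "build_design_matrix",
    "solve_bsgol",
    "SSS_BLOCKS",
    "YEAST_GENE_COMPLEMENT",
]

# The standard yeast mitochondrial gene complement: 8 protein-coding genes,
# 2 rRNAs, the RNase P RNA (rpm1), the ribosomal protein var1 and 24 tRNAs.
YEAST_GENE_COMPLEMENT: tuple[str, ...] = (
    "cox1", "cox2", "cox3", "cob", "atp6", "atp8", "atp9",
    "var1", "rnl", "rns", "rpm1",
    "trnT2", "trnC", "trnH", "trnL", "trnQ", "trnK", "trnR1", "trnG",
    "trnD", "trnS1", "trnR2", "trnA", "trnI", "trnY", "trnN", "trnM1",
    "trnF", "trnT1", "trnV", "trnM2", "trnP", "trnE", "trnW", "trnS2",
)

# Seven syntenic orthologous blocks (transcriptional units) covering all 35
# genes; block 1 carries rnl, sixteen tRNAs and cox2, block 7 atp9/trnS2/var1.
SSS_BLOCKS: dict[str, tuple[str, ...]] = {
    "block1": ("rnl", "trnT2", "trnC", "trnH", "trnL", "trnQ", "trnK", "trnR1",
               "trnG", "trnD", "trnS1", "trnR2", "trnA", "trnI", "trnY", "trnN",
               "trnM1", "cox2"),
    "block2": ("trnF", "trnT1", "trnV", "cox3"),
    "block3": ("trnM2", "rpm1", "trnP"),
    "block4": ("cox1", "atp8", "atp6"),
    "block5": ("trnE", "cob"),
    "block6": ("rns", "trnW"),
    "block7": ("atp9", "trnS2", "var1"),
}


@dataclass
class GeneOrder:
    """A signed circular order of orthologous markers for one genome."""

    genome_id: str
    markers: list[tuple[str, int]]  # (name, +1/-1) around the circle

    def __post_init__(self) -> None:
        names = [m for m, _ in self.markers]
        if len(names) != len(set(names)):
            raise ValueError(f"{self.genome_id}: duplicate marker names")
        if len(names) < 2:
            raise ValueError(f"{self.genome_id}: need at least 2 markers")
        if any(s not in (1, -1) for _, s in self.markers):
            raise ValueError("marker signs must be +1/-1")

    @property
    def marker_set(self) -> frozenset:
        return frozenset(m for m, _ in self.markers)

    def restricted_to(self, shared: frozenset) -> "GeneOrder":
        kept = [(m, s) for m, s in self.markers if m in shared]
        return GeneOrder(genome_id=self.genome_id, markers=kept)


def _adjacencies(order: GeneOrder) -> set[frozenset]:
    """Unordered, sign-blind neighbor pairs on the circular order."""
    names = [m for m, _ in order.markers]
    n = len(names)
    return {frozenset((names[i], names[(i + 1) % n])) for i in range(n)}


def goc(a: GeneOrder, b: GeneOrder) -> tuple[float, int, int]:
    """Gene order conservation between two genomes.

    Both orders are restricted to their shared markers before adjacency
    extraction; adjacencies are unordered and sign-blind.  Returns
    ``(GOC, N_orthologues, N_contiguous)``.
    """
    shared = a.marker_set & b.marker_set
    if len(shared) < 2:
        raise ValueError("fewer than 2 shared markers")
    ra, rb = a.restricted_to(shared), b.restricted_to(shared)
    n_contig = len(_adjacencies(ra) & _adjacencies(rb))
    return n_contig / len(shared), len(shared), n_contig


@dataclass
class GOCMatrix:
    """Symmetric GOC matrix over a set of genomes, with GOL = 1 - GOC."""

    ids: list[str]
    goc_values: np.ndarray

    @classmethod
    def from_orders(cls, orders: list[GeneOrder]) -> "GOCMatrix":
        ids = [o.genome_id for o in orders]
        k = len(orders)
        mat = np.eye(k)
        for i, j in combinations(range(k), 2):
            g, _, _ = goc(orders[i], orders[j])
            mat[i, j] = mat[j, i] = g
        return cls(ids=ids, goc_values=mat)

    @property
    def gol_values(self) -> np.ndarray:
        return 1.0 - self.goc_values

    def to_frame(self, kind: str = "goc") -> pd.DataFrame:
        vals = self.goc_values if kind == "goc" else self.gol_values
        return pd.DataFrame(vals, index=self.ids, columns=self.ids)

    def pair_gol_vector(self, pairs: list[tuple[str, str]]) -> np.ndarray:
        idx = {g: i for i, g in enumerate(self.ids)}
        return np.array([self.gol_values[idx[u], idx[v]] for u, v in pairs])


# ---------------------------------------------------------------------------
# DCJ


def _extremity_adjacencies(order: GeneOrder) -> set[frozenset]:
    """Adjacencies of signed-marker extremities (head/tail) on the circle."""
    ms = order.markers
    n = len(ms)
    adj = set()
    for i in range(n):
        (m1, s1), (m2, s2) = ms[i], ms[(i + 1) % n]
        left = (m1, "h") if s1 == 1 else (m1, "t")
        right = (m2, "t") if s2 == 1 else (m2, "h")
        adj.add(frozenset((left, right)))
    return adj


def dcj_distance(a: GeneOrder, b: GeneOrder) -> int:
    """Minimal number of double-cut-and-join operations between two orders.

    Both genomes must be single circular chromosomes over the same marker
    set.  d = N - C with C the cycle count of the adjacency graph.
    """
    if a.marker_set != b.marker_set:
        raise ValueError("marker sets differ")
    adj_a = _extremity_adjacencies(a)
    adj_b = _extremity_adjacencies(b)
    neighbor_a: dict = {}
    neighbor_b: dict = {}
    for adj, store in ((adj_a, neighbor_a), (adj_b, neighbor_b)):
        for pair in adj:
            if len(pair) == 1:  # single-marker circle: head adjacent to tail
                (x,) = pair
                store[x] = x
            else:
                x, y = pair
                store[x] = y
                store[y] = x
    n = len(a.marker_set)
    seen: set = set()
    cycles = 0
    for start in neighbor_a:
        if start in seen:
            continue
        cycles += 1
        cur, use_a = start, True
        while True:
            seen.add(cur)
            cur = (neighbor_a if use_a else neighbor_b)[cur]
            seen.add(cur)
            use_a = not use_a
            if cur == start and use_a:
                break
    return n - cycles


# ---------------------------------------------------------------------------
# Branch-specific GOL


def leaf_pairs(tree: dendropy.Tree) -> list[tuple[str, str]]:
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    return list(combinations(labels, 2))


def build_design_matrix(tree: dendropy.Tree):
    """Boolean pair x branch incidence matrix of an unrooted binary tree.

    Row i corresponds to an unordered leaf pair (pairs sorted
    lexicographically), column j to a branch of the derooted tree (ordered by
    a deterministic bipartition sort); entry 1 means the branch lies on the
    path between the two leaves.  Returns ``(matrix, pairs, branch_table)``
    where ``branch_table`` is a DataFrame with branch index, length and the
    leaf set on the far side.
    """
    tree = tree.clone(depth=1)
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels")
    tree.deroot()
    all_leaves = frozenset(labels)
    edges = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        edges.append((below, node.edge.length if node.edge.length is not None else 0.0))
    # deterministic branch order: by smaller-side size, then sorted labels
    def _key(e):
        below = e[0]
        side = below if len(below) <= len(all_leaves - below) else all_leaves - below
        return (len(side), tuple(sorted(side)))

    edges.sort(key=_key)
    pairs = list(combinations(sorted(labels), 2))
    B = np.zeros((len(pairs), len(edges)), dtype=int)
    for j, (below, _) in enumerate(edges):
        for i, (u, v) in enumerate(pairs):
            if (u in below) != (v in below):
                B[i, j] = 1
    branch_table = pd.DataFrame(
        {
            "branch": np.arange(1, len(edges) + 1),
            "length": [ln for _, ln in edges],
            "clade": [",".join(sorted(bl if len(bl) <= len(all_leaves - bl) else all_leaves - bl))
                      for bl, _ in edges],
        }
    )
    return B, pairs, branch_table


@dataclass
class BranchRateSolution:
    """Per-branch GOL apportionment and rates on a phylogeny."""

    bsgol: np.ndarray           # x_j >= 0 per branch
    objective: float            # L at the solution
    branch_lengths: np.ndarray
    rates: np.ndarray           # x_j / length_j, NaN where length is 0
    unidentifiable: np.ndarray  # True for branches with an all-zero design column
    branch_table: pd.DataFrame = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "branch": np.arange(1, len(self.bsgol) + 1),
                "bsGOL": self.bsgol,
                "branch_length": self.branch_lengths,
                "rate": self.rates,
                "unidentifiable": self.unidentifiable,
            }
        )
        if self.branch_table is not None:
            out["clade"] = self.branch_table["clade"].values
        return out


def solve_bsgol(
    B: np.ndarray,
    gol: np.ndarray,
    branch_lengths: np.ndarray | None = None,
    *,
    nonnegative: bool = True,
    branch_table: pd.DataFrame = None,
) -> BranchRateSolution:
    """Apportion pairwise GOL values to branches by (non-negative) least squares.

    Minimizes L = ||B x - gol||^2; by default subject to x >= 0 (negative
    gene-order loss on a branch is meaningless).  The unconstrained mode uses
    the minimum-norm least-squares solution for comparison.  Rates divide
    each x_j by its branch length; zero-length branches yield NaN rates.
    """
    B = np.asarray(B, dtype=float)
    gol = np.asarray(gol, dtype=float)
    if B.shape[0] != gol.shape[0]:
        raise ValueError("design matrix rows and GOL vector disagree")
    if np.any((gol < -1e-12) | (gol > 1 + 1e-12)):
        raise ValueError("GOL values must lie in [0, 1]")
    col_zero = ~B.any(axis=0)
    if nonnegative:
        x, _ = nnls(B, gol)
    else:
        x, *_ = np.linalg.lstsq(B, gol, rcond=None)
    L = float(np.sum((B @ x - gol) ** 2))
    if branch_lengths is None and branch_table is not None:
        branch_lengths = branch_table["length"].to_numpy(dtype=float)
    if branch_lengths is None:
        branch_lengths = np.full(B.shape[1], np.nan)
    branch_lengths = np.asarray(branch_lengths, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rates = np.where(branch_lengths > 0, x / branch_lengths, np.nan)
    return BranchRateSolution(
        bsgol=x,
        objective=L,
        branch_lengths=branch_lengths,
        rates=rates,
        unidentifiable=col_zero,
        branch_table=branch_table,
    )


def goc_matrix(orders: list[GeneOrder]) -> GOCMatrix:
    """Convenience wrapper: all-pairs GOC over a list of gene orders."""
    return GOCMatrix.from_orders(orders)
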