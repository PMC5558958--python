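"""Synthetic annotated mitochondrial genomes with ground truth.

The generator emulates the architecture of a yeast mitochondrial genome: a
circular, strongly AT-biased (~80% AT) molecule carrying the standard 35-gene
complement (8 proteins, 2 rRNAs, rpm1, var1 and 24 tRNAs), optional group
I/II introns in *cox1*, *cob* and *rnl*, and intergenic regions built from
near-pure A/T spacers, residual filler, free-standing ORFs, *ori* elements
with internal GC clusters, and GC-cluster insertions drawn from consensus
families.  Gene sequences evolve along a supplied phylogeny by point
mutation, and gene orders evolve by inversions and transpositions whose
per-branch counts are Poisson in (branch length x per-branch intensity).

Every stochastic choice flows from one seeded generator, so identical seeds
give byte-identical genomes, and every planted element is recorded in a
:class:`SimulationTruth` so detector output can be scored against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .gene_order import GeneOrder, SSS_BLOCKS, YEAST_GENE_COMPLEMENT
from .genome_io import FeatureAnnotation, GenomeRecord, write_genome
from .intron_atlas import IntronRecord

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate",
    "simulate_gene_orders",
    "brownian_branch_multipliers",
    "score_detection",
    "write_truth",
    "DEFAULT_TREE",
]

# Fifteen-taxon tree patterned on the five sensu stricto yeasts plus ten
# relatives from the Kazachstania/Naumovozyma, Candida/Nakaseomyces and
# Lachancea lineages; basal trifurcation, so the tree is unrooted binary
# with 2*15-3 = 27 branches.
DEFAULT_TREE = (
    "((((Scer:0.05,Spar:0.05):0.03,Smik:0.08):0.02,(Skud:0.07,Suva:0.08):0.03):0.25,"
    "((Kser:0.12,Ncas:0.14):0.08,((Cgla:0.16,Ndel:0.14):0.05,"
    "(Ccas:0.12,Nbac:0.18):0.06):0.04):0.12,"
    "((Lklu:0.10,Lthe:0.08):0.04,(Ldas:0.09,Lmey:0.07):0.05):0.30);"
)

# Exon lengths (bp) for the standard complement; tRNAs default to 75 bp.
GENE_LENGTHS: dict[str, int] = {
    "cox1": 1602, "cox2": 753, "cox3": 810, "cob": 1158,
    "atp6": 780, "atp8": 147, "atp9": 231,
    "var1": 1197, "rnl": 3296, "rns": 1649, "rpm1": 440,
}
TRNA_LENGTH = 75

# Intron loci planted per host gene: (insertion site in intron-free coding
# coordinates, group label, whether the intron carries an ORF).  Ten cox1
# loci, seven cob loci and the single rnl locus mirror the observed atlas.
INTRON_LOCI: dict[str, tuple[tuple[int, str, bool], ...]] = {
    "cox1": (
        (168, "II", True), (312, "II", True), (470, "I", False), (640, "I", False),
        (735, "I", True), (870, "I", True), (1002, "I", True), (1130, "I", True),
        (1285, "I", True), (1410, "II", False),
    ),
    "cob": (
        (130, "I", False), (385, "I", True), (520, "II", False), (740, "I", True),
        (885, "I", True), (990, "I", False), (1100, "I", True),
    ),
    "rnl": ((2716, "I", True),),
}

# Synthetic GC-cluster family consensus sequences: short GC-rich (~80%)
# elements in the style of the mobile clusters that riddle yeast mtDNA
# intergenic DNA.  Constructed sequences, not database entries; mutually
# dissimilar (pairwise alignment identity < 0.56, including reverse
# complements) so family grouping is well posed.
DEFAULT_CLUSTER_FAMILIES: tuple[str, ...] = (
    "GCGGGCAGGACGGTCCGAGGTGCGCGCCCCGTGCTC",
    "CTCGGACCACCGGCCCCGCTCCCAGGCAGGCCCGACC",
    "CCCGGTCCAGGACGCCACCGCTGCGTGGCG",
    "CCAGGGTCGTGGTGCAGCCCTCGTCCCCCCGCC",
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _seq_to_str(idx: np.ndarray) -> str:
    return bytes(_BASES[idx]).decode()


def _str_to_idx(seq: str) -> np.ndarray:
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    arr = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (arr < 0).any():
        raise ValueError("sequence contains non-ACGT characters")
    return arr.astype(np.int8)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.int8)


def _mutate(rng: np.random.Generator, arr: np.ndarray, p: float) -> np.ndarray:
    """Point-mutate each site with probability p to one of the 3 other bases."""
    out = arr.copy()
    if p <= 0 or len(arr) == 0:
        return out
    hits = np.flatnonzero(rng.random(len(arr)) < p)
    if len(hits):
        out[hits] = (out[hits] + rng.integers(1, 4, size=len(hits))) % 4
    return out


def _revcomp_idx(arr: np.ndarray) -> np.ndarray:
    return (3 - arr)[::-1].astype(np.int8)


def _suppress_gc_windows(arr: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Break chance GC-rich windows in background sequence.

    I.i.d. sampling at 20-30% GC occasionally produces windows that satisfy
    the cluster detection thresholds (>= 7/8 or >= 12/16 GC); real coding and
    spacer DNA disperses its G/C.  Any such window loses a central G/C base
    (mutated to A/T) until none remain, so the only detectable clusters in a
    generated genome are the planted ones.
    """
    arr = arr.copy()
    if len(arr) < 8:
        return arr
    while True:
        gc = ((arr == 1) | (arr == 2)).astype(np.int64)
        cs = np.concatenate([[0], np.cumsum(gc)])
        hit = None
        for w, t in ((8, 7), (16, 12)):
            if len(arr) >= w:
                sums = cs[w:] - cs[: len(arr) - w + 1]
                idx = np.flatnonzero(sums >= t)
                if len(idx):
                    hit = (int(idx[0]), w)
                    break
        if hit is None:
            return arr
        b, w = hit
        window_gc = np.flatnonzero(gc[b : b + w])
        k = int(window_gc[len(window_gc) // 2])
        arr[b + k] = 0 if rng.random() < 0.5 else 3


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the emulated study conditions."""

    seed: int = 0
    tree_newick: str = DEFAULT_TREE
    target_at_fraction: float = 0.80
    coding_gc: float = 0.30                      # genes, introns, ORFs
    spacer_gc: float = 0.05                      # AT spacers (must stay < 0.1)
    gene_lengths: dict = field(default_factory=lambda: dict(GENE_LENGTHS))
    trna_length: int = TRNA_LENGTH
    point_mutation_rate: float = 0.10            # per site per unit branch length
    # introns
    intron_loci: dict = field(default_factory=lambda: {k: tuple(v) for k, v in INTRON_LOCI.items()})
    intron_presence_prob: float = 0.5
    intron_length_range: tuple[int, int] = (800, 2200)
    # GC clusters
    cluster_families: tuple[str, ...] = DEFAULT_CLUSTER_FAMILIES
    cluster_count_range: tuple[int, int] = (12, 36)
    cluster_mutation_rate: float = 0.01
    exonic_cluster_rate: float = 0.0             # leak rates; clusters stay intergenic by default
    intronic_cluster_rate: float = 0.0
    # ori elements
    ori_count_range: tuple[int, int] = (1, 8)
    ori_core_length: int = 180
    # free-standing ORFs
    orf_count_range: tuple[int, int] = (1, 5)
    orf_length_range: tuple[int, int] = (300, 1500)
    # intergenic geometry
    spacer_length_range: tuple[int, int] = (400, 1400)
    short_spacer_range: tuple[int, int] = (50, 150)
    residual_length_range: tuple[int, int] = (100, 400)
    motif_prob: float = 0.3                      # chance of a WTATAAGTA site per region
    # rearrangements: per-branch intensity multipliers follow geometric
    # Brownian motion along the tree (rearrangement rates are strongly
    # lineage-structured: whole clades are fast or slow together)
    inversion_rate: float = 4.0                  # events per unit branch length
    transposition_rate: float = 5.0
    rate_sigma: float = 1.5                      # Brownian spread of log intensity (0 = uniform)

    def validate(self) -> None:
        if not 0 < self.target_at_fraction < 1:
            raise ValueError("target_at_fraction must lie in (0,1)")
        for p in (self.intron_presence_prob, self.motif_prob,
                  self.exonic_cluster_rate, self.intronic_cluster_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0,1]")
        if not self.gene_lengths:
            raise ValueError("gene complement must be non-empty")
        if not 0 <= self.spacer_gc < 0.1:
            raise ValueError("spacer_gc must stay below the 0.1 spacer threshold")


@dataclass
class SimulationTruth:
    """Everything the generator planted, for recovery scoring."""

    genomes: dict[str, GenomeRecord]
    gene_orders: dict[str, GeneOrder]            # per leaf
    node_orders: dict[str, list]                 # per tree node (internal + leaves)
    branch_table: pd.DataFrame                   # clade, length, multiplier, events by type
    clusters: dict[str, list[tuple[tuple[int, int], str]]]   # leaf -> [(interval, family)]
    spacers: dict[str, list[tuple[int, int]]]
    oris: dict[str, list[tuple[int, int]]]
    introns: list[IntronRecord]
    intron_loci: dict[str, list[str]]            # true locus id -> member names
    config: SimulationConfig = None

    def leaf_ids(self) -> list[str]:
        return sorted(self.genomes)


# ---------------------------------------------------------------------------
# Tree helpers


def _load_tree(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    if len(tree.leaf_nodes()) < 2:
        raise ValueError("tree must have at least 2 leaves")
    tree.deroot()
    return tree


def _edge_clade(node, all_leaves: frozenset) -> str:
    below = frozenset(lf.taxon.label for lf in node.leaf_iter())
    side = below if len(below) <= len(all_leaves - below) else all_leaves - below
    return ",".join(sorted(side))


def brownian_branch_multipliers(
    tree: dendropy.Tree | str,
    rng: np.random.Generator,
    sigma: float = 1.5,
) -> dict[str, float]:
    """Per-branch rate multipliers from geometric Brownian motion on the tree.

    Log intensity diffuses along branches with standard deviation
    ``sigma * sqrt(branch length)``; each branch's multiplier is the
    midpoint intensity, normalized to mean 1 over branches.  This produces
    the phylogenetically autocorrelated, lineage-structured rate variation
    seen in real data (entire clades fast or slow together).  Keys are the
    same clade strings used by the gene-order branch tables, so a fixed
    draw can be replayed across replicate simulations.
    """
    if isinstance(tree, str):
        tree = _load_tree(tree)
    else:
        tree = tree.clone(depth=1)
        tree.deroot()
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    logm = {id(tree.seed_node): 0.0}
    vals: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        ln = node.edge.length if node.edge.length is not None else 0.0
        logm[id(node)] = logm[id(node.parent_node)] + float(rng.normal(0.0, sigma * math.sqrt(ln)))
        vals[_edge_clade(node, all_leaves)] = math.exp(
            (logm[id(node.parent_node)] + logm[id(node)]) / 2)
    mean = sum(vals.values()) / len(vals)
    return {k: v / mean for k, v in vals.items()}


# ---------------------------------------------------------------------------
# Gene-order evolution


def _apply_inversion(order: list, rng: np.random.Generator) -> list:
    n = len(order)
    s = int(rng.integers(0, n))
    length = int(rng.integers(1, n))  # arc of 1..n-1 markers
    rot = order[s:] + order[:s]
    arc = [(m, -sg) for m, sg in reversed(rot[:length])]
    out = arc + rot[length:]
    return out


def _apply_transposition(order: list, rng: np.random.Generator) -> list:
    n = len(order)
    if n < 3:
        return list(order)
    s = int(rng.integers(0, n))
    length = int(rng.integers(1, n - 1))  # leave at least one marker behind
    rot = order[s:] + order[:s]
    arc, rest = rot[:length], rot[length:]
    dest = int(rng.integers(1, len(rest) + 1))  # insertion point among the rest
    return rest[:dest] + arc + rest[dest:]


def simulate_gene_orders(
    tree: dendropy.Tree | str,
    root_order: list[tuple[str, int]],
    rng: np.random.Generator,
    *,
    inversion_rate: float = 4.0,
    transposition_rate: float = 5.0,
    rate_sigma: float = 1.0,
    branch_multipliers: dict[str, float] | None = None,
):
    """Evolve a signed circular gene order along a tree.

    Per branch, inversion and transposition counts are Poisson in
    (rate x multiplier x branch length), with lognormal per-branch
    multipliers of spread ``rate_sigma`` (mean 1); pass
    ``branch_multipliers`` (clade key -> multiplier, as produced in the
    returned table) to hold intensities fixed across replicate runs.
    Returns ``(node_orders, branch_table)`` where ``branch_table`` rows
    carry the branch's clade key, length, multiplier, event counts, and the
    true event intensity per unit length.
    """
    if isinstance(tree, str):
        tree = _load_tree(tree)
    else:
        tree = tree.clone(depth=1)
        tree.deroot()
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())

    node_orders: dict = {}
    rows = []
    root = tree.seed_node
    node_orders[id(root)] = list(root_order)
    named: dict[str, list] = {"__root__": list(root_order)}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent_order = node_orders[id(node.parent_node)]
        length = node.edge.length if node.edge.length is not None else 0.0
        clade = _edge_clade(node, all_leaves)
        if branch_multipliers is not None:
            mult = float(branch_multipliers[clade])
        elif rate_sigma > 0:
            mult = float(np.exp(rng.normal(0.0, rate_sigma) - rate_sigma**2 / 2))
        else:
            mult = 1.0
        lam_inv = inversion_rate * mult * length
        lam_tr = transposition_rate * mult * length
        n_inv = int(rng.poisson(lam_inv))
        n_tr = int(rng.poisson(lam_tr))
        order = list(parent_order)
        ops = ["inv"] * n_inv + ["tr"] * n_tr
        perm = rng.permutation(len(ops)) if ops else []
        for k in perm:
            order = _apply_inversion(order, rng) if ops[k] == "inv" else _apply_transposition(order, rng)
        node_orders[id(node)] = order
        label = node.taxon.label if node.is_leaf() else f"node{len(rows)}"
        named[label] = order
        rows.append(
            {
                "clade": clade,
                "length": length,
                "multiplier": mult,
                "inversions": n_inv,
                "transpositions": n_tr,
                "intensity": (inversion_rate + transposition_rate) * mult,
            }
        )
    branch_table = pd.DataFrame(rows)
    return named, branch_table


# ---------------------------------------------------------------------------
# Full genome simulation


def _root_gene_order(gene_lengths: dict) -> list[tuple[str, int]]:
    """Root order: the seven syntenic blocks laid head to tail."""
    order = []
    for block in SSS_BLOCKS.values():
        order.extend((g, 1) for g in block)
    known = {g for g, _ in order}
    order.extend((g, 1) for g in gene_lengths if g not in known)
    return order


def _evolve_sequences(
    tree: dendropy.Tree,
    root_seqs: dict[str, np.ndarray],
    rate: float,
    rng: np.random.Generator,
) -> dict[str, dict[str, np.ndarray]]:
    """Evolve every named sequence down the tree; returns leaf -> name -> seq."""
    at_node: dict[int, dict[str, np.ndarray]] = {id(tree.seed_node): root_seqs}
    leaves: dict[str, dict[str, np.ndarray]] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            current = at_node[id(node)]
        else:
            parent = at_node[id(node.parent_node)]
            length = node.edge.length if node.edge.length is not None else 0.0
            p = 1.0 - math.exp(-rate * length)
            current = {
                name: _suppress_gc_windows(_mutate(rng, seq, p), rng)
                for name, seq in sorted(parent.items())
            }
            at_node[id(node)] = current
        if node.is_leaf():
            leaves[node.taxon.label] = current
    return leaves


class _Assembler:
    """Accumulates sequence segments and truth intervals for one leaf genome."""

    def __init__(self, leaf: str):
        self.leaf = leaf
        self.parts: list[np.ndarray] = []
        self.pos = 0
        self.features: list[FeatureAnnotation] = []
        self.clusters: list[tuple[tuple[int, int], str]] = []
        self.spacers: list[tuple[int, int]] = []
        self.oris: list[tuple[int, int]] = []

    def add(self, seq: np.ndarray) -> tuple[int, int]:
        self.parts.append(seq)
        start = self.pos
        self.pos += len(seq)
        return start, self.pos

    def genome(self) -> GenomeRecord:
        full = _seq_to_str(np.concatenate(self.parts))
        return GenomeRecord(id=self.leaf, sequence=full, topology="circular",
                            features=self.features)


def _feature_kind(gene: str) -> str:
    if gene.startswith("trn"):
        return "trna"
    if gene in ("rnl", "rns"):
        return "rrna"
    if gene == "rpm1":
        return "rnap"
    return "gene_exon"


def simulate(cfg: SimulationConfig) -> SimulationTruth:
    """Generate one genome per tree leaf, plus complete ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    tree = _load_tree(cfg.tree_newick)
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())

    gene_lengths = dict(cfg.gene_lengths)
    for g in YEAST_GENE_COMPLEMENT:
        if g.startswith("trn"):
            gene_lengths.setdefault(g, cfg.trna_length)

    # --- root sequences: genes and intron-locus ancestral sequences
    root_seqs: dict[str, np.ndarray] = {}
    for g in sorted(gene_lengths):
        root_seqs[g] = _suppress_gc_windows(_random_seq(rng, gene_lengths[g], cfg.coding_gc), rng)
    locus_ids: list[tuple[str, int, str, bool, str]] = []  # (gene, site, group, orf, locus_id)
    for gene, loci in sorted(cfg.intron_loci.items()):
        for k, (site, group, has_orf) in enumerate(sorted(loci), start=1):
            lid = f"{gene}_{k}"
            locus_ids.append((gene, site, group, has_orf, lid))
            length = int(rng.integers(*cfg.intron_length_range))
            root_seqs[f"intron:{lid}"] = _suppress_gc_windows(
                _random_seq(rng, length, cfg.coding_gc), rng)

    leaf_seqs = _evolve_sequences(tree, root_seqs, cfg.point_mutation_rate, rng)

    # --- intron presence per (locus, leaf)
    presence: dict[tuple[str, str], bool] = {}
    for _, _, _, _, lid in locus_ids:
        for leaf in leaves:
            presence[(lid, leaf)] = bool(rng.random() < cfg.intron_presence_prob)

    # --- gene orders along the tree (lineage-structured rate multipliers)
    root_order = _root_gene_order(gene_lengths)
    mults = (brownian_branch_multipliers(tree, rng, cfg.rate_sigma)
             if cfg.rate_sigma > 0 else None)
    node_orders, branch_table = simulate_gene_orders(
        tree, root_order, rng,
        inversion_rate=cfg.inversion_rate,
        transposition_rate=cfg.transposition_rate,
        rate_sigma=0.0,
        branch_multipliers=mults,
    )
    leaf_orders = {lf: node_orders[lf] for lf in leaves}

    # --- per-leaf assembly
    genomes: dict[str, GenomeRecord] = {}
    truth_clusters: dict[str, list] = {}
    truth_spacers: dict[str, list] = {}
    truth_oris: dict[str, list] = {}
    intron_records: list[IntronRecord] = []
    locus_members: dict[str, list[str]] = {lid: [] for *_, lid in locus_ids}

    fam_seqs = [_str_to_idx(s) for s in cfg.cluster_families]

    for leaf in leaves:
        asm = _Assembler(leaf)
        order = leaf_orders[leaf]
        n_regions = len(order)

        # plan intergenic content
        n_cl = int(rng.integers(cfg.cluster_count_range[0], cfg.cluster_count_range[1] + 1))
        n_ori = int(rng.integers(cfg.ori_count_range[0], cfg.ori_count_range[1] + 1))
        n_orf = int(rng.integers(cfg.orf_count_range[0], cfg.orf_count_range[1] + 1))
        ori_regions = set(rng.choice(n_regions, size=min(n_ori, n_regions), replace=False).tolist())
        orf_regions = set(rng.choice(n_regions, size=min(n_orf, n_regions), replace=False).tolist())
        cl_assign = rng.integers(0, n_regions, size=n_cl)

        def _cluster_instance():
            fam = int(rng.integers(0, len(fam_seqs)))
            seq = _mutate(rng, fam_seqs[fam], cfg.cluster_mutation_rate)
            if rng.random() < 0.5:
                seq = _revcomp_idx(seq)
            return seq, f"F{fam + 1}"

        # pre-build every element so composition can be balanced exactly
        region_elements: list[list[tuple[str, np.ndarray, str]]] = [[] for _ in range(n_regions)]
        for r in range(n_regions):
            if r in orf_regions:
                length = int(rng.integers(*cfg.orf_length_range)) // 3 * 3
                body = _suppress_gc_windows(
                    _random_seq(rng, max(length - 6, 3), cfg.coding_gc), rng)
                orf = np.concatenate([_str_to_idx("ATG"), body, _str_to_idx("TAA")])
                region_elements[r].append(("orf", orf, ""))
            if r in ori_regions:
                # ori: AT core with two internal GC clusters, the classic layout
                c1, f1 = _cluster_instance()
                c2, f2 = _cluster_instance()
                core = cfg.ori_core_length
                a1 = _random_seq(rng, core // 3, 0.02)
                a2 = _random_seq(rng, core // 3, 0.02)
                a3 = _random_seq(rng, core - 2 * (core // 3), 0.02)
                ori = np.concatenate([a1, c1, a2, c2, a3])
                # internal cluster offsets within the ori element
                off1 = (len(a1), len(a1) + len(c1), f1)
                off2 = (len(a1) + len(c1) + len(a2),
                        len(a1) + len(c1) + len(a2) + len(c2), f2)
                region_elements[r].append(("ori", ori, (off1, off2)))
        for r in cl_assign:
            seq, fam = _cluster_instance()
            region_elements[int(r)].append(("gc_cluster", seq, fam))

        # draw spacer/residual geometry: per region, one long spacer then a
        # short spacer after each element, plus residual filler at both ends
        region_spacers: list[list[int]] = []
        residual_lens = []
        for r in range(n_regions):
            lens = [int(rng.integers(*cfg.spacer_length_range))]
            lens += [int(rng.integers(*cfg.short_spacer_range)) for _ in region_elements[r]]
            region_spacers.append(lens)
            residual_lens.append((int(rng.integers(*cfg.residual_length_range)),
                                  int(rng.integers(*cfg.residual_length_range))))

        # --- exact composition balance: solve residual GC so the whole
        # genome hits target AT in expectation
        genic_len = genic_gc = 0
        seqs = leaf_seqs[leaf]
        for g, _ in order:
            arr = seqs[g]
            genic_len += len(arr)
            genic_gc += int(((arr == 1) | (arr == 2)).sum())
            for gene, site, group, has_orf, lid in locus_ids:
                if gene == g and presence[(lid, leaf)]:
                    iarr = seqs[f"intron:{lid}"]
                    genic_len += len(iarr)
                    genic_gc += int(((iarr == 1) | (iarr == 2)).sum())
        el_len = el_gc = 0
        for r in range(n_regions):
            for _, arr, _ in region_elements[r]:
                el_len += len(arr)
                el_gc += int(((arr == 1) | (arr == 2)).sum())
        sp_total = sum(sum(lens) for lens in region_spacers)
        res_total = sum(a + b for a, b in residual_lens)
        total_len = genic_len + el_len + sp_total + res_total
        target_gc_bases = (1 - cfg.target_at_fraction) * total_len
        need = target_gc_bases - genic_gc - el_gc - cfg.spacer_gc * sp_total
        residual_gc = min(max(need / res_total, 0.02), 0.5) if res_total else 0.25

        # --- lay the genome down
        intron_count_per_gene: dict[str, int] = {}
        for r, (g, sign) in enumerate(order):
            # gene body: exons interleaved with present introns
            coding = seqs[g]
            ivs = []  # (site, intron array, lid, group, has_orf) sorted by site
            for gene, site, group, has_orf, lid in locus_ids:
                if gene == g and presence[(lid, leaf)] and 10 <= site <= len(coding) - 10:
                    ivs.append((site, seqs[f"intron:{lid}"], lid, group, has_orf))
            ivs.sort()
            pieces = []
            exon_bounds = []  # in gene-forward coordinates
            intron_bounds = []
            cursor = 0
            offset = 0
            for site, iarr, lid, group, has_orf in ivs:
                pieces.append(coding[cursor:site])
                exon_bounds.append((offset, offset + (site - cursor)))
                offset += site - cursor
                pieces.append(iarr)
                intron_bounds.append((offset, offset + len(iarr), lid, group, has_orf, site))
                offset += len(iarr)
                cursor = site
            pieces.append(coding[cursor:])
            exon_bounds.append((offset, offset + len(coding) - cursor))
            offset += len(coding) - cursor
            full = np.concatenate(pieces) if len(pieces) > 1 else pieces[0]
            if sign < 0:
                full = _revcomp_idx(full)
            gstart, gend = asm.add(full)
            L = len(full)

            def _map(a: int, b: int) -> tuple[int, int]:
                return (gstart + a, gstart + b) if sign > 0 else (gstart + L - b, gstart + L - a)

            strand = "+" if sign > 0 else "-"
            asm.features.append(
                FeatureAnnotation(
                    kind=_feature_kind(g), gene_name=g, strand=strand,
                    intervals=tuple(sorted(_map(a, b) for a, b in exon_bounds if b > a)),
                )
            )
            for a, b, lid, group, has_orf, site in intron_bounds:
                asm.features.append(
                    FeatureAnnotation(kind="intron", gene_name=g, strand=strand,
                                      intervals=(_map(a, b),), subtype=f"group_{group}")
                )
                ordinal = intron_count_per_gene.get(g, 0) + 1
                intron_count_per_gene[g] = ordinal
                rec = IntronRecord(
                    species=leaf, host_gene=g, ordinal=ordinal, insertion_site=site,
                    flank5=_seq_to_str(coding[site - 10:site]),
                    flank3=_seq_to_str(coding[site:site + 10]),
                    group=group, has_orf=has_orf,
                )
                intron_records.append(rec)
                locus_members[lid].append(rec.name)

            # intergenic region following this gene
            res_a, res_b = residual_lens[r]
            asm.add(_suppress_gc_windows(_random_seq(rng, res_a, residual_gc), rng))
            if rng.random() < cfg.motif_prob:
                w = "A" if rng.random() < 0.5 else "T"
                asm.add(_str_to_idx(w + "TATAAGTA"))
            s0, e0 = asm.add(_random_seq(rng, region_spacers[r][0], cfg.spacer_gc))
            asm.spacers.append((s0, e0))
            for k, (kind, arr, meta) in enumerate(region_elements[r]):
                estart, eend = asm.add(arr)
                if kind == "gc_cluster":
                    asm.clusters.append(((estart, eend), meta))
                elif kind == "ori":
                    asm.oris.append((estart, eend))
                    asm.features.append(
                        FeatureAnnotation(kind="ori", gene_name=f"ori{len(asm.oris)}",
                                          strand="+", intervals=((estart, eend),))
                    )
                    for off_s, off_e, fam in meta:
                        asm.clusters.append(((estart + off_s, estart + off_e), fam))
                elif kind == "orf":
                    asm.features.append(
                        FeatureAnnotation(kind="intergenic_orf",
                                          gene_name=f"orf{r}", strand="+",
                                          intervals=((estart, eend),))
                    )
                ss, se = asm.add(_random_seq(rng, region_spacers[r][k + 1], cfg.spacer_gc))
                asm.spacers.append((ss, se))
            asm.add(_suppress_gc_windows(_random_seq(rng, res_b, residual_gc), rng))

        genomes[leaf] = asm.genome()
        truth_clusters[leaf] = asm.clusters
        truth_spacers[leaf] = asm.spacers
        truth_oris[leaf] = asm.oris

    gene_order_objs = {
        lf: GeneOrder(genome_id=lf, markers=list(leaf_orders[lf])) for lf in leaves
    }
    return SimulationTruth(
        genomes=genomes,
        gene_orders=gene_order_objs,
        node_orders=node_orders,
        branch_table=branch_table,
        clusters=truth_clusters,
        spacers=truth_spacers,
        oris=truth_oris,
        introns=intron_records,
        intron_loci={k: sorted(v) for k, v in locus_members.items() if v},
        config=cfg,
    )


def write_truth(truth: SimulationTruth, outdir: str | Path) -> None:
    """Emit FASTA + feature TSV per genome and truth tables as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if truth.config is not None:
        (outdir / "tree.nwk").write_text(truth.config.tree_newick.strip() + "\n")
    for leaf, g in sorted(truth.genomes.items()):
        write_genome(g, outdir / f"{leaf}.fasta")
    rows = []
    for leaf, cls in sorted(truth.clusters.items()):
        for (s, e), fam in cls:
            rows.append({"genome": leaf, "start": s, "end": e, "family": fam, "class": "gc_cluster"})
    for leaf, sps in sorted(truth.spacers.items()):
        for s, e in sps:
            rows.append({"genome": leaf, "start": s, "end": e, "family": "", "class": "at_spacer"})
    for leaf, oris in sorted(truth.oris.items()):
        for s, e in oris:
            rows.append({"genome": leaf, "start": s, "end": e, "family": "", "class": "ori"})
    pd.DataFrame(rows).to_csv(outdir / "truth_elements.tsv", sep="\t", index=False)
    orows = []
    for leaf, order in sorted(truth.gene_orders.items()):
        for pos, (m, s) in enumerate(order.markers):
            orows.append({"genome": leaf, "position": pos, "marker": m,
                          "strand": "+" if s > 0 else "-"})
    pd.DataFrame(orows).to_csv(outdir / "truth_gene_orders.tsv", sep="\t", index=False)
    truth.branch_table.to_csv(outdir / "truth_branches.tsv", sep="\t", index=False)
    irows = [
        {"name": r.name, "flank5": r.flank5, "flank3": r.flank3,
         "group": r.group, "has_orf": r.has_orf}
        for r in truth.introns
    ]
    pd.DataFrame(irows).to_csv(outdir / "truth_introns.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# Scoring


def _interval_positions(iv: tuple[int, int], n: int) -> frozenset:
    s, e = iv
    return frozenset(t % n for t in range(s, e))


def _match_intervals(true_ivs, pred_ivs, n: int, min_overlap: float = 0.8):
    """Greedy 1-1 matching of intervals by reciprocal overlap >= min_overlap."""
    cand = []
    tsets = [_interval_positions(iv, n) for iv in true_ivs]
    psets = [_interval_positions(iv, n) for iv in pred_ivs]
    for i, ts in enumerate(tsets):
        for j, ps in enumerate(psets):
            ov = len(ts & ps)
            if ts and ps and ov / len(ts) >= min_overlap and ov / len(ps) >= min_overlap:
                cand.append((ov, i, j))
    cand.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_t: set[int] = set()
    used_p: set[int] = set()
    tp = 0
    for ov, i, j in cand:
        if i in used_t or j in used_p:
            continue
        used_t.add(i)
        used_p.add(j)
        tp += 1
    return tp


def _prf(tp: int, n_pred: int, n_true: int) -> tuple[float, float, float]:
    p = tp / n_pred if n_pred else (1.0 if n_true == 0 else 0.0)
    r = tp / n_true if n_true else 1.0
    f = 2 * p * r / (p + r) if (p + r) else 0.0
    return p, r, f


def score_detection(
    truth: SimulationTruth,
    predicted_clusters: dict[str, list] | None = None,
    predicted_spacers: dict[str, list] | None = None,
    predicted_loci: list | None = None,
    *,
    min_overlap: float = 0.8,
) -> dict[str, tuple[float, float, float]]:
    """Precision / recall / F1 of detector output against the planted truth.

    Interval classes (clusters, spacers) match by reciprocal overlap >=
    ``min_overlap``; an intron locus matches when its member set equals a
    true locus's member set exactly.  Scores pool over all genomes.
    """

    def _ivs(objs):
        return [tuple(getattr(o, "interval", o))[:2] for o in objs]

    out: dict[str, tuple[float, float, float]] = {}
    if predicted_clusters is not None:
        tp = npred = ntrue = 0
        for leaf, preds in sorted(predicted_clusters.items()):
            n = len(truth.genomes[leaf].sequence)
            t_ivs = [iv for iv, _ in truth.clusters.get(leaf, [])]
            p_ivs = _ivs(preds)
            tp += _match_intervals(t_ivs, p_ivs, n, min_overlap)
            npred += len(p_ivs)
            ntrue += len(t_ivs)
        out["gc_cluster"] = _prf(tp, npred, ntrue)
    if predicted_spacers is not None:
        tp = npred = ntrue = 0
        for leaf, preds in sorted(predicted_spacers.items()):
            n = len(truth.genomes[leaf].sequence)
            t_ivs = truth.spacers.get(leaf, [])
            p_ivs = _ivs(preds)
            tp += _match_intervals(t_ivs, p_ivs, n, min_overlap)
            npred += len(p_ivs)
            ntrue += len(t_ivs)
        out["at_spacer"] = _prf(tp, npred, ntrue)
    if predicted_loci is not None:
        true_sets = {frozenset(v) for v in truth.intron_loci.values()}
        pred_sets = []
        for locus in predicted_loci:
            members = getattr(locus, "members", locus)
            names = frozenset(getattr(m, "name", m) for m in members)
            pred_sets.append(names)
        tp = sum(ps in true_sets for ps in pred_sets)
        out["intron_locus"] = _prf(tp, len(pred_sets), len(true_sets))
    return out
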