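"""Cross-species homology assignment of mitochondrial introns.

Yeast mtDNA introns sit in *cox1*, *cob* and *rnl* and are gained and lost
rapidly.  Introns from different species are assigned to the same locus when
they interrupt the same host gene at an equivalent position, judged primarily
by conservation of the 10-bp exon sequences flanking the insertion site and
secondarily by proximity of the insertion offsets in intron-free coding
coordinates.  Loci are connected components under single-linkage; a
component that would give one species two introns is split at its weakest
link.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .conservation import AlignmentMatrix, conserved_identity

__all__ = [
    "IntronRecord",
    "IntronLocus",
    "assign_loci",
    "presence_matrix",
    "locus_identity",
    "read_intron_table",
    "flank_identity",
]

HOST_GENES = ("cox1", "cob", "rnl")
FLANK_LEN = 10


@dataclass(frozen=True)
class IntronRecord:
    """One intron observed in one species.

    ``insertion_site`` is the 1-based nucleotide offset in the intron-free
    coding sequence after which the intron inserts; ``flank5``/``flank3`` are
    the 10-bp exon sequences on either side of the insertion point.
    """

    species: str
    host_gene: str
    ordinal: int               # which intron of this gene in this species (1-based)
    insertion_site: int
    flank5: str
    flank3: str
    group: str = "unknown"     # I / II / unknown
    has_orf: bool = False

    def __post_init__(self) -> None:
        if len(self.flank5) != FLANK_LEN or len(self.flank3) != FLANK_LEN:
            raise ValueError(
                f"{self.name}: flanks must be exactly {FLANK_LEN} bp "
                f"(got {len(self.flank5)}/{len(self.flank3)})"
            )
        if self.insertion_site < 1:
            raise ValueError(f"{self.name}: insertion site must be >= 1")

    @property
    def name(self) -> str:
        # Species_Gene_ID_Loc naming, e.g. Smik_COX1_1_168
        return f"{self.species}_{self.host_gene.upper()}_{self.ordinal}_{self.insertion_site}"

    @property
    def flanks(self) -> str:
        return (self.flank5 + self.flank3).upper()


def flank_identity(a: IntronRecord, b: IntronRecord) -> float:
    """Ungapped identity over the concatenated 20-bp flanks."""
    fa, fb = a.flanks, b.flanks
    return sum(x == y for x, y in zip(fa, fb)) / len(fa)


@dataclass
class IntronLocus:
    """A cross-species equivalence class of introns (at most one per species)."""

    locus_id: str
    host_gene: str
    members: list[IntronRecord]

    @property
    def species(self) -> list[str]:
        return sorted(r.species for r in self.members)

    @property
    def mean_site(self) -> float:
        return float(np.mean([r.insertion_site for r in self.members]))


def _linked(a: IntronRecord, b: IntronRecord, cutoff: float, site_window: int) -> bool:
    if a.host_gene != b.host_gene:
        return False
    ident = flank_identity(a, b)
    if ident >= cutoff:
        return True
    return ident >= cutoff - 0.1 and abs(a.insertion_site - b.insertion_site) <= site_window


def assign_loci(
    introns: list[IntronRecord],
    flank_identity_cutoff: float = 0.8,
    site_window: int = 30,
) -> list[IntronLocus]:
    """Cluster introns into homologous loci by flank conservation.

    Two introns link when they share the host gene and either their 20-bp
    flank identity reaches ``flank_identity_cutoff``, or it reaches
    ``cutoff - 0.1`` while the insertion sites differ by at most
    ``site_window`` nt (flank conservation outranks positional proximity).
    Connected components are loci; any component containing two introns of
    one species is split by removing its weakest link until valid.  Loci are
    ordered per host gene by mean insertion site.
    """
    order = {id(r): i for i, r in enumerate(introns)}
    G = nx.Graph()
    for i, r in enumerate(introns):
        G.add_node(i)
    for i in range(len(introns)):
        for j in range(i + 1, len(introns)):
            a, b = introns[i], introns[j]
            if _linked(a, b, flank_identity_cutoff, site_window):
                G.add_edge(i, j, weight=flank_identity(a, b))

    def _has_duplicate(comp: set[int]) -> bool:
        sp = [introns[i].species for i in comp]
        return len(sp) != len(set(sp))

    # split components with duplicated species at their weakest link
    changed = True
    while changed:
        changed = False
        for comp in list(nx.connected_components(G)):
            if len(comp) > 1 and _has_duplicate(comp):
                sub = G.subgraph(comp)
                # deterministic weakest edge: lowest identity, then node order
                u, v, _ = min(
                    sub.edges(data="weight"),
                    key=lambda e: (e[2], min(e[0], e[1]), max(e[0], e[1])),
                )
                G.remove_edge(u, v)
                changed = True
                break

    comps = [sorted(c) for c in nx.connected_components(G)]
    # group loci per host gene, order by mean insertion site
    loci: list[IntronLocus] = []
    per_gene: dict[str, list[list[int]]] = {}
    for comp in comps:
        per_gene.setdefault(introns[comp[0]].host_gene, []).append(comp)
    for gene, comps_g in per_gene.items():
        comps_g.sort(key=lambda c: (float(np.mean([introns[i].insertion_site for i in c])),
                                    min(c)))
        for k, comp in enumerate(comps_g, start=1):
            members = sorted((introns[i] for i in comp), key=lambda r: r.species)
            loci.append(IntronLocus(locus_id=f"{gene}_{k}", host_gene=gene, members=members))
    loci.sort(key=lambda l: (l.host_gene, int(l.locus_id.rsplit("_", 1)[1])))
    return loci


def presence_matrix(
    loci: list[IntronLocus],
    species_list: list[str],
    lineages: dict[str, list[str]] | None = None,
):
    """Binary locus x species presence matrix, plus per-lineage intron counts.

    A lineage "has" a locus when at least one of its species carries it.
    Returns ``(matrix, lineage_counts)``; ``lineage_counts`` is ``None``
    unless a lineage map is supplied.
    """
    mat = pd.DataFrame(
        0,
        index=[l.locus_id for l in loci],
        columns=list(species_list),
        dtype=int,
    )
    for l in loci:
        for r in l.members:
            if r.species in mat.columns:
                mat.loc[l.locus_id, r.species] = 1
    counts = None
    if lineages is not None:
        counts = {}
        for name, members in lineages.items():
            cols = [s for s in members if s in mat.columns]
            counts[name] = int((mat[cols].sum(axis=1) > 0).sum()) if cols else 0
    return mat, counts


def locus_identity(aligned_members: list[str], mode: str = "nucleotide") -> float | None:
    """Conserved-column identity of a locus's aligned member sequences.

    ``mode`` is ``orf_amino_acid`` for intron-ORF protein alignments or
    ``nucleotide`` for ORF-less introns.  A single-member locus is not
    computable (reported as '-' in tables) and returns ``None``.
    """
    if mode not in ("orf_amino_acid", "nucleotide"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(aligned_members) < 2:
        return None
    alphabet = "amino acid" if mode == "orf_amino_acid" else "nucleotide"
    aln = AlignmentMatrix(
        ids=[f"m{i}" for i in range(len(aligned_members))],
        rows=list(aligned_members),
        alphabet=alphabet,
    )
    return conserved_identity(aln)


def read_intron_table(path: str | Path) -> list[IntronRecord]:
    """Read introns from TSV with the Species_Gene_ID_Loc naming convention.

    Columns: name (e.g. Smik_COX1_1_168), flank5, flank3, group, has_orf.
    """
    tab = pd.read_csv(path, sep="\t")
    out = []
    for _, row in tab.iterrows():
        species, gene, ordinal, site = str(row["name"]).rsplit("_", 3)[-4:]
        out.append(
            IntronRecord(
                species=species,
                host_gene=gene.lower(),
                ordinal=int(ordinal),
                insertion_site=int(site),
                flank5=str(row["flank5"]),
                flank3=str(row["flank3"]),
                group=str(row.get("group", "unknown")),
                has_orf=bool(row.get("has_orf", False)),
            )
        )
    return out
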