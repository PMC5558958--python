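"""Genome, annotation, tree and alignment I/O plus the five-part genome partition.

Yeast mitochondrial genomes are compact circular molecules whose length
variation is dominated by non-coding DNA.  This module holds the core record
types (:class:`GenomeRecord`, :class:`FeatureAnnotation`), readers for GenBank
flat files and FASTA + TSV feature tables, and the exclusive interval
partition of a genome into genes, introns and intergenic sub-parts (ORFs,
*ori* elements, GC clusters, AT spacers and residual sequence).

Coordinates are 0-based half-open internally; external files use the 1-based
inclusive GenBank convention.  Circular genomes are linearized at position 0
and origin-wrapping features are stored as two intervals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "FeatureAnnotation",
    "GenomeRecord",
    "GenomePartition",
    "read_genome",
    "write_genome",
    "build_partition",
    "intergenic_fraction_of_variation",
    "read_tree",
    "intergenic_intervals",
    "to_external",
    "to_internal",
]

FEATURE_KINDS = ("gene_exon", "intron", "intergenic_orf", "ori", "trna", "rrna", "rnap")

# bp-precedence when intergenic sub-features nest (e.g. ori elements with
# intervening GC clusters): each base is credited once, to the highest class.
PARTITION_PRECEDENCE = ("gene_exon", "intron", "intergenic_orf", "ori", "gc_cluster", "at_spacer", "residual")

VALID_BASES = frozenset("ACGTN")


def to_internal(start_1based: int, end_inclusive: int) -> tuple[int, int]:
    """Convert a 1-based inclusive coordinate pair to 0-based half-open."""
    return start_1based - 1, end_inclusive


def to_external(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval back to 1-based inclusive."""
    return start + 1, end


@dataclass(frozen=True)
class FeatureAnnotation:
    """A single annotated feature: exon(s) of a gene, an intron, an ORF, ...

    ``intervals`` is a list of 0-based half-open ``(start, end)`` pairs,
    ordered along the strand; a feature wrapping the circular origin is stored
    as two intervals.
    """

    kind: str
    gene_name: str
    strand: str
    intervals: tuple[tuple[int, int], ...]
    subtype: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.intervals:
            raise ValueError(f"feature {self.gene_name!r} has no intervals")
        for s, e in self.intervals:
            if e <= s:
                raise ValueError(f"feature {self.gene_name!r} has empty interval [{s},{e})")
        object.__setattr__(self, "intervals", tuple((int(s), int(e)) for s, e in self.intervals))

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    @property
    def start(self) -> int:
        return self.intervals[0][0]


@dataclass
class GenomeRecord:
    """A (usually circular) mitochondrial genome with its feature annotations."""

    id: str
    sequence: str
    topology: str = "circular"
    features: list[FeatureAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) == 0:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"genome {self.id!r}: non-ACGTN characters {sorted(bad)}")
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"unknown topology {self.topology!r}")
        n = len(self.sequence)
        for f in self.features:
            for s, e in f.intervals:
                if not (0 <= s < e <= n):
                    raise ValueError(
                        f"genome {self.id!r}: feature {f.gene_name!r} interval [{s},{e}) "
                        f"outside sequence of length {n}"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_sequence(self, f: FeatureAnnotation) -> str:
        return "".join(self.sequence[s:e] for s, e in f.intervals)


def _wrap_intervals(start0: int, end_excl: int, n: int, circular: bool) -> tuple[tuple[int, int], ...]:
    """Normalize a possibly origin-wrapping span into 1 or 2 in-range intervals."""
    if start0 < end_excl:
        return ((start0, end_excl),)
    if not circular:
        raise ValueError(f"wrapping interval {start0}..{end_excl} on linear genome")
    return ((start0, n), (0, end_excl))


def _check_gene_exons(features: Sequence[FeatureAnnotation]) -> None:
    """Reject overlapping exon intervals within any one gene."""
    for f in features:
        ivs = sorted(f.intervals)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"gene {f.gene_name!r}: overlapping exons [{s1},{e1}) and [{s2},{e2})")


_GENBANK_KIND = {
    "CDS": "gene_exon",
    "gene": "gene_exon",
    "tRNA": "trna",
    "rRNA": "rrna",
    "intron": "intron",
    "rep_origin": "ori",
    "ncRNA": "rnap",
    "ORF": "intergenic_orf",
}


def read_genome(path: str | Path, dialect: str = "fasta+tsv", *, topology: str = "circular") -> GenomeRecord:
    """Read an annotated genome.

    ``dialect="genbank"`` reads a GenBank flat file; ``dialect="fasta+tsv"``
    expects ``<path>`` to be a FASTA file with a sibling ``<stem>.features.tsv``
    table (columns gene, kind, strand, start, end; 1-based inclusive; an end
    smaller than the start denotes an origin-wrapping feature on a circular
    genome).
    """
    path = Path(path)
    if dialect == "genbank":
        rec = SeqIO.read(str(path), "genbank")
        seq = str(rec.seq).upper()
        topo = rec.annotations.get("topology", topology)
        feats: list[FeatureAnnotation] = []
        for sf in rec.features:
            if sf.type == "source":
                continue
            kind = _GENBANK_KIND.get(sf.type, sf.type)
            name = sf.qualifiers.get("gene", sf.qualifiers.get("label", [sf.type]))[0]
            strand = "-" if sf.location.strand == -1 else "+"
            ivs = tuple(sorted((int(p.start), int(p.end)) for p in sf.location.parts))
            feats.append(FeatureAnnotation(kind=kind, gene_name=name, strand=strand, intervals=ivs))
        g = GenomeRecord(id=rec.id, sequence=seq, topology=topo, features=feats)
    elif dialect == "fasta+tsv":
        rec = SeqIO.read(str(path), "fasta")
        seq = str(rec.seq).upper()
        n = len(seq)
        tsv = path.parent / (path.stem + ".features.tsv")
        feats = []
        if tsv.exists():
            tab = pd.read_csv(tsv, sep="\t", dtype={"gene": str, "kind": str, "strand": str})
            grouped: dict[tuple, list[tuple[int, int]]] = {}
            for _, row in tab.iterrows():
                start0, end_excl = to_internal(int(row["start"]), int(row["end"]))
                if not (0 <= start0 < n) or end_excl > n or end_excl < 0:
                    raise ValueError(
                        f"{path.name}: feature {row['gene']!r} coordinates "
                        f"{row['start']}..{row['end']} outside 1..{n}"
                    )
                key = (str(row["gene"]), str(row["kind"]), str(row["strand"]))
                grouped.setdefault(key, []).extend(
                    _wrap_intervals(start0, end_excl, n, topology == "circular"))
            for (name, kind, strand), ivs in grouped.items():
                # rows appear in strand order; a wrapped row already expands
                # to its two segments in that order
                feats.append(
                    FeatureAnnotation(kind=kind, gene_name=name, strand=strand,
                                      intervals=tuple(ivs))
                )
        g = GenomeRecord(id=rec.id, sequence=seq, topology=topology, features=feats)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    _check_gene_exons([f for f in g.features if f.kind == "gene_exon"])
    return g


def write_genome(g: GenomeRecord, fasta_path: str | Path) -> None:
    """Write FASTA + ``<stem>.features.tsv`` (1-based inclusive coordinates)."""
    fasta_path = Path(fasta_path)
    with open(fasta_path, "w") as fh:
        fh.write(f">{g.id}\n")
        for i in range(0, len(g.sequence), 70):
            fh.write(g.sequence[i : i + 70] + "\n")
    rows = []
    n = len(g.sequence)
    for f in g.features:
        # re-fuse a wrapped pair back into one external row
        if len(f.intervals) == 2 and f.intervals[0][1] == n and f.intervals[1][0] == 0:
            s, e = f.intervals[0][0], f.intervals[1][1]
            rows.append((f.gene_name, f.kind, f.strand, s + 1, e))
        else:
            for s, e in f.intervals:
                rows.append((f.gene_name, f.kind, f.strand, s + 1, e))
    tab = pd.DataFrame(rows, columns=["gene", "kind", "strand", "start", "end"])
    tab.to_csv(fasta_path.parent / (fasta_path.stem + ".features.tsv"), sep="\t", index=False)


# ---------------------------------------------------------------------------
# Partition


@dataclass
class GenomePartition:
    """Exclusive tiling of a genome into genes / introns / intergenic parts.

    ``part_sizes`` covers the top level (genes + introns + intergenic ==
    genome length); ``intergenic_sizes`` subdivides the intergenic part into
    orf / ori / gc_cluster / at_spacer / residual, again summing exactly.
    """

    genome_id: str
    genome_length: int
    part_sizes: dict[str, int]
    intergenic_sizes: dict[str, int]
    part_intervals: dict[str, list[tuple[int, int]]]

    def validate(self) -> None:
        top = sum(self.part_sizes.values())
        if top != self.genome_length:
            raise AssertionError(
                f"{self.genome_id}: parts sum to {top}, genome length {self.genome_length}"
            )
        sub = sum(self.intergenic_sizes.values())
        if sub != self.part_sizes["intergenic"]:
            raise AssertionError(
                f"{self.genome_id}: intergenic sub-parts sum to {sub}, "
                f"intergenic is {self.part_sizes['intergenic']}"
            )

    def to_frame(self) -> pd.DataFrame:
        row = {"genome": self.genome_id, "length": self.genome_length}
        row.update(self.part_sizes)
        row.update({k: v for k, v in self.intergenic_sizes.items()})
        return pd.DataFrame([row])


def _mask_from_intervals(n: int, intervals: Iterable[tuple[int, int]]) -> np.ndarray:
    m = np.zeros(n, dtype=bool)
    for s, e in intervals:
        m[s:e] = True
    return m


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean array as half-open intervals."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def build_partition(g: GenomeRecord, clusters=None, spacers=None) -> GenomePartition:
    """Partition a genome into the five-part accounting used for size tables.

    ``clusters`` / ``spacers`` are optional lists of objects with an
    ``interval`` attribute (see :mod:`mitoarch.compositional`) or bare
    ``(start, end)`` tuples, computed on the same genome.  Overlaps are
    resolved by precedence gene_exon > intron > intergenic_orf > ori >
    gc_cluster > at_spacer > residual so that every base is counted once.
    """
    n = len(g.sequence)
    if g.topology == "linear":
        for f in g.features:
            if any(e > n for _, e in f.intervals):
                raise ValueError(f"feature {f.gene_name} extends past linear genome end")

    def _ivs(objs):
        out = []
        for o in objs or []:
            iv = getattr(o, "interval", o)
            out.append((int(iv[0]), int(iv[1])))
        return out

    by_kind: dict[str, list[tuple[int, int]]] = {k: [] for k in PARTITION_PRECEDENCE}
    for f in g.features:
        if f.kind in ("gene_exon", "trna", "rrna", "rnap"):
            by_kind["gene_exon"].extend(f.intervals)
        elif f.kind == "intron":
            by_kind["intron"].extend(f.intervals)
        elif f.kind == "intergenic_orf":
            by_kind["intergenic_orf"].extend(f.intervals)
        elif f.kind == "ori":
            by_kind["ori"].extend(f.intervals)
        # unknown kinds fall through to intergenic residual
    by_kind["gc_cluster"] = _ivs(clusters)
    by_kind["at_spacer"] = _ivs(spacers)

    claimed = np.zeros(n, dtype=bool)
    sizes: dict[str, int] = {}
    intervals: dict[str, list[tuple[int, int]]] = {}
    for kind in PARTITION_PRECEDENCE[:-1]:
        m = _mask_from_intervals(n, by_kind[kind]) & ~claimed
        sizes[kind] = int(m.sum())
        intervals[kind] = _runs(m)
        claimed |= m
    sizes["residual"] = int(n - claimed.sum())
    intervals["residual"] = _runs(~claimed)

    part_sizes = {
        "genes": sizes["gene_exon"],
        "introns": sizes["intron"],
        "intergenic": n - sizes["gene_exon"] - sizes["intron"],
    }
    intergenic_sizes = {
        "orf": sizes["intergenic_orf"],
        "ori": sizes["ori"],
        "gc_cluster": sizes["gc_cluster"],
        "at_spacer": sizes["at_spacer"],
        "residual": sizes["residual"],
    }
    part = GenomePartition(
        genome_id=g.id,
        genome_length=n,
        part_sizes=part_sizes,
        intergenic_sizes=intergenic_sizes,
        part_intervals=intervals,
    )
    part.validate()
    return part


def intergenic_intervals(g: GenomeRecord) -> list[tuple[int, int]]:
    """Intervals not covered by gene exons or introns (intergenic regions)."""
    n = len(g.sequence)
    genic = np.zeros(n, dtype=bool)
    for f in g.features:
        if f.kind in ("gene_exon", "trna", "rrna", "rnap", "intron"):
            for s, e in f.intervals:
                genic[s:e] = True
    return _runs(~genic)


def intergenic_fraction_of_variation(partitions: Sequence[GenomePartition], reference_id: str):
    """OLS of genome size on intergenic size across genomes.

    Returns ``(slope, intercept, r_squared)``.  The reference genome (the one
    with the smallest intergenic load, *C. glabrata* in the original study)
    must be among the inputs; it anchors the comparison but the fit itself is
    ordinary least squares over all genomes.
    """
    if len(partitions) < 3:
        raise ValueError("need at least 3 genomes for a regression")
    ids = [p.genome_id for p in partitions]
    if reference_id not in ids:
        raise ValueError(f"reference genome {reference_id!r} not among inputs")
    x = np.array([p.part_sizes["intergenic"] for p in partitions], dtype=float)
    y = np.array([float(p.genome_length) for p in partitions])
    if np.ptp(x) == 0:
        raise ValueError("zero variance in intergenic sizes")
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), float(r2)


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a Newick tree with branch lengths; leaf labels must be unique."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    except Exception as exc:  # dendropy raises schema-specific parse errors
        raise ValueError(f"could not parse tree: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels in tree")
    return tree
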