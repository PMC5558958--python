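"""Conserved-column identity statistics over multiple sequence alignments.

The central statistic is the proportion of alignment columns in which every
sequence carries the same non-gap residue ("completely conserved columns").
It is applied to per-gene nucleotide alignments, to intron ORF amino-acid
alignments, and to genome-wide protein sets, where a one-sided hypergeometric
test asks whether highly conserved proteins (identity above a threshold) are
over-represented in one group relative to a pooled background.

Alignments themselves are external inputs (aligned FASTA); the built-in
Needleman–Wunsch aligner (match +1, mismatch -1, gap -2) exists for pairwise
fixtures and for the short GC-cluster / intron comparisons elsewhere in the
package.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import Align, SeqIO
from scipy.stats import hypergeom

__all__ = [
    "AlignmentMatrix",
    "read_alignment",
    "conserved_identity",
    "high_identity_enrichment",
    "pairwise_identity",
    "global_align",
    "read_omega_table",
]

GAP = "-"


@dataclass
class AlignmentMatrix:
    """A rectangular alignment: rows are sequences, columns are positions."""

    ids: list[str]
    rows: list[str]
    alphabet: str = "nucleotide"

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 sequences")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"unequal row lengths: {sorted(lengths)}")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])


def read_alignment(path: str | Path, alphabet: str = "nucleotide") -> AlignmentMatrix:
    recs = list(SeqIO.parse(str(path), "fasta"))
    return AlignmentMatrix(ids=[r.id for r in recs], rows=[str(r.seq) for r in recs], alphabet=alphabet)


def conserved_identity(a: AlignmentMatrix) -> float:
    """Fraction of columns where all rows share one non-gap residue.

    The denominator is the full alignment length; columns containing any gap
    (including all-gap columns) count as non-conserved.
    """
    if a.n_columns == 0:
        raise ValueError("alignment has zero columns")
    mat = np.array([list(r) for r in a.rows])
    same = (mat == mat[0]).all(axis=0)
    nongap = (mat != GAP).all(axis=0)
    return float((same & nongap).sum() / mat.shape[1])


def high_identity_enrichment(group_a, group_b, threshold: float = 0.9) -> float:
    """One-sided hypergeometric test for enrichment of high-identity entries.

    The population is the pooled identities of both groups; a "success" is an
    identity strictly greater than ``threshold``; the sample is ``group_a``.
    Returns the exact upper tail P(X >= k_a).
    """
    group_a = list(map(float, group_a))
    group_b = list(map(float, group_b))
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    pooled = group_a + group_b
    if any(not 0 <= v <= 1 for v in pooled):
        raise ValueError("identities must lie in [0, 1]")
    N = len(pooled)
    K = sum(v > threshold for v in pooled)
    n_a = len(group_a)
    k_a = sum(v > threshold for v in group_a)
    return float(hypergeom.sf(k_a - 1, N, K, n_a))


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


_ALIGNER = _make_aligner()


def global_align(a: str, b: str) -> tuple[str, str]:
    """Needleman-Wunsch global alignment (match +1, mismatch -1, gap -2).

    Returns the two gapped rows of one optimal alignment (the aligner's
    deterministic first traceback).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aln = _ALIGNER.align(a.upper(), b.upper())[0]
    return str(aln[0]), str(aln[1])


def pairwise_identity(a: str, b: str, mode: str = "ungapped") -> float:
    """Identity between two sequences.

    ``ungapped`` compares position by position and requires equal lengths;
    ``global_alignment`` first aligns with the module's NW aligner, then
    scores the fraction of alignment columns with identical non-gap residues.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if mode == "ungapped":
        if len(a) != len(b):
            raise ValueError(f"ungapped mode requires equal lengths ({len(a)} vs {len(b)})")
        ga, gb = a.upper(), b.upper()
    elif mode == "global_alignment":
        ga, gb = global_align(a, b)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return conserved_identity(AlignmentMatrix(ids=["a", "b"], rows=[ga, gb]))


def read_omega_table(path: str | Path):
    """Ingest a TSV of externally computed dN/dS (omega) values.

    Expected columns: gene, lineage, omega.  The package never computes
    omega; this reader exists so selection summaries can be assembled
    alongside the identity tables.
    """
    import pandas as pd

    tab = pd.read_csv(path, sep="\t")
    missing = {"gene", "lineage", "omega"} - set(tab.columns)
    if missing:
        raise ValueError(f"omega table missing columns: {sorted(missing)}")
    return tab
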