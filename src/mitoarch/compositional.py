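"""GC clusters, AT spacers and compositional statistics of AT-rich genomes.

Yeast mitochondrial intergenic DNA is a near-pure A/T background invaded by
short GC-rich mobile elements ("GC clusters").  Detection is a two-pass
coverage scheme: a position belongs to a cluster when it lies inside at least
one window of length >= 16 with GC fraction >= 0.75 (pass 1); detected runs
are masked and the remaining stretches rescanned at length >= 8, GC >= 0.85
(pass 2); finally clusters separated by fewer than 10 bp are joined,
transitively.  Cluster extent is therefore the union of qualifying windows,
which is unambiguous and directly checkable against an exhaustive substring
enumeration.

Families group clusters (together with their reverse complements) by global
alignment identity via UPGMA, with greedy retention of the largest groups and
a column-majority consensus; AT spacers are the long (> 20 bp) near-pure A/T
(GC < 0.1) intergenic fragments left once clusters containing a G/C
tetranucleotide are excised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .conservation import global_align, pairwise_identity

__all__ = [
    "GCCluster",
    "GCClusterFamily",
    "ATSpacer",
    "detect_gc_clusters",
    "group_gc_clusters",
    "main_families",
    "is_palindromic_like",
    "detect_at_spacers",
    "dinucleotide_ratio",
    "scan_motif",
    "gc_fraction",
    "revcomp",
]

_COMP = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def gc_fraction(seq: str) -> float:
    """G+C fraction; N and other ambiguity codes count as non-GC."""
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


@dataclass
class GCCluster:
    """A detected GC-rich segment.

    ``interval`` is 0-based half-open on the linearized genome; ``end`` may
    exceed the genome length when the cluster wraps the circular origin.
    """

    interval: tuple[int, int]
    sequence: str
    pass_label: str = "pass1"
    gc_fraction: float = 0.0
    genome_id: str = ""

    def __post_init__(self) -> None:
        self.gc_fraction = gc_fraction(self.sequence)

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


@dataclass
class GCClusterFamily:
    """A group of mutually similar GC clusters with a consensus sequence."""

    family_id: str
    members: list[tuple[int, str]]  # (cluster index, orientation '+'/'-')
    consensus: str

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ATSpacer:
    """A long near-pure A/T intergenic fragment."""

    interval: tuple[int, int]
    sequence: str
    gc_fraction: float = 0.0
    genome_id: str = ""

    def __post_init__(self) -> None:
        self.gc_fraction = gc_fraction(self.sequence)

    @property
    def length(self) -> int:
        return self.interval[1] - self.interval[0]


# ---------------------------------------------------------------------------
# Coverage detection


def _check_sequence(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    return seq


def _covered_intervals(gc: np.ndarray, min_len: int, thresh: float, max_len: int) -> list[tuple[int, int]]:
    """Union of all windows [a,b) with b-a in [min_len, max_len] and mean(gc) >= thresh.

    Exact integer arithmetic: per-base score q*gc - p for thresh = p/q; a
    window qualifies iff its score sum is >= 0.  For each start a, every
    qualifying window is contained in [a, maxend(a)), so the union is the
    merge of those intervals.  maxend is found by binary descent on a sparse
    table of prefix-score range maxima.
    """
    n = len(gc)
    if n < min_len:
        return []
    frac = Fraction(thresh).limit_denominator(10**6)
    p, q = frac.numerator, frac.denominator
    score = gc.astype(np.int64) * q - p
    P = np.concatenate([[0], np.cumsum(score)])  # length n+1

    # sparse table over P for range max queries
    K = max(1, int(np.floor(np.log2(len(P)))) + 1)
    table = [P]
    j = 1
    while (1 << j) <= len(P):
        prev = table[-1]
        half = 1 << (j - 1)
        table.append(np.maximum(prev[:-half], prev[half:]))
        j += 1

    def range_max(lo: int, hi: int) -> int:  # inclusive indices into P
        k = (hi - lo + 1).bit_length() - 1
        t = table[k]
        return max(t[lo], t[hi - (1 << k) + 1])

    def last_ge(lo: int, hi: int, v: int) -> int:
        """Largest index b in [lo, hi] with P[b] >= v, or -1."""
        if lo > hi or range_max(lo, hi) < v:
            return -1
        while lo < hi:
            mid = (lo + hi) // 2
            if range_max(mid + 1, hi) >= v:
                lo = mid + 1
            else:
                hi = mid
        return lo

    out: list[tuple[int, int]] = []
    for a in range(n - min_len + 1):
        lo, hi = a + min_len, min(a + max_len, n)
        b = last_ge(lo, hi, int(P[a]))
        if b >= 0:
            if out and a <= out[-1][1]:
                if b > out[-1][1]:
                    out[-1] = (out[-1][0], b)
            else:
                out.append((a, b))
    return out


def _detect_on_segment(seq01: np.ndarray, min_len: int, thresh: float) -> list[tuple[int, int]]:
    return _covered_intervals(seq01, min_len, thresh, max_len=len(seq01))


def detect_gc_clusters(
    seq: str,
    topology: str = "linear",
    *,
    min_len1: int = 16,
    min_gc1: float = 0.75,
    min_len2: int = 8,
    min_gc2: float = 0.85,
    join_gap: int = 10,
    genome_id: str = "",
) -> list[GCCluster]:
    """Two-pass GC-cluster detection with transitive joining.

    Pass 1 covers every position inside a window of length >= ``min_len1``
    and GC >= ``min_gc1``; covered runs are masked and pass 2 rescans the
    unmasked stretches (windows may not cross masked positions) at
    ``min_len2`` / ``min_gc2``.  Pooled clusters separated by a gap smaller
    than ``join_gap`` are joined transitively.  On circular topology windows
    may wrap the origin, with cluster length capped at the genome length.
    """
    seq = _check_sequence(seq)
    n = len(seq)
    if n == 0:
        return []
    gc = np.frombuffer(seq.encode(), dtype=np.uint8)
    gc01 = ((gc == ord("G")) | (gc == ord("C"))).astype(np.int64)
    circular = topology == "circular"

    def detect_circular(arr01: np.ndarray, min_len: int, thresh: float) -> list[tuple[int, int]]:
        m = len(arr01)
        if m < min_len:
            return []
        doubled = np.concatenate([arr01, arr01])
        ivs = _covered_intervals(doubled, min_len, thresh, max_len=m)
        covered = np.zeros(m, dtype=bool)
        for s, e in ivs:
            if s >= m:
                continue
            for t in range(s, min(e, s + m)):
                covered[t % m] = True
        return _circular_runs(covered)

    if circular:
        pass1 = detect_circular(gc01, min_len1, min_gc1)
    else:
        pass1 = _detect_on_segment(gc01, min_len1, min_gc1)

    # mask and rescan
    masked = np.zeros(n, dtype=bool)
    for s, e in pass1:
        for t in range(s, e):
            masked[t % n] = True
    pass2: list[tuple[int, int]] = []
    if circular and not masked.any():
        pass2 = detect_circular(gc01, min_len2, min_gc2)
    else:
        for s, e in _unmasked_segments(masked, circular):
            idx = np.arange(s, e) % n
            sub = gc01[idx]
            for a, b in _detect_on_segment(sub, min_len2, min_gc2):
                pass2.append((s + a, s + b))

    labelled = [(s % n, s % n + (e - s), lab)
                for runs, lab in ((pass1, "pass1"), (pass2, "pass2"))
                for s, e in runs]
    clusters = _join_clusters(labelled, n, circular, join_gap)
    doubled_seq = seq + seq
    return [
        GCCluster(interval=(s, e), sequence=doubled_seq[s:e], pass_label=lab, genome_id=genome_id)
        for s, e, lab in clusters
    ]


def _circular_runs(covered: np.ndarray) -> list[tuple[int, int]]:
    """Maximal covered runs on a circle; a run crossing the origin gets end > n."""
    m = len(covered)
    if covered.all():
        return [(0, m)]
    if not covered.any():
        return []
    ext = np.concatenate([covered, covered])
    runs = []
    i = 0
    while i < 2 * m:
        if ext[i] and (i == 0 or not ext[i - 1]):
            j = i
            while j < 2 * m and ext[j]:
                j += 1
            if i < m:
                runs.append((i, j))
            i = j
        else:
            i += 1
    # keep only runs that start in the first copy and were not already counted
    out = []
    for s, e in runs:
        if s == 0 and covered[m - 1]:
            continue  # this run is the tail of a wrapping run reported from its true start
        out.append((s, min(e, s + m)))
    return sorted(out)


def _unmasked_segments(masked: np.ndarray, circular: bool) -> list[tuple[int, int]]:
    """Maximal unmasked stretches; on a circle a wrapping stretch has end > n."""
    free = ~masked
    if circular:
        return _circular_runs(free)
    n = len(masked)
    segs = []
    i = 0
    while i < n:
        if free[i]:
            j = i
            while j < n and free[j]:
                j += 1
            segs.append((i, j))
            i = j
        else:
            i += 1
    return segs


def _join_clusters(labelled, n: int, circular: bool, join_gap: int):
    """Transitively join clusters with gaps < join_gap; returns (s, e, label)."""
    if not labelled:
        return []
    labelled = sorted(labelled)
    merged = [list(labelled[0])]
    for s, e, lab in labelled[1:]:
        ps, pe, plab = merged[-1]
        if s - pe < join_gap:
            merged[-1] = [ps, max(pe, e), plab if (plab == lab and s <= pe) else "joined"]
        else:
            merged.append([s, e, lab])
    if circular and len(merged) > 1:
        # join across the origin
        fs, fe, flab = merged[0]
        ls, le, llab = merged[-1]
        if (fs + n) - le < join_gap and le - ls < n:
            merged[-1] = [ls, fe + n, "joined"]
            merged.pop(0)
    # cap lengths at genome length
    out = []
    for s, e, lab in merged:
        out.append((s, min(e, s + n), lab))
    return out


# ---------------------------------------------------------------------------
# Family grouping


def _center_star_msa(seqs: Sequence[str]) -> list[str]:
    """Deterministic center-star multiple alignment using the NW aligner.

    The center is the sequence minimizing total alignment distance (ties:
    lowest index).  All others are pairwise-aligned to the center and merged
    by propagating center gaps, the classic star-alignment construction.
    """
    k = len(seqs)
    if k == 1:
        return [seqs[0]]
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = 1.0 - pairwise_identity(seqs[i], seqs[j], mode="global_alignment")
            dist[i, j] = dist[j, i] = d
    center = int(np.argmin(dist.sum(axis=1)))
    # merged center with gaps accumulated across all pairwise alignments
    pair_alns = []
    for j in range(k):
        if j == center:
            continue
        gc_row, gj_row = global_align(seqs[center], seqs[j])
        pair_alns.append((j, gc_row, gj_row))
    # master gap pattern: count max gaps between consecutive center residues
    L = len(seqs[center])
    gap_before = np.zeros(L + 1, dtype=int)
    for _, gc_row, _ in pair_alns:
        pos = 0
        run = 0
        for ch in gc_row:
            if ch == "-":
                run += 1
            else:
                gap_before[pos] = max(gap_before[pos], run)
                run = 0
                pos += 1
        gap_before[L] = max(gap_before[L], run)

    def expand(gc_row: str, gx_row: str) -> str:
        """Re-space one pairwise alignment onto the master center coordinates."""
        out = []
        pos = 0
        run_chars: list[str] = []
        for cch, xch in zip(gc_row, gx_row):
            if cch == "-":
                run_chars.append(xch)
            else:
                out.append("-" * (gap_before[pos] - len(run_chars)) + "".join(run_chars))
                out.append(xch)
                run_chars = []
                pos += 1
        out.append("-" * (gap_before[L] - len(run_chars)) + "".join(run_chars))
        return "".join(out)

    rows = [""] * k
    center_row = []
    for pos in range(L):
        center_row.append("-" * gap_before[pos] + seqs[center][pos])
    center_row.append("-" * gap_before[L])
    rows[center] = "".join(center_row)
    for j, gc_row, gj_row in pair_alns:
        rows[j] = expand(gc_row, gj_row)
    assert len({len(r) for r in rows}) == 1
    return rows


def _majority_consensus(rows: Sequence[str]) -> str:
    """Column-majority consensus; ties broken alphabetically; gap columns dropped."""
    cols = zip(*rows)
    out = []
    for col in cols:
        counts: dict[str, int] = {}
        for ch in col:
            counts[ch] = counts.get(ch, 0) + 1
        best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        if best != "-":
            out.append(best)
    return "".join(out)


def group_gc_clusters(
    clusters: Sequence[GCCluster],
    identity_cutoff: float = 0.6,
    overlap_cutoff: float = 0.8,
) -> list[GCClusterFamily]:
    """Group GC clusters into families via their mutual alignment identity.

    Each cluster is pooled with its reverse complement; all-vs-all global
    alignment distances (1 - identity) feed a UPGMA tree which is cut at
    height ``1 - identity_cutoff``.  A reverse-complement entry co-occurring
    with its forward mate in one group is dropped.  Groups are retained
    greedily by descending size, discarding any whose cluster-id overlap with
    already retained families exceeds ``overlap_cutoff``; retained members
    are deduplicated so no cluster sits in two families.  The consensus is
    the column majority over a center-star alignment of the group.
    """
    if not 0 < identity_cutoff < 1:
        raise ValueError("identity_cutoff must lie in (0, 1)")
    if not clusters:
        raise ValueError("need at least one cluster")
    entries: list[tuple[int, str, str]] = []
    for i, c in enumerate(clusters):
        seq = c.sequence if isinstance(c, GCCluster) else str(c)
        entries.append((i, "+", seq.upper()))
        entries.append((i, "-", revcomp(seq.upper())))
    m = len(entries)
    if m == 2:
        d = 1.0 - pairwise_identity(entries[0][2], entries[1][2], mode="global_alignment")
        groups = [[0, 1]] if d <= 1.0 - identity_cutoff else [[0], [1]]
    else:
        dist = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                d = 1.0 - pairwise_identity(entries[i][2], entries[j][2], mode="global_alignment")
                dist[i, j] = dist[j, i] = max(d, 0.0)
        Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
        labels = hierarchy.fcluster(Z, t=1.0 - identity_cutoff, criterion="distance")
        groups = [list(np.flatnonzero(labels == g)) for g in sorted(set(labels))]

    # drop the '-' entry of any cluster whose '+' entry shares the group
    cleaned: list[list[int]] = []
    for grp in groups:
        ids_fwd = {entries[e][0] for e in grp if entries[e][1] == "+"}
        kept = [e for e in grp if not (entries[e][1] == "-" and entries[e][0] in ids_fwd)]
        if kept:
            cleaned.append(kept)

    cleaned.sort(key=lambda grp: (-len(grp), min(entries[e][0] for e in grp)))
    retained: list[list[int]] = []
    seen: set[int] = set()
    for grp in cleaned:
        ids = {entries[e][0] for e in grp}
        if ids and len(ids & seen) / len(ids) > overlap_cutoff:
            continue
        kept = [e for e in grp if entries[e][0] not in seen]
        if not kept:
            continue
        retained.append(kept)
        seen |= {entries[e][0] for e in kept}

    families = []
    for fi, grp in enumerate(retained, start=1):
        # orient every member consistently with the group's first entry so
        # the consensus is computed over one strand
        ref = entries[grp[0]][2]
        oriented: list[tuple[int, str, str]] = []
        for e in grp:
            idx, ori, seq = entries[e]
            if seq != ref:
                fwd = pairwise_identity(seq, ref, mode="global_alignment")
                rev = pairwise_identity(revcomp(seq), ref, mode="global_alignment")
                if rev > fwd:
                    seq = revcomp(seq)
                    ori = "-" if ori == "+" else "+"
            oriented.append((idx, ori, seq))
        seqs = [seq for _, _, seq in oriented]
        rows = _center_star_msa(seqs) if len(seqs) > 1 else seqs
        consensus = _majority_consensus(rows)
        members = sorted((idx, ori) for idx, ori, _ in oriented)
        families.append(GCClusterFamily(family_id=f"F{fi}", members=members, consensus=consensus))
    return families


def main_families(families: Sequence[GCClusterFamily], min_size: int = 8) -> list[GCClusterFamily]:
    """The 'main' sub-families: those with at least ``min_size`` members."""
    return [f for f in families if f.size >= min_size]


def is_palindromic_like(c, threshold: float = 0.8) -> bool:
    """True when a cluster aligns to its own reverse complement at >= threshold identity."""
    seq = (c.sequence if hasattr(c, "sequence") else str(c)).upper()
    if len(seq) < 2:
        return False
    return pairwise_identity(seq, revcomp(seq), mode="global_alignment") >= threshold


# ---------------------------------------------------------------------------
# AT spacers and dinucleotides


def _has_gc_tetranucleotide(seq: str) -> bool:
    run = 0
    for ch in seq:
        run = run + 1 if ch in "GC" else 0
        if run >= 4:
            return True
    return False


def detect_at_spacers(
    g,
    intergenic_ivs: Sequence[tuple[int, int]] | None = None,
    clusters: Sequence[GCCluster] | None = None,
    *,
    min_len: int = 20,
    max_gc: float = 0.1,
) -> list[ATSpacer]:
    """AT spacers: long near-pure A/T intergenic fragments.

    Within each intergenic interval, GC clusters containing at least one G/C
    tetranucleotide are excised; each remaining maximal fragment longer than
    ``min_len`` bp with GC fraction below ``max_gc`` is a spacer.
    """
    from .genome_io import intergenic_intervals as _default_ivs

    seq = g.sequence
    n = len(seq)
    if intergenic_ivs is None:
        intergenic_ivs = _default_ivs(g)
    if clusters is None:
        clusters = detect_gc_clusters(seq, g.topology, genome_id=g.id)
    excised = np.zeros(n, dtype=bool)
    for c in clusters:
        if _has_gc_tetranucleotide(c.sequence):
            s, e = c.interval
            for t in range(s, e):
                excised[t % n] = True
    spacers = []
    for s, e in intergenic_ivs:
        frag_start = None
        for pos in list(range(s, e)) + [e]:
            inside = pos < e and not excised[pos % n]
            if inside and frag_start is None:
                frag_start = pos
            elif not inside and frag_start is not None:
                sub = "".join(seq[t % n] for t in range(frag_start, pos))
                if len(sub) > min_len and gc_fraction(sub) < max_gc:
                    spacers.append(ATSpacer(interval=(frag_start, pos), sequence=sub, genome_id=g.id))
                frag_start = None
    return spacers


def dinucleotide_ratio(spacers: Iterable) -> float | None:
    """(AT+TA)/(AA+TT) over overlapping dinucleotides pooled across spacers.

    Returns ``None`` when the denominator is zero (undefined ratio).
    """
    counts = {"AT": 0, "TA": 0, "AA": 0, "TT": 0}
    any_spacer = False
    for sp in spacers:
        any_spacer = True
        seq = (sp.sequence if hasattr(sp, "sequence") else str(sp)).upper()
        for i in range(len(seq) - 1):
            di = seq[i : i + 2]
            if di in counts:
                counts[di] += 1
    if not any_spacer:
        raise ValueError("need at least one spacer")
    denom = counts["AA"] + counts["TT"]
    if denom == 0:
        return None
    return (counts["AT"] + counts["TA"]) / denom


def scan_motif(seq: str, motif: str, strand: str = "+", topology: str = "linear") -> list[tuple[int, str]]:
    """All (possibly overlapping) IUPAC matches of ``motif``.

    Returns ``(start, strand)`` pairs with starts on the forward strand;
    reverse-strand hits are occurrences of the motif's reverse complement.
    Circular topology allows matches wrapping the origin.
    """
    seq = _check_sequence(seq)
    motif = motif.upper()
    bad = set(motif) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC codes in motif: {sorted(bad)}")
    if strand not in ("+", "-", "both"):
        raise ValueError(f"invalid strand {strand!r}")
    n, m = len(seq), len(motif)
    if m == 0 or n == 0:
        return []
    scan_seq = seq + seq[: m - 1] if (topology == "circular" and n >= m) else seq
    out = []
    patterns = []
    if strand in ("+", "both"):
        patterns.append((motif, "+"))
    if strand in ("-", "both"):
        patterns.append((revcomp(motif), "-"))
    for pat, st in patterns:
        allowed = [set(IUPAC[ch]) for ch in pat]
        for i in range(len(scan_seq) - m + 1):
            if i >= n:
                break
            if all(scan_seq[i + k] in allowed[k] for k in range(m)):
                out.append((i, st))
    return sorted(out)
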