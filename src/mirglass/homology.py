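"""Ortholog sequence divergence, evolutionary rate classes, genomic clusters.

Divergence between orthologous hairpins / mature arms is the p-distance of a
global affine-gap alignment: substituted columns divided by gap-free columns,
with U and T treated as the same symbol.  No multiple-hit correction is
applied -- at the divergences typical of congeneric *Drosophila* miRNAs the
raw proportion is the quantity of interest.

Clusters follow the classic genomic definition: miRNA loci on the same
chromosome and strand whose inter-locus gap is at most ``max_gap`` (10 kb)
chain into one cluster (single linkage).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .annotation_io import MicroRNALocus, OrthologPair, loci_by_id

logger = logging.getLogger(__name__)

#: (match, mismatch, gap_open, gap_extend); a gap of length L costs
#: gap_open + L * gap_extend
DEFAULT_SCORING: tuple[float, float, float, float] = (1.0, -1.0, -5.0, -2.0)

_VALID_NT = set("ACGTU")

NEG = -np.inf


@dataclass
class PairwiseAlignment:
    """A global pairwise alignment: two equal-length gapped rows and a score."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            if ca == "-" and cb == "-":
                raise ValueError("alignment contains a column gapped in both rows")


def _check_seq(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    up = seq.upper()
    bad = set(up) - _VALID_NT
    if bad:
        raise ValueError(f"{name}: non-nucleotide symbol(s) {sorted(bad)}")
    return up.replace("U", "T")


def align_pair(
    seq_a: str,
    seq_b: str,
    scoring: tuple[float, float, float, float] = DEFAULT_SCORING,
) -> PairwiseAlignment:
    """Optimal global alignment under affine gap scoring (Gotoh).

    Ties during traceback are broken deterministically: diagonal, then up
    (gap in the second sequence), then left.  The returned rows reproduce the
    input sequences when gaps are removed.
    """
    a = _check_seq(seq_a, "seq_a")
    b = _check_seq(seq_b, "seq_b")
    match, mismatch, go, ge = scoring
    n, m = len(a), len(b)

    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    sub = np.where(av[:, None] == bv[None, :], match, mismatch)  # n x m

    M = np.full((n + 1, m + 1), NEG)
    U = np.full((n + 1, m + 1), NEG)  # up: consume a, gap in b
    L = np.full((n + 1, m + 1), NEG)  # left: consume b, gap in a
    M[0, 0] = 0.0
    j_idx = np.arange(m + 1)
    # L along a row unrolls to a running max because the gap cost is linear
    # in the gap length once opened: L[i,j] = go + j*ge + max_{k<j}(best[k] - k*ge)
    for i in range(n + 1):
        if i > 0:
            prev_best = np.maximum(M[i - 1], np.maximum(U[i - 1], L[i - 1]))
            M[i, 1:] = sub[i - 1] + prev_best[:-1]
            M[i, 0] = NEG
            U[i] = np.maximum(np.maximum(M[i - 1], L[i - 1]) + go + ge, U[i - 1] + ge)
        best_mu = np.maximum(M[i], U[i])
        run = np.maximum.accumulate(best_mu - ge * j_idx)
        L[i, 1:] = go + ge * j_idx[1:] + run[:-1]
        L[i, 0] = NEG

    # traceback; preference order diagonal (M) > up (U) > left (L)
    states = (M, U, L)
    i, j = n, m
    here = [M[i, j], U[i, j], L[i, j]]
    state = int(np.argmax(here))  # argmax returns the first max -> M>U>L
    rows_a: list[str] = []
    rows_b: list[str] = []
    while i > 0 or j > 0:
        if state == 0:
            rows_a.append(a[i - 1])
            rows_b.append(b[j - 1])
            target = M[i, j] - sub[i - 1, j - 1]
            i, j = i - 1, j - 1
            cand = [M[i, j], U[i, j], L[i, j]]
        elif state == 1:
            rows_a.append(a[i - 1])
            rows_b.append("-")
            val = U[i, j]
            i = i - 1
            cand = [M[i, j] + go + ge, U[i, j] + ge, L[i, j] + go + ge]
            target = val
        else:
            rows_a.append("-")
            rows_b.append(b[j - 1])
            val = L[i, j]
            j = j - 1
            cand = [M[i, j] + go + ge, U[i, j] + go + ge, L[i, j] + ge]
            target = val
        if i == 0 and j == 0:
            break
        state = next(k for k in range(3) if cand[k] == target)

    score = float(max(M[n, m], U[n, m], L[n, m]))
    return PairwiseAlignment(
        aligned_a="".join(reversed(rows_a)),
        aligned_b="".join(reversed(rows_b)),
        score=score,
    )


def substitutions_per_site(alignment: PairwiseAlignment) -> float:
    """p-distance: substituted columns / gap-free columns, U==T, gaps excluded."""
    subs = sites = 0
    for ca, cb in zip(alignment.aligned_a.upper(), alignment.aligned_b.upper()):
        if ca == "-" or cb == "-":
            continue
        sites += 1
        if ca.replace("U", "T") != cb.replace("U", "T"):
            subs += 1
    if sites == 0:
        raise ValueError("alignment has no gap-free columns; p-distance undefined")
    return subs / sites


def annotate_divergence(
    pairs: Sequence[OrthologPair],
    loci_a: Sequence[MicroRNALocus] | Mapping[str, MicroRNALocus],
    loci_b: Sequence[MicroRNALocus] | Mapping[str, MicroRNALocus],
    scoring: tuple[float, float, float, float] = DEFAULT_SCORING,
    fields: tuple[str, ...] = ("hairpin", "mature"),
) -> list[OrthologPair]:
    """Set hairpin and/or mature substitutions-per-site on each pair.

    Mature divergence pools both arms: substitutions summed over the shared
    arm alignments divided by their summed gap-free sites.  Pairs with no
    shared annotated arm keep ``mature_div`` unset.
    """
    if not isinstance(loci_a, Mapping):
        loci_a = loci_by_id(loci_a)
    if not isinstance(loci_b, Mapping):
        loci_b = loci_by_id(loci_b)
    for pair in pairs:
        la, lb = loci_a[pair.id_a], loci_b[pair.id_b]
        if "hairpin" in fields:
            if not la.hairpin_seq or not lb.hairpin_seq:
                raise ValueError(f"missing hairpin sequence for pair {pair.id_a}/{pair.id_b}")
            pair.hairpin_div = substitutions_per_site(
                align_pair(la.hairpin_seq, lb.hairpin_seq, scoring)
            )
        if "mature" in fields:
            shared = sorted(set(la.mature_seqs) & set(lb.mature_seqs))
            subs = sites = 0
            for arm in shared:
                aln = align_pair(la.mature_seqs[arm], lb.mature_seqs[arm], scoring)
                p = substitutions_per_site(aln)
                n_sites = sum(
                    1 for x, y in zip(aln.aligned_a, aln.aligned_b) if x != "-" and y != "-"
                )
                subs += round(p * n_sites)
                sites += n_sites
            pair.mature_div = subs / sites if sites else None
    return list(pairs)


def classify_rates(pairs: Sequence[OrthologPair], divergence_field: str) -> list[OrthologPair]:
    """Tertile split into low/medium/high evolutionary-rate classes.

    Sort ascending on the chosen divergence field (stable on (value, id_a));
    the first ceil(n/3) pairs are ``low``, the last ceil(n/3) ``high``, the
    remainder ``medium``.  Pairs without the field set are left ``unset``.
    """
    if divergence_field not in ("hairpin_div", "mature_div"):
        raise ValueError(f"unknown divergence field {divergence_field!r}")
    usable = [p for p in pairs if getattr(p, divergence_field) is not None]
    if len(usable) < 3:
        raise ValueError(f"need >= 3 pairs with {divergence_field} set, have {len(usable)}")
    ordered = sorted(usable, key=lambda p: (getattr(p, divergence_field), p.id_a))
    n = len(ordered)
    k = math.ceil(n / 3)
    values = [getattr(p, divergence_field) for p in ordered]
    if values[k - 1] == values[k] or values[n - k - 1] == values[n - k]:
        logger.warning("tertile boundary falls inside a tie; split is stable-sort determined")
    for idx, pair in enumerate(ordered):
        if idx < k:
            pair.rate_class = "low"
        elif idx >= n - k:
            pair.rate_class = "high"
        else:
            pair.rate_class = "medium"
    return list(pairs)


@dataclass
class ClusterAssignment:
    """Genomic miRNA clusters: locus -> cluster id and ordered member lists."""

    locus_to_cluster: dict[str, str] = field(default_factory=dict)
    clusters: dict[str, list[str]] = field(default_factory=dict)

    def multi_member_clusters(self) -> dict[str, list[str]]:
        return {cid: members for cid, members in self.clusters.items() if len(members) > 1}


def find_clusters(loci: Sequence[MicroRNALocus], max_gap: int = 10000) -> ClusterAssignment:
    """Chain same-strand loci within ``max_gap`` bp into clusters.

    Loci are sorted by start per (chrom, strand); a locus joins the open
    cluster when the gap between its start and the cluster's rightmost end so
    far is <= ``max_gap`` (inclusive).  With half-open intervals the gap is
    exactly the number of bases between the loci, so overlap gives a gap
    <= 0 and always joins.  Equivalent to all-pairs single linkage.
    """
    groups: dict[tuple[str, str], list[MicroRNALocus]] = {}
    for locus in loci:
        groups.setdefault((locus.chrom, locus.strand), []).append(locus)

    raw_clusters: list[list[MicroRNALocus]] = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda l: (l.hairpin_interval, l.locus_id))
        current = [members[0]]
        max_end = members[0].hairpin_interval[1]
        for locus in members[1:]:
            gap = locus.hairpin_interval[0] - max_end
            if gap <= max_gap:
                current.append(locus)
            else:
                raw_clusters.append(current)
                current = [locus]
            max_end = max(max_end, locus.hairpin_interval[1])
        raw_clusters.append(current)

    raw_clusters.sort(key=lambda c: (c[0].chrom, c[0].hairpin_interval, c[0].strand))
    assignment = ClusterAssignment()
    for idx, members in enumerate(raw_clusters, start=1):
        cid = f"cls{idx:03d}"
        assignment.clusters[cid] = [l.locus_id for l in members]
        for locus in members:
            assignment.locus_to_cluster[locus.locus_id] = cid
    return assignment
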