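"""From aligned small-RNA reads to filtered, normalized, stage-pooled matrices.

Reads are counted per mature arm with fractional weights for multi-mappers:
a 19-24 nt read aligning to k distinct hairpin loci contributes 1/k to each,
so total read mass is conserved.  Within a locus the read is attributed to the
mature arm whose interval contains the read's 5'-most aligned base (the
processing-defined, least variable end of a miRNA); reads matching no arm fall
into a per-locus "hairpin-other" bucket that is excluded from mature counts.

The downstream order is fixed: low-expression filtering and stage pooling act
on raw fractional counts, normalization to RPM (reads per million mapping to
miRNAs) comes after, replicate averaging last.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import pysam

from .annotation_io import (
    ExpressionMatrix,
    LibrarySample,
    MicroRNALocus,
    arm_row_id,
    loci_by_id,
)

logger = logging.getLogger(__name__)


@dataclass
class CountingConfig:
    """Read-counting and filtering parameters.

    min/max_read_len bound the small-RNA size range counted as mature miRNA
    (19-24 nt by default); rows whose summed raw count over all libraries is
    below ``min_total_reads`` are dropped before normalization.
    """

    min_read_len: int = 19
    max_read_len: int = 24
    min_total_reads: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.min_read_len <= self.max_read_len:
            raise ValueError("require 0 < min_read_len <= max_read_len")
        if self.min_total_reads < 0:
            raise ValueError("min_total_reads must be >= 0")


@dataclass
class CountColumn:
    """Result of counting one library: per-arm fractional counts, the
    hairpin-other bucket, and the number of retained query names."""

    counts: pd.Series  # indexed by locus-arm row id
    other: pd.Series  # per-locus mass not attributed to a mature arm
    n_retained_reads: int


def count_mirna_reads(
    sam_path: str | Path,
    loci: Sequence[MicroRNALocus],
    config: CountingConfig | None = None,
) -> CountColumn:
    """Count 19-24 nt reads per mature arm from a SAM aligned to hairpins.

    The SAM must be aligned against the hairpin reference sequences, with
    reference names equal to locus ids; a multi-mapped read appears as
    several alignment records sharing one query name and receives weight
    1/k per distinct locus hit.
    """
    config = config or CountingConfig()
    index = loci_by_id(loci)

    # query name -> {locus_id: five-prime position on the hairpin}
    hits: dict[str, dict[str, int]] = {}
    n_skipped = 0
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for ref in sam.references:
            if ref not in index:
                raise ValueError(f"SAM reference {ref!r} is not an annotated locus")
        for rec in sam:
            if rec.is_unmapped or rec.reference_name is None:
                n_skipped += 1
                continue
            rlen = rec.query_length or rec.infer_query_length() or 0
            if not config.min_read_len <= rlen <= config.max_read_len:
                n_skipped += 1
                continue
            locus_id = rec.reference_name
            five_prime = rec.reference_end - 1 if rec.is_reverse else rec.reference_start
            hits.setdefault(rec.query_name, {})[locus_id] = five_prime

    arm_rows = [rid for locus in loci for rid in locus.arm_ids()]
    counts = pd.Series(0.0, index=pd.Index(arm_rows, name="feature_id"))
    other = pd.Series(0.0, index=pd.Index([l.locus_id for l in loci], name="locus_id"))
    for qname, locus_hits in hits.items():
        weight = 1.0 / len(locus_hits)
        for locus_id, pos in locus_hits.items():
            locus = index[locus_id]
            for arm, (ms, me) in locus.mature_intervals.items():
                if ms <= pos < me:
                    counts[arm_row_id(locus_id, arm)] += weight
                    break
            else:
                other[locus_id] += weight
    if not hits:
        logger.warning("%s: no retained reads; all-zero count column", sam_path)
    logger.info(
        "%s: %d retained query names, %d records skipped (unmapped/off-length)",
        sam_path, len(hits), n_skipped,
    )
    return CountColumn(counts=counts, other=other, n_retained_reads=len(hits))


def count_libraries(
    sam_paths: Mapping[str, str | Path],
    loci: Sequence[MicroRNALocus],
    config: CountingConfig | None = None,
    species: str | None = None,
) -> ExpressionMatrix:
    """Count several libraries into one raw fractional-count matrix
    (rows = locus-arm ids, columns = library ids)."""
    columns = {
        lib: count_mirna_reads(path, loci, config).counts
        for lib, path in sam_paths.items()
    }
    data = pd.DataFrame(columns)
    return ExpressionMatrix(data=data, unit="raw_fractional_count", species=species)


def filter_low_expression(
    matrix: ExpressionMatrix, config: CountingConfig | None = None
) -> ExpressionMatrix:
    """Drop rows with fewer than ``min_total_reads`` summed over all libraries.

    "Fewer than" is strict: a row totalling exactly the threshold survives.
    Must run on raw counts (before normalization), over all libraries of the
    species.
    """
    config = config or CountingConfig()
    if matrix.unit != "raw_fractional_count":
        raise ValueError("low-expression filtering must precede normalization "
                         f"(unit is {matrix.unit!r})")
    totals = matrix.data.sum(axis=1)
    keep = totals >= config.min_total_reads
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filtered %d rows with < %d total reads", dropped, config.min_total_reads)
    return ExpressionMatrix(data=matrix.data.loc[keep].copy(), unit=matrix.unit,
                            species=matrix.species)


def normalize_rpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each column to reads per million mapping to miRNAs."""
    if matrix.unit not in ("raw_fractional_count", "rpm"):
        raise ValueError(f"cannot RPM-normalize unit {matrix.unit!r}")
    totals = matrix.data.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total library column(s): {list(zero.index)}")
    data = matrix.data * (1e6 / totals)
    return ExpressionMatrix(data=data, unit="rpm", species=matrix.species)


def average_replicates(
    matrix: ExpressionMatrix, samples: Sequence[LibrarySample]
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Average RPM columns within each replicate group.

    Returns the averaged matrix (one column per replicate group, in first-
    appearance order) and a per-row SD side table (ddof=1; NaN for singleton
    groups).  Separate-sex adult libraries sharing one group average the
    same way.
    """
    if matrix.unit != "rpm":
        raise ValueError("replicate averaging expects RPM values")
    by_lib = {s.library_id: s for s in samples}
    groups: dict[str, list[str]] = {}
    for col in matrix.data.columns:
        if col not in by_lib:
            raise ValueError(f"library {col!r} missing from sample sheet")
        sample = by_lib[col]
        groups.setdefault(sample.replicate_group, []).append(col)
    for group, cols in groups.items():
        species = {by_lib[c].species for c in cols}
        if len(species) > 1:
            raise ValueError(f"replicate group {group!r} mixes species {sorted(species)}")
    means = {g: matrix.data[cols].mean(axis=1) for g, cols in groups.items()}
    sds = {g: matrix.data[cols].std(axis=1, ddof=1) for g, cols in groups.items()}
    mean_df = pd.DataFrame(means)
    sd_df = pd.DataFrame(sds)
    # column means of per-group averages still sum to 1e6, so the unit holds
    return ExpressionMatrix(data=mean_df, unit="rpm", species=matrix.species), sd_df


def pool_stages(
    matrix: ExpressionMatrix, pooling_map: Mapping[str, Sequence[str]]
) -> ExpressionMatrix:
    """Sum raw-count columns into pooled stages (pooling precedes RPM).

    ``pooling_map`` maps a pooled label to member columns; columns not
    mentioned pass through unchanged, keeping their position of first member.
    """
    if matrix.unit != "raw_fractional_count":
        raise ValueError("stage pooling operates on raw counts, before normalization")
    assigned: dict[str, str] = {}
    for pooled, members in pooling_map.items():
        for col in members:
            if col in assigned:
                raise ValueError(f"column {col!r} assigned to pools {assigned[col]!r} "
                                 f"and {pooled!r}")
            if col not in matrix.data.columns:
                raise ValueError(f"pooling map names unknown column {col!r}")
            assigned[col] = pooled
    out_cols: dict[str, pd.Series] = {}
    done_pools: set[str] = set()
    for col in matrix.data.columns:
        if col in assigned:
            pooled = assigned[col]
            if pooled not in done_pools:
                out_cols[pooled] = matrix.data[list(pooling_map[pooled])].sum(axis=1)
                done_pools.add(pooled)
        else:
            out_cols[col] = matrix.data[col]
    return ExpressionMatrix(data=pd.DataFrame(out_cols), unit=matrix.unit,
                            species=matrix.species)


#: default pooling of D. virilis-style 2-h embryonic windows onto the coarser
#: D. melanogaster-style stage granularity (cleavage; gastrulation + germband
#: elongation; germband shortening)
DEFAULT_POOLING_MAP_B: dict[str, list[str]] = {
    "e0-4": ["e0-2", "e2-4"],
    "e4-10": ["e4-6", "e6-8", "e8-10"],
    "e10-16": ["e10-12", "e12-14", "e14-16"],
}


def collapse_arms(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Sum the mature-arm rows of each locus into one locus-level row.

    Row ids must be ``<locus>-5p`` / ``<locus>-3p``; used for per-locus
    temporal profiles where the ortholog table is hairpin-level.
    """
    locus_ids = [rid.rsplit("-", 1)[0] for rid in matrix.data.index]
    data = matrix.data.groupby(pd.Index(locus_ids, name="feature_id"), sort=False).sum()
    return ExpressionMatrix(data=data, unit=matrix.unit, species=matrix.species)
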