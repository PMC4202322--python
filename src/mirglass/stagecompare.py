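"""All-versus-all stage similarity within and between species.

Stage-wise expression vectors (RPM over ortholog-matched miRNAs) are compared
with Spearman's rank correlation -- robust to the non-normality and
sequencing-bias outliers typical of small-RNA counts -- or, as an alternative
metric, the Euclidean distance of per-gene z-scored profiles.  Within-species
matrices are hierarchically clustered (average linkage on 1 - rho) and the
cross-species matrix is summarised along the homologous-stage diagonal into an
hourglass profile: if mid-embryonic stages are the most conserved, the
diagonal peaks in the middle and the hourglass score is positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import ExpressionMatrix

logger = logging.getLogger(__name__)

#: default homologous stage pairs (species A granularity vs pooled species B),
#: ordered by developmental time
DEFAULT_STAGE_MAP: list[tuple[str, str]] = [
    ("e0-1", "e0-4"),
    ("e2-6", "e4-10"),
    ("e6-10", "e10-16"),
    ("e12-24", "e16-30"),
    ("larva", "larva"),
    ("adult", "adult"),
]


@dataclass
class StageCorrelationResult:
    """Stage x stage similarity matrix with optional replicate SD and
    dendrogram leaf orders.  ``values`` holds rho for metric ``spearman``
    and distances for ``euclidean_z``."""

    values: pd.DataFrame
    metric: str
    species_a: str | None = None
    species_b: str | None = None
    replicate_sd: pd.DataFrame | None = None
    row_order: list[str] | None = None
    col_order: list[str] | None = None

    @property
    def row_stages(self) -> list[str]:
        return list(self.values.index)

    @property
    def col_stages(self) -> list[str]:
        return list(self.values.columns)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman's rho: Pearson correlation of midranks (average ranks on ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman's rho undefined")
    return float(stats.spearmanr(x, y).statistic)


def pearson_of_ranks(x, y) -> float:
    """Definitional route: rank with midranks, then Pearson (oracle for tests)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def _matched_rows(
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    ortholog_map: Mapping[str, str] | None,
) -> tuple[list[str], list[str]]:
    if ortholog_map is None:
        shared = [r for r in matrix_a.row_ids if r in set(matrix_b.row_ids)]
        return shared, shared
    rows_a, rows_b = [], []
    b_rows = set(matrix_b.row_ids)
    for ra in matrix_a.row_ids:
        rb = ortholog_map.get(ra)
        if rb is not None and rb in b_rows:
            rows_a.append(ra)
            rows_b.append(rb)
    return rows_a, rows_b


def correlation_matrix(
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    ortholog_map: Mapping[str, str] | None = None,
    metric: str = "spearman",
) -> StageCorrelationResult:
    """All-versus-all stage similarity between two RPM matrices.

    Rows are matched via ``ortholog_map`` (identity on shared row ids when
    ``None``, the within-species case).  ``spearman`` stores rho per stage
    pair; ``euclidean_z`` z-scores each gene across its own species' stages
    first (zero-variance genes dropped from both sides) and stores distances.
    """
    if matrix_a.unit != "rpm" or matrix_b.unit != "rpm":
        raise ValueError("correlation_matrix expects RPM matrices")
    if metric not in ("spearman", "euclidean_z"):
        raise ValueError(f"unknown metric {metric!r}")
    rows_a, rows_b = _matched_rows(matrix_a, matrix_b, ortholog_map)
    if len(rows_a) < 3:
        raise ValueError(f"only {len(rows_a)} shared rows; need >= 3")
    A = matrix_a.data.loc[rows_a]
    B = matrix_b.data.loc[rows_b]

    if metric == "spearman":
        ranks_a = A.rank(axis=0)
        ranks_b = B.rank(axis=0)
        cells = np.empty((A.shape[1], B.shape[1]))
        for i, ca in enumerate(ranks_a.columns):
            for j, cb in enumerate(ranks_b.columns):
                cells[i, j] = np.corrcoef(ranks_a[ca], ranks_b[cb])[0, 1]
        values = pd.DataFrame(cells, index=A.columns, columns=B.columns)
    else:
        za = _zscore_rows(A)
        zb = _zscore_rows(B)
        keep_a = za.index[~za.isna().any(axis=1)]
        keep_map = dict(zip(rows_a, rows_b))
        keep_pairs = [(ra, keep_map[ra]) for ra in keep_a
                      if not zb.loc[keep_map[ra]].isna().any()]
        if len(keep_pairs) < len(rows_a):
            logger.info("euclidean_z: dropped %d zero-variance rows",
                        len(rows_a) - len(keep_pairs))
        za = za.loc[[p[0] for p in keep_pairs]].to_numpy()
        zb = zb.loc[[p[1] for p in keep_pairs]].to_numpy()
        diff = za[:, :, None] - zb[:, None, :]
        values = pd.DataFrame(np.sqrt((diff ** 2).sum(axis=0)),
                              index=A.columns, columns=B.columns)

    return StageCorrelationResult(
        values=values, metric=metric,
        species_a=matrix_a.species, species_b=matrix_b.species,
    )


def _zscore_rows(df: pd.DataFrame) -> pd.DataFrame:
    mu = df.mean(axis=1)
    sd = df.std(axis=1, ddof=0)
    z = df.sub(mu, axis=0).div(sd, axis=0)
    return z


def zscore_matrix(matrix: ExpressionMatrix, drop_constant: bool = True) -> ExpressionMatrix:
    """Per-gene z-scores across stages (the heatmap transform for ortholog
    profile displays)."""
    z = _zscore_rows(matrix.data)
    if drop_constant:
        z = z.dropna(axis=0, how="any")
    return ExpressionMatrix(data=z, unit="z", species=matrix.species)


def replicate_spread(
    matrices_per_replicate: Sequence[ExpressionMatrix],
    matrix_b: ExpressionMatrix,
    ortholog_map: Mapping[str, str] | None = None,
    metric: str = "spearman",
) -> StageCorrelationResult:
    """Mean and SD of stage-pair coefficients across replicate matrices.

    Each replicate matrix is compared against ``matrix_b``; per cell the mean
    coefficient and its SD over replicates (ddof=1) are reported.  With a
    single replicate the SD is left unset.
    """
    if not matrices_per_replicate:
        raise ValueError("need at least one replicate matrix")
    results = [
        correlation_matrix(m, matrix_b, ortholog_map, metric)
        for m in matrices_per_replicate
    ]
    stack = np.stack([r.values.to_numpy() for r in results])
    mean = pd.DataFrame(stack.mean(axis=0), index=results[0].values.index,
                        columns=results[0].values.columns)
    if len(results) < 2:
        logger.warning("single replicate: SD of coefficients unset")
        sd = None
    else:
        sd = pd.DataFrame(stack.std(axis=0, ddof=1), index=mean.index, columns=mean.columns)
    return StageCorrelationResult(
        values=mean, metric=metric, replicate_sd=sd,
        species_a=results[0].species_a, species_b=results[0].species_b,
    )


def _average_linkage_order(D: np.ndarray, labels: list[str]) -> list[str]:
    """Deterministic UPGMA leaf order: scan-order tie-breaking, merged
    cluster replaces the left partner."""
    clusters: list[list[int]] = [[i] for i in range(len(labels))]
    dmat: list[list[float]] = [list(map(float, row)) for row in D]
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if best is None or dmat[i][j] < best[0]:
                    best = (dmat[i][j], i, j)
        _, i, j = best
        ni, nj = len(clusters[i]), len(clusters[j])
        merged_row = [
            (ni * dmat[i][k] + nj * dmat[j][k]) / (ni + nj)
            for k in range(len(clusters))
        ]
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
        del merged_row[j]
        del dmat[j]
        for row in dmat:
            del row[j]
        for k in range(len(clusters)):
            dmat[i][k] = dmat[k][i] = merged_row[k]
        dmat[i][i] = 0.0
    return [labels[i] for i in clusters[0]]


def hcluster(result: StageCorrelationResult) -> StageCorrelationResult:
    """Order stages by average-linkage hierarchical clustering.

    Distances are 1 - rho for the Spearman metric and the stored distances
    for ``euclidean_z``.  Sets ``row_order``/``col_order`` to the dendrogram
    leaf order (deterministic: ties resolved in input scan order).
    """
    values = result.values
    if values.shape[0] != values.shape[1] or not np.allclose(
        values.to_numpy(), values.to_numpy().T, atol=1e-12
    ):
        raise ValueError("hierarchical clustering requires a symmetric within-species matrix")
    if result.metric == "spearman":
        D = 1.0 - values.to_numpy()
    else:
        D = values.to_numpy().copy()
    np.fill_diagonal(D, 0.0)
    order = _average_linkage_order(D, list(values.index))
    result.row_order = order
    result.col_order = list(order)
    return result


@dataclass
class HourglassProfile:
    """Cross-species similarity along the homologous-stage diagonal.

    ``score`` = mean similarity over the designated mid pairs minus the mean
    over the first and last pair; positive is hourglass-consistent.
    """

    stage_pairs: list[tuple[str, str]]
    diagonal: list[float]
    argmax_index: int
    argmax_pair: tuple[str, str]
    mid_indices: list[int]
    score: float
    best_partner_for_a: dict[str, str] = field(default_factory=dict)
    best_partner_for_b: dict[str, str] = field(default_factory=dict)


def hourglass_profile(
    cross_species_result: StageCorrelationResult,
    homologous_pairs: Sequence[tuple[str, str]],
    mid_indices: Sequence[int] | None = None,
) -> HourglassProfile:
    """Extract the homologous-stage diagonal and score its hourglass shape.

    ``homologous_pairs`` are (stage_a, stage_b) in developmental-time order.
    The default mid window is the middle third of the pairs
    (indices floor(n/3) .. n-1-floor(n/3)); terminals are the first and last
    pair.  For the ``euclidean_z`` metric similarities are negated distances.
    """
    pairs = list(homologous_pairs)
    n = len(pairs)
    if n < 3:
        raise ValueError("need >= 3 homologous stage pairs")
    values = cross_species_result.values
    sim = values if cross_species_result.metric == "spearman" else -values
    diagonal = [float(sim.loc[sa, sb]) for sa, sb in pairs]
    if mid_indices is None:
        lo = n // 3
        mid_indices = list(range(lo, n - lo))
    else:
        mid_indices = list(mid_indices)
        if not all(0 <= i < n for i in mid_indices):
            raise ValueError("mid_indices out of range")
    argmax_index = int(np.argmax(diagonal))  # first max on ties
    score = float(np.mean([diagonal[i] for i in mid_indices])
                  - np.mean([diagonal[0], diagonal[-1]]))
    best_a = {sa: str(sim.loc[sa].idxmax()) for sa in sim.index}
    best_b = {sb: str(sim[sb].idxmax()) for sb in sim.columns}
    return HourglassProfile(
        stage_pairs=pairs,
        diagonal=diagonal,
        argmax_index=argmax_index,
        argmax_pair=pairs[argmax_index],
        mid_indices=mid_indices,
        score=score,
        best_partner_for_a=best_a,
        best_partner_for_b=best_b,
    )
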