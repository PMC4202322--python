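"""Per-ortholog temporal-profile conservation and its controls.

For every 1-to-1 ortholog pair, the RPM time course over the comparable
(pooled) stages is correlated between species with Pearson's r.  Two
references frame those values: genomically clustered miRNAs within one
species (expected to be co-transcribed, a positive control) and random
cross-species miRNA pairs (a negative control).  Group differences are tested
with the two-sided Wilcoxon rank-sum test, and the relationship between
sequence divergence and temporal conservation with Pearson correlation.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import ExpressionMatrix, OrthologPair
from .homology import ClusterAssignment

logger = logging.getLogger(__name__)

PAIR_KINDS = ("ortholog", "cluster_within_a", "cluster_within_b", "random_cross")


@dataclass
class ProfileCorrelationRecord:
    """Pearson r between the temporal profiles of one pair of miRNAs."""

    pair_kind: str
    id_1: str
    id_2: str
    r: float
    n_stages: int

    def __post_init__(self) -> None:
        if self.pair_kind not in PAIR_KINDS:
            raise ValueError(f"unknown pair_kind {self.pair_kind!r}")
        if self.n_stages < 3:
            raise ValueError("profile correlations need >= 3 stages")
        if not math.isfinite(self.r):
            raise ValueError("r must be finite")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Pearson's r undefined")
    return float(stats.pearsonr(x, y).statistic)


def _check_stage_map(stage_map: Sequence[tuple[str, str]]) -> None:
    sa = [p[0] for p in stage_map]
    sb = [p[1] for p in stage_map]
    if len(set(sa)) != len(sa) or len(set(sb)) != len(sb):
        raise ValueError("stage_map must be 1-to-1 (no stage repeated)")


def ortholog_profile_correlations(
    matrix_a_staged: ExpressionMatrix,
    matrix_b_staged: ExpressionMatrix,
    pairs: Sequence[OrthologPair],
    stage_map: Sequence[tuple[str, str]],
) -> list[ProfileCorrelationRecord]:
    """Temporal Pearson r for each ortholog pair over homologous stages.

    Matrices are locus-level staged RPM (see ``quantify.collapse_arms``);
    ``stage_map`` aligns species-A stage labels 1-to-1 with species-B labels.
    Pairs with a constant profile on either side are skipped with a log entry.
    """
    _check_stage_map(stage_map)
    stages_a = [p[0] for p in stage_map]
    stages_b = [p[1] for p in stage_map]
    records: list[ProfileCorrelationRecord] = []
    n_skipped = 0
    for pair in pairs:
        if pair.id_a not in matrix_a_staged.data.index:
            continue
        if pair.id_b not in matrix_b_staged.data.index:
            continue
        x = matrix_a_staged.data.loc[pair.id_a, stages_a].to_numpy(dtype=float)
        y = matrix_b_staged.data.loc[pair.id_b, stages_b].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            n_skipped += 1
            continue
        records.append(
            ProfileCorrelationRecord(
                pair_kind="ortholog", id_1=pair.id_a, id_2=pair.id_b,
                r=pearson_r(x, y), n_stages=len(stage_map),
            )
        )
    if n_skipped:
        logger.info("skipped %d ortholog pairs with constant profiles", n_skipped)
    return records


def cluster_profile_correlations(
    staged_matrix: ExpressionMatrix,
    clusters: ClusterAssignment,
    pair_kind: str = "cluster_within_a",
) -> list[ProfileCorrelationRecord]:
    """Pearson r for every unordered within-cluster pair of distinct miRNAs."""
    records: list[ProfileCorrelationRecord] = []
    present = set(staged_matrix.data.index)
    n_stages = staged_matrix.data.shape[1]
    for members in clusters.multi_member_clusters().values():
        usable = [m for m in members if m in present]
        for id_1, id_2 in itertools.combinations(usable, 2):
            x = staged_matrix.data.loc[id_1].to_numpy(dtype=float)
            y = staged_matrix.data.loc[id_2].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            records.append(
                ProfileCorrelationRecord(
                    pair_kind=pair_kind, id_1=id_1, id_2=id_2,
                    r=pearson_r(x, y), n_stages=n_stages,
                )
            )
    return records


def random_pair_null(
    matrix_a_staged: ExpressionMatrix,
    matrix_b_staged: ExpressionMatrix,
    pairs: Sequence[OrthologPair],
    stage_map: Sequence[tuple[str, str]],
    n_draws: int,
    seed: int,
) -> list[ProfileCorrelationRecord]:
    """Negative control: r for random non-orthologous cross-species pairs.

    Draws ``n_draws`` (id_a, id_b) combinations uniformly without replacement
    from the non-ortholog cross product; deterministic given ``seed``.
    Constant-profile draws are skipped, so fewer records may return.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    _check_stage_map(stage_map)
    stages_a = [p[0] for p in stage_map]
    stages_b = [p[1] for p in stage_map]
    ortho = {(p.id_a, p.id_b) for p in pairs}
    ids_a = list(matrix_a_staged.data.index)
    ids_b = list(matrix_b_staged.data.index)
    combos = [(ia, ib) for ia in ids_a for ib in ids_b if (ia, ib) not in ortho]
    if n_draws > len(combos):
        raise ValueError(
            f"n_draws={n_draws} exceeds {len(combos)} available non-ortholog combinations"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(combos), size=n_draws, replace=False)
    records: list[ProfileCorrelationRecord] = []
    for idx in chosen:
        id_1, id_2 = combos[int(idx)]
        x = matrix_a_staged.data.loc[id_1, stages_a].to_numpy(dtype=float)
        y = matrix_b_staged.data.loc[id_2, stages_b].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        records.append(
            ProfileCorrelationRecord(
                pair_kind="random_cross", id_1=id_1, id_2=id_2,
                r=pearson_r(x, y), n_stages=len(stage_map),
            )
        )
    return records


def compare_groups(
    records_x: Sequence[ProfileCorrelationRecord],
    records_y: Sequence[ProfileCorrelationRecord],
) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of two r distributions.

    ``statistic`` is the rank sum W of the first group under midranks;
    ``p`` is the two-sided normal-approximation p-value.
    """
    if len(records_x) < 3 or len(records_y) < 3:
        raise ValueError("each group needs >= 3 records")
    rx = np.array([rec.r for rec in records_x])
    ry = np.array([rec.r for rec in records_y])
    ranks = stats.rankdata(np.concatenate([rx, ry]))
    w = float(ranks[: len(rx)].sum())
    p = float(stats.ranksums(rx, ry).pvalue)
    return {
        "statistic": w,
        "p": p,
        "n_x": len(rx),
        "n_y": len(ry),
        "median_x": float(np.median(rx)),
        "median_y": float(np.median(ry)),
        "mean_x": float(np.mean(rx)),
        "mean_y": float(np.mean(ry)),
    }


def rate_conservation_association(
    ortholog_records: Sequence[ProfileCorrelationRecord],
    pairs: Sequence[OrthologPair],
    divergence_field: str = "hairpin_div",
) -> dict:
    """Pearson correlation between sequence divergence and temporal r.

    Returns the correlation, its two-sided t-based p-value, and the temporal
    r values split by evolutionary rate class (low/medium/high).
    """
    if divergence_field not in ("hairpin_div", "mature_div"):
        raise ValueError(f"unknown divergence field {divergence_field!r}")
    by_id = {p.id_a: p for p in pairs}
    div, temp, classes = [], [], []
    for rec in ortholog_records:
        pair = by_id.get(rec.id_1)
        if pair is None:
            continue
        d = getattr(pair, divergence_field)
        if d is None:
            continue
        div.append(d)
        temp.append(rec.r)
        classes.append(pair.rate_class)
    if len(div) < 5:
        raise ValueError(f"need >= 5 pairs with both temporal r and {divergence_field}")
    div_arr = np.asarray(div)
    if np.ptp(div_arr) == 0:
        raise ValueError("constant divergence vector: association undefined")
    res = stats.pearsonr(div_arr, np.asarray(temp))
    by_class: dict[str, list[float]] = {}
    for cls, r in zip(classes, temp):
        by_class.setdefault(cls, []).append(r)
    return {
        "r": float(res.statistic),
        "p": float(res.pvalue),
        "n": len(div),
        "by_class": by_class,
    }


def records_to_frame(records: Sequence[ProfileCorrelationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"pair_kind": r.pair_kind, "id_1": r.id_1, "id_2": r.id_2,
             "r": r.r, "n_stages": r.n_stages}
            for r in records
        ],
        columns=["pair_kind", "id_1", "id_2", "r", "n_stages"],
    )
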