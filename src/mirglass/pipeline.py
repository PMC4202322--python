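"""End-to-end orchestration: config in, results bundle out.

The stage order is fixed by the method: count -> filter (< 10 total reads)
-> pool (raw counts) -> normalize (RPM) -> average replicates -> stage
correlation matrices -> ortholog/cluster/null profile correlations -> rate
classes and association -> hourglass profile.  ``analyze_counts`` runs the
analysis on in-memory objects; ``run_pipeline`` wraps it with config/file
handling.  Output is written only after every stage succeeded, so an aborted
run leaves no partial bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from . import annotation_io as aio
from . import homology
from . import ortho_profiles as prof
from . import quantify
from . import stagecompare

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineResult:
    """Everything the pipeline computes, before any file is written."""

    within_a: stagecompare.StageCorrelationResult | None = None
    within_b: stagecompare.StageCorrelationResult | None = None
    cross: stagecompare.StageCorrelationResult | None = None
    pooled_cross: stagecompare.StageCorrelationResult | None = None
    staged_a: aio.ExpressionMatrix | None = None
    pooled_rpm_b: aio.ExpressionMatrix | None = None
    zscaled_orthologs: pd.DataFrame | None = None
    profile_records: list[prof.ProfileCorrelationRecord] = field(default_factory=list)
    ortholog_records: list[prof.ProfileCorrelationRecord] = field(default_factory=list)
    group_tests: dict[str, dict] = field(default_factory=dict)
    pairs: list[aio.OrthologPair] = field(default_factory=list)
    rate_association: dict[str, dict] = field(default_factory=dict)
    hourglass: stagecompare.HourglassProfile | None = None
    run_log: dict[str, Any] = field(default_factory=dict)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        wrapper.__name__ = fn.__name__
        return wrapper
    return deco


def _staged_rpm(matrix, samples, species):
    """filter -> normalize -> average replicates; columns = stage labels."""
    rpm = quantify.normalize_rpm(matrix)
    averaged, _ = quantify.average_replicates(
        rpm, [s for s in samples if s.species == species])
    return averaged


@_stage("stagecompare.within_species")
def _within(raw, samples, species):
    staged = _staged_rpm(raw, samples, species)
    result = stagecompare.correlation_matrix(staged, staged, None, "spearman")
    return stagecompare.hcluster(result)


@_stage("stagecompare.cross_species")
def _cross(raw_a, raw_b, samples, arm_map, species_a, species_b):
    staged_a = _staged_rpm(raw_a, samples, species_a)
    staged_b = _staged_rpm(raw_b, samples, species_b)
    cross = stagecompare.correlation_matrix(staged_a, staged_b, arm_map, "spearman")

    # replicate spread needs every species-A stage group at one common
    # replicate count >= 2; otherwise the SD stays unset
    a_samples = [s for s in samples if s.species == species_a]
    groups: dict[str, list[str]] = {}
    for s in a_samples:
        groups.setdefault(s.replicate_group, []).append(s.library_id)
    sizes = {len(v) for v in groups.values()}
    if len(sizes) == 1 and sizes != {1}:
        n_rep = sizes.pop()
        rpm_a = quantify.normalize_rpm(raw_a)
        rep_matrices = []
        for r in range(n_rep):
            data = rpm_a.data[[groups[g][r] for g in groups]].copy()
            data.columns = list(groups)
            rep_matrices.append(aio.ExpressionMatrix(
                data=data, unit="rpm", species=species_a))
        spread = stagecompare.replicate_spread(rep_matrices, staged_b, arm_map)
        cross.replicate_sd = spread.replicate_sd
    else:
        logger.warning("unequal replicate counts; cross-species SD unset")
    return cross, staged_a, staged_b


@_stage("stagecompare.pooled")
def _pooled(raw_b, samples, species_b, staged_a, arm_map, pooling_map):
    b_samples = [s for s in samples if s.species == species_b]
    lib_to_stage = {s.library_id: s.stage_label for s in b_samples}
    data_b = raw_b.data.rename(columns=lib_to_stage)
    raw_b_staged = aio.ExpressionMatrix(data=data_b, unit="raw_fractional_count",
                                        species=species_b)
    pooled_raw_b = quantify.pool_stages(raw_b_staged, pooling_map)
    pooled_rpm_b = quantify.normalize_rpm(pooled_raw_b)
    pooled_cross = stagecompare.correlation_matrix(staged_a, pooled_rpm_b, arm_map,
                                                   "spearman")
    return pooled_cross, pooled_rpm_b


@_stage("stagecompare.zscaled")
def _ztable(staged_a, pooled_rpm_b, pairs, stage_map):
    za = stagecompare.zscore_matrix(quantify.collapse_arms(staged_a)).data
    zb = stagecompare.zscore_matrix(quantify.collapse_arms(pooled_rpm_b)).data
    rows = []
    for pair in pairs:
        if pair.id_a not in za.index or pair.id_b not in zb.index:
            continue
        row = {"id_a": pair.id_a, "id_b": pair.id_b}
        row.update({f"a:{s}": za.loc[pair.id_a, s] for s, _ in stage_map})
        row.update({f"b:{s}": zb.loc[pair.id_b, s] for _, s in stage_map})
        rows.append(row)
    return pd.DataFrame(rows)


@_stage("ortho_profiles")
def _profiles(staged_a, pooled_rpm_b, pairs, loci_a, loci_b, stage_map,
              n_null_draws, seed):
    loc_a = quantify.collapse_arms(staged_a)
    loc_b = quantify.collapse_arms(pooled_rpm_b)
    records = prof.ortholog_profile_correlations(loc_a, loc_b, pairs, stage_map)
    rec_ca = prof.cluster_profile_correlations(
        loc_a, homology.find_clusters(loci_a), "cluster_within_a")
    rec_cb = prof.cluster_profile_correlations(
        loc_b, homology.find_clusters(loci_b), "cluster_within_b")
    n_draws = n_null_draws if n_null_draws is not None else max(len(records), 1)
    rec_null = prof.random_pair_null(loc_a, loc_b, pairs, stage_map, n_draws, seed)
    tests = {}
    for name, other in (("ortholog_vs_random", rec_null),
                        ("ortholog_vs_cluster_a", rec_ca),
                        ("ortholog_vs_cluster_b", rec_cb)):
        if len(other) >= 3 and len(records) >= 3:
            tests[name] = prof.compare_groups(records, other)
    return records + rec_ca + rec_cb + rec_null, records, tests


@_stage("homology")
def _divergence(pairs, loci_a, loci_b, ortholog_records, fields):
    loci_a = aio.loci_by_id(loci_a)
    loci_b = aio.loci_by_id(loci_b)
    homology.annotate_divergence(pairs, loci_a, loci_b, fields=fields)
    association = {}
    for fld in fields:
        column = f"{fld}_div"
        homology.classify_rates(pairs, column)
        association[column] = prof.rate_conservation_association(
            ortholog_records, pairs, column)
    return association


@_stage("hourglass")
def _hourglass(pooled_cross, stage_map, mid_indices):
    return stagecompare.hourglass_profile(pooled_cross, stage_map, mid_indices)


def analyze_counts(
    raw_a: aio.ExpressionMatrix,
    raw_b: aio.ExpressionMatrix,
    samples: Sequence[aio.LibrarySample],
    loci_a: Sequence[aio.MicroRNALocus],
    loci_b: Sequence[aio.MicroRNALocus],
    pairs: Sequence[aio.OrthologPair],
    *,
    counting: quantify.CountingConfig | None = None,
    pooling_map_b: Mapping[str, Sequence[str]] | None = None,
    stage_map: Sequence[tuple[str, str]] | None = None,
    mid_indices: Sequence[int] | None = None,
    n_null_draws: int | None = None,
    divergence_fields: tuple[str, ...] = ("hairpin", "mature"),
    seed: int = 0,
) -> PipelineResult:
    """Run the full analysis on in-memory raw count matrices.

    ``raw_a``/``raw_b`` are unfiltered raw fractional counts with library
    columns; ``stage_map`` pairs species-A stage labels with (pooled)
    species-B labels in developmental order.  Pass an empty
    ``divergence_fields`` to skip sequence alignment and rate analysis.
    """
    counting = counting or quantify.CountingConfig()
    pooling_map_b = pooling_map_b if pooling_map_b is not None \
        else quantify.DEFAULT_POOLING_MAP_B
    stage_map = [tuple(p) for p in (stage_map or stagecompare.DEFAULT_STAGE_MAP)]
    species_a, species_b = raw_a.species, raw_b.species
    pairs = list(pairs)
    arm_map = aio.expand_pairs_to_arms(pairs, loci_a, loci_b)

    result = PipelineResult(pairs=pairs)
    raw_a = quantify.filter_low_expression(raw_a, counting)
    raw_b = quantify.filter_low_expression(raw_b, counting)
    result.within_a = _within(raw_a, samples, species_a)
    result.within_b = _within(raw_b, samples, species_b)
    result.cross, staged_a, _ = _cross(raw_a, raw_b, samples, arm_map,
                                       species_a, species_b)
    result.staged_a = staged_a
    result.pooled_cross, pooled_rpm_b = _pooled(
        raw_b, samples, species_b, staged_a, arm_map, pooling_map_b)
    result.pooled_rpm_b = pooled_rpm_b
    result.profile_records, result.ortholog_records, result.group_tests = _profiles(
        staged_a, pooled_rpm_b, pairs, loci_a, loci_b, stage_map, n_null_draws, seed)
    result.zscaled_orthologs = _ztable(staged_a, pooled_rpm_b, pairs, stage_map)
    if divergence_fields:
        result.rate_association = _divergence(
            pairs, loci_a, loci_b, result.ortholog_records, divergence_fields)
    result.hourglass = _hourglass(result.pooled_cross, stage_map, mid_indices)
    return result


def _load_config(config: str | Path | Mapping) -> dict:
    if isinstance(config, Mapping):
        return dict(config)
    with open(config) as fh:
        return yaml.safe_load(fh)


@_stage("load")
def _load_inputs(cfg: dict):
    paths = cfg["paths"]
    loci_a = aio.load_annotations(paths["gff_a"], paths["hairpin_fasta_a"],
                                  paths["mature_fasta_a"], cfg["species_a"])
    loci_b = aio.load_annotations(paths["gff_b"], paths["hairpin_fasta_b"],
                                  paths["mature_fasta_b"], cfg["species_b"])
    samples = aio.load_samples(paths["samples"])
    return loci_a, loci_b, samples


@_stage("quantify")
def _load_counts(cfg: dict, loci_a, loci_b, counting):
    paths = cfg["paths"]
    out = {}
    for species, loci, key in ((cfg["species_a"], loci_a, "a"),
                               (cfg["species_b"], loci_b, "b")):
        if f"counts_{key}" in paths:
            matrix = aio.load_count_matrix(paths[f"counts_{key}"])
            matrix.species = species
        else:
            sams = {k.split(":", 1)[1]: p for k, p in paths.items()
                    if k.startswith("sam:") and k.split(":", 1)[1].startswith(species)}
            if not sams:
                raise ValueError(f"no counts table or SAM paths for species {species}")
            matrix = quantify.count_libraries(sams, loci, counting, species=species)
        out[species] = matrix
    return out[cfg["species_a"]], out[cfg["species_b"]]


@_stage("stagecompare.cross_species")
def _require_orthologs(cfg, loci_a, loci_b):
    if "orthologs" not in cfg["paths"]:
        raise ValueError("config names no ortholog table (required for the "
                         "cross-species comparison)")
    return aio.load_orthologs(cfg["paths"]["orthologs"], loci_a, loci_b)


def run_pipeline(config: str | Path | Mapping, outdir: str | Path | None = None
                 ) -> PipelineResult:
    """Run the whole analysis from a single config (YAML path or mapping).

    Deterministic given inputs and the config's ``seed``.  When ``outdir``
    is given, the results bundle is written there after all stages succeed.
    """
    cfg = _load_config(config)
    seed = int(cfg.get("seed", 0))
    counting = quantify.CountingConfig(**cfg.get("counting", {}))
    loci_a, loci_b, samples = _load_inputs(cfg)
    raw_a, raw_b = _load_counts(cfg, loci_a, loci_b, counting)
    pairs = _require_orthologs(cfg, loci_a, loci_b)
    result = analyze_counts(
        raw_a, raw_b, samples, loci_a, loci_b, pairs,
        counting=counting,
        pooling_map_b=cfg.get("pooling_map_b"),
        stage_map=cfg.get("stage_map"),
        mid_indices=cfg.get("mid_indices"),
        n_null_draws=cfg.get("n_null_draws"),
        seed=seed,
    )
    canonical = yaml.safe_dump(cfg, sort_keys=True)
    result.run_log = {
        "mirglass_version": __version__,
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": seed,
        "n_ortholog_pairs": len(result.pairs),
        "n_profile_records": len(result.profile_records),
    }
    if outdir is not None:
        write_bundle(result, outdir)
    return result


def _write_matrix(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", lineterminator="\n")


def write_bundle(result: PipelineResult, outdir: str | Path) -> None:
    """Write the results bundle: correlation matrices, z-scaled ortholog
    table, profile-correlation records, divergence table, JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, res in (("within_a", result.within_a), ("within_b", result.within_b)):
        _write_matrix(res.values, outdir / f"{name}_spearman.tsv")
        (outdir / f"{name}_leaf_order.json").write_text(
            json.dumps(res.row_order, indent=1) + "\n")
    _write_matrix(result.cross.values, outdir / "cross_spearman.tsv")
    if result.cross.replicate_sd is not None:
        _write_matrix(result.cross.replicate_sd, outdir / "cross_spearman_sd.tsv")
    _write_matrix(result.pooled_cross.values, outdir / "pooled_cross_spearman.tsv")
    result.zscaled_orthologs.to_csv(outdir / "zscaled_orthologs.tsv", sep="\t",
                                    index=False, float_format="%.10g",
                                    lineterminator="\n")
    prof.records_to_frame(result.profile_records).to_csv(
        outdir / "profile_correlations.tsv", sep="\t", index=False,
        float_format="%.10g", lineterminator="\n")
    aio.write_orthologs(result.pairs, outdir / "ortholog_divergence.tsv",
                        with_divergence=True)
    hourglass = result.hourglass
    summary = {
        "group_tests": result.group_tests,
        "rate_association": result.rate_association,
        "hourglass": {
            "stage_pairs": hourglass.stage_pairs,
            "diagonal": hourglass.diagonal,
            "argmax_index": hourglass.argmax_index,
            "argmax_pair": hourglass.argmax_pair,
            "mid_indices": hourglass.mid_indices,
            "score": hourglass.score,
            "best_partner_for_a": hourglass.best_partner_for_a,
            "best_partner_for_b": hourglass.best_partner_for_b,
        },
        "run_log": result.run_log,
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True, default=float) + "\n")
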