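"""Synthetic two-species miRNA developmental datasets with known ground truth.

The generator emulates a two-species *Drosophila*-style study design: two
genomes sharing 1-to-1 ortholog miRNA families plus species-specific loci,
per-family sequence divergence (i.i.d. per-site substitutions at a family
rate), genomic clustering (same strand, < 10 kb gaps), smooth temporal
expression profiles on a common developmental clock with species B running
``time_scale`` (default 1.5x) slower, stage-dependent cross-species
expression divergence (a U-shaped per-stage noise SD embeds an hourglass; a
flat one embeds none), multinomial library-depth count sampling with
replicates, and optional SAM read simulation including multi-mapping
paralogs and off-length decoy reads.

Every emitted file loads back through :mod:`mirglass.annotation_io`
unchanged, and the ground truth (rates, ortholog map, clusters, stage means,
designed divergence profile) is retained so analysis results can be checked
against what was simulated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from .annotation_io import (
    ExpressionMatrix,
    LibrarySample,
    MicroRNALocus,
    OrthologPair,
    SYMBOLIC_STAGES,
    arm_row_id,
    write_annotations,
    write_count_matrix,
    write_orthologs,
    write_samples,
)

NUCLEOTIDES = np.array(list("ACGU"))

#: indices (into the default homologous stage map) of the stage pairs where
#: the default U-shaped divergence profile places the conservation peak:
#: gastrulation + germband elongation and germband shortening
DESIGNED_MID_PAIR_INDICES: tuple[int, ...] = (1, 2)


def default_stage_grid_a() -> list[tuple[str, float, float]]:
    """Species-A stages: four embryonic windows (h), larva, adult."""
    return [
        ("e0-1", 0.0, 1.0),
        ("e2-6", 2.0, 6.0),
        ("e6-10", 6.0, 10.0),
        ("e12-24", 12.0, 24.0),
        ("larva", 24.0, 120.0),
        ("adult", 120.0, 240.0),
    ]


def default_stage_grid_b() -> list[tuple[str, float, float]]:
    """Species-B stages on its own (1.5x slower) clock: eight 2-h embryonic
    windows, a late-embryo window, larva, adult."""
    grid = [(f"e{t}-{t + 2}", float(t), float(t + 2)) for t in range(0, 16, 2)]
    grid += [("e16-30", 16.0, 30.0), ("larva", 30.0, 180.0), ("adult", 180.0, 360.0)]
    return grid


def hourglass_divergence_profile() -> dict[str, float]:
    """U-shaped per-stage log-noise SD for species B: terminal stages diverge,
    gastrulation-to-germband stages are conserved."""
    return {
        "e0-2": 1.0, "e2-4": 0.9,
        "e4-6": 0.35, "e6-8": 0.3, "e8-10": 0.3, "e10-12": 0.35,
        "e12-14": 0.4, "e14-16": 0.45,
        "e16-30": 0.7, "larva": 0.9, "adult": 1.1,
    }


def flat_divergence_profile(sd: float = 0.5) -> dict[str, float]:
    """Stage-independent divergence: every species-B stage gets the same SD."""
    return {label: sd for label, _, _ in default_stage_grid_b()}


@dataclass
class SimulationConfig:
    """All knobs of the two-species simulation; defaults mirror the study
    design being emulated (118 ortholog pairs, 172/123 expressed miRNAs,
    6 + 11 stage groups, 1.5x time scaling)."""

    n_ortholog_families: int = 118
    n_specific_a: int = 54
    n_specific_b: int = 5
    n_clusters: int = 8
    cluster_size_range: tuple[int, int] = (2, 4)
    hairpin_len: int = 90
    arm_len: int = 22
    substitution_rate_range: tuple[float, float] = (0.0, 0.2)
    time_scale: float = 1.5
    species_a: str = "spcA"
    species_b: str = "spcB"
    stages_a: list[tuple[str, float, float]] = field(default_factory=default_stage_grid_a)
    stages_b: list[tuple[str, float, float]] = field(default_factory=default_stage_grid_b)
    stage_divergence_sd: dict[str, float] = field(default_factory=hourglass_divergence_profile)
    library_depth: int = 1_000_000
    replicates_a: int = 2
    replicates_b: int = 1
    multimap_fraction: float = 0.1
    decoy_fraction: float = 0.02
    cluster_noise_sd: float = 0.15
    chrom_len: int = 5_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_ortholog_families", "n_specific_a", "n_specific_b", "n_clusters",
                     "library_depth", "replicates_a", "replicates_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.substitution_rate_range
        if not 0 <= lo <= hi <= 1:
            raise ValueError("substitution_rate_range must satisfy 0 <= lo <= hi <= 1")
        if not 0 <= self.multimap_fraction <= 1 or not 0 <= self.decoy_fraction <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        if self.time_scale <= 0:
            raise ValueError("time_scale must be > 0")
        if self.hairpin_len < 2 * self.arm_len + 12:
            raise ValueError("hairpin too short for two arms and a loop")
        for grid_name in ("stages_a", "stages_b"):
            grid = getattr(self, grid_name)
            prev_end = -math.inf
            for label, start, end in grid:
                if not start < end:
                    raise ValueError(f"{grid_name}: window {label} has start >= end")
                if start < prev_end:
                    raise ValueError(f"{grid_name}: windows overlap at {label}")
                prev_end = end
        missing = {label for label, _, _ in self.stages_b} - set(self.stage_divergence_sd)
        if missing:
            raise ValueError(f"stage_divergence_sd missing stages {sorted(missing)}")
        size_lo, size_hi = self.cluster_size_range
        if not 2 <= size_lo <= size_hi:
            raise ValueError("cluster sizes must be >= 2")
        if self.n_clusters * size_hi > self.n_ortholog_families:
            raise ValueError("too many clustered families for n_ortholog_families")


@dataclass
class FamilyProfile:
    """Smooth continuous expression profile on the species-A clock (hours).

    ``maternal``: exponential decay from deposition; ``pulse``: a Gaussian
    zygotic expression window; ``constant``: flat.  A small constant baseline
    keeps every stage mean positive.
    """

    kind: str
    abundance: float
    tau: float = 0.0
    center: float = 0.0
    width: float = 1.0
    baseline_frac: float = 0.02
    #: per-stage-label multipliers for post-embryonic stages (larva/adult):
    #: tissue-composition effects shared by orthologs but independent between
    #: unrelated miRNAs
    stage_multipliers: dict[str, float] = field(default_factory=dict)

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.kind == "maternal":
            core = np.exp(-t / self.tau)
        elif self.kind == "pulse":
            core = np.exp(-0.5 * ((t - self.center) / self.width) ** 2)
        elif self.kind == "constant":
            core = np.ones_like(t)
        else:  # pragma: no cover
            raise ValueError(f"unknown profile kind {self.kind!r}")
        return self.abundance * (core + self.baseline_frac)

    def window_mean(self, start: float, end: float, label: str | None = None,
                    n_grid: int = 33) -> float:
        t = np.linspace(start, end, n_grid)
        factor = self.stage_multipliers.get(label, 1.0) if label else 1.0
        return factor * float(np.mean(self(t)))


@dataclass
class GroundTruth:
    """Everything the analysis should recover, keyed on species-A ids where
    a pair is involved."""

    ortholog_map: dict[str, str] = field(default_factory=dict)
    true_rates: dict[str, float] = field(default_factory=dict)
    clusters_a: dict[str, list[str]] = field(default_factory=dict)
    clusters_b: dict[str, list[str]] = field(default_factory=dict)
    multimap_groups_a: list[list[str]] = field(default_factory=list)
    multimap_groups_b: list[list[str]] = field(default_factory=list)
    stage_divergence_sd: dict[str, float] = field(default_factory=dict)
    designed_mid_pair_indices: list[int] = field(default_factory=list)
    stage_means_a: pd.DataFrame | None = None
    stage_means_b: pd.DataFrame | None = None

    def to_json_dict(self) -> dict:
        out = {
            "ortholog_map": self.ortholog_map,
            "true_rates": self.true_rates,
            "clusters_a": self.clusters_a,
            "clusters_b": self.clusters_b,
            "multimap_groups_a": self.multimap_groups_a,
            "multimap_groups_b": self.multimap_groups_b,
            "stage_divergence_sd": self.stage_divergence_sd,
            "designed_mid_pair_indices": self.designed_mid_pair_indices,
        }
        for name in ("stage_means_a", "stage_means_b"):
            df = getattr(self, name)
            if df is not None:
                out[name] = {
                    "index": list(df.index),
                    "columns": list(df.columns),
                    "values": [[round(v, 6) for v in row] for row in df.to_numpy().tolist()],
                }
        return out


@dataclass
class SimulatedGenomes:
    loci_a: list[MicroRNALocus]
    loci_b: list[MicroRNALocus]
    ortholog_pairs: list[OrthologPair]
    truth: GroundTruth
    profiles: dict[str, FamilyProfile] = field(default_factory=dict)  # keyed by locus id
    arm_fractions: dict[str, dict[str, float]] = field(default_factory=dict)
    cluster_scales: dict[str, float] = field(default_factory=dict)


@dataclass
class SimulatedExpression:
    samples: list[LibrarySample]
    counts_a: ExpressionMatrix
    counts_b: ExpressionMatrix


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genomes: SimulatedGenomes
    expression: SimulatedExpression


# ---------------------------------------------------------------------------
# sequence-level simulation
# ---------------------------------------------------------------------------

def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(NUCLEOTIDES, size=length))


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """i.i.d. per-site substitution: each site mutates with probability
    ``rate`` to one of the three other nucleotides (no indels)."""
    equiv = {"T": "U", "U": "T"}
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    for i in np.flatnonzero(hit):
        base = arr[i]
        excluded = {base, equiv.get(base, base)}
        choices = np.array([nt for nt in NUCLEOTIDES if nt not in excluded])
        arr[i] = rng.choice(choices)
    return "".join(arr)


def _make_locus(
    locus_id: str,
    species: str,
    chrom: str,
    strand: str,
    start: int,
    hairpin_seq: str,
    arm_len: int,
) -> MicroRNALocus:
    n = len(hairpin_seq)
    intervals = {"5p": (5, 5 + arm_len), "3p": (n - 5 - arm_len, n - 5)}
    return MicroRNALocus(
        locus_id=locus_id,
        species=species,
        chrom=chrom,
        strand=strand,
        hairpin_interval=(start, start + n),
        mature_intervals=intervals,
        hairpin_seq=hairpin_seq,
        mature_seqs={arm: hairpin_seq[s:e] for arm, (s, e) in intervals.items()},
    )


def simulate_genomes(config: SimulationConfig) -> SimulatedGenomes:
    """Simulate both annotated genomes, the ortholog truth and cluster truth.

    Ortholog species-B hairpins derive from species A by i.i.d. per-site
    substitution at a family rate drawn uniformly from
    ``substitution_rate_range`` (independently of everything else).
    Clustered families sit on one strand with gaps <= 10 kb; all other
    inter-locus gaps exceed 10 kb.  A ``multimap_fraction`` of the
    species-specific loci gets an identical-sequence paralog far away.
    """
    ss = np.random.SeedSequence([config.seed, 101])
    rng = np.random.default_rng(ss)
    n_fam = config.n_ortholog_families

    family_ids = [f"{i + 1:03d}" for i in range(n_fam)]
    ids_a = [f"{config.species_a}-mir-{f}" for f in family_ids]
    ids_b = [f"{config.species_b}-mir-{f}" for f in family_ids]
    rates = rng.uniform(*config.substitution_rate_range, size=n_fam)

    hairpins_a = [random_sequence(config.hairpin_len, rng) for _ in range(n_fam)]
    hairpins_b = [mutate_sequence(h, r, rng) for h, r in zip(hairpins_a, rates)]

    spec_a = [f"{config.species_a}-mir-s{i + 1:03d}" for i in range(config.n_specific_a)]
    spec_b = [f"{config.species_b}-mir-s{i + 1:03d}" for i in range(config.n_specific_b)]

    # cluster memberships (mirrored across species: synteny)
    order = rng.permutation(n_fam)
    cluster_members: list[list[int]] = []
    cursor = 0
    for _ in range(config.n_clusters):
        size = int(rng.integers(config.cluster_size_range[0],
                                config.cluster_size_range[1] + 1))
        cluster_members.append(list(order[cursor:cursor + size]))
        cursor += size
    singleton_fams = list(order[cursor:])

    truth = GroundTruth(
        ortholog_map=dict(zip(ids_a, ids_b)),
        true_rates=dict(zip(ids_a, rates.tolist())),
        stage_divergence_sd=dict(config.stage_divergence_sd),
        designed_mid_pair_indices=list(DESIGNED_MID_PAIR_INDICES),
    )

    def place_species(species: str, ids: list[str], hairpins: list[str],
                      specific_ids: list[str], clusters_key: str,
                      multimap_key: str) -> list[MicroRNALocus]:
        chrom = f"{species}_chr2"
        loci: list[MicroRNALocus] = []
        pos = int(rng.integers(10_000, 50_000))
        seq_of = dict(zip(ids, hairpins))
        for sid in specific_ids:
            seq_of[sid] = random_sequence(config.hairpin_len, rng)
        # multimap paralogs duplicate species-specific loci
        n_multi = int(round(config.multimap_fraction * len(specific_ids)))
        multi_parents = list(specific_ids[:n_multi])
        groups = getattr(truth, multimap_key)
        clusters = getattr(truth, clusters_key)

        units: list[list[str]] = []  # placement units: clusters then singletons
        for ci, members in enumerate(cluster_members):
            units.append([ids[m] for m in members])
        units += [[ids[m]] for m in singleton_fams]
        units += [[sid] for sid in specific_ids]
        paralog_ids = []
        for parent in multi_parents:
            pid = f"{parent}p2"
            seq_of[pid] = seq_of[parent]
            paralog_ids.append(pid)
            groups.append([parent, pid])
            units.append([pid])

        for ui, unit in enumerate(units):
            strand = "+" if rng.random() < 0.5 else "-"
            if len(unit) > 1:
                clusters[f"{species}_cls{len(clusters) + 1:03d}"] = list(unit)
            for k, lid in enumerate(unit):
                if k > 0:
                    pos += int(rng.integers(200, 9_000))  # intra-cluster gap <= 10 kb
                loci.append(_make_locus(lid, species, chrom, strand, pos,
                                        seq_of[lid], config.arm_len))
                pos += config.hairpin_len
            pos += int(rng.integers(12_000, 40_000))  # > 10 kb between units
            if pos > config.chrom_len:
                raise ValueError(
                    f"infeasible placement: {species} loci exceed chrom_len="
                    f"{config.chrom_len}"
                )
        return loci

    loci_a = place_species(config.species_a, ids_a, hairpins_a, spec_a,
                           "clusters_a", "multimap_groups_a")
    loci_b = place_species(config.species_b, ids_b, hairpins_b, spec_b,
                           "clusters_b", "multimap_groups_b")
    pairs = [OrthologPair(id_a=a, id_b=b) for a, b in zip(ids_a, ids_b)]

    genomes = SimulatedGenomes(loci_a=loci_a, loci_b=loci_b,
                               ortholog_pairs=pairs, truth=truth)
    _assign_profiles(config, genomes, np.random.default_rng(
        np.random.SeedSequence([config.seed, 202])))
    return genomes


def _draw_profile(rng: np.random.Generator) -> FamilyProfile:
    """Draw one temporal profile.

    Pulse centers are log-uniform over the whole life cycle (1-240 h on the
    species-A clock) with widths proportional to the center, so expression
    windows range from sharp early-embryonic bursts to broad larval/adult
    domains; this shape diversity is what makes random cross-species pairs
    essentially uncorrelated, as a negative control requires.
    """
    kind = rng.choice(["maternal", "pulse", "constant"], p=[0.25, 0.65, 0.10])
    abundance = float(rng.lognormal(mean=math.log(300.0), sigma=1.5))
    multipliers = {
        "larva": float(rng.lognormal(0.0, 1.0)),
        "adult": float(rng.lognormal(0.0, 1.0)),
    }
    if kind == "maternal":
        return FamilyProfile(kind=kind, abundance=abundance,
                             tau=float(rng.uniform(2.0, 6.0)),
                             stage_multipliers=multipliers)
    if kind == "pulse":
        center = float(np.exp(rng.uniform(math.log(1.0), math.log(240.0))))
        width = max(2.0, center * float(rng.uniform(0.2, 0.6)))
        return FamilyProfile(kind=kind, abundance=abundance, center=center,
                             width=width, stage_multipliers=multipliers)
    return FamilyProfile(kind=kind, abundance=abundance,
                         stage_multipliers=multipliers)


def _assign_profiles(config: SimulationConfig, genomes: SimulatedGenomes,
                     rng: np.random.Generator) -> None:
    """One profile per ortholog family (shared across species); cluster
    members share their cluster's primary-transcript profile up to a
    member-specific scale; species-specific and paralog loci get their own."""
    truth = genomes.truth
    clustered_a: dict[str, str] = {}  # locus -> cluster id (species A naming)
    for cid, members in truth.clusters_a.items():
        for m in members:
            clustered_a[m] = cid

    cluster_profiles: dict[str, FamilyProfile] = {
        cid: _draw_profile(rng) for cid in sorted(truth.clusters_a)
    }
    id_b_of = truth.ortholog_map

    for locus in genomes.loci_a:
        lid = locus.locus_id
        if lid in clustered_a:
            base = cluster_profiles[clustered_a[lid]]
            scale = float(rng.lognormal(0.0, config.cluster_noise_sd))
            prof = FamilyProfile(kind=base.kind, abundance=base.abundance * scale,
                                 tau=base.tau, center=base.center, width=base.width,
                                 stage_multipliers=dict(base.stage_multipliers))
        else:
            prof = _draw_profile(rng)
        genomes.profiles[lid] = prof
        if lid in id_b_of:  # ortholog family: species B shares the profile
            genomes.profiles[id_b_of[lid]] = prof
        frac = float(rng.uniform(0.7, 0.95))
        arms = {"5p": frac, "3p": 1.0 - frac} if rng.random() < 0.5 else \
               {"5p": 1.0 - frac, "3p": frac}
        genomes.arm_fractions[lid] = arms
        if lid in id_b_of:
            genomes.arm_fractions[id_b_of[lid]] = dict(arms)

    ids_a_set = {l.locus_id for l in genomes.loci_a}
    for locus in genomes.loci_b:
        if locus.locus_id in genomes.profiles:
            continue
        genomes.profiles[locus.locus_id] = _draw_profile(rng)
        genomes.arm_fractions[locus.locus_id] = (
            {"5p": 0.85, "3p": 0.15} if rng.random() < 0.5 else {"5p": 0.15, "3p": 0.85}
        )
    assert ids_a_set  # silence linters; species A always non-empty in practice


# ---------------------------------------------------------------------------
# expression-level simulation
# ---------------------------------------------------------------------------

def _stage_means(
    config: SimulationConfig,
    genomes: SimulatedGenomes,
    species: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """True per-arm mean expression per stage (arbitrary concentration units).

    Species B evaluates the shared profile on the rescaled clock
    (t_A = t_B / time_scale) and applies per-(family, stage) multiplicative
    log-normal divergence noise with the configured per-stage SD.
    """
    is_b = species == config.species_b
    loci = genomes.loci_b if is_b else genomes.loci_a
    grid = config.stages_b if is_b else config.stages_a
    clustered = set()
    for members in (genomes.truth.clusters_b if is_b
                    else genomes.truth.clusters_a).values():
        clustered.update(members)
    rows: dict[str, list[float]] = {}
    labels = [g[0] for g in grid]
    for locus in loci:
        prof = genomes.profiles[locus.locus_id]
        means = []
        for label, start, end in grid:
            if is_b:
                start, end = start / config.time_scale, end / config.time_scale
            means.append(prof.window_mean(start, end, label=label))
        means = np.asarray(means)
        if locus.locus_id in clustered:
            # members of one primary transcript: shared profile times small
            # per-member per-stage noise
            means = means * np.exp(
                rng.normal(0.0, config.cluster_noise_sd, size=len(means)))
        if is_b:
            sds = np.array([config.stage_divergence_sd[label] for label in labels])
            means = means * np.exp(rng.normal(0.0, 1.0, size=len(means)) * sds)
        for arm, frac in genomes.arm_fractions[locus.locus_id].items():
            if arm in locus.mature_intervals:
                rows[arm_row_id(locus.locus_id, arm)] = (means * frac).tolist()
    return pd.DataFrame.from_dict(rows, orient="index", columns=labels)


def simulate_expression(
    config: SimulationConfig, genomes: SimulatedGenomes
) -> SimulatedExpression:
    """Sample per-library integer count tables from the true stage means.

    Each library is an independent multinomial draw of ``library_depth``
    reads over the mature-arm rows, with probabilities proportional to the
    stage's true arm means; replicates are independent draws.
    """
    noise_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    means_a = _stage_means(config, genomes, config.species_a, noise_rng)
    means_b = _stage_means(config, genomes, config.species_b, noise_rng)
    genomes.truth.stage_means_a = means_a
    genomes.truth.stage_means_b = means_b

    samples: list[LibrarySample] = []
    counts: dict[str, pd.DataFrame] = {}
    for species, means, grid, n_rep in (
        (config.species_a, means_a, config.stages_a, config.replicates_a),
        (config.species_b, means_b, config.stages_b, config.replicates_b),
    ):
        lib_cols: dict[str, np.ndarray] = {}
        for si, (label, start, end) in enumerate(grid):
            mu = means[label].to_numpy()
            if mu.sum() <= 0:
                raise ValueError(f"all-zero stage mean vector for {species} {label}")
            p = mu / mu.sum()
            for rep in range(1, n_rep + 1):
                lib_id = f"{species}_{label}_r{rep}"
                lib_rng = np.random.default_rng(
                    np.random.SeedSequence([config.seed, 404, hash_label(species), si, rep])
                )
                lib_cols[lib_id] = lib_rng.multinomial(config.library_depth, p).astype(float)
                window: tuple[float, float] | str = (
                    label if label in SYMBOLIC_STAGES else (start, end)
                )
                samples.append(
                    LibrarySample(
                        library_id=lib_id, species=species, stage_label=label,
                        time_window=window, replicate_group=label,
                    )
                )
        counts[species] = pd.DataFrame(lib_cols, index=means.index)

    return SimulatedExpression(
        samples=samples,
        counts_a=ExpressionMatrix(data=counts[config.species_a],
                                  unit="raw_fractional_count", species=config.species_a),
        counts_b=ExpressionMatrix(data=counts[config.species_b],
                                  unit="raw_fractional_count", species=config.species_b),
    )


def hash_label(label: str) -> int:
    """Small deterministic hash for seeding sub-streams (python hash() is
    salted per process, so it cannot be used)."""
    h = 0
    for ch in label:
        h = (h * 31 + ord(ch)) % 1_000_003
    return h


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Genomes + expression in one call."""
    genomes = simulate_genomes(config)
    expression = simulate_expression(config, genomes)
    return SimulatedDataset(config=config, genomes=genomes, expression=expression)


# ---------------------------------------------------------------------------
# read-level simulation (SAM)
# ---------------------------------------------------------------------------

def _arm_identity_groups(loci: Sequence[MicroRNALocus]) -> dict[tuple[str, str], list[str]]:
    """Group loci whose mature arm sequence is identical (multi-mapping)."""
    by_seq: dict[tuple[str, str], list[str]] = {}
    for locus in loci:
        for arm, seq in locus.mature_seqs.items():
            by_seq.setdefault((arm, seq.upper().replace("U", "T")), []).append(locus.locus_id)
    groups: dict[tuple[str, str], list[str]] = {}
    for (arm, _), members in by_seq.items():
        for lid in members:
            groups[(lid, arm)] = members
    return groups


def simulate_reads(
    config: SimulationConfig,
    counts_column: pd.Series,
    loci: Sequence[MicroRNALocus],
    sam_path: str | Path,
    seed: int,
) -> None:
    """Write one library's reads as SAM aligned to the hairpin references.

    Each counted read becomes a 19-24 nt sequence anchored at its arm's 5'
    end (0-1 nt start jitter), emitted once per locus carrying an identical
    arm (multi-mapping records share the query name).  A ``decoy_fraction``
    of extra 18-nt reads exercises the length filter.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    by_id = {l.locus_id: l for l in loci}
    groups = _arm_identity_groups(loci)

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": l.locus_id, "LN": l.length} for l in loci],
    }
    ref_index = {l.locus_id: i for i, l in enumerate(loci)}
    arm_rows = [rid for rid in counts_column.index if counts_column[rid] > 0]
    total = int(counts_column.sum())
    n_decoy = int(round(config.decoy_fraction * total))

    with pysam.AlignmentFile(str(sam_path), "w", header=header) as sam:
        counter = 0

        def emit(locus_id: str, arm: str, length: int, qname: str) -> None:
            locus = by_id[locus_id]
            ms, me = locus.mature_intervals[arm]
            off = int(rng.integers(0, 2))
            start = ms + off
            length = min(length, locus.length - start)
            seq = locus.hairpin_seq[start:start + length].upper().replace("U", "T")
            for target in groups[(locus_id, arm)]:
                rec = pysam.AlignedSegment()
                rec.query_name = qname
                rec.query_sequence = seq
                rec.flag = 0
                rec.reference_id = ref_index[target]
                rec.reference_start = start
                rec.mapping_quality = 255
                rec.cigartuples = [(0, length)]
                sam.write(rec)

        for rid in arm_rows:
            locus_id, arm = rid.rsplit("-", 1)
            n_reads = int(counts_column[rid])
            lengths = rng.integers(19, 25, size=n_reads)
            for length in lengths:
                counter += 1
                emit(locus_id, arm, int(length), f"r{counter:08d}")
        for _ in range(n_decoy):
            counter += 1
            rid = arm_rows[int(rng.integers(0, len(arm_rows)))]
            locus_id, arm = rid.rsplit("-", 1)
            emit(locus_id, arm, 18, f"d{counter:08d}")


# ---------------------------------------------------------------------------
# dataset output
# ---------------------------------------------------------------------------

def write_dataset(
    outdir: str | Path,
    dataset: SimulatedDataset,
    with_sam: bool = False,
) -> dict[str, str]:
    """Write the full file tree (GFF3/FASTA/TSV/JSON, optional SAM) and a run
    config naming every path; everything loads back via annotation_io."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = dataset.config
    g = dataset.genomes
    e = dataset.expression

    paths = {
        "gff_a": str(outdir / f"{cfg.species_a}.gff3"),
        "hairpin_fasta_a": str(outdir / f"{cfg.species_a}.hairpin.fa"),
        "mature_fasta_a": str(outdir / f"{cfg.species_a}.mature.fa"),
        "gff_b": str(outdir / f"{cfg.species_b}.gff3"),
        "hairpin_fasta_b": str(outdir / f"{cfg.species_b}.hairpin.fa"),
        "mature_fasta_b": str(outdir / f"{cfg.species_b}.mature.fa"),
        "orthologs": str(outdir / "orthologs.tsv"),
        "samples": str(outdir / "samples.tsv"),
        "counts_a": str(outdir / f"counts_{cfg.species_a}.tsv"),
        "counts_b": str(outdir / f"counts_{cfg.species_b}.tsv"),
        "ground_truth": str(outdir / "ground_truth.json"),
    }
    write_annotations(g.loci_a, paths["gff_a"], paths["hairpin_fasta_a"],
                      paths["mature_fasta_a"])
    write_annotations(g.loci_b, paths["gff_b"], paths["hairpin_fasta_b"],
                      paths["mature_fasta_b"])
    write_orthologs(g.ortholog_pairs, paths["orthologs"])
    write_samples(e.samples, paths["samples"])
    write_count_matrix(e.counts_a, paths["counts_a"])
    write_count_matrix(e.counts_b, paths["counts_b"])
    with open(paths["ground_truth"], "w") as fh:
        json.dump(g.truth.to_json_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")

    if with_sam:
        sam_dir = outdir / "sam"
        sam_dir.mkdir(exist_ok=True)
        for sample in e.samples:
            matrix = e.counts_a if sample.species == cfg.species_a else e.counts_b
            loci = g.loci_a if sample.species == cfg.species_a else g.loci_b
            sam_path = sam_dir / f"{sample.library_id}.sam"
            simulate_reads(cfg, matrix.data[sample.library_id], loci, sam_path,
                           seed=cfg.seed + hash_label(sample.library_id))
            paths[f"sam:{sample.library_id}"] = str(sam_path)

    run_config = {
        "species_a": cfg.species_a,
        "species_b": cfg.species_b,
        "paths": paths,
        "seed": cfg.seed,
        "time_scale": cfg.time_scale,
    }
    config_path = outdir / "run_config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(run_config, fh, sort_keys=True)
    paths["run_config"] = str(config_path)
    return paths
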