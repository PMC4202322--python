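"""Shared fixtures: hand-built annotation fixtures and a small simulated
two-species dataset reused across test modules."""

from __future__ import annotations

from pathlib import Path

import pytest

from mirglass.annotation_io import MicroRNALocus
from mirglass.synthetic_data import SimulationConfig, SimulatedDataset, simulate_dataset


def make_locus(
    locus_id: str = "locX",
    species: str = "spcA",
    chrom: str = "chr2L",
    strand: str = "+",
    start: int = 1000,
    hairpin_seq: str | None = None,
    arm_len: int = 22,
    hairpin_len: int = 90,
) -> MicroRNALocus:
    if hairpin_seq is None:
        # deterministic non-random hairpin
        hairpin_seq = ("ACGU" * ((hairpin_len + 3) // 4))[:hairpin_len]
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


def write_sam(path: Path, loci, records: list[tuple]) -> Path:
    """Minimal SAM writer for fixtures.

    records: (qname, flag, rname, pos_1based, seq)
    """
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for locus in loci:
        lines.append(f"@SQ\tSN:{locus.locus_id}\tLN:{locus.length}")
    for qname, flag, rname, pos, seq in records:
        cigar = f"{len(seq)}M" if flag != 4 else "*"
        lines.append(
            f"{qname}\t{flag}\t{rname}\t{pos}\t255\t{cigar}\t*\t0\t0\t{seq}\t*"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=11,
        n_ortholog_families=30,
        n_specific_a=10,
        n_specific_b=4,
        n_clusters=3,
        library_depth=50_000,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config) -> SimulatedDataset:
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def default_dataset() -> SimulatedDataset:
    """Study-sized dataset at the generator defaults (118 ortholog pairs)."""
    return simulate_dataset(SimulationConfig(seed=7))
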