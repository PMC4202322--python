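"""Reading, writing and validation of every external format the pipeline touches.

The pipeline consumes miRBase-dialect GFF3 annotations (``miRNA_primary_transcript``
hairpins with ``miRNA`` mature arms linked by ``Derives_from``), hairpin and mature
FASTA, a two-column 1-to-1 ortholog table, a TSV sample sheet and TSV count
matrices.  Everything is converted at the boundary into a small set of validated
in-memory types; all internal genomic arithmetic is 0-based half-open.

Mature-arm intervals are stored in *hairpin-local reading-direction* coordinates:
for a minus-strand locus the stored hairpin sequence is the reverse complement of
the genome (i.e. the transcript) and the mature offsets count along it.  This
means no downstream code ever branches on strand.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

HAIRPIN_TYPE = "miRNA_primary_transcript"
MATURE_TYPE = "miRNA"

#: symbolic (non-numeric) stage labels accepted in sample sheets
SYMBOLIC_STAGES = frozenset({"larva", "adult", "adult_male", "adult_female"})

VALID_UNITS = ("raw_fractional_count", "rpm", "z")


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


def _norm_seq(seq: str) -> str:
    """Uppercase and collapse the U/T distinction for comparisons."""
    return seq.upper().replace("U", "T")


@dataclass
class MicroRNALocus:
    """One annotated miRNA hairpin with its mature arm(s).

    ``hairpin_interval`` is genomic, 0-based half-open.  ``mature_intervals``
    are hairpin-local, 0-based half-open, along the reading direction, keyed
    by arm label (``5p``/``3p``).  ``hairpin_seq``/``mature_seqs`` are the
    reading-direction (transcript) sequences.
    """

    locus_id: str
    species: str
    chrom: str
    strand: str
    hairpin_interval: tuple[int, int]
    mature_intervals: dict[str, tuple[int, int]] = field(default_factory=dict)
    hairpin_seq: str = ""
    mature_seqs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"{self.locus_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        hs, he = self.hairpin_interval
        if not 0 <= hs < he:
            raise AnnotationError(f"{self.locus_id}: bad hairpin interval {self.hairpin_interval}")
        for arm, (ms, me) in self.mature_intervals.items():
            if arm not in ("5p", "3p"):
                raise AnnotationError(f"{self.locus_id}: unknown arm label {arm!r}")
            if not 0 <= ms < me <= he - hs:
                raise AnnotationError(
                    f"{self.locus_id}: mature {arm} interval [{ms},{me}) not inside "
                    f"hairpin of length {he - hs}"
                )
        if self.hairpin_seq and len(self.hairpin_seq) != he - hs:
            raise AnnotationError(
                f"{self.locus_id}: hairpin sequence length {len(self.hairpin_seq)} "
                f"!= interval length {he - hs}"
            )
        for arm, seq in self.mature_seqs.items():
            ms, me = self.mature_intervals[arm]
            if self.hairpin_seq and _norm_seq(seq) != _norm_seq(self.hairpin_seq[ms:me]):
                raise AnnotationError(
                    f"{self.locus_id}: mature {arm} sequence does not match the "
                    f"hairpin subsequence at [{ms},{me})"
                )

    @property
    def length(self) -> int:
        return self.hairpin_interval[1] - self.hairpin_interval[0]

    def arm_ids(self) -> list[str]:
        """Row ids of the annotated mature arms, e.g. ``mel-mir-001-5p``."""
        return [arm_row_id(self.locus_id, arm) for arm in sorted(self.mature_intervals)]


def arm_row_id(locus_id: str, arm: str) -> str:
    return f"{locus_id}-{arm}"


def split_arm_row_id(row_id: str) -> tuple[str, str]:
    locus, _, arm = row_id.rpartition("-")
    if arm not in ("5p", "3p"):
        raise ValueError(f"{row_id!r} is not a locus-arm row id")
    return locus, arm


@dataclass
class LibrarySample:
    """One sequencing library: species, stage, time window, replicate group."""

    library_id: str
    species: str
    stage_label: str
    time_window: tuple[float, float] | str
    replicate_group: str

    def __post_init__(self) -> None:
        if isinstance(self.time_window, str):
            if self.time_window not in SYMBOLIC_STAGES:
                raise AnnotationError(
                    f"{self.library_id}: symbolic stage must be one of "
                    f"{sorted(SYMBOLIC_STAGES)}, got {self.time_window!r}"
                )
        else:
            start, end = self.time_window
            if not start < end:
                raise AnnotationError(
                    f"{self.library_id}: time window start {start} must be < end {end}"
                )


@dataclass
class OrthologPair:
    """A 1-to-1 ortholog link between one locus in each species.

    Divergences are substitutions per gap-free aligned site (p-distance);
    ``None`` means not yet computed / not computable.
    """

    id_a: str
    id_b: str
    hairpin_div: float | None = None
    mature_div: float | None = None
    rate_class: str = "unset"

    def __post_init__(self) -> None:
        for name, div in (("hairpin_div", self.hairpin_div), ("mature_div", self.mature_div)):
            if div is not None and not (div >= 0.0 and div == div):
                raise AnnotationError(f"{self.id_a}/{self.id_b}: {name} must be finite and >= 0")
        if self.rate_class not in ("low", "medium", "high", "unset"):
            raise AnnotationError(f"bad rate_class {self.rate_class!r}")


@dataclass
class ExpressionMatrix:
    """Loci(-arm) x libraries (or stages) expression values with a unit tag.

    ``unit`` is one of ``raw_fractional_count`` (possibly fractional read
    counts), ``rpm`` (reads per million mapping to miRNAs) or ``z``
    (per-row z-scores, the only unit allowed to be negative).
    """

    data: pd.DataFrame
    unit: str
    species: str | None = None

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")
        if self.unit != "z" and (self.data.to_numpy() < 0).any():
            raise ValueError(f"negative entries not allowed for unit={self.unit!r}")
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("duplicate row or column ids in expression matrix")
        if self.unit == "rpm":
            totals = self.data.sum(axis=0)
            bad = totals[(totals - 1e6).abs() > 1.0]  # 1e-6 relative of 1e6
            if len(bad):
                raise ValueError(
                    f"rpm columns must sum to 1e6; offending columns: {list(bad.index)[:5]}"
                )

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.data.columns)


# ---------------------------------------------------------------------------
# GFF3 + FASTA annotations
# ---------------------------------------------------------------------------

def _local_interval(
    hairpin: tuple[int, int], mature: tuple[int, int], strand: str
) -> tuple[int, int]:
    """Genomic mature interval -> hairpin-local reading-direction interval."""
    hs, he = hairpin
    ms, me = mature
    if strand == "+":
        return ms - hs, me - hs
    return he - me, he - ms


def _genomic_interval(
    hairpin: tuple[int, int], local: tuple[int, int], strand: str
) -> tuple[int, int]:
    hs, he = hairpin
    ls, le = local
    if strand == "+":
        return hs + ls, hs + le
    return he - le, he - ls


def load_annotations(
    gff_path: str | Path,
    hairpin_fasta_path: str | Path,
    mature_fasta_path: str | Path,
    species: str,
) -> list[MicroRNALocus]:
    """Load miRBase-dialect GFF3 + FASTA into validated :class:`MicroRNALocus`.

    GFF coordinates (1-based closed) are converted to internal 0-based
    half-open; minus-strand sequences are stored reading-direction with
    hairpin-local mature intervals.  Mature features link to their hairpin via
    ``Derives_from``, falling back to an ID-prefix match.
    """
    gff_text = Path(gff_path).read_text()
    if not any(line.strip() and not line.startswith("#") for line in gff_text.splitlines()):
        logger.warning("empty GFF file %s: no loci loaded", gff_path)
        return []
    db = gffutils.create_db(
        gff_text, dbfn=":memory:", from_string=True, force=True,
        keep_order=True, merge_strategy="error",
    )

    hairpin_seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(hairpin_fasta_path), "fasta")}
    mature_seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(mature_fasta_path), "fasta")}

    hairpins: dict[str, gffutils.Feature] = {}
    matures: list[gffutils.Feature] = []
    for feat in db.all_features():
        if feat.featuretype == HAIRPIN_TYPE:
            fid = feat.attributes["ID"][0]
            if fid in hairpins:
                raise AnnotationError(f"duplicate hairpin id {fid!r} in {gff_path}")
            hairpins[fid] = feat
        elif feat.featuretype == MATURE_TYPE:
            matures.append(feat)
        else:
            logger.warning("skipping GFF feature of unknown type %r", feat.featuretype)

    loci: dict[str, MicroRNALocus] = {}
    for fid, feat in hairpins.items():
        if fid not in hairpin_seqs:
            raise AnnotationError(f"hairpin {fid!r} has no FASTA record")
        interval = (feat.start - 1, feat.end)  # 1-based closed -> 0-based half-open
        loci[fid] = MicroRNALocus(
            locus_id=fid,
            species=species,
            chrom=feat.seqid,
            strand=feat.strand,
            hairpin_interval=interval,
            hairpin_seq=hairpin_seqs[fid],
        )

    seen_mature_ids: set[str] = set()
    for feat in matures:
        mid = feat.attributes["ID"][0]
        if mid in seen_mature_ids:
            raise AnnotationError(f"duplicate mature id {mid!r}")
        seen_mature_ids.add(mid)
        parent = feat.attributes.get("Derives_from", [None])[0]
        if parent is None:
            candidates = [h for h in loci if mid.startswith(h)]
            parent = max(candidates, key=len) if candidates else None
        if parent is None or parent not in loci:
            raise AnnotationError(
                f"mature feature {mid!r} has no parent hairpin "
                f"(Derives_from missing and no ID-prefix match)"
            )
        locus = loci[parent]
        genomic = (feat.start - 1, feat.end)
        local = _local_interval(locus.hairpin_interval, genomic, locus.strand)
        ls, le = local
        if not 0 <= ls < le <= locus.length:
            raise AnnotationError(f"mature {mid!r} does not lie within hairpin {parent!r}")
        mid_point = (ls + le) / 2
        arm = "5p" if mid_point < locus.length / 2 else "3p"
        if arm in locus.mature_intervals:
            # both arms on the same side: keep positional order instead
            arm = "3p" if ls > list(locus.mature_intervals.values())[0][0] else "5p"
        if mid not in mature_seqs:
            raise AnnotationError(f"mature {mid!r} has no FASTA record")
        seq = mature_seqs[mid]
        if _norm_seq(seq) != _norm_seq(locus.hairpin_seq[ls:le]):
            raise AnnotationError(
                f"mature {mid!r} sequence does not match hairpin {parent!r} at "
                f"local interval [{ls},{le})"
            )
        locus.mature_intervals[arm] = local
        locus.mature_seqs[arm] = seq

    return list(loci.values())


def write_annotations(
    loci: Sequence[MicroRNALocus],
    gff_path: str | Path,
    hairpin_fasta_path: str | Path,
    mature_fasta_path: str | Path,
) -> None:
    """Write loci back to miRBase-dialect GFF3 + hairpin/mature FASTA."""
    lines = ["##gff-version 3"]
    hp_records, mat_records = [], []
    for locus in loci:
        hs, he = locus.hairpin_interval
        lines.append(
            "\t".join([
                locus.chrom, "mirglass", HAIRPIN_TYPE, str(hs + 1), str(he), ".",
                locus.strand, ".", f"ID={locus.locus_id};Name={locus.locus_id}",
            ])
        )
        hp_records.append(SeqRecord(Seq(locus.hairpin_seq), id=locus.locus_id, description=""))
        for arm in sorted(locus.mature_intervals):
            gs, ge = _genomic_interval(locus.hairpin_interval, locus.mature_intervals[arm], locus.strand)
            mid = arm_row_id(locus.locus_id, arm)
            lines.append(
                "\t".join([
                    locus.chrom, "mirglass", MATURE_TYPE, str(gs + 1), str(ge), ".",
                    locus.strand, ".",
                    f"ID={mid};Name={mid};Derives_from={locus.locus_id}",
                ])
            )
            mat_records.append(SeqRecord(Seq(locus.mature_seqs[arm]), id=mid, description=""))
    Path(gff_path).write_text("\n".join(lines) + "\n")
    SeqIO.write(hp_records, str(hairpin_fasta_path), "fasta")
    SeqIO.write(mat_records, str(mature_fasta_path), "fasta")


# ---------------------------------------------------------------------------
# Ortholog table
# ---------------------------------------------------------------------------

def load_orthologs(
    tsv_path: str | Path,
    loci_a: Sequence[MicroRNALocus],
    loci_b: Sequence[MicroRNALocus],
) -> list[OrthologPair]:
    """Load a two-column 1-to-1 ortholog table (divergences unset).

    Ids must resolve in the respective locus sets and appear at most once
    (1-to-1 orthology).
    """
    ids_a = {l.locus_id for l in loci_a}
    ids_b = {l.locus_id for l in loci_b}
    pairs: list[OrthologPair] = []
    seen_a: set[str] = set()
    seen_b: set[str] = set()
    with open(tsv_path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if row[0] in ("id_a", "species_a_id"):  # optional header
                continue
            id_a, id_b = row[0].strip(), row[1].strip()
            if id_a in seen_a or id_b in seen_b:
                raise AnnotationError(
                    f"ortholog table is not 1-to-1: {id_a!r} or {id_b!r} listed twice"
                )
            if id_a not in ids_a:
                raise AnnotationError(f"unknown species-A locus id {id_a!r} in ortholog table")
            if id_b not in ids_b:
                raise AnnotationError(f"unknown species-B locus id {id_b!r} in ortholog table")
            seen_a.add(id_a)
            seen_b.add(id_b)
            pairs.append(OrthologPair(id_a=id_a, id_b=id_b))
    return pairs


def write_orthologs(pairs: Sequence[OrthologPair], tsv_path: str | Path,
                    with_divergence: bool = False) -> None:
    with open(tsv_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if with_divergence:
            writer.writerow(["id_a", "id_b", "hairpin_div", "mature_div", "rate_class"])
            for p in pairs:
                writer.writerow([
                    p.id_a, p.id_b,
                    "" if p.hairpin_div is None else f"{p.hairpin_div:.6f}",
                    "" if p.mature_div is None else f"{p.mature_div:.6f}",
                    p.rate_class,
                ])
        else:
            writer.writerow(["id_a", "id_b"])
            for p in pairs:
                writer.writerow([p.id_a, p.id_b])


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

def load_samples(sheet_path: str | Path) -> list[LibrarySample]:
    """Load the TSV sample sheet (library_id, species, stage_label,
    time_start, time_end, replicate_group).  Empty time fields mean a symbolic
    stage (larva/adult/adult_male/adult_female)."""
    samples: list[LibrarySample] = []
    seen: set[str] = set()
    with open(sheet_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            lib = row["library_id"].strip()
            if lib in seen:
                raise AnnotationError(f"duplicate library_id {lib!r} in sample sheet")
            seen.add(lib)
            t0, t1 = row.get("time_start", "").strip(), row.get("time_end", "").strip()
            window: tuple[float, float] | str
            if t0 == "" and t1 == "":
                window = row["stage_label"].strip()
            else:
                window = (float(t0), float(t1))
            samples.append(
                LibrarySample(
                    library_id=lib,
                    species=row["species"].strip(),
                    stage_label=row["stage_label"].strip(),
                    time_window=window,
                    replicate_group=row["replicate_group"].strip(),
                )
            )
    return samples


def write_samples(samples: Sequence[LibrarySample], sheet_path: str | Path) -> None:
    with open(sheet_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["library_id", "species", "stage_label", "time_start", "time_end",
                         "replicate_group"])
        for s in samples:
            if isinstance(s.time_window, str):
                t0 = t1 = ""
            else:
                t0, t1 = (f"{t:g}" for t in s.time_window)
            writer.writerow([s.library_id, s.species, s.stage_label, t0, t1, s.replicate_group])


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

def write_count_matrix(matrix: ExpressionMatrix, tsv_path: str | Path) -> None:
    """TSV with a ``# unit:`` header comment, row ids in the first column."""
    with open(tsv_path, "w") as fh:
        fh.write(f"# unit: {matrix.unit}\n")
        if matrix.species is not None:
            fh.write(f"# species: {matrix.species}\n")
        matrix.data.to_csv(fh, sep="\t", index_label="feature_id", float_format="%.10g",
                           lineterminator="\n")


def load_count_matrix(tsv_path: str | Path) -> ExpressionMatrix:
    unit, species = None, None
    with open(tsv_path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].partition(":")
            key, value = key.strip(), value.strip()
            if key == "unit":
                unit = value
            elif key == "species":
                species = value
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        data = pd.read_csv(fh, sep="\t", index_col="feature_id")
    if unit is None:
        raise AnnotationError(f"count matrix {tsv_path} is missing the '# unit:' header")
    return ExpressionMatrix(data=data, unit=unit, species=species)


def loci_by_id(loci: Iterable[MicroRNALocus]) -> dict[str, MicroRNALocus]:
    out: dict[str, MicroRNALocus] = {}
    for locus in loci:
        if locus.locus_id in out:
            raise AnnotationError(f"duplicate locus id {locus.locus_id!r}")
        out[locus.locus_id] = locus
    return out


def expand_pairs_to_arms(
    pairs: Sequence[OrthologPair],
    loci_a: Mapping[str, MicroRNALocus] | Sequence[MicroRNALocus],
    loci_b: Mapping[str, MicroRNALocus] | Sequence[MicroRNALocus],
) -> dict[str, str]:
    """Map arm-level row ids of species A to species B over shared arms.

    Used to match arm-level expression rows across species when only
    hairpin-level ortholog pairs are annotated.
    """
    if not isinstance(loci_a, Mapping):
        loci_a = loci_by_id(loci_a)
    if not isinstance(loci_b, Mapping):
        loci_b = loci_by_id(loci_b)
    mapping: dict[str, str] = {}
    for pair in pairs:
        la, lb = loci_a[pair.id_a], loci_b[pair.id_b]
        for arm in sorted(set(la.mature_intervals) & set(lb.mature_intervals)):
            mapping[arm_row_id(pair.id_a, arm)] = arm_row_id(pair.id_b, arm)
    return mapping
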