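"""Genome, variant and annotation I/O plus genome composition summaries.

Conventions: external formats (FASTA, VCF, GFF3, variant TSV) use 1-based
inclusive coordinates; internal arrays are 0-based half-open. Sequences are
uppercased on read and restricted to the {A,C,G,T,N} alphabet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: 32 pyrimidine-centered trinucleotides, center-C block then center-T,
#: 5' flank major, 3' flank minor.
PYRIMIDINE_TRINUCS: tuple[str, ...] = tuple(
    f"{five}{center}{three}" for center in "CT" for five in "ACGT" for three in "ACGT"
)

# base -> small integer; A,C,G,T -> 0..3, N -> 4, anything else -> 255
_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _BASE_CODE[ord(_b)] = _i


class FormatError(ValueError):
    """Raised on malformed input files."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an ACGTN string as uint8 codes (A=0, C=1, G=2, T=3, N=4)."""
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        bad = seq[int(np.argmax(codes == 255))]
        raise FormatError(f"invalid base {bad!r} in sequence")
    return codes


@dataclass(frozen=True)
class Genome:
    """An ordered collection of named uppercase nucleotide sequences."""

    contigs: Mapping[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not name:
                raise FormatError("empty contig name")
            if not seq:
                raise FormatError(f"contig {name!r} has empty sequence")
            if set(seq) - VALID_BASES:
                raise FormatError(f"contig {name!r} contains non-ACGTN characters")

    def __contains__(self, name: str) -> bool:
        return name in self.contigs

    def __getitem__(self, name: str) -> str:
        return self.contigs[name]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.contigs)

    def length(self, name: str) -> int:
        return len(self.contigs[name])

    def total_length(self, exclude_n: bool = False) -> int:
        if exclude_n:
            return sum(len(s) - s.count("N") for s in self.contigs.values())
        return sum(len(s) for s in self.contigs.values())

    def base_at(self, contig: str, pos: int) -> str:
        """Base at a 1-based position."""
        return self.contigs[contig][pos - 1]

    def reverse_complement(self) -> "Genome":
        return Genome({n: reverse_complement(s) for n, s in self.contigs.items()})


@dataclass(frozen=True, order=True)
class MutationRecord:
    """A single-nucleotide substitution in 1-based genome coordinates."""

    contig: str
    pos: int
    ref: str
    alt: str
    sample: str = "sample"

    def __post_init__(self) -> None:
        if self.ref not in "ACGT" or len(self.ref) != 1:
            raise ValueError(f"ref must be one of A/C/G/T, got {self.ref!r}")
        if self.alt not in "ACGT" or len(self.alt) != 1:
            raise ValueError(f"alt must be one of A/C/G/T, got {self.alt!r}")
        if self.ref == self.alt:
            raise ValueError("alt must differ from ref")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity of the change, ignoring the sample label."""
        return (self.contig, self.pos, self.ref, self.alt)


def validate_records(records: Iterable[MutationRecord], genome: Genome) -> None:
    """Check positions are in bounds and ref fields match the genome.

    A ref mismatch is an error, never a silent strand flip: downstream
    generation-0 differencing relies on trustworthy ref fields.
    """
    for rec in records:
        if rec.contig not in genome:
            raise ValueError(f"record on unknown contig {rec.contig!r}")
        if rec.pos > genome.length(rec.contig):
            raise ValueError(
                f"position {rec.pos} beyond end of contig {rec.contig!r} "
                f"({genome.length(rec.contig)} bp)"
            )
        actual = genome.base_at(rec.contig, rec.pos)
        if actual != rec.ref:
            raise ValueError(
                f"ref mismatch at {rec.contig}:{rec.pos}: record says {rec.ref}, "
                f"genome has {actual}"
            )


def read_fasta(path: str | Path) -> Genome:
    """Read a (multi-record) FASTA file into a Genome, uppercasing sequences."""
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if not name:
            raise FormatError(f"{path}: record with empty header")
        if name in contigs:
            raise FormatError(f"{path}: duplicate contig name {name!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {name!r} has empty sequence")
        contigs[name] = seq
    if not contigs:
        raise FormatError(f"{path}: no FASTA records found")
    return Genome(contigs)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _read_variants_vcf(path: str | Path, sample: str | None) -> list[MutationRecord]:
    label = sample if sample is not None else Path(path).stem
    records: list[MutationRecord] = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            ref = rec.ref.upper() if rec.ref else ""
            for alt in rec.alts or ():
                alt = alt.upper()
                if len(ref) == 1 and len(alt) == 1 and ref in "ACGT" and alt in "ACGT":
                    records.append(MutationRecord(rec.chrom, rec.pos, ref, alt, label))
                else:
                    n_skipped += 1  # indel / MNV / symbolic allele
    if n_skipped:
        logger.info("read_variants(%s): skipped %d non-SNV allele(s)", path, n_skipped)
    return records


def _read_variants_tsv(path: str | Path, sample: str | None) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"contig", "pos", "ref", "alt", "sample"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    records: list[MutationRecord] = []
    n_skipped = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        try:
            pos = int(row.pos)
        except (TypeError, ValueError):
            raise FormatError(f"{path}: unparsable coordinate {row.pos!r} on line {i}")
        ref, alt = str(row.ref).upper(), str(row.alt).upper()
        if len(ref) == 1 and len(alt) == 1 and ref in "ACGT" and alt in "ACGT" and ref != alt:
            label = sample if sample is not None else str(row.sample)
            records.append(MutationRecord(str(row.contig), pos, ref, alt, label))
        else:
            n_skipped += 1
    if n_skipped:
        logger.info("read_variants(%s): skipped %d non-SNV row(s)", path, n_skipped)
    return records


def read_variants(
    path: str | Path, dialect: str = "vcf", sample: str | None = None
) -> list[MutationRecord]:
    """Read single-nucleotide substitutions from a VCF or a variant TSV.

    Only SNVs are returned; indels and MNVs are skipped with a logged count.
    Multi-allelic VCF records are expanded to one record per ALT allele.

    Parameters
    ----------
    dialect
        ``"vcf"`` for VCF v4 text, ``"tsv"`` for a tab-separated table with
        header columns contig, pos, ref, alt, sample (extra columns ignored).
    sample
        Overrides the sample label (defaults to the file stem for VCF and
        the per-row sample column for TSV).
    """
    if dialect == "vcf":
        return _read_variants_vcf(path, sample)
    if dialect == "tsv":
        return _read_variants_tsv(path, sample)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'vcf' or 'tsv')")


def write_variants_tsv(records: Sequence[MutationRecord], path: str | Path) -> None:
    """Write records to the TSV dialect accepted by :func:`read_variants`."""
    df = pd.DataFrame(
        {
            "contig": [r.contig for r in records],
            "pos": [r.pos for r in records],
            "ref": [r.ref for r in records],
            "alt": [r.alt for r in records],
            "sample": [r.sample for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Region annotation

#: Default mapping of GFF3 feature types to region classes.
DEFAULT_CLASS_MAP: dict[str, str] = {
    "CDS": "CDS",
    "five_prime_UTR": "UTR",
    "three_prime_UTR": "UTR",
    "intron": "intron",
    "ncRNA": "ncRNA",
    "rRNA": "ncRNA",
    "tRNA": "ncRNA",
    "snRNA": "ncRNA",
    "snoRNA": "ncRNA",
}

#: Overlap resolution order, highest priority first; positions covered by
#: several features get the highest-priority class. "intergenic" is implicit.
DEFAULT_PRIORITY: tuple[str, ...] = ("CDS", "UTR", "intron", "ncRNA")

INTERGENIC = "intergenic"


@dataclass
class RegionAnnotation:
    """Per-position region classes for a genome.

    ``classes`` lists region classes with ``intergenic`` first (code 0);
    ``labels`` maps each contig to a uint8 array of class codes.
    """

    classes: tuple[str, ...]
    labels: dict[str, np.ndarray]
    class_fractions: dict[str, float]
    intervals: list[tuple[str, int, int, str]] = field(default_factory=list)

    def class_at(self, contig: str, pos: int) -> str:
        """Region class at a 1-based position."""
        return self.classes[self.labels[contig][pos - 1]]

    def class_codes(self, contig: str, positions: np.ndarray) -> np.ndarray:
        return self.labels[contig][np.asarray(positions) - 1]


def annotation_from_intervals(
    intervals: Sequence[tuple[str, int, int, str]],
    genome: Genome,
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> RegionAnnotation:
    """Build a RegionAnnotation from (contig, start, end, class) 1-based
    inclusive intervals, resolving overlaps by ``priority`` (highest first)."""
    extra = [c for c in {cls for *_x, cls in intervals} if c not in priority and c != INTERGENIC]
    order = list(priority) + sorted(extra)
    classes = (INTERGENIC,) + tuple(order)
    code = {c: i for i, c in enumerate(classes)}

    labels = {
        name: np.zeros(genome.length(name), dtype=np.uint8) for name in genome.names
    }
    # paint lowest priority first so higher-priority classes overwrite
    for cls in reversed(order):
        for contig, start, end, icls in intervals:
            if icls != cls:
                continue
            if contig not in genome:
                raise FormatError(f"interval on unknown contig {contig!r}")
            if start < 1 or end > genome.length(contig) or start > end:
                raise FormatError(
                    f"interval {contig}:{start}-{end} outside contig bounds"
                )
            labels[contig][start - 1 : end] = code[cls]

    total = genome.total_length()
    counts = np.zeros(len(classes), dtype=np.int64)
    for arr in labels.values():
        counts += np.bincount(arr, minlength=len(classes))
    fractions = {cls: counts[i] / total for i, cls in enumerate(classes)}
    fractions = {c: f for c, f in fractions.items() if f > 0 or c == INTERGENIC}
    return RegionAnnotation(classes, labels, fractions, list(intervals))


def read_gff_regions(
    path: str | Path,
    genome: Genome,
    class_map: Mapping[str, str] | None = None,
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> RegionAnnotation:
    """Read a GFF3 file and label every genome position with a region class.

    Feature types are mapped through ``class_map`` (unmapped types ignored);
    overlaps resolve by ``priority``; uncovered positions are "intergenic".
    """
    class_map = dict(DEFAULT_CLASS_MAP if class_map is None else class_map)
    intervals: list[tuple[str, int, int, str]] = []
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=["seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes"],
            dtype={"seqid": str, "type": str},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["seqid", "type", "start", "end"])
    for row in df.itertuples(index=False):
        cls = class_map.get(str(row.type))
        if cls is None:
            continue
        intervals.append((str(row.seqid), int(row.start), int(row.end), cls))
    return annotation_from_intervals(intervals, genome, priority)


# ---------------------------------------------------------------------------
# Trinucleotide composition


@dataclass(frozen=True)
class TrinucFrequencies:
    """Relative frequencies of the 32 pyrimidine-centered trinucleotides,
    both strands collapsed."""

    freq: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.freq) != set(PYRIMIDINE_TRINUCS):
            raise ValueError("frequency table must cover exactly the 32 "
                             "pyrimidine-centered trinucleotides")
        vals = np.array([self.freq[t] for t in PYRIMIDINE_TRINUCS])
        if (vals < 0).any():
            raise ValueError("negative trinucleotide frequency")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {vals.sum()}, expected 1")

    def as_vector(self) -> np.ndarray:
        """Frequencies in :data:`PYRIMIDINE_TRINUCS` order."""
        return np.array([self.freq[t] for t in PYRIMIDINE_TRINUCS])

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "TrinucFrequencies":
        return cls(dict(zip(PYRIMIDINE_TRINUCS, np.asarray(vec, dtype=float))))

    @classmethod
    def uniform(cls) -> "TrinucFrequencies":
        return cls.from_vector(np.full(32, 1 / 32))


def collapsed_trinuc_codes(codes: np.ndarray) -> np.ndarray:
    """Pyrimidine-collapsed trinucleotide index (0..31) for every full window.

    ``codes`` is a uint8-encoded contig. Returns an int array of length
    ``len(codes) - 2`` with -1 at windows containing N. Index layout matches
    :data:`PYRIMIDINE_TRINUCS`: 16 * (center is T) + 4 * five_prime + three_prime.
    """
    left = codes[:-2].astype(np.int64)
    center = codes[1:-1].astype(np.int64)
    right = codes[2:].astype(np.int64)
    valid = (left < 4) & (center < 4) & (right < 4)
    # complement of code i (A0 C1 G2 T3) is 3 - i
    pyr = (center == 1) | (center == 3)
    l = np.where(pyr, left, 3 - right)
    c = np.where(pyr, center, 3 - center)
    r = np.where(pyr, right, 3 - left)
    idx = 16 * (c == 3).astype(np.int64) + 4 * l + r
    return np.where(valid, idx, -1)


def trinucleotide_frequencies(genome: Genome) -> TrinucFrequencies:
    """Count every overlapping 3-mer, collapsing purine-centered windows onto
    their reverse complement, and normalize to relative frequencies.

    Windows containing N are excluded from the denominator.
    """
    counts = np.zeros(32, dtype=np.int64)
    for seq in genome.contigs.values():
        if len(seq) < 3:
            continue
        idx = collapsed_trinuc_codes(encode_sequence(seq))
        idx = idx[idx >= 0]
        counts += np.bincount(idx, minlength=32)
    total = counts.sum()
    if total == 0:
        raise ValueError("genome contains no valid (N-free) trinucleotide window")
    return TrinucFrequencies.from_vector(counts / total)


def read_trinuc_table(path: str | Path) -> TrinucFrequencies:
    """Read a 32-row `trinucleotide<TAB>frequency` table (# lines = comments).

    The table is renormalized to sum exactly 1 to absorb printed rounding.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"trinucleotide": str})
    if not {"trinucleotide", "frequency"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns trinucleotide, frequency")
    freq = dict(zip(df["trinucleotide"], df["frequency"].astype(float)))
    total = sum(freq.values())
    if total <= 0:
        raise FormatError(f"{path}: frequencies sum to {total}")
    return TrinucFrequencies({t: f / total for t, f in freq.items()})


def write_trinuc_table(
    freqs: TrinucFrequencies, path: str | Path, comment: str | None = None
) -> None:
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("trinucleotide\tfrequency\n")
        for t in PYRIMIDINE_TRINUCS:
            fh.write(f"{t}\t{freqs.freq[t]:.10g}\n")
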