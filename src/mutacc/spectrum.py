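"""96-channel trinucleotide substitution spectra and derived summaries.

Every single-base substitution is reported on the strand where the mutated
base is a pyrimidine (C or T), the convention used by the COSMIC SBS
catalog: a substitution with a purine reference is reverse-complemented
(ref, alt and both flanks complemented, flanks swapped) before being
assigned to one of the 96 channels "X[R>A]Y".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import Genome, MutationRecord, validate_records

logger = logging.getLogger(__name__)

SUBSTITUTION_TYPES: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Canonical channel order: substitution-type major (C>A block first),
#: then 5' flank, then 3' flank, each A,C,G,T.
CHANNELS_96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_TYPES
    for five in "ACGT"
    for three in "ACGT"
)

_CHANNEL_INDEX: dict[str, int] = {c: i for i, c in enumerate(CHANNELS_96)}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}

#: Boolean mask (6, 96): row t selects the 16 channels of substitution type t.
TYPE_MASKS: np.ndarray = np.array(
    [[ch[2:5] == sub for ch in CHANNELS_96] for sub in SUBSTITUTION_TYPES]
)


def channel_components(channel: str) -> tuple[str, str, str, str]:
    """Split "X[R>A]Y" into (five_prime, ref, alt, three_prime)."""
    return channel[0], channel[2], channel[4], channel[6]


def channel_trinuc(channel: str) -> str:
    """The pyrimidine-centered trinucleotide context of a channel."""
    five, ref, _alt, three = channel_components(channel)
    return f"{five}{ref}{three}"


#: index (96,) mapping each channel to its context in PYRIMIDINE_TRINUCS order
from .genome_io import PYRIMIDINE_TRINUCS  # noqa: E402

CHANNEL_TRINUC_INDEX: np.ndarray = np.array(
    [PYRIMIDINE_TRINUCS.index(channel_trinuc(c)) for c in CHANNELS_96]
)


def classify_substitution(record: MutationRecord, genome: Genome) -> str | None:
    """Map a validated SNV to its pyrimidine-centric 96-channel key.

    Returns None (the "no-context" signal) when the position sits at a
    contig edge or the trinucleotide window contains an N; callers skip
    and log such records.
    """
    seq = genome[record.contig]
    if record.pos < 2 or record.pos > len(seq) - 1:
        return None
    window = seq[record.pos - 2 : record.pos + 1]
    if "N" in window:
        return None
    five, ref, three = window[0], window[1], window[2]
    if ref != record.ref:
        raise ValueError(
            f"ref mismatch at {record.contig}:{record.pos}: record says "
            f"{record.ref}, genome has {ref}"
        )
    alt = record.alt
    if ref in "AG":  # purine reference: report on the opposite strand
        five, three = _COMP[three], _COMP[five]
        ref, alt = _COMP[ref], _COMP[alt]
    return f"{five}[{ref}>{alt}]{three}"


@dataclass
class Spectrum96:
    """Counts or proportions over the 96 substitution channels."""

    values: np.ndarray
    normalized: bool
    n_mutations: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (96,):
            raise ValueError("spectrum must have exactly 96 channels")
        if (self.values < 0).any():
            raise ValueError("spectrum values must be non-negative")
        if self.normalized and abs(self.values.sum() - 1.0) > 1e-9:
            raise ValueError("normalized spectrum must sum to 1")

    def __getitem__(self, channel: str) -> float:
        return float(self.values[_CHANNEL_INDEX[channel]])

    def proportions(self) -> np.ndarray:
        if self.normalized:
            return self.values.copy()
        total = self.values.sum()
        if total == 0:
            raise ValueError("cannot normalize an all-zero spectrum")
        return self.values / total

    def to_frame(self) -> pd.DataFrame:
        """TSV-ready table: channel, count, proportion."""
        props = self.proportions() if self.values.sum() > 0 else np.zeros(96)
        counts = (
            self.values.astype(int)
            if not self.normalized
            else np.round(self.values * self.n_mutations).astype(int)
        )
        return pd.DataFrame(
            {"channel": CHANNELS_96, "count": counts, "proportion": props}
        )

    @classmethod
    def from_mapping(
        cls, values: Mapping[str, float], normalized: bool, n_mutations: int = 0
    ) -> "Spectrum96":
        vec = np.zeros(96)
        for ch, v in values.items():
            vec[_CHANNEL_INDEX[ch]] = v
        return cls(vec, normalized, n_mutations)


def write_spectrum_tsv(spectrum: Spectrum96, path) -> None:
    spectrum.to_frame().to_csv(path, sep="\t", index=False)


def read_spectrum_tsv(path) -> Spectrum96:
    df = pd.read_csv(path, sep="\t")
    vec = np.zeros(96)
    for ch, p in zip(df["channel"], df["proportion"].astype(float)):
        vec[_CHANNEL_INDEX[ch]] = p
    total = vec.sum()
    n = int(df["count"].sum()) if "count" in df else 0
    return Spectrum96(vec / total, normalized=True, n_mutations=n)


def build_spectrum(
    records: Iterable[MutationRecord],
    genome: Genome,
    normalized: bool = False,
    validate: bool = True,
) -> Spectrum96:
    """Tally records into a 96-channel spectrum.

    Records without a full N-free trinucleotide context are excluded from
    both numerator and denominator (count logged).
    """
    records = list(records)
    if validate:
        validate_records(records, genome)
    counts = np.zeros(96)
    n_skipped = 0
    for rec in records:
        channel = classify_substitution(rec, genome)
        if channel is None:
            n_skipped += 1
            continue
        counts[_CHANNEL_INDEX[channel]] += 1
    if n_skipped:
        logger.info("build_spectrum: skipped %d record(s) without full context", n_skipped)
    n = int(counts.sum())
    if normalized:
        if n == 0:
            raise ValueError("no classifiable records: cannot build normalized spectrum")
        return Spectrum96(counts / n, normalized=True, n_mutations=n)
    return Spectrum96(counts, normalized=False, n_mutations=n)


def aggregate_cohort_spectrum(per_sample: Sequence[Spectrum96]) -> Spectrum96:
    """Average per-sample proportion vectors with equal sample weights.

    This is the "average percentage across all individual samples" cohort
    summary; pooling raw counts instead is offered by `pool_counts`.
    """
    if not per_sample:
        raise ValueError("need at least one spectrum")
    if not all(s.normalized for s in per_sample):
        raise ValueError("cohort aggregation requires normalized per-sample spectra")
    mean = np.mean([s.values for s in per_sample], axis=0)
    mean = mean / mean.sum()  # guard accumulated rounding
    return Spectrum96(mean, normalized=True, n_mutations=sum(s.n_mutations for s in per_sample))


def pool_counts(per_sample: Sequence[Spectrum96]) -> Spectrum96:
    """Pool raw per-sample counts into one count spectrum."""
    if not per_sample:
        raise ValueError("need at least one spectrum")
    if any(s.normalized for s in per_sample):
        raise ValueError("pooling requires count spectra")
    total = np.sum([s.values for s in per_sample], axis=0)
    return Spectrum96(total, normalized=False, n_mutations=int(total.sum()))


@dataclass(frozen=True)
class SixTypePercentages:
    """Percentages of the six pyrimidine-centric substitution types."""

    pct: Mapping[str, float]

    def __getitem__(self, sub: str) -> float:
        return float(self.pct[sub])


def six_type_percentages(spectrum: Spectrum96) -> SixTypePercentages:
    """Collapse the 16 flank channels of each substitution type to a percentage."""
    props = spectrum.proportions()
    pct = {
        sub: float(props[TYPE_MASKS[i]].sum() * 100)
        for i, sub in enumerate(SUBSTITUTION_TYPES)
    }
    return SixTypePercentages(pct)


#: The published discriminator for POLE exonuclease-domain-mutant genomes,
#: on the percent scale, thresholds inclusive as printed:
#: C>A >= 20 %, T>G >= 4 %, C>G <= 0.6 %.
POLE_CRITERIA: tuple[tuple[str, str, float], ...] = (
    ("C>A", ">=", 20.0),
    ("T>G", ">=", 4.0),
    ("C>G", "<=", 0.6),
)


def pole_discriminator(six: SixTypePercentages) -> tuple[bool, list[dict]]:
    """Apply the three-rule POLE-EDM discriminator to six-type percentages.

    Returns (verdict, report); the report lists each criterion's observed
    value, threshold and pass flag.
    """
    report = []
    verdict = True
    for sub, op, threshold in POLE_CRITERIA:
        value = six[sub]
        passed = value >= threshold if op == ">=" else value <= threshold
        verdict &= passed
        report.append(
            {"type": sub, "operator": op, "threshold": threshold,
             "value": value, "passed": passed}
        )
    return verdict, report


@dataclass
class RegionDistribution:
    """Observed vs expected percentage of mutations per genomic region class."""

    observed_pct: dict[str, float]
    expected_pct: dict[str, float]
    n: int

    def to_frame(self) -> pd.DataFrame:
        classes = sorted(set(self.observed_pct) | set(self.expected_pct))
        return pd.DataFrame(
            {
                "region": classes,
                "observed_pct": [self.observed_pct.get(c, 0.0) for c in classes],
                "expected_pct": [self.expected_pct.get(c, 0.0) for c in classes],
            }
        )


def region_distribution(records, annotation) -> RegionDistribution:
    """Observed per-class mutation percentages against genome-composition
    expectation (class fraction x 100)."""
    records = list(records)
    if not records:
        raise ValueError("no records: region distribution undefined")
    observed: dict[str, int] = {}
    for rec in records:
        if rec.contig not in annotation.labels:
            raise ValueError(f"record on unannotated contig {rec.contig!r}")
        cls = annotation.class_at(rec.contig, rec.pos)
        observed[cls] = observed.get(cls, 0) + 1
    n = len(records)
    observed_pct = {c: 100 * k / n for c, k in observed.items()}
    expected_pct = {c: 100 * f for c, f in annotation.class_fractions.items()}
    return RegionDistribution(observed_pct, expected_pct, n)
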