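"""Base composition around mutation sites and AT-run enrichment.

Windows of 2*halfwidth+1 bp (103 bp by default) centered on each mutated
position are aligned on the reference strand as given — no pyrimidine
collapse, since the analysis concerns the raw genomic neighbourhood — and
per-position mononucleotide frequencies are computed. "AT-rich regions"
are operationalized as maximal runs of consecutive A/T bases on the
reference strand (a strand-symmetric definition); enrichment of mutations
inside runs of a given length class is tested with a chi-squared
goodness-of-fit against the genome-composition expectation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import Genome, MutationRecord, encode_sequence, validate_records

logger = logging.getLogger(__name__)

DEFAULT_HALFWIDTH = 51  # 103-bp windows

#: AT-run length classes (closed intervals; None = unbounded).
DEFAULT_RUN_BINS: tuple[tuple[int, int | None], ...] = ((9, 20), (21, 50), (51, None))


@dataclass
class FlankProfile:
    """Per-position base frequencies around aligned mutation sites.

    ``freq`` is 4 x (2*halfwidth+1) (rows A, C, G, T; columns offsets
    -halfwidth..+halfwidth with 0 the mutated site, pre-mutation base).
    ``n_sites_per_position`` gives each column's effective denominator:
    window positions truncated by a contig end or covering an N do not
    contribute.
    """

    freq: np.ndarray
    n_sites_per_position: np.ndarray
    halfwidth: int

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.halfwidth, self.halfwidth + 1)

    def base_freq(self, base: str, offset: int) -> float:
        return float(self.freq["ACGT".index(base), offset + self.halfwidth])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.freq.T, columns=list("ACGT"))
        df.insert(0, "offset", self.offsets)
        df["n"] = self.n_sites_per_position
        return df


def _accumulate_profile(
    centers: Iterable[tuple[str, int]], genome: Genome, halfwidth: int
) -> FlankProfile:
    width = 2 * halfwidth + 1
    counts = np.zeros((4, width), dtype=np.int64)
    denom = np.zeros(width, dtype=np.int64)
    encoded = {name: encode_sequence(seq) for name, seq in genome.contigs.items()}
    n_centers = 0
    for contig, pos in centers:
        n_centers += 1
        codes = encoded[contig]
        center0 = pos - 1
        lo = max(0, center0 - halfwidth)
        hi = min(len(codes), center0 + halfwidth + 1)
        window = codes[lo:hi]
        cols = np.arange(lo, hi) - center0 + halfwidth
        valid = window < 4  # N contributes nothing at its position
        cols = cols[valid]
        bases = window[valid]
        np.add.at(counts, (bases, cols), 1)
        np.add.at(denom, cols, 1)
    if n_centers == 0:
        raise ValueError("no sites: flank profile undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(denom > 0, counts / denom, 0.0)
    return FlankProfile(freq, denom, halfwidth)


def flank_profile(
    records: Sequence[MutationRecord],
    genome: Genome,
    halfwidth: int = DEFAULT_HALFWIDTH,
    validate: bool = True,
) -> FlankProfile:
    """Align windows centered on each mutation and tally base frequencies."""
    if halfwidth < 1:
        raise ValueError("halfwidth must be >= 1")
    records = list(records)
    if validate:
        validate_records(records, genome)
    return _accumulate_profile(((r.contig, r.pos) for r in records), genome, halfwidth)


def random_control_profile(
    genome: Genome,
    n: int,
    seed: int,
    halfwidth: int = DEFAULT_HALFWIDTH,
) -> FlankProfile:
    """Profile of n windows at uniformly random valid centers (full window
    inside the contig, no N anywhere in it), as a flatness control.

    Sampling is with replacement when n exceeds the number of valid
    centers (warned).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    candidates: list[tuple[str, np.ndarray]] = []
    total = 0
    for name, seq in genome.contigs.items():
        codes = encode_sequence(seq)
        if len(codes) < 2 * halfwidth + 1:
            continue
        # center c valid iff window [c-hw, c+hw] is N-free
        has_n = np.convolve((codes == 4).astype(np.int32),
                            np.ones(2 * halfwidth + 1, dtype=np.int32), "valid")
        centers0 = np.flatnonzero(has_n == 0) + halfwidth
        if centers0.size:
            candidates.append((name, centers0))
            total += centers0.size
    if total == 0:
        raise ValueError("genome too short (or too N-rich) for any full window")
    replace = n > total
    if replace:
        logger.warning(
            "random_control_profile: n=%d exceeds %d valid centers; sampling "
            "with replacement", n, total,
        )
    flat_contigs = np.concatenate(
        [np.full(c.size, i) for i, (_n, c) in enumerate(candidates)]
    )
    flat_centers = np.concatenate([c for _n, c in candidates])
    pick = rng.choice(total, size=n, replace=replace)
    names = [candidates[i][0] for i in flat_contigs[pick]]
    centers = ((nm, int(c0) + 1) for nm, c0 in zip(names, flat_centers[pick]))
    return _accumulate_profile(centers, genome, halfwidth)


@dataclass(frozen=True)
class ATAsymmetry:
    """Mean A/T frequencies over a flank range on each side of the site."""

    a_left: float
    t_left: float
    a_right: float
    t_right: float

    @property
    def delta_left(self) -> float:
        return self.a_left - self.t_left

    @property
    def delta_right(self) -> float:
        return self.a_right - self.t_right

    @property
    def asymmetry(self) -> float:
        """(A - T) difference between right and left flanks; 0 for any
        left/right-symmetric profile."""
        return self.delta_right - self.delta_left


def at_asymmetry_score(
    profile: FlankProfile, flank_range: tuple[int, int] = (1, 12)
) -> ATAsymmetry:
    """Descriptive A/T strand asymmetry over offsets +lo..+hi and -hi..-lo."""
    lo, hi = flank_range
    if not (1 <= lo <= hi <= profile.halfwidth):
        raise ValueError("flank_range must satisfy 1 <= lo <= hi <= halfwidth")
    c = profile.halfwidth
    right = slice(c + lo, c + hi + 1)
    left = slice(c - hi, c - lo + 1)
    a_row, t_row = profile.freq[0], profile.freq[3]
    return ATAsymmetry(
        a_left=float(a_row[left].mean()),
        t_left=float(t_row[left].mean()),
        a_right=float(a_row[right].mean()),
        t_right=float(t_row[right].mean()),
    )


@dataclass
class ATRunEnrichment:
    """Observed vs expected distribution of mutations over AT-run length
    classes, with a chi-squared goodness-of-fit."""

    bins: dict[str, dict]  # label -> observed_count / observed_pct / expected_pct
    chi2: float
    p: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"bin": label, **vals} for label, vals in self.bins.items()]
        )


def _bin_label(lo: int, hi: int | None) -> str:
    return f"{lo}-{hi}" if hi is not None else f">{lo - 1}"


def _run_lengths(codes: np.ndarray) -> np.ndarray:
    """Length of the maximal A/T run covering each position (0 outside)."""
    at = (codes == 0) | (codes == 3)
    out = np.zeros(len(codes), dtype=np.int64)
    if not at.any():
        return out
    padded = np.concatenate([[0], at.astype(np.int8), [0]])
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)  # exclusive
    for s, e in zip(starts, ends):
        out[s:e] = e - s
    return out


def at_run_enrichment(
    records: Sequence[MutationRecord],
    genome: Genome,
    bins: Sequence[tuple[int, int | None]] = DEFAULT_RUN_BINS,
    validate: bool = True,
) -> ATRunEnrichment:
    """Assign each mutation to the AT run containing its (pre-mutation)
    position, bin runs by length, and chi-square observed counts against
    the genome-wide fraction of positions in each class.

    The test includes an implicit "outside" class (positions not inside any
    run at least the shortest bin's length) so expected proportions sum to
    1; no continuity correction.
    """
    records = list(records)
    if not records:
        raise ValueError("no records: enrichment undefined")
    if validate:
        validate_records(records, genome)

    run_len = {name: _run_lengths(encode_sequence(seq))
               for name, seq in genome.contigs.items()}

    min_len = min(lo for lo, _hi in bins)
    labels = [_bin_label(lo, hi) for lo, hi in bins]

    def bin_of(length: int) -> str | None:
        for (lo, hi), label in zip(bins, labels):
            if length >= lo and (hi is None or length <= hi):
                return label
        return None

    # genome-wide expected fractions (record-independent)
    genome_counts = dict.fromkeys(labels + ["outside"], 0)
    for lengths in run_len.values():
        for (lo, hi), label in zip(bins, labels):
            in_bin = lengths >= lo if hi is None else (lengths >= lo) & (lengths <= hi)
            genome_counts[label] += int(in_bin.sum())
    total_len = genome.total_length()
    genome_counts["outside"] = total_len - sum(genome_counts[l] for l in labels)
    expected_frac = {k: v / total_len for k, v in genome_counts.items()}

    observed = dict.fromkeys(labels + ["outside"], 0)
    for rec in records:
        length = int(run_len[rec.contig][rec.pos - 1])
        label = bin_of(length) if length >= min_len else None
        observed[label if label is not None else "outside"] += 1

    n = len(records)
    obs = np.array([observed[k] for k in labels + ["outside"]], dtype=float)
    exp = np.array([expected_frac[k] * n for k in labels + ["outside"]])
    keep = exp > 0
    if obs[~keep].sum() > 0:  # mutations in a class the genome lacks
        chi2, p = float("inf"), 0.0
    else:
        chi2, p = stats.chisquare(obs[keep], exp[keep])

    result_bins = {
        label: {
            "observed_count": int(observed[label]),
            "observed_pct": 100 * observed[label] / n,
            "expected_pct": 100 * expected_frac[label],
        }
        for label in labels + ["outside"]
    }
    return ATRunEnrichment(result_bins, float(chi2), float(p), n)
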