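"""Mutation-accumulation (MA) lineage analysis.

Lineages are passaged single colonies; mutations are the variants present
in the endpoint (generation ~200) sample but absent from the founder
(generation 0), filtered to a cross-replicate consensus: variants at a
position reported by several variant files are kept only when every file
reporting that position reports the identical change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .genome_io import Genome, MutationRecord

logger = logging.getLogger(__name__)

DEFAULT_GENERATIONS = 200


def difference_variants(
    g200_records: Iterable[MutationRecord],
    g0_records: Iterable[MutationRecord],
) -> list[MutationRecord]:
    """Records present at generation 200 but not at generation 0.

    Identity is the full (contig, pos, ref, alt) key: the same position
    with a different alt in g0 does not mask a g200 record.
    """
    g0_keys = {r.key for r in g0_records}
    return [r for r in g200_records if r.key not in g0_keys]


def consensus_variants(
    per_replicate: Sequence[Sequence[MutationRecord]],
    strict_intersection: bool = False,
) -> list[MutationRecord]:
    """Cross-replicate consensus with union semantics and a conflict veto.

    Positions seen in only one replicate's variant file are kept (union);
    at positions present in several files, records survive only if every
    file reporting the position reports the identical change(s) — any
    disagreement drops all records at that position (logged).
    ``strict_intersection`` keeps only positions present in every file.
    """
    if not per_replicate:
        raise ValueError("need at least one replicate list")
    by_pos: dict[tuple[str, int], list[frozenset]] = {}
    first_records: dict[tuple[str, int], list[MutationRecord]] = {}
    for rep in per_replicate:
        seen_here: dict[tuple[str, int], set] = {}
        for rec in rep:
            pos_key = (rec.contig, rec.pos)
            seen_here.setdefault(pos_key, set()).add((rec.ref, rec.alt))
            first_records.setdefault(pos_key, [])
            if not any(r.key == rec.key for r in first_records[pos_key]):
                first_records[pos_key].append(rec)
        for pos_key, changes in seen_here.items():
            by_pos.setdefault(pos_key, []).append(frozenset(changes))

    kept: list[MutationRecord] = []
    n_conflict = 0
    n_reps = len(per_replicate)
    for pos_key, change_sets in by_pos.items():
        if strict_intersection and len(change_sets) < n_reps:
            continue
        if len(set(change_sets)) > 1:
            n_conflict += 1
            continue
        kept.extend(first_records[pos_key])
    if n_conflict:
        logger.info("consensus_variants: dropped %d position(s) with "
                    "conflicting changes", n_conflict)
    return sorted(kept)


@dataclass
class LineageResult:
    """Mutations accumulated by one MA lineage."""

    strain: str
    lineage: str
    snvs: list[MutationRecord] = field(default_factory=list)
    n_indel: int = 0
    generations: float = DEFAULT_GENERATIONS
    genome_length: int = 0  # N-excluded bp used for per-bp rates

    @property
    def n_snv(self) -> int:
        return len(self.snvs)

    @property
    def rate_per_bp_per_gen(self) -> float:
        if self.generations <= 0:
            raise ValueError("generations must be positive")
        if self.genome_length <= 0:
            return float("nan")
        return self.n_snv / (self.generations * self.genome_length)


def lineage_from_calls(
    strain: str,
    lineage: str,
    g200_replicates: Sequence[Sequence[MutationRecord]],
    g0_replicates: Sequence[Sequence[MutationRecord]],
    genome: Genome,
    generations: float = DEFAULT_GENERATIONS,
    n_indel: int = 0,
) -> LineageResult:
    """Consensus-then-difference pipeline for one lineage."""
    g200 = consensus_variants(g200_replicates)
    g0 = consensus_variants(g0_replicates)
    snvs = difference_variants(g200, g0)
    return LineageResult(
        strain, lineage, snvs, n_indel, generations,
        genome.total_length(exclude_n=True),
    )


def lineage_summary(
    lineages: Sequence[LineageResult],
    generations: float | None = None,
) -> pd.DataFrame:
    """Per-strain mean and (min, max) range of SNV/indel counts and the
    per-bp per-generation substitution rate."""
    if not lineages:
        raise ValueError("no lineages")
    gens = generations if generations is not None else lineages[0].generations
    if gens <= 0:
        raise ValueError("generations must be positive")
    df = pd.DataFrame(
        {
            "strain": [l.strain for l in lineages],
            "n_snv": [l.n_snv for l in lineages],
            "n_indel": [l.n_indel for l in lineages],
            "genome_length": [l.genome_length for l in lineages],
        }
    )
    out = df.groupby("strain", sort=False).agg(
        n_lineages=("n_snv", "size"),
        mean_snv=("n_snv", "mean"),
        min_snv=("n_snv", "min"),
        max_snv=("n_snv", "max"),
        mean_indel=("n_indel", "mean"),
        min_indel=("n_indel", "min"),
        max_indel=("n_indel", "max"),
        genome_length=("genome_length", "first"),
    )
    out["rate_per_bp_per_gen"] = out["mean_snv"] / (gens * out["genome_length"])
    return out.reset_index()


def strain_summary_from_counts(
    snv_counts: dict[str, Sequence[int]],
    generations: float = DEFAULT_GENERATIONS,
    genome_length: int | None = None,
) -> pd.DataFrame:
    """Summary straight from per-lineage SNV totals (as printed in MA
    experiment tables) when the full variant lists are not at hand."""
    if generations <= 0:
        raise ValueError("generations must be positive")
    rows = []
    for strain, counts in snv_counts.items():
        counts = list(counts)
        mean = sum(counts) / len(counts)
        rows.append(
            {
                "strain": strain,
                "n_lineages": len(counts),
                "mean_snv": mean,
                "min_snv": min(counts),
                "max_snv": max(counts),
                "rate_per_bp_per_gen": (
                    mean / (generations * genome_length) if genome_length else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)


def fold_change(summary: pd.DataFrame, strain_a: str, strain_b: str) -> float:
    """Ratio of mean SNV counts between two strains."""
    means = summary.set_index("strain")["mean_snv"]
    if means[strain_b] == 0:
        raise ValueError(f"strain {strain_b!r} has zero mean SNVs")
    return float(means[strain_a] / means[strain_b])


def read_manifest(path) -> pd.DataFrame:
    """Batch manifest: strain, lineage, g0_file, g200_file (TSV)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"strain", "lineage", "g0_file", "g200_file"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df
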