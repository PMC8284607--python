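"""Synthetic-data generators with the statistical structure each analysis
stage assumes, so the whole pipeline runs without external downloads.

Every generator is deterministic under a fixed seed and reports realized
(not just requested) parameters where the construction is stochastic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .fluctuation import FluctuationExperiment
from .genome_io import (
    Genome,
    MutationRecord,
    PYRIMIDINE_TRINUCS,
    TrinucFrequencies,
    collapsed_trinuc_codes,
    encode_sequence,
    trinucleotide_frequencies,
)
from .spectrum import (
    CHANNELS_96,
    SUBSTITUTION_TYPES,
    Spectrum96,
    channel_components,
)

logger = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = "ACGT"


# ---------------------------------------------------------------------------
# Genomes


def _expand_target_to_64(target: TrinucFrequencies) -> np.ndarray:
    """Split each collapsed frequency evenly between a trinucleotide and its
    reverse complement, giving a distribution over all 64 3-mers."""
    q = np.zeros((4, 4, 4))
    for tri, f in target.freq.items():
        l, c, r = (_BASES.index(b) for b in tri)
        rl, rc, rr = 3 - r, 3 - c, 3 - l  # reverse complement indices
        q[l, c, r] += f / 2
        q[rl, rc, rr] += f / 2
    return q


def simulate_genome(
    length: int,
    seed: int,
    trinuc_target: TrinucFrequencies | None = None,
    name: str = "sim_1",
) -> Genome:
    """A single-contig random genome.

    Without a target: i.i.d. uniform bases. With one: a second-order Markov
    chain with conditionals p(z | xy) derived from the 64-mer expansion of
    the collapsed target, so realized pyrimidine-collapsed 3-mer
    frequencies approach the target (recover them with
    :func:`mutacc.genome_io.trinucleotide_frequencies`).
    """
    if length < 3:
        raise ValueError("length must be >= 3")
    rng = np.random.default_rng(seed)
    if trinuc_target is None:
        bases = rng.integers(0, 4, size=length)
        seq = "".join(_BASES[b] for b in bases)
        return Genome({name: seq})

    q = _expand_target_to_64(trinuc_target)
    if q.sum() <= 0:
        raise ValueError("infeasible trinucleotide target (all zero)")
    pair_marginal = q.sum(axis=2)  # P(xy) implied by the 3-mer distribution
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = np.where(pair_marginal[..., None] > 0,
                        q / np.where(pair_marginal[..., None] > 0,
                                     pair_marginal[..., None], 1.0),
                        0.0)
    # start state from the pair marginal
    flat_pairs = pair_marginal.ravel() / pair_marginal.sum()
    start = rng.choice(16, p=flat_pairs)
    x, y = divmod(int(start), 4)
    out = np.empty(length, dtype=np.int64)
    out[0], out[1] = x, y
    uniforms = rng.random(length - 2)
    cum = np.cumsum(cond, axis=2)
    # guard contexts with zero mass: fall back to the pair marginal's column mix
    fallback = np.cumsum(q.sum(axis=(0, 1)) / q.sum())
    for i in range(2, length):
        row = cum[x, y]
        if row[-1] <= 0:
            z = int(np.searchsorted(fallback, uniforms[i - 2] * fallback[-1]))
        else:
            z = int(np.searchsorted(row, uniforms[i - 2] * row[-1]))
        out[i] = z
        x, y = y, z
    seq = "".join(_BASES[b] for b in out)
    return Genome({name: seq})


# ---------------------------------------------------------------------------
# Mutations drawn from a signature


def _as_signature_vector(signature) -> np.ndarray:
    if isinstance(signature, Spectrum96):
        vec = signature.proportions()
    else:
        vec = np.asarray(signature, dtype=float)
    if vec.shape != (96,):
        raise ValueError("signature must be a 96-vector")
    if (vec < 0).any() or vec.sum() <= 0:
        raise ValueError("signature must be non-negative with positive mass")
    return vec / vec.sum()


def simulate_mutations(
    genome: Genome,
    signature,
    n: int,
    seed: int,
    sample: str = "sim",
) -> list[MutationRecord]:
    """Draw n SNVs i.i.d. from a 96-channel signature.

    Each draw picks a channel, then a uniformly random genomic site whose
    pyrimidine-collapsed context matches the channel's trinucleotide, and
    emits the substitution on the reference strand (reverse-complemented
    when the reference base there is a purine). Sites may repeat across
    draws (logged). A channel with signature mass but no eligible site is
    an error.
    """
    vec = _as_signature_vector(signature)
    rng = np.random.default_rng(seed)

    # index genome sites by collapsed trinucleotide context
    sites: dict[int, list[tuple[str, int]]] = {i: [] for i in range(32)}
    for cname, seq in genome.contigs.items():
        if len(seq) < 3:
            continue
        idx = collapsed_trinuc_codes(encode_sequence(seq))
        for ctx in range(32):
            for pos0 in np.flatnonzero(idx == ctx):
                sites[ctx].append((cname, int(pos0) + 2))  # center, 1-based

    channel_ctx = [PYRIMIDINE_TRINUCS.index(
        f"{channel_components(c)[0]}{channel_components(c)[1]}{channel_components(c)[3]}"
    ) for c in CHANNELS_96]
    for ch_i, mass in enumerate(vec):
        if mass > 0 and not sites[channel_ctx[ch_i]]:
            raise ValueError(
                f"channel {CHANNELS_96[ch_i]} has signature mass but no "
                f"matching context in the genome"
            )

    if n == 0:
        return []
    channel_draws = rng.choice(96, size=n, p=vec)
    records: list[MutationRecord] = []
    seen_positions: set[tuple[str, int]] = set()
    n_repeat = 0
    for ch_i in channel_draws:
        channel = CHANNELS_96[ch_i]
        _five, ref, alt, _three = channel_components(channel)
        pool = sites[channel_ctx[ch_i]]
        cname, pos = pool[int(rng.integers(len(pool)))]
        genome_ref = genome.base_at(cname, pos)
        if genome_ref in "AG":  # site is on the purine strand: flip the change
            ref_out, alt_out = _COMP[ref], _COMP[alt]
        else:
            ref_out, alt_out = ref, alt
        if (cname, pos) in seen_positions:
            n_repeat += 1
        seen_positions.add((cname, pos))
        records.append(MutationRecord(cname, pos, ref_out, alt_out, sample))
    if n_repeat:
        logger.info("simulate_mutations: %d draw(s) reused a genomic site", n_repeat)
    return records


# ---------------------------------------------------------------------------
# Fluctuation experiments


def simulate_fluctuation(
    mu: float,
    N0: int,
    N_t: int,
    n_cultures: int,
    epsilon: float = 1.0,
    seed: int = 0,
    max_expected_mutations: float = 1e4,
) -> FluctuationExperiment:
    """Parallel cultures under the classic discrete-growth Luria-Delbruck
    construction.

    Mutations arise with per-division probability mu along growth from N0
    to N_t cells; the expected number per culture is m = mu * (N_t - N0).
    A mutation occurring when the population has N cells founds a clone of
    final size ~ N_t / N; plating a fraction epsilon thins mutant cells
    binomially. Counts are mutant colonies per culture.
    """
    if not (0 < N0 < N_t):
        raise ValueError("need 0 < N0 < N_t")
    if mu < 0:
        raise ValueError("mu must be non-negative")
    if not (0 < epsilon <= 1):
        raise ValueError("epsilon must be in (0, 1]")
    m = mu * (N_t - N0)
    if m > max_expected_mutations:
        raise ValueError(
            f"m = mu*(N_t-N0) = {m:.3g} is too large to simulate colony "
            f"counts; reduce mu or the culture size"
        )
    rng = np.random.default_rng(seed)
    n_mut = rng.poisson(m, size=n_cultures)
    counts = np.zeros(n_cultures, dtype=np.int64)
    for i, k in enumerate(n_mut):
        if k == 0:
            continue
        # division index -> population size at which each mutation arose
        sizes = rng.integers(N0, N_t, size=k)
        clones = N_t // sizes  # final cells descending from each mutation
        mutants = int(clones.sum())
        counts[i] = rng.binomial(mutants, epsilon) if epsilon < 1 else mutants
    return FluctuationExperiment(tuple(int(c) for c in counts), float(N_t), epsilon)


# ---------------------------------------------------------------------------
# AT-asymmetric flanks


@dataclass
class EmbeddedAsymmetry:
    """Mutations planted at sites with an engineered A/T flank asymmetry."""

    records: list[MutationRecord]
    realized_excess: float
    requested_excess: float


def embed_at_asymmetry(
    genome: Genome,
    n: int,
    excess: float,
    side: str = "right",
    seed: int = 0,
    flank_range: tuple[int, int] = (1, 12),
    tolerance: float = 0.05,
) -> EmbeddedAsymmetry:
    """Place n dummy C>A mutations at cytosines whose flank on ``side``
    shows an (A - T) frequency elevated by ``excess`` over the genome
    background, so downstream asymmetry scores recover ``excess``.

    Candidate sites are scored by the (A - T) fraction over the chosen
    flank offsets; the n sites whose scores are closest to
    background + excess are selected (after a seeded shuffle, so ties
    break reproducibly). Errors if the genome cannot supply the excess
    within ``tolerance``.
    """
    if not (0 <= excess <= 0.75):
        raise ValueError("excess must be in [0, 0.75]")
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = flank_range
    rng = np.random.default_rng(seed)

    cand_contig: list[str] = []
    cand_pos: list[np.ndarray] = []
    cand_score: list[np.ndarray] = []
    for cname, seq in genome.contigs.items():
        codes = encode_sequence(seq)
        L = len(codes)
        if L < 2 * hi + 1:
            continue
        at_signed = np.where(codes == 0, 1.0, np.where(codes == 3, -1.0, 0.0))
        at_signed[codes == 4] = 0.0
        csum = np.concatenate([[0.0], np.cumsum(at_signed)])
        centers0 = np.arange(hi, L - hi)
        if side == "right":
            score = (csum[centers0 + hi + 1] - csum[centers0 + lo]) / (hi - lo + 1)
        else:
            score = (csum[centers0 - lo + 1] - csum[centers0 - hi]) / (hi - lo + 1)
        is_c = codes[centers0] == 1  # plant C>A, so the center must be C
        cand_contig.append(cname)
        cand_pos.append(centers0[is_c] + 1)
        cand_score.append(score[is_c])
    if not cand_pos or sum(p.size for p in cand_pos) == 0:
        raise ValueError("no eligible cytosine centers with full flanks")

    names = np.concatenate(
        [np.full(p.size, i) for i, p in enumerate(cand_pos)]
    )
    pos = np.concatenate(cand_pos)
    score = np.concatenate(cand_score)
    background = float(score.mean())
    target = background + excess

    order = rng.permutation(pos.size)
    names, pos, score = names[order], pos[order], score[order]
    if pos.size < n:
        raise ValueError(f"only {pos.size} eligible sites for n={n}")
    # scores are quantized (multiples of 1/flank-width), so nearest-to-target
    # selection alone would bias the mean; greedily alternate between sites
    # below and above the target to steer the running mean onto it
    below = np.argsort(np.where(score <= target, target - score, np.inf), kind="stable")
    above = np.argsort(np.where(score > target, score - target, np.inf), kind="stable")
    n_below = int((score <= target).sum())
    n_above = pos.size - n_below
    pick_list: list[int] = []
    bi = ai = 0
    running = 0.0
    for step in range(n):
        take_below = (running > target * step) if step else (n_below > 0)
        if take_below and bi < n_below:
            idx = below[bi]; bi += 1
        elif ai < n_above:
            idx = above[ai]; ai += 1
        else:
            idx = below[bi]; bi += 1
        pick_list.append(int(idx))
        running += float(score[idx])
    pick = np.array(pick_list)
    realized = float(score[pick].mean()) - background
    if abs(realized - excess) > tolerance:
        raise ValueError(
            f"cannot achieve requested excess {excess:.3f} in this genome "
            f"(best realized {realized:.3f})"
        )
    records = [
        MutationRecord(cand_contig[int(ci)], int(p), "C", "A", "embedded")
        for ci, p in zip(names[pick], pos[pick])
    ]
    return EmbeddedAsymmetry(records, realized, excess)


# ---------------------------------------------------------------------------
# Signature and catalog construction


def pole_like_signature() -> np.ndarray:
    """A 96-channel signature emulating the fission-yeast POLE-proofreading
    hypermutator: six-type mass C>A 33%, C>G 0%, C>T 25%, T>A 5%, T>C 22%,
    T>G 15%, with C>A concentrated in the NCT (especially TCT) context and
    T>G in the NTT (especially TTT) context.
    """
    type_mass = {"C>A": 0.33, "C>G": 0.0, "C>T": 0.25,
                 "T>A": 0.05, "T>C": 0.22, "T>G": 0.15}
    vec = np.zeros(96)
    for i, ch in enumerate(CHANNELS_96):
        five, ref, alt, three = channel_components(ch)
        sub = f"{ref}>{alt}"
        mass = type_mass[sub]
        if mass == 0:
            continue
        if sub == "C>A":
            # 3' T contexts dominate; TCT the strongest
            w = 4.0 if (five, three) == ("T", "T") else (2.0 if three == "T" else 0.3)
        elif sub == "T>G":
            w = 4.0 if (five, three) == ("T", "T") else (2.0 if three == "T" else 0.3)
        else:
            w = 1.0
        vec[i] = mass * w
    # renormalize within each type to keep the six-type split exact
    for sub, mass in type_mass.items():
        sel = np.array([ch[2:5] == sub for ch in CHANNELS_96])
        if vec[sel].sum() > 0:
            vec[sel] = vec[sel] / vec[sel].sum() * mass
    return vec / vec.sum()


def flat_signature() -> np.ndarray:
    return np.full(96, 1 / 96)


def random_signature(seed: int, concentration: float = 0.5) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.dirichlet(np.full(96, concentration))


def make_catalog(n_random: int = 6, seed: int = 0, include: dict | None = None):
    """A synthetic signature catalog: optional named signatures plus
    Dirichlet-random fillers, in the COSMIC container format."""
    from .signatures import SignatureCatalog

    names: list[str] = []
    cols: list[np.ndarray] = []
    for name, vec in (include or {}).items():
        names.append(name)
        cols.append(_as_signature_vector(vec))
    for i in range(n_random):
        names.append(f"SBS_R{i+1}")
        cols.append(random_signature(seed + 1000 + i))
    return SignatureCatalog(tuple(names), np.stack(cols, axis=1))


# ---------------------------------------------------------------------------
# Study-condition defaults

#: Fission-yeast-like genome composition: ~64% A+T.
POMBE_LIKE_AT = 0.64

#: Fluctuation-assay emulation: a 0.25 ml culture inoculated from
#: 10^4 cells/ml grows to saturation (~10^8 cells/ml).
FLUCTUATION_N0 = 2_500
FLUCTUATION_NT = 25_000_000
#: Plated fraction in the assay protocol (0.15 ml of 0.25 ml).
FLUCTUATION_EPSILON = 0.6
#: Expected mutations per wild-type culture; the hypermutator strains are
#: defined relative to it (exonuclease-null 14x, P287R-like 70x, i.e. 70x
#: and 5x rate contrasts).
FLUCTUATION_M_WT = 0.5
STRAIN_RATE_FOLDS = {"wt": 1.0, "exonull": 14.0, "p287r": 70.0}


def strain_fluctuation_experiments(
    n_cultures: int = 960,
    epsilon: float = 1.0,
    seed: int = 0,
) -> dict[str, FluctuationExperiment]:
    """One simulated fluctuation experiment per strain at the default
    rate contrasts (wild type, exonuclease-null 14x, P287R-like 70x)."""
    mu_wt = FLUCTUATION_M_WT / (FLUCTUATION_NT - FLUCTUATION_N0)
    out = {}
    for i, (name, fold) in enumerate(STRAIN_RATE_FOLDS.items()):
        out[name] = simulate_fluctuation(
            mu_wt * fold, FLUCTUATION_N0, FLUCTUATION_NT, n_cultures,
            epsilon, seed=seed * 97 + i,
        )
    return out


def pombe_like_genome(length: int = 200_000, seed: int = 7) -> Genome:
    """An AT-rich random genome emulating fission-yeast base composition
    (i.i.d. with P(A)=P(T)=0.32, P(C)=P(G)=0.18)."""
    rng = np.random.default_rng(seed)
    p = np.array([POMBE_LIKE_AT / 2, (1 - POMBE_LIKE_AT) / 2,
                  (1 - POMBE_LIKE_AT) / 2, POMBE_LIKE_AT / 2])
    bases = rng.choice(4, size=length, p=p)
    return Genome({"sim_1": "".join(_BASES[b] for b in bases)})


def exome_like_trinuc_freqs(seed: int = 11, length: int = 400_000) -> TrinucFrequencies:
    """Trinucleotide frequencies of a GC-richer, CpG-depleted random
    sequence, emulating exome-like composition for humanization tests."""
    rng = np.random.default_rng(seed)
    p = np.array([0.24, 0.26, 0.26, 0.24])
    bases = rng.choice(4, size=length, p=p).tolist()
    # thin CpG dinucleotides to ~25% of their iid rate
    for i in range(1, length):
        if bases[i - 1] == 1 and bases[i] == 2 and rng.random() > 0.25:
            bases[i] = int(rng.choice([0, 1, 3]))
    genome = Genome({"exome_like": "".join(_BASES[b] for b in bases)})
    return trinucleotide_frequencies(genome)
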