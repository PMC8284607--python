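"""Luria-Delbruck fluctuation analysis via the Ma-Sandri-Sarkar MLE.

Parallel cultures grown from a small inoculum are plated on selective
medium; the number of resistant colonies per culture follows the heavy-
tailed Luria-Delbruck distribution whose single parameter m is the
expected number of mutations per culture. The Ma-Sandri-Sarkar recursion
gives the pmf exactly:

    p_0 = exp(-m)
    p_k = (m / k) * sum_{i=0}^{k-1} p_i / (k - i + 1)

m is estimated by maximizing the log likelihood over cultures; plating
only a fraction epsilon of each culture is corrected by the standard
m = m_obs * (epsilon - 1) / (epsilon * ln(epsilon)) adjustment, and the
per-cell mutation rate is m / N_t with N_t the final cells per culture.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.optimize import brentq, minimize_scalar

logger = logging.getLogger(__name__)

_LOG_M_BOUNDS = (math.log(1e-10), math.log(1e6))
_CHI2_95_HALF = stats.chi2.ppf(0.95, df=1) / 2  # 1.9207...
DEFAULT_KMAX_CAP = 10_000


@dataclass(frozen=True)
class FluctuationExperiment:
    """Mutant colony counts from parallel cultures.

    counts: resistant colonies per culture; N_t: final viable cells per
    culture (from dilution plating); epsilon: fraction of each culture
    plated on selective medium.
    """

    counts: tuple[int, ...]
    N_t: float
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        if len(self.counts) < 2:
            raise ValueError("need at least 2 parallel cultures")
        if any(c < 0 for c in self.counts):
            raise ValueError("negative colony count")
        if self.N_t <= 0:
            raise ValueError("N_t must be positive")
        if not (0 < self.epsilon <= 1):
            raise ValueError("epsilon must be in (0, 1]")


@dataclass
class MutationRateEstimate:
    """MSS maximum-likelihood estimate for one experiment.

    m_hat is the (plating-corrected, when enabled) expected mutations per
    culture; rate = m_hat / N_t; ci95 is a profile-likelihood interval on
    m_hat (NaN bounds when bracketing fails).
    """

    m_hat: float
    rate: float
    ci95: tuple[float, float]
    loglik: float
    m_obs: float  # uncorrected MLE on the observed (plated) counts
    epsilon: float
    N_t: float


def luria_delbruck_pmf(m: float, kmax: int) -> np.ndarray:
    """Probabilities p_0..p_kmax of the Luria-Delbruck mutant-count
    distribution by the Ma-Sandri-Sarkar recursion."""
    if m < 0:
        raise ValueError("m must be non-negative")
    if kmax < 0:
        raise ValueError("kmax must be non-negative")
    p = np.zeros(kmax + 1)
    p[0] = math.exp(-m)
    if kmax == 0 or m == 0:
        return p
    # reciprocal weights 1/(k - i + 1) for i = 0..k-1
    recip = 1.0 / np.arange(2, kmax + 2)
    for k in range(1, kmax + 1):
        p[k] = (m / k) * float(p[:k] @ recip[k - 1 :: -1])
    return p


def plating_correction(epsilon: float) -> float:
    """Multiplier converting the m estimated from a plated fraction
    epsilon of each culture to the whole-culture m: (e-1)/(e ln e)."""
    if not (0 < epsilon <= 1):
        raise ValueError("epsilon must be in (0, 1]")
    if epsilon == 1.0:
        return 1.0
    return (epsilon - 1.0) / (epsilon * math.log(epsilon))


def _log_likelihood(m: float, counts: np.ndarray, mult: np.ndarray, kmax: int) -> float:
    """Sum over cultures of log p_k(m); counts above kmax use the tail mass."""
    if m == 0:
        return 0.0 if counts.max() == 0 else -math.inf
    pmf_max = min(int(counts.max()), kmax)
    p = luria_delbruck_pmf(m, pmf_max)
    ll = 0.0
    for k, n_k in zip(counts, mult):
        if k <= pmf_max:
            pk = p[k]
        else:  # lumped tail for counts beyond the cap
            pk = max(1.0 - p.sum(), 0.0)
        if pk <= 0:
            return -math.inf
        ll += n_k * math.log(pk)
    return ll


def mss_mle(
    experiment: FluctuationExperiment,
    correct_plating: bool = True,
    rate_convention: str = "per_culture",
    kmax_cap: int = DEFAULT_KMAX_CAP,
) -> MutationRateEstimate:
    """Maximize the MSS likelihood over m (bounded search on log m).

    rate_convention: "per_culture" gives rate = m / N_t (mutations per
    cell per culture growth); "per_division" gives m / (N_t * ln 2).
    All-zero counts give m_hat = 0 with a one-sided upper CI.
    """
    counts_arr = np.asarray(experiment.counts)
    uniq, mult = np.unique(counts_arr, return_counts=True)

    eps_mult = plating_correction(experiment.epsilon) if correct_plating else 1.0

    def finish(m_obs: float, loglik: float, ci_obs: tuple[float, float]) -> MutationRateEstimate:
        m_hat = m_obs * eps_mult
        ci = (ci_obs[0] * eps_mult, ci_obs[1] * eps_mult)
        if rate_convention == "per_culture":
            rate = m_hat / experiment.N_t
        elif rate_convention == "per_division":
            rate = m_hat / (experiment.N_t * math.log(2))
        else:
            raise ValueError(f"unknown rate convention {rate_convention!r}")
        return MutationRateEstimate(
            m_hat, rate, ci, loglik, m_obs, experiment.epsilon, experiment.N_t
        )

    if counts_arr.max() == 0:
        # likelihood exp(-n m) is monotone: m_hat = 0, one-sided interval
        upper = _CHI2_95_HALF / len(counts_arr)
        return finish(0.0, 0.0, (0.0, upper))

    def negll(log_m: float) -> float:
        return -_log_likelihood(math.exp(log_m), uniq, mult, kmax_cap)

    res = minimize_scalar(negll, bounds=_LOG_M_BOUNDS, method="bounded",
                          options={"xatol": 1e-10})
    m_obs = math.exp(res.x)
    ll_max = -res.fun

    # profile-likelihood CI: m where loglik drops by chi2_1(0.95)/2
    def drop(m: float) -> float:
        return _log_likelihood(m, uniq, mult, kmax_cap) - (ll_max - _CHI2_95_HALF)

    lo = hi = math.nan
    try:
        lo = brentq(drop, 1e-12, m_obs) if drop(1e-12) < 0 else 0.0
        m_hi = m_obs
        while drop(m_hi * 2) > 0 and m_hi < 1e7:
            m_hi *= 2
        hi = brentq(drop, m_obs, m_hi * 2)
    except ValueError:
        logger.warning("mss_mle: CI bracketing failed; returning NaN bounds")
        lo = hi = math.nan
    return finish(m_obs, ll_max, (lo, hi))


def grid_search_mle(
    experiment: FluctuationExperiment,
    grid: np.ndarray | None = None,
    kmax_cap: int = DEFAULT_KMAX_CAP,
) -> float:
    """Brute-force m maximizing the MSS likelihood on a grid (uncorrected
    for plating); independent oracle for the bounded optimizer."""
    counts_arr = np.asarray(experiment.counts)
    uniq, mult = np.unique(counts_arr, return_counts=True)
    if counts_arr.max() == 0:
        return 0.0
    if grid is None:
        center = max(counts_arr.mean(), 0.1)
        grid = np.geomspace(center / 100, center * 100, 4001)
    lls = [_log_likelihood(m, uniq, mult, kmax_cap) for m in grid]
    return float(grid[int(np.argmax(lls))])


@dataclass(frozen=True)
class RateRatio:
    """Fold change between two per-cell mutation rates."""

    ratio: float
    ci95: tuple[float, float]


def rate_ratio(a: MutationRateEstimate, b: MutationRateEstimate) -> RateRatio:
    """Ratio of per-cell rates a/b with an interval combining the two
    profile CIs on the log scale (delta-method style)."""
    if b.rate <= 0:
        raise ValueError(
            "denominator rate is zero; use the p0-based upper bound on the "
            "denominator m instead of a ratio"
        )
    if a.rate <= 0:
        raise ValueError("numerator rate is zero; ratio degenerate")
    ratio = a.rate / b.rate

    def se_log(est: MutationRateEstimate) -> float:
        lo, hi = est.ci95
        if not (math.isfinite(lo) and math.isfinite(hi)) or lo <= 0:
            return math.nan
        return (math.log(hi) - math.log(lo)) / (2 * 1.959963984540054)

    se = math.sqrt(se_log(a) ** 2 + se_log(b) ** 2)
    if math.isnan(se):
        return RateRatio(ratio, (math.nan, math.nan))
    half = 1.959963984540054 * se
    return RateRatio(ratio, (ratio * math.exp(-half), ratio * math.exp(half)))


def read_fluctuation_tsv(path, N_t: float, epsilon: float = 1.0) -> dict[str, FluctuationExperiment]:
    """Read a `strain<TAB>count` table (one row per culture) into one
    experiment per strain, all sharing N_t and epsilon."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if not {"strain", "count"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns strain, count")
    out = {}
    for strain, grp in df.groupby("strain", sort=False):
        out[str(strain)] = FluctuationExperiment(
            tuple(int(c) for c in grp["count"]), N_t=N_t, epsilon=epsilon
        )
    return out
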