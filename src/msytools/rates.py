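"""Branch-length tests, pedigree calibration and molecular-clock dating.

Under a constant mutation rate and equal generation intervals, branches
descending from the same split accumulate mutations at the same Poisson
rate. ``poisson_equal_branch_test`` tests that equality with a chi-square
statistic and a simulated p-value; ``generation_weighted_test`` allows
unequal expectations (e.g. generation-number weights). Mutation rates are
calibrated from observed de novo mutations over counted pedigree
generations, and TMRCAs follow from a closed-form Poisson clock.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class BranchTestResult:
    statistic: float
    p_value: float
    n_sims: int
    seed: int

    @property
    def p_se(self) -> float:
        """Binomial Monte-Carlo standard error of the p-value estimate."""
        p = self.p_value
        return float(np.sqrt(p * (1 - p) / self.n_sims))


def _chisq_equal(counts: np.ndarray) -> np.ndarray:
    """X^2 against the row mean; rows of all-zero counts score 0."""
    counts = np.atleast_2d(counts)
    nbar = counts.mean(axis=1, keepdims=True)
    safe = np.where(nbar > 0, nbar, 1.0)
    x2 = ((counts - nbar) ** 2 / safe).sum(axis=1)
    return np.where(nbar[:, 0] > 0, x2, 0.0)


def poisson_equal_branch_test(
    counts: Sequence[int],
    n_sims: int = 10_000,
    seed: int = 0,
    conditioning: str = "poisson",
) -> BranchTestResult:
    """Chi-square test of equal per-branch mutation counts, simulated p.

    The statistic is ``X^2 = sum_i (n_i - nbar)^2 / nbar``. With
    ``conditioning="poisson"`` (default) replicate count vectors are drawn
    Poisson with the common mean ``nbar`` and scored with the same statistic
    (each against its own mean); with ``conditioning="total"`` replicates
    are multinomial with the observed total and equal cell probabilities,
    which for two branches reproduces the exact conditional binomial test.
    The p-value is the fraction of replicates at least as extreme as the
    observation.
    """
    obs = np.asarray(counts, dtype=float)
    if obs.size < 2:
        raise ValueError("need at least two branch counts")
    if np.any(obs < 0):
        raise ValueError("counts must be >= 0")
    if not np.any(obs > 0):
        raise ValueError("all counts are zero; common expectation undefined")
    nbar = obs.mean()
    statistic = float(_chisq_equal(obs)[0])
    rng = np.random.default_rng(seed)
    if conditioning == "poisson":
        sims = rng.poisson(nbar, size=(n_sims, obs.size))
    elif conditioning == "total":
        probs = np.full(obs.size, 1.0 / obs.size)
        sims = rng.multinomial(int(obs.sum()), probs, size=n_sims)
    else:
        raise ValueError("conditioning must be 'poisson' or 'total'")
    p = float(np.mean(_chisq_equal(sims) >= statistic - 1e-12))
    return BranchTestResult(statistic, p, n_sims, seed)


def exact_binomial_branch_test(n1: int, n2: int) -> float:
    """Exact two-branch oracle: conditional on the total, n1 ~ Bin(n, 1/2)."""
    if n1 < 0 or n2 < 0 or n1 + n2 == 0:
        raise ValueError("need non-negative counts with a positive total")
    return float(stats.binomtest(n1, n1 + n2, 0.5).pvalue)


def generation_weighted_test(
    counts: Sequence[int],
    expected_weights: Sequence[float],
    n_sims: int = 10_000,
    seed: int = 0,
) -> BranchTestResult:
    """Chi-square test for given probabilities with a simulated p-value.

    Expected counts are ``e_i = N * w_i / sum(w)``; replicates resample N
    trials multinomially with those probabilities and are scored against
    the same expectations.
    """
    obs = np.asarray(counts, dtype=float)
    w = np.asarray(expected_weights, dtype=float)
    if obs.shape != w.shape:
        raise ValueError("counts and weights must have the same length")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    total = int(obs.sum())
    if total == 0:
        raise ValueError("all counts are zero")
    probs = w / w.sum()
    expected = total * probs
    statistic = float((((obs - expected) ** 2) / expected).sum())
    rng = np.random.default_rng(seed)
    sims = rng.multinomial(total, probs, size=n_sims)
    sim_stats = (((sims - expected) ** 2) / expected).sum(axis=1)
    p = float(np.mean(sim_stats >= statistic))
    return BranchTestResult(statistic, p, n_sims, seed)


# ---------------------------------------------------------------------------
# pedigrees


@dataclass(frozen=True)
class PedigreeLink:
    father_id: str
    son_id: str
    father_birth: int
    son_birth: int

    def __post_init__(self) -> None:
        if self.son_birth <= self.father_birth:
            raise ValueError(
                f"{self.son_id} born {self.son_birth} not after father "
                f"{self.father_id} born {self.father_birth}"
            )


def mean_generation_interval(
    links: Iterable[PedigreeLink],
    ancestor_id: str,
    descendant_ids: Sequence[str],
) -> tuple[float, float, int]:
    """Mean generation interval and generation count along patrilines.

    For each descendant, the unique father chain up to the ancestor gives a
    generation count and a birth-year span; the returned interval is the
    mean over descendants of ``span / generations`` (the pooled ratio
    ``total span / total generations`` generally differs slightly and can
    be recomputed from the returned pieces). ``n_pairs`` counts distinct
    links traversed.
    """
    father_of: dict[str, PedigreeLink] = {}
    for ln in links:
        if ln.son_id in father_of and father_of[ln.son_id] != ln:
            raise ValueError(f"{ln.son_id} has multiple fathers")
        father_of[ln.son_id] = ln
    births: dict[str, int] = {}
    for ln in father_of.values():
        births[ln.son_id] = ln.son_birth
        births.setdefault(ln.father_id, ln.father_birth)

    intervals: list[float] = []
    gens: list[int] = []
    used: set[tuple[str, str]] = set()
    for d in descendant_ids:
        node = d
        steps = 0
        seen = {node}
        while node != ancestor_id:
            ln = father_of.get(node)
            if ln is None:
                raise ValueError(f"descendant {d!r} is not connected to {ancestor_id!r}")
            used.add((ln.father_id, ln.son_id))
            node = ln.father_id
            if node in seen:
                raise ValueError(f"pedigree cycle detected at {node!r}")
            seen.add(node)
            steps += 1
        if steps == 0:
            raise ValueError(f"descendant {d!r} equals the ancestor")
        span = births[d] - births[ancestor_id]
        intervals.append(span / steps)
        gens.append(steps)
    return float(np.mean(intervals)), float(np.mean(gens)), len(used)


# ---------------------------------------------------------------------------
# rates and dating


@dataclass(frozen=True)
class RateEstimate:
    mean_denovo: float
    generations: float
    length_bp: int
    rate_per_gen: float
    generation_interval_years: float | None = None
    rate_per_year: float | None = None


def estimate_mutation_rate(
    mean_denovo: float, generations: float, length_bp: float
) -> float:
    """Mutations per site per generation from observed de novo counts."""
    if mean_denovo <= 0 or generations <= 0 or length_bp <= 0:
        raise ValueError("all inputs must be positive")
    return mean_denovo / generations / length_bp


def rate_per_year(rate_per_gen: float, interval_years: float) -> float:
    if interval_years <= 0:
        raise ValueError("generation interval must be positive")
    return rate_per_gen / interval_years


@dataclass(frozen=True)
class TmrcaEstimate:
    mutations: int
    years: float
    ci_low: float
    ci_high: float


def poisson_ci(k: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) confidence interval for a Poisson mean from count k."""
    alpha = 1 - conf
    low = 0.0 if k == 0 else float(stats.chi2.ppf(alpha / 2, 2 * k) / 2)
    high = float(stats.chi2.ppf(1 - alpha / 2, 2 * (k + 1)) / 2)
    return low, high


def clock_tmrca(
    mutations: int,
    length_bp: float,
    rate_per_gen: float,
    interval_low: float,
    interval_high: float,
) -> TmrcaEstimate:
    """Closed-form Poisson clock: years back to the MRCA from a branch count.

    The point estimate uses the midpoint generation interval; the interval
    combines the exact Poisson 95% CI on the mutation count with the
    generation-interval range, taking the envelope.
    """
    if mutations < 0:
        raise ValueError("mutations must be >= 0")
    if length_bp <= 0 or rate_per_gen <= 0:
        raise ValueError("length and rate must be positive")
    if not (0 < interval_low <= interval_high):
        raise ValueError("need 0 < interval_low <= interval_high")
    mid = (interval_low + interval_high) / 2.0

    def years_for(k: float, interval: float) -> float:
        return k * interval / (length_bp * rate_per_gen)

    point = years_for(mutations, mid)
    k_lo, k_hi = poisson_ci(mutations)
    ci_low = years_for(k_lo, interval_low)
    ci_high = years_for(k_hi, interval_high)
    return TmrcaEstimate(mutations, point, ci_low, ci_high)
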