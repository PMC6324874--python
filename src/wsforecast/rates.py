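"""Mutation-rate estimation from fluctuation assays (Luria–Delbrück).

Parallel cultures grown from small inocula accumulate mutants whose counts
follow the heavy-tailed Luria–Delbrück distribution.  The expected number of
mutations per culture, m, is estimated by the Ma–Sandri–Sarkar maximum
likelihood estimator (MSS-MLE) built on the Lea–Coulson recursion

    p_0 = exp(−m),   p_r = (m / r) · Σ_{i=0}^{r−1} p_i / (r − i + 1),

and converted to a per-cell, per-generation mutation rate μ = m / N_t with
N_t the final population size.  Confidence intervals use Stewart's
log-normal approximation σ_ln m = 1.225 · m^{−0.315} / √C with C parallel
cultures, and two estimates are compared by a normal test on ln m — a test
that is strictly valid only when the final population sizes are similar,
which is flagged on the result.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

__all__ = [
    "FluctuationDataset",
    "RateEstimate",
    "RateComparison",
    "ld_pmf",
    "mss_mle",
    "compare_rates",
    "rate_sum",
]

#: counts above this are pooled into a single tail class in the likelihood
DEFAULT_COUNT_CAP = 150


@dataclass(frozen=True)
class FluctuationDataset:
    """Mutant counts from C parallel cultures plus the final population size."""

    mutant_counts: tuple[int, ...]
    final_population: float
    label: str = ""

    def __post_init__(self):
        if len(self.mutant_counts) == 0:
            raise ValueError("at least one culture is required")
        if any(c < 0 for c in self.mutant_counts):
            raise ValueError("mutant counts must be non-negative")
        if self.final_population <= 0:
            raise ValueError("final population size must be positive")

    @property
    def n_cultures(self) -> int:
        return len(self.mutant_counts)

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write one row per culture with N_t recorded in a comment header."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"# final_population\t{self.final_population:g}\n")
            fh.write(f"# label\t{self.label}\n")
            fh.write("culture\tcount\n")
            for i, c in enumerate(self.mutant_counts):
                fh.write(f"{i}\t{c}\n")

    @classmethod
    def from_tsv(cls, path: str | Path,
                 final_population: float | None = None) -> "FluctuationDataset":
        path = Path(path)
        label = ""
        with path.open() as fh:
            lines = fh.readlines()
        body = []
        for line in lines:
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("\t")
                if key == "final_population" and final_population is None:
                    final_population = float(value)
                elif key == "label":
                    label = value
            else:
                body.append(line)
        if final_population is None:
            raise ValueError("final_population missing from file header and argument")
        df = pd.read_csv(pd.io.common.StringIO("".join(body)), sep="\t")
        return cls(tuple(int(c) for c in df["count"]), final_population, label)


@dataclass(frozen=True)
class RateEstimate:
    """MSS-MLE result: mutations per culture and rate per cell per generation."""

    m_hat: float
    mu_hat: float
    ci95: tuple[float, float]
    sigma_ln_m: float
    n_cultures: int
    final_population: float
    label: str = ""
    degenerate: bool = False


@dataclass(frozen=True)
class RateComparison:
    """Two-tailed comparison of two rate estimates on the ln m scale.

    ``population_size_caveat`` is set when final population sizes differ by
    more than 10%; the test has only been validated for similar N_t.
    """

    z: float
    p_value: float
    population_size_caveat: bool


def ld_pmf(m: float, r_max: int) -> np.ndarray:
    """Luria–Delbrück probabilities p_0..p_{r_max} (Lea–Coulson formulation).

    Equivalent to a compound Poisson(m) of clone sizes with
    P(size = k) = 1 / (k (k + 1)).
    """
    if m < 0:
        raise ValueError("m must be non-negative")
    p = np.zeros(r_max + 1)
    p[0] = np.exp(-m)
    # weights w[k] = 1/(k+1) for a clone of size k contributing to the recursion
    inv = 1.0 / (np.arange(r_max + 1) + 1.0)
    for r in range(1, r_max + 1):
        # sum_{i=0}^{r-1} p_i / (r - i + 1)
        p[r] = (m / r) * np.dot(p[:r], inv[r - np.arange(r)])
    return p


def _log_likelihood(m: float, counts: np.ndarray, tallies: np.ndarray,
                    cap: int, n_over: int) -> float:
    pmf = ld_pmf(m, cap)
    pmf = np.clip(pmf, 1e-300, None)
    ll = float(np.dot(tallies, np.log(pmf[counts])))
    if n_over:
        tail = max(1.0 - float(np.sum(pmf)), 1e-300)
        ll += n_over * np.log(tail)
    return ll


def mss_mle(
    data: FluctuationDataset,
    count_cap: int = DEFAULT_COUNT_CAP,
    ci_method: str = "stewart",
) -> RateEstimate:
    """Ma–Sandri–Sarkar maximum-likelihood estimate of m and μ = m / N_t.

    Counts above ``count_cap`` are pooled into a tail class with the survivor
    probability so that jackpot cultures do not dominate the recursion.  When
    every culture has zero mutants the estimate degenerates to m = 0 (the
    p0 method gives m = −ln(C_0/C) = 0) and is flagged.
    """
    counts_all = np.asarray(data.mutant_counts)
    C = data.n_cultures
    if np.all(counts_all == 0):
        return RateEstimate(0.0, 0.0, (0.0, 0.0), float("nan"), C,
                            data.final_population, data.label, degenerate=True)

    capped = counts_all[counts_all <= count_cap]
    n_over = int(np.sum(counts_all > count_cap))
    uniq, tallies = np.unique(capped, return_counts=True)

    mean = float(np.mean(np.minimum(counts_all, count_cap)))
    upper = max(10.0, 3.0 * mean + 5.0)
    res = minimize_scalar(
        lambda m: -_log_likelihood(m, uniq, tallies, count_cap, n_over),
        bounds=(1e-8, upper),
        method="bounded",
        options={"xatol": 1e-10},
    )
    m_hat = float(res.x)
    mu_hat = m_hat / data.final_population

    if ci_method != "stewart":
        raise ValueError("only the Stewart log-normal CI is implemented")
    sigma = 1.225 * m_hat ** (-0.315) / np.sqrt(C)
    lo = float(np.exp(np.log(m_hat) - 1.96 * sigma) / data.final_population)
    hi = float(np.exp(np.log(m_hat) + 1.96 * sigma) / data.final_population)
    return RateEstimate(m_hat, mu_hat, (lo, hi), float(sigma), C,
                        data.final_population, data.label)


def compare_rates(a: RateEstimate, b: RateEstimate) -> RateComparison:
    """Two-tailed normal test of ln m_a vs ln m_b with Stewart variances."""
    if a.m_hat <= 0 or b.m_hat <= 0:
        raise ValueError("cannot compare a zero rate estimate on the log scale")
    z = (np.log(a.m_hat) - np.log(b.m_hat)) / np.sqrt(
        a.sigma_ln_m**2 + b.sigma_ln_m**2
    )
    p = float(2.0 * norm.sf(abs(z)))
    nt = (a.final_population, b.final_population)
    caveat = abs(nt[0] - nt[1]) > 0.1 * max(nt)
    return RateComparison(float(z), min(p, 1.0), caveat)


def rate_sum(estimates: dict[str, RateEstimate] | list[RateEstimate]) -> float:
    """Arithmetic sum of per-pathway mutation rates μ."""
    vals = estimates.values() if isinstance(estimates, dict) else estimates
    vals = list(vals)
    if not vals:
        raise ValueError("at least one estimate is required")
    return float(sum(e.mu_hat for e in vals))
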