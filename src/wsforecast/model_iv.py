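"""Monte-Carlo Bayesian model of pathway usage (null Model IV).

Model IV refines the reaction-count model by giving mutations pleiotropic
and continuous effects.  A *mutation vector* m assigns each mutable reaction
of a pathway a change in {−1, 0, +1} (disabling / none / enabling).  The
probability that the pathway produces a wrinkly spreader decomposes as

    P(WS ∩ m ∩ pathway) = Σ_i  P(WS | m_i) · P(m_i)

where the prior P(m_i) is a product of per-reaction probabilities (p_e for
an enabling change, p_d for a disabling one) and the conditional
P(WS | m_i) is estimated by Monte-Carlo: for each of n random parameter
sets the baseline ODE system is integrated to steady state, each mutated
reaction's rate is multiplied by a random effect size (10^U[0,2] enabling,
10^U[−2,0] disabling), the mutated system is integrated for the time the
baseline took to settle, and the draw counts as WS when the reporter
exceeds the baseline level.

Vectors requiring changes in more than one genetic component (no single
protein touches every altered reaction) are *inadmissible*: they keep their
prior mass but contribute zero WS probability.  Mutational hotspots enter
as per-reaction multipliers on both p_e and p_d.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .networks import (
    ReactionNetwork,
    SteadyStateResult,
    integrate_to_steady_state,
    sample_parameters,
    simulate_for,
)

__all__ = [
    "MutationPrior",
    "SamplingConfig",
    "PathwayPosterior",
    "ModelIVSampler",
    "enumerate_vectors",
    "is_admissible",
    "vector_prior",
    "conditional_ws_probability",
    "pathway_posterior",
    "hotspot_posterior",
    "sensitivity_suite",
    "SamplingError",
]

MutationVector = tuple[int, ...]


class SamplingError(RuntimeError):
    """Raised when too many parameter draws fail to reach steady state."""


@dataclass(frozen=True)
class MutationPrior:
    """Per-reaction mutation probabilities with optional hotspot multipliers.

    ``hotspot_multipliers`` maps reaction ids (e.g. ``"r2"``) to a factor k
    applied to both p_e and p_d of that reaction; reactions not listed have
    k = 1.
    """

    p_e: float
    p_d: float
    hotspot_multipliers: Mapping[str, float] = field(default_factory=dict)

    def reaction_probs(self, network: ReactionNetwork) -> np.ndarray:
        """Array of (p_enabling, p_disabling, p_none) per mutable reaction."""
        if self.p_e < 0 or self.p_d < 0:
            raise ValueError("p_e and p_d must be non-negative")
        out = np.empty((network.n_mutable, 3))
        for j, rid in enumerate(network.mutable_ids):
            k = float(self.hotspot_multipliers.get(rid, 1.0))
            if k <= 0:
                raise ValueError(f"hotspot multiplier for {rid} must be positive")
            if k * (self.p_e + self.p_d) >= 1:
                raise ValueError(
                    f"invalid prior: k*(p_e + p_d) >= 1 for reaction {rid}"
                )
            out[j] = (k * self.p_e, k * self.p_d, 1.0 - k * (self.p_e + self.p_d))
        return out


@dataclass(frozen=True)
class SamplingConfig:
    """Monte-Carlo settings for conditional WS-probability estimation.

    Defaults follow the study conditions: 1000 parameter sets, rate
    constants 10^U[−2,2], initial concentrations U[0,10], enabling effect
    sizes 10^U[0,2] and disabling 10^U[−2,0].  ``increase_threshold`` is the
    relative factor by which the mutated reporter must exceed the baseline
    to count as WS (a hair above 1 to suppress integrator noise).
    """

    n_parameter_sets: int = 1000
    rate_range: tuple[float, float] = (-2.0, 2.0)
    conc_range: tuple[float, float] = (0.0, 10.0)
    enabling_effect_range: tuple[float, float] = (0.0, 2.0)
    disabling_effect_range: tuple[float, float] = (-2.0, 0.0)
    increase_threshold: float = 1.001
    seed: int = 0
    horizon: float = 1e5
    max_nonconverged_frac: float = 0.1

    def __post_init__(self):
        if self.n_parameter_sets < 1:
            raise ValueError("n_parameter_sets must be >= 1")
        for name in ("rate_range", "conc_range", "enabling_effect_range",
                     "disabling_effect_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered")


@dataclass
class PathwayPosterior:
    """Eq.-style posterior for one pathway.

    ``total`` is Σ prior × conditional over admissible non-baseline vectors;
    ``vectors`` records (m, prior, conditional, MC standard error) per
    admissible vector; ``reaction_contributions`` gives, per reaction, the
    normalized share of the total carried by vectors altering that reaction.
    """

    pathway: str
    total: float
    vectors: list[tuple[MutationVector, float, float, float]]
    reaction_contributions: dict[str, float]
    prior: MutationPrior
    config: SamplingConfig


# ---------------------------------------------------------------------------
# combinatorics
# ---------------------------------------------------------------------------

def enumerate_vectors(network: ReactionNetwork) -> list[MutationVector]:
    """All 3^n mutation vectors, including the all-zero baseline."""
    return [m for m in product((-1, 0, 1), repeat=network.n_mutable)]


def is_admissible(network: ReactionNetwork, m: Sequence[int]) -> bool:
    """Single-genetic-component rule.

    True iff some protein of the pathway participates in every reaction the
    vector alters, so that one mutated component could plausibly cause all
    the changes.  The all-zero vector is admissible.
    """
    m = tuple(m)
    if len(m) != network.n_mutable:
        raise ValueError("vector length must equal the mutable reaction count")
    support = {rid for rid, mi in zip(network.mutable_ids, m) if mi != 0}
    if not support:
        return True
    return any(support <= rset for rset in network.protein_map.values())


def vector_prior(
    m: Sequence[int], prior: MutationPrior, network: ReactionNetwork
) -> float:
    """Prior probability of a mutation vector.

    Product over reactions of k_j·p_e (+1), k_j·p_d (−1) or
    1 − k_j·(p_e + p_d) (0); sums to 1 over all 3^n vectors.
    """
    probs = prior.reaction_probs(network)
    m = tuple(m)
    if len(m) != network.n_mutable:
        raise ValueError("vector length must equal the mutable reaction count")
    out = 1.0
    for j, mi in enumerate(m):
        out *= probs[j, {1: 0, -1: 1, 0: 2}[mi]]
    return out


# ---------------------------------------------------------------------------
# Monte-Carlo estimation
# ---------------------------------------------------------------------------

def _vector_code(m: Sequence[int]) -> int:
    code = 0
    for mi in m:
        code = 3 * code + (mi + 1)
    return code


class ModelIVSampler:
    """Shared-draw Monte-Carlo estimator of P(WS | m) for one pathway.

    One set of parameter draws (with their baseline steady states) is reused
    across all mutation vectors — common random numbers, so ratios between
    vectors and pathways stabilize at moderate sample sizes.  Conditional
    estimates are cached per vector; effect-size randomness is seeded
    deterministically from ``(config.seed, vector)`` so results do not
    depend on evaluation order.
    """

    def __init__(self, network: ReactionNetwork, config: SamplingConfig):
        self.network = network
        self.config = config
        self._baselines: list[SteadyStateResult] | None = None
        self._params = None
        self._cache: dict[MutationVector, tuple[float, float]] = {}

    # -- baselines ---------------------------------------------------------
    def _ensure_baselines(self) -> None:
        if self._baselines is not None:
            return
        cfg = self.config
        rng = np.random.default_rng([cfg.seed, 0x5A17])
        params, baselines = [], []
        for _ in range(cfg.n_parameter_sets):
            p = sample_parameters(self.network, rng, cfg.rate_range, cfg.conc_range)
            params.append(p)
            baselines.append(
                integrate_to_steady_state(self.network, p, horizon=cfg.horizon)
            )
        n_bad = sum(not b.converged for b in baselines)
        if n_bad > cfg.max_nonconverged_frac * cfg.n_parameter_sets:
            raise SamplingError(
                f"{self.network.name}: {n_bad}/{cfg.n_parameter_sets} baseline "
                "draws failed to reach steady state"
            )
        self._params = params
        self._baselines = baselines

    @property
    def n_valid(self) -> int:
        self._ensure_baselines()
        return sum(b.converged for b in self._baselines)

    # -- conditionals ------------------------------------------------------
    def conditional(self, m: Sequence[int]) -> tuple[float, float]:
        """Estimate (P(WS | m), binomial standard error)."""
        m = tuple(int(x) for x in m)
        if m in self._cache:
            return self._cache[m]
        if not is_admissible(self.network, m):
            raise ValueError(f"vector {m} is not admissible in {self.network.name}")
        cfg = self.config
        if all(mi == 0 for mi in m):
            self._cache[m] = (0.0, 0.0)
            return self._cache[m]
        self._ensure_baselines()
        rng = np.random.default_rng([cfg.seed, 0xEFFE, _vector_code(m)])
        mutated_idx = [j for j, mi in enumerate(m) if mi != 0]
        hits = 0
        n_valid = 0
        for p, base in zip(self._params, self._baselines):
            if not base.converged:
                continue
            mult = np.ones(self.network.n_mutable)
            for j in mutated_idx:
                rng_range = (
                    cfg.enabling_effect_range if m[j] > 0 else cfg.disabling_effect_range
                )
                mult[j] = 10.0 ** rng.uniform(*rng_range)
            y = simulate_for(self.network, p, mult, base.t_ss)
            if y is None:
                continue
            n_valid += 1
            if (
                y[self.network.reporter_index]
                > cfg.increase_threshold * base.reporter_level + 1e-12
            ):
                hits += 1
        if n_valid < (1 - cfg.max_nonconverged_frac) * cfg.n_parameter_sets:
            raise SamplingError(
                f"{self.network.name} {m}: only {n_valid}/{cfg.n_parameter_sets} "
                "draws usable"
            )
        p_hat = hits / n_valid
        se = float(np.sqrt(p_hat * (1.0 - p_hat) / n_valid))
        self._cache[m] = (p_hat, se)
        return self._cache[m]

    def admissible_vectors(self, include_baseline: bool = False) -> list[MutationVector]:
        return [
            m
            for m in enumerate_vectors(self.network)
            if is_admissible(self.network, m) and (include_baseline or any(m))
        ]

    # -- posterior ---------------------------------------------------------
    def posterior(self, prior: MutationPrior) -> PathwayPosterior:
        records = []
        total = 0.0
        for m in self.admissible_vectors():
            pr = vector_prior(m, prior, self.network)
            cond, se = self.conditional(m)
            records.append((m, pr, cond, se))
            total += pr * cond
        raw = {}
        for j, rid in enumerate(self.network.mutable_ids):
            raw[rid] = sum(pr * cond for m, pr, cond, _ in records if m[j] != 0)
        norm = sum(raw.values())
        contrib = {
            rid: (v / norm if norm > 0 else 0.0) for rid, v in raw.items()
        }
        return PathwayPosterior(
            self.network.name, total, records, contrib, prior, self.config
        )


def conditional_ws_probability(
    network: ReactionNetwork,
    m: Sequence[int],
    config: SamplingConfig,
    sampler: ModelIVSampler | None = None,
) -> tuple[float, float]:
    """Monte-Carlo estimate of P(WS | m) with its binomial standard error.

    Pass a :class:`ModelIVSampler` to share parameter draws (and cached
    estimates) across vectors.
    """
    sampler = sampler or ModelIVSampler(network, config)
    return sampler.conditional(m)


def pathway_posterior(
    network: ReactionNetwork,
    prior: MutationPrior,
    config: SamplingConfig,
    sampler: ModelIVSampler | None = None,
) -> PathwayPosterior:
    """Total P(WS ∩ m ∩ pathway) with per-vector and per-reaction breakdown."""
    sampler = sampler or ModelIVSampler(network, config)
    return sampler.posterior(prior)


def hotspot_posterior(
    network: ReactionNetwork,
    prior: MutationPrior,
    config: SamplingConfig,
    hotspot_reactions: Sequence[str] = ("r2", "r3"),
    k: float = 5.0,
    sampler: ModelIVSampler | None = None,
) -> PathwayPosterior:
    """Posterior with a k-fold hotspot on the given reactions.

    The canonical use is the *awsX* hotspot, which touches reactions r2
    (AwsO–AwsX sequestration) and r3 (AwsX–AwsR inhibition) of the Aws
    system; k scales both p_e and p_d of those reactions.
    """
    if k < 1:
        raise ValueError("hotspot factor k must be >= 1")
    mult = dict(prior.hotspot_multipliers)
    for rid in hotspot_reactions:
        if rid not in network.mutable_ids:
            raise ValueError(f"{rid} is not a mutable reaction of {network.name}")
        mult[rid] = mult.get(rid, 1.0) * k
    hot_prior = replace(prior, hotspot_multipliers=mult)
    return pathway_posterior(network, hot_prior, config, sampler=sampler)


# ---------------------------------------------------------------------------
# sensitivity analysis
# ---------------------------------------------------------------------------

SENSITIVITY_REGIMES: dict[str, dict] = {
    "default": {},
    "wide_concentrations": {"conc_range": (0.0, 50.0)},
    "wide_rates": {"rate_range": (-3.0, 3.0)},
    "compressed_effects": {
        "enabling_effect_range": (0.0, 1.0),
        "disabling_effect_range": (-1.0, 0.0),
    },
}


def sensitivity_suite(
    networks: Sequence[ReactionNetwork],
    prior: MutationPrior,
    config: SamplingConfig,
    regimes: Mapping[str, dict] | None = None,
) -> pd.DataFrame:
    """Posterior totals and pairwise ratios under alternative sampling regimes.

    Runs :func:`pathway_posterior` for every network under the default
    configuration plus three perturbed regimes (wider initial concentrations
    U[0,50]; wider rate constants 10^U[−3,3]; compressed effect sizes
    10^U[−1,1] split into enabling 10^U[0,1] and disabling 10^U[−1,0]) and
    tabulates totals and ratios per regime.
    """
    regimes = dict(SENSITIVITY_REGIMES if regimes is None else regimes)
    rows = []
    for regime, overrides in regimes.items():
        cfg = replace(config, **overrides)
        totals = {
            net.name: pathway_posterior(net, prior, cfg).total for net in networks
        }
        row = {"regime": regime, **{f"total_{k}": v for k, v in totals.items()}}
        names = list(totals)
        for a, b in zip(names, names[1:] + names[:1]):
            if len(names) > 1 and totals[b] > 0:
                row[f"{a}/{b}"] = totals[a] / totals[b]
        order = sorted(totals, key=totals.get, reverse=True)
        row["ranking"] = ">".join(order)
        rows.append(row)
    return pd.DataFrame(rows)
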