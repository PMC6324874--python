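"""Closed-form null models of pathway usage and their hotspot corrections.

Three nested null models predict the relative probability that adaptive
wrinkly-spreader mutations arise via the Wsp, Aws or Mws pathway:

* **Model I** — mutational target size proportional to nucleotide count:
  P(pathway used) = 1 − (1 − p)^n with n the locus length in bp, ≈ n·p for
  n·p ≪ 1.
* **Model II** — gene count as target-size proxy: same formula with n the
  number of genes.
* **Model III** — counts of enabling and disabling *reactions* (from the
  network models) as the target; under equal per-reaction probabilities the
  usage weights are simply n_d + n_e.

Each model has a hotspot-corrected variant in which one site (the 33-bp
*awsX* deletion hotspot) mutates at ``k`` times the background probability,
and :func:`solve_hotspot_factor` inverts the hotspot formula for the ``k``
that reproduces an observed usage ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

from scipy.optimize import brentq

__all__ = [
    "UsagePrediction",
    "HotspotSpec",
    "model_i_usage",
    "model_ii_usage",
    "model_ii_hotspot_usage",
    "model_iii_usage",
    "model_iii_hotspot_usage",
    "solve_hotspot_factor",
]


@dataclass(frozen=True)
class HotspotSpec:
    """A single mutational hotspot: one site mutating ``factor_k``-fold faster.

    ``kind`` records which probability the factor scales: the per-site
    probability ``p`` (Model II) or the disabling-reaction probability
    ``p_d`` (Model III).
    """

    pathway: str
    factor_k: float
    kind: str = "p"

    def __post_init__(self):
        if self.factor_k <= 0:
            raise ValueError("hotspot factor k must be positive")


@dataclass
class UsagePrediction:
    """Per-pathway usage probabilities with pairwise ratios.

    ``exact`` holds 1−(1−p)^n; ``approx`` the binomial approximation n·p
    (for Model III regimes, the raw weights).  ``ratios`` maps "A/B" to the
    ratio of approximate usage.
    """

    model: str
    exact: dict[str, float]
    approx: dict[str, float]
    params: dict = field(default_factory=dict)

    @property
    def ratios(self) -> dict[str, float]:
        out = {}
        for a, b in combinations(self.approx, 2):
            if self.approx[b] > 0:
                out[f"{a}/{b}"] = self.approx[a] / self.approx[b]
            if self.approx[a] > 0:
                out[f"{b}/{a}"] = self.approx[b] / self.approx[a]
        return out


def _target_size_usage(model: str, sizes: Mapping[str, float], p: float,
                       size_name: str) -> UsagePrediction:
    if not 0 <= p < 1:
        raise ValueError("per-unit mutation probability p must be in [0, 1)")
    if any(n <= 0 for n in sizes.values()):
        raise ValueError(f"{size_name} must be positive")
    exact = {pw: 1.0 - (1.0 - p) ** n for pw, n in sizes.items()}
    approx = {pw: n * p for pw, n in sizes.items()}
    return UsagePrediction(model, exact, approx, {"p": p, size_name: dict(sizes)})


def model_i_usage(bp_lengths: Mapping[str, float], p: float) -> UsagePrediction:
    """Null Model I: locus length in nucleotides as mutational target size."""
    return _target_size_usage("I", bp_lengths, p, "bp_lengths")


def model_ii_usage(gene_counts: Mapping[str, float], p: float) -> UsagePrediction:
    """Null Model II: gene count as mutational target size."""
    return _target_size_usage("II", gene_counts, p, "gene_counts")


def model_ii_hotspot_usage(gene_count: int, p: float, k: float) -> float:
    """Model II usage probability with one gene carrying a k-fold hotspot.

    Returns ``k p + (1 − k p)(n − 1) p``: either the hotspot mutates, or it
    does not and one of the remaining ``n − 1`` genes does (binomial
    approximation).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if not 0 <= k * p < 1:
        raise ValueError("k*p must be in [0, 1)")
    return k * p + (1.0 - k * p) * (gene_count - 1) * p


def model_iii_usage(
    reaction_counts: Mapping[str, tuple[int, int]],
    regime: str | tuple[float, float] = "equal",
) -> UsagePrediction:
    """Null Model III: enabling/disabling reaction counts as the target.

    Parameters
    ----------
    reaction_counts
        Per pathway ``(n_disabling, n_enabling)``, as produced by
        :func:`wsforecast.networks.classify_reactions`.
    regime
        ``"equal"`` weights pathways by n_d + n_e, ``"disabling_only"`` by
        n_d, ``"enabling_only"`` by n_e.  A numeric pair ``(p_d, p_e)`` gives
        the full probability ``1 − (1 − p_d)^n_d (1 − p_e)^n_e``.
    """
    for pw, (nd, ne) in reaction_counts.items():
        if nd < 0 or ne < 0:
            raise ValueError(f"{pw}: reaction counts must be non-negative")
    if regime == "equal":
        approx = {pw: float(nd + ne) for pw, (nd, ne) in reaction_counts.items()}
        exact = dict(approx)
        params = {"regime": "equal"}
    elif regime == "disabling_only":
        approx = {pw: float(nd) for pw, (nd, ne) in reaction_counts.items()}
        exact = dict(approx)
        params = {"regime": "disabling_only"}
    elif regime == "enabling_only":
        approx = {pw: float(ne) for pw, (nd, ne) in reaction_counts.items()}
        exact = dict(approx)
        params = {"regime": "enabling_only"}
    else:
        p_d, p_e = regime
        if not (0 <= p_d < 1 and 0 <= p_e < 1):
            raise ValueError("p_d and p_e must be in [0, 1)")
        exact = {
            pw: 1.0 - (1.0 - p_d) ** nd * (1.0 - p_e) ** ne
            for pw, (nd, ne) in reaction_counts.items()
        }
        approx = {pw: nd * p_d + ne * p_e for pw, (nd, ne) in reaction_counts.items()}
        params = {"regime": "numeric", "p_d": p_d, "p_e": p_e}
    params["reaction_counts"] = dict(reaction_counts)
    return UsagePrediction("III", exact, approx, params)


def model_iii_hotspot_usage(
    n_disabling: int, n_enabling: int, p_d: float, p_e: float, k: float
) -> float:
    """Model III usage probability with a k-fold hotspot on one disabling reaction.

    Sum of three disjoint events: the hotspot mutates (``k p_d``); it does
    not, but another disabling reaction does; neither does, but an enabling
    reaction does::

        k p_d + (1 − k p_d)[1 − (1 − p_d)^(n_d − 1)]
              + (1 − k p_d)(1 − p_d)^(n_d − 1)[1 − (1 − p_e)^n_e]
    """
    if n_disabling < 1:
        raise ValueError("the hotspot sits on a disabling reaction; n_disabling >= 1")
    if not 0 <= k * p_d < 1:
        raise ValueError("k*p_d must be in [0, 1)")
    if not (0 <= p_d < 1 and 0 <= p_e < 1):
        raise ValueError("p_d and p_e must be in [0, 1)")
    no_hot = 1.0 - k * p_d
    no_other_d = (1.0 - p_d) ** (n_disabling - 1)
    return (
        k * p_d
        + no_hot * (1.0 - no_other_d)
        + no_hot * no_other_d * (1.0 - (1.0 - p_e) ** n_enabling)
    )


def solve_hotspot_factor(
    model: str,
    target_ratio: float,
    pathway_params: Mapping,
    background_params: Mapping,
    bracket: tuple[float, float] = (1e-6, 1e3),
    rtol: float = 1e-6,
) -> float:
    """Solve for the hotspot factor k matching an observed usage ratio.

    The predicted ratio is usage(hotspot pathway; k) / usage(background
    pathway), with the hotspot pathway's formula carrying the factor.  For
    Model II the small-p limit is used, so the ratio is
    ``(k + n − 1) / n_background`` — the limit in which the published factors
    back-solve exactly.  For Model III the full finite-p formulas are used.

    Parameters
    ----------
    model : {"II", "III"}
    target_ratio
        Observed usage ratio (hotspot pathway over background pathway), e.g.
        a ratio of measured mutation rates.
    pathway_params
        Model II: ``{"n": genes}``.  Model III: ``{"n_disabling": ...,
        "n_enabling": ..., "p_d": ..., "p_e": ...}``.
    background_params
        Model II: ``{"n": genes}``.  Model III: as above, without k.
    """
    if target_ratio <= 0:
        raise ValueError("target_ratio must be positive")

    if model == "II":
        n_hot = pathway_params["n"]
        n_bg = background_params["n"]

        def predicted(k):
            return (k + n_hot - 1.0) / n_bg

    elif model == "III":
        bg = model_iii_hotspot_usage(
            background_params["n_disabling"],
            background_params["n_enabling"],
            background_params["p_d"],
            background_params["p_e"],
            k=1.0,
        )

        def predicted(k):
            return (
                model_iii_hotspot_usage(
                    pathway_params["n_disabling"],
                    pathway_params["n_enabling"],
                    pathway_params["p_d"],
                    pathway_params["p_e"],
                    k,
                )
                / bg
            )

    else:
        raise ValueError("model must be 'II' or 'III'")

    lo, hi = bracket
    if model == "III":
        # keep k*p_d inside [0, 1)
        hi = min(hi, (1.0 - 1e-12) / max(pathway_params["p_d"], 1e-300))
    f_lo, f_hi = predicted(lo) - target_ratio, predicted(hi) - target_ratio
    if f_lo * f_hi > 0:
        raise ValueError(
            f"no hotspot factor in bracket [{lo:g}, {hi:g}] reproduces "
            f"ratio {target_ratio:g}"
        )
    return float(brentq(lambda k: predicted(k) - target_ratio, lo, hi, rtol=rtol))
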