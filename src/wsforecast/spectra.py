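"""Mutation-spectrum analytics: hotspots, rate-adjusted fractions, selection bias.

A mutation spectrum is the multiset of independent wrinkly-spreader (WS)
mutations identified in a pathway, each a (pathway, gene, mutation id,
count) record, optionally tagged with the condition under which the mutants
were isolated (with or without selection).  Three analyses are provided:

* a resampling test for mutational hotspots — how often would the observed
  maximum multiplicity arise if all observed mutation types were equally
  likely;
* mutation-rate-adjusted fractions — the share of all WS-causing mutations
  attributable to each mutation, weighting pathways by their measured
  mutation rates rather than by mutant counts;
* contingency comparison of spectra obtained with versus without selection,
  per pathway or per gene (Fisher exact tests with Benjamini–Hochberg
  adjustment).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, false_discovery_control

__all__ = [
    "load_reference_spectrum",
    "MutationRecord",
    "MutationSpectrum",
    "HotspotTestResult",
    "hotspot_resampling_test",
    "max_multiplicity_tail",
    "rate_adjusted_fractions",
    "compare_selection_spectra",
]


@dataclass(frozen=True)
class MutationRecord:
    """One distinct mutation with its observed multiplicity."""

    pathway: str
    gene: str
    mutation_id: str
    count: int
    condition: str = "no_selection"

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass
class MutationSpectrum:
    """A collection of mutation records with per-pathway totals."""

    records: list[MutationRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def pathway_totals(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r.pathway] = out.get(r.pathway, 0) + r.count
        return out

    @property
    def total(self) -> int:
        return sum(r.count for r in self.records)

    def restrict(self, pathway: str | None = None,
                 condition: str | None = None) -> "MutationSpectrum":
        recs = [
            r
            for r in self.records
            if (pathway is None or r.pathway == pathway)
            and (condition is None or r.condition == condition)
        ]
        return MutationSpectrum(recs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.pathway, r.gene, r.mutation_id, r.count, r.condition)
                for r in self.records
            ],
            columns=["pathway", "gene", "mutation_id", "count", "condition"],
        )

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MutationSpectrum":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls.from_frame(df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MutationSpectrum":
        recs = [
            MutationRecord(
                str(row.pathway),
                str(row.gene),
                str(row.mutation_id),
                int(row.count),
                str(getattr(row, "condition", "no_selection")),
            )
            for row in df.itertuples()
        ]
        return cls(recs)


def load_reference_spectrum(condition: str | None = None) -> MutationSpectrum:
    """The packaged reference WS mutation spectrum.

    Transcribes the published main-text counts (105 no-selection mutants:
    wsp 46 / aws 41 / mws 18, the awsX 33-bp-deletion hotspot at 20, awsR
    T27P at 9, wspA at 15/46, and the 24-mutant selection-era spectrum with
    15 Wsp hits and no wspA).  Rows whose mutation id starts with ``syn_``
    are synthetic fillers for counts the published tables do not itemize.
    """
    path = Path(__file__).parent / "data" / "reference_spectrum.tsv"
    spectrum = MutationSpectrum.from_tsv(path)
    if condition is not None:
        spectrum = spectrum.restrict(condition=condition)
    return spectrum


@dataclass(frozen=True)
class HotspotTestResult:
    """Resampling-test outcome.

    ``p_estimate`` is the fraction of resampled spectra whose maximum
    multiplicity reached the observed one; when no replicate reached it,
    ``is_upper_bound`` is set and ``p_estimate`` holds the rule-of-three
    bound 3 / n_reps.
    """

    p_estimate: float
    hits: int
    n_reps: int
    is_upper_bound: bool


def max_multiplicity_tail(
    n_draws: int,
    n_types: int,
    observed_max: int,
    n_reps: int,
    seed: int | None = None,
    chunk: int = 100_000,
) -> HotspotTestResult:
    """P(max multiplicity ≥ observed_max) under uniform draws over n_types.

    The null spectrum is ``n_draws`` mutations falling uniformly on
    ``n_types`` equally likely mutation types; the statistic is the largest
    multiplicity of any one type.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if observed_max > n_draws:
        raise ValueError("observed_max cannot exceed the number of draws")
    rng = np.random.default_rng(seed)
    probs = np.full(n_types, 1.0 / n_types)
    hits = 0
    done = 0
    while done < n_reps:
        b = min(chunk, n_reps - done)
        maxima = rng.multinomial(n_draws, probs, size=b).max(axis=1)
        hits += int(np.sum(maxima >= observed_max))
        done += b
    if hits == 0:
        return HotspotTestResult(3.0 / n_reps, 0, n_reps, True)
    return HotspotTestResult(hits / n_reps, hits, n_reps, False)


def hotspot_resampling_test(
    spectrum: MutationSpectrum,
    observed_max: int | None = None,
    n_reps: int = 1_000_000,
    seed: int | None = None,
    n_types: int | None = None,
) -> HotspotTestResult:
    """Hotspot test for a single-pathway spectrum.

    Resamples N mutations (N = pathway total) uniformly over the K distinct
    observed mutation types and asks how often the maximum multiplicity
    reaches ``observed_max`` (default: the spectrum's own maximum).
    ``n_types`` overrides K when the number of known WS-causing mutation
    types exceeds the number observed in this sample.
    """
    if not spectrum.records:
        raise ValueError("spectrum is empty")
    pathways = {r.pathway for r in spectrum.records}
    if len(pathways) > 1:
        raise ValueError("restrict the spectrum to a single pathway first")
    n_draws = spectrum.total
    k = n_types if n_types is not None else len(spectrum.records)
    if observed_max is None:
        observed_max = max(r.count for r in spectrum.records)
    return max_multiplicity_tail(n_draws, k, observed_max, n_reps, seed)


def rate_adjusted_fractions(
    spectrum: MutationSpectrum, rates: Mapping[str, float]
) -> pd.DataFrame:
    """Fraction of all WS-causing mutations attributable to each mutation.

    Weights each pathway by its measured mutation rate:
    fraction = (count / pathway_total) × (rate_pathway / Σ rates), so a
    pathway's share of the total is its rate share regardless of how many
    mutants were sequenced from it.  Fractions sum to 1.
    """
    totals = spectrum.pathway_totals
    missing = set(totals) - set(rates)
    if missing:
        raise ValueError(f"no mutation rate supplied for pathway(s): {sorted(missing)}")
    if any(rates[p] <= 0 for p in totals):
        raise ValueError("mutation rates must be positive")
    rate_total = sum(rates[p] for p in totals)
    rows = [
        {
            "pathway": r.pathway,
            "gene": r.gene,
            "mutation_id": r.mutation_id,
            "count": r.count,
            "fraction": (r.count / totals[r.pathway]) * (rates[r.pathway] / rate_total),
        }
        for r in spectrum.records
    ]
    return pd.DataFrame(rows).sort_values("fraction", ascending=False, ignore_index=True)


def compare_selection_spectra(
    no_sel: MutationSpectrum,
    sel: MutationSpectrum,
    level: str = "gene",
) -> pd.DataFrame:
    """Category-wise contingency comparison of two spectra.

    For each category (gene or pathway), tests the 2×2 table
    (category vs rest) × (no_selection vs selection) with a two-sided
    Fisher exact test.  ``direction`` is "enriched" when the category's
    share is larger under selection, "depleted" when smaller.  Raw p-values
    and Benjamini–Hochberg q-values are both reported.
    """
    if level not in ("gene", "pathway"):
        raise ValueError("level must be 'gene' or 'pathway'")
    if not no_sel.records or not sel.records:
        raise ValueError("both spectra must be nonempty")

    def tally(spec: MutationSpectrum) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in spec.records:
            key = getattr(r, level)
            if level == "gene" and (not key or key == "nan"):
                raise ValueError("gene-level comparison requires gene fields")
            out[key] = out.get(key, 0) + r.count
        return out

    a, b = tally(no_sel), tally(sel)
    n_a, n_b = sum(a.values()), sum(b.values())
    rows = []
    for cat in sorted(set(a) | set(b)):
        ca, cb = a.get(cat, 0), b.get(cat, 0)
        table = [[ca, n_a - ca], [cb, n_b - cb]]
        _, p = fisher_exact(table, alternative="two-sided")
        share_a = ca / n_a if n_a else 0.0
        share_b = cb / n_b if n_b else 0.0
        if share_b > share_a:
            direction = "enriched"
        elif share_b < share_a:
            direction = "depleted"
        else:
            direction = "unchanged"
        rows.append(
            {
                level: cat,
                "n_no_selection": ca,
                "n_selection": cb,
                "share_no_selection": share_a,
                "share_selection": share_b,
                "direction": direction,
                "p_value": float(p),
            }
        )
    df = pd.DataFrame(rows)
    df["q_value"] = false_discovery_control(df["p_value"], method="bh")
    return df
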