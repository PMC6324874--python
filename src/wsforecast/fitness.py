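"""Selection coefficients from 1:1 competition assays.

A focal wrinkly-spreader mutant is mixed 1:1 with a GFP-marked reference
strain and the ratio R of focal to reference cells is measured before and
after a fixed period of growth.  The per-generation selection coefficient is

    s = ln(R(t) / R(0)) / t,

with t the number of generations from viable counts.  The cost of the GFP
marker is removed by subtracting the selection coefficient of a control
competition between isogenic marked and unmarked reference strains.
Competitions destabilized by smooth revertants (>5% smooth colonies) are
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence
import warnings

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

__all__ = [
    "CompetitionAssay",
    "selection_coefficient",
    "marker_corrected_s",
    "group_compare",
    "filter_destabilized",
    "SMOOTH_EXCLUSION_FRACTION",
]

#: competitions with more than this fraction of smooth colonies are excluded
SMOOTH_EXCLUSION_FRACTION = 0.05


@dataclass(frozen=True)
class CompetitionAssay:
    """One pairwise competition: initial/final ratios and generations elapsed."""

    ratio_initial: float
    ratio_final: float
    generations: float
    mutant: str = ""
    replicate: int = 0
    is_marker_control: bool = False
    smooth_fraction: float = 0.0

    def __post_init__(self):
        if self.ratio_initial <= 0 or self.ratio_final <= 0:
            raise ValueError("competition ratios must be positive")
        if self.generations <= 0:
            raise ValueError("generations must be positive")


def selection_coefficient(assay: CompetitionAssay) -> float:
    """Per-generation selection coefficient s = ln(R(t)/R(0)) / t."""
    return float(np.log(assay.ratio_final / assay.ratio_initial) / assay.generations)


def marker_corrected_s(focal_s: float, control_s: float) -> float:
    """Remove the marker cost: focal s minus the isogenic marked-vs-unmarked s."""
    return focal_s - control_s


def filter_destabilized(
    assays: Iterable[CompetitionAssay],
    max_smooth_fraction: float = SMOOTH_EXCLUSION_FRACTION,
) -> list[CompetitionAssay]:
    """Drop competitions with more than ``max_smooth_fraction`` smooth colonies."""
    return [a for a in assays if a.smooth_fraction <= max_smooth_fraction]


def group_compare(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Pairwise Welch t-tests between groups of selection coefficients.

    Returns one row per unordered pair with group means, standard
    deviations, sizes and the two-tailed p-value.  Groups with fewer than
    two replicates are excluded with a warning.
    """
    usable = {}
    for name, vals in groups.items():
        vals = list(vals)
        if len(vals) < 2:
            warnings.warn(f"group {name!r} has fewer than 2 replicates; excluded")
            continue
        usable[name] = np.asarray(vals, dtype=float)
    rows = []
    for a, b in combinations(sorted(usable), 2):
        res = ttest_ind(usable[a], usable[b], equal_var=False)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "mean_a": float(np.mean(usable[a])),
                "mean_b": float(np.mean(usable[b])),
                "sd_a": float(np.std(usable[a], ddof=1)),
                "sd_b": float(np.std(usable[b], ddof=1)),
                "n_a": len(usable[a]),
                "n_b": len(usable[b]),
                "p_value": float(res.pvalue),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "group_a", "group_b", "mean_a", "mean_b",
            "sd_a", "sd_b", "n_a", "n_b", "p_value",
        ],
    )


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def assays_to_tsv(assays: Iterable[CompetitionAssay], path: str | Path) -> None:
    pd.DataFrame(
        [
            (a.mutant, a.replicate, a.ratio_initial, a.ratio_final,
             a.generations, a.is_marker_control, a.smooth_fraction)
            for a in assays
        ],
        columns=["mutant", "replicate", "R0", "Rt", "generations",
                 "marker_control", "smooth_fraction"],
    ).to_csv(path, sep="\t", index=False)


def assays_from_tsv(path: str | Path) -> list[CompetitionAssay]:
    df = pd.read_csv(path, sep="\t")
    return [
        CompetitionAssay(
            ratio_initial=float(r.R0),
            ratio_final=float(r.Rt),
            generations=float(r.generations),
            mutant=str(r.mutant),
            replicate=int(r.replicate),
            is_marker_control=bool(r.marker_control),
            smooth_fraction=float(getattr(r, "smooth_fraction", 0.0)),
        )
        for r in df.itertuples()
    ]
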