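"""Synthetic generators emulating the three experimental data classes.

The study's wet-lab inputs are (i) fluctuation-assay mutant counts across
parallel cultures, (ii) mutation spectra of independently isolated WS
mutants and (iii) 1:1 competition-assay ratio trajectories.  These
generators produce data of exactly those shapes, with the assumptions the
analysis modules make:

* fluctuation cultures follow the Lea–Coulson process (deterministic
  growth, no mutant death, complete plating) whose mutant-count
  distribution is the one the MSS maximum-likelihood estimator fits — the
  number of mutations per culture is Poisson(m) with m = μ·(N_t − N_0) and
  each mutation founds a clone of size ⌊1/U⌋, U ~ U(0,1);
* spectra are multinomial draws over a site table whose weights encode
  per-site rate multipliers (hotspots);
* competition ratios follow R(t) = R(0)·e^{s·t} with multiplicative
  log-normal noise and an optional marker-cost offset.

A slower discrete per-generation simulator of the fluctuation process is
included as an independent cross-check of the Lea–Coulson sampler.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fitness import CompetitionAssay
from .rates import FluctuationDataset
from .spectra import MutationSpectrum

__all__ = [
    "FluctuationSimSpec",
    "SpectrumSimSpec",
    "simulate_fluctuation_cultures",
    "simulate_fluctuation_discrete",
    "simulate_spectrum",
    "simulate_competition",
    "paper_like_bundle",
]


@dataclass(frozen=True)
class FluctuationSimSpec:
    """Conditions of one fluctuation assay.

    Defaults mirror the study design: 60 parallel cultures founded by ~10^2
    cells grown to N_t = 5×10^7 — small enough that the expected number of
    mutations per well stays below 0.5 at the measured rates (~10^-9/cell/
    generation), which keeps mutant-fitness bias negligible.
    """

    mu: float
    n_initial: float = 1e2
    n_final: float = 5e7
    n_cultures: int = 60
    seed: int | None = None
    label: str = ""

    def __post_init__(self):
        if not 0 <= self.mu < 1:
            raise ValueError("mu must be in [0, 1)")
        if not self.n_final > self.n_initial > 0:
            raise ValueError("need n_final > n_initial > 0")

    @property
    def m(self) -> float:
        """Expected mutations per culture."""
        return self.mu * (self.n_final - self.n_initial)


@dataclass(frozen=True)
class SpectrumSimSpec:
    """Site table for spectrum simulation.

    ``sites`` is a DataFrame with columns pathway, gene, mutation_id and
    weight; relative weights encode hotspot multipliers.
    """

    sites: pd.DataFrame
    n_mutants: int
    seed: int | None = None
    condition: str = "no_selection"

    def __post_init__(self):
        if len(self.sites) == 0:
            raise ValueError("site table is empty")
        if (self.sites["weight"] <= 0).any():
            raise ValueError("site weights must be positive")


def simulate_fluctuation_cultures(spec: FluctuationSimSpec) -> FluctuationDataset:
    """Draw Lea–Coulson mutant counts for C parallel cultures.

    Per culture: M ~ Poisson(m) mutations, each founding a clone whose final
    size is ⌊1/U⌋ capped at N_t (the heavy-tailed Lea–Coulson clone-size
    law for deterministic exponential growth); the mutant count is the sum
    of clone sizes.
    """
    m = spec.m
    if m > 100:
        raise ValueError(
            f"expected mutations per culture m = {m:.3g} > 100 is outside the "
            "regime the MSS estimator is intended for"
        )
    rng = np.random.default_rng(spec.seed)
    counts = []
    for _ in range(spec.n_cultures):
        n_mut = rng.poisson(m)
        if n_mut == 0:
            counts.append(0)
            continue
        u = rng.random(n_mut)
        clones = np.minimum(np.floor(1.0 / u), spec.n_final)
        counts.append(int(np.sum(clones)))
    return FluctuationDataset(tuple(counts), spec.n_final, spec.label)


def simulate_fluctuation_discrete(spec: FluctuationSimSpec) -> FluctuationDataset:
    """Discrete per-generation fluctuation simulator (cross-check oracle).

    The wild-type population doubles each generation; new mutations arise
    Poisson(μ · births) per generation and each mutant clone then doubles
    deterministically for the remaining generations.  Slower than the
    Lea–Coulson sampler but assumption-compatible with it.
    """
    rng = np.random.default_rng(spec.seed)
    n_gen = int(np.ceil(np.log2(spec.n_final / spec.n_initial)))
    counts = []
    for _ in range(spec.n_cultures):
        total = 0.0
        pop = spec.n_initial
        for g in range(n_gen):
            births = pop  # doubling: as many births as existing cells
            new_mut = rng.poisson(spec.mu * births)
            total += new_mut * 2.0 ** (n_gen - g - 1)
            pop *= 2.0
        counts.append(int(total))
    return FluctuationDataset(tuple(counts), spec.n_final, spec.label)


def simulate_spectrum(spec: SpectrumSimSpec) -> MutationSpectrum:
    """Multinomial draw of n mutants over the site table."""
    rng = np.random.default_rng(spec.seed)
    w = spec.sites["weight"].to_numpy(dtype=float)
    counts = rng.multinomial(spec.n_mutants, w / w.sum())
    df = spec.sites.assign(count=counts, condition=spec.condition)
    df = df[df["count"] > 0][["pathway", "gene", "mutation_id", "count", "condition"]]
    return MutationSpectrum.from_frame(df.reset_index(drop=True))


def simulate_competition(
    s_true: float,
    generations: float,
    noise_sd: float,
    n_replicates: int,
    seed: int | None = None,
    ratio_initial: float = 1.0,
    mutant: str = "",
    marker_cost: float = 0.0,
    is_marker_control: bool = False,
) -> list[CompetitionAssay]:
    """Noisy 1:1 competition trajectories with a known selection coefficient.

    R(t) = R(0) · exp((s_true − marker_cost) · t) · exp(ε), ε ~ N(0, noise_sd²);
    ``marker_cost`` shifts the apparent coefficient the way a costly
    fluorescent marker on the reference strain's competitor would.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for rep in range(n_replicates):
        eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        rt = ratio_initial * np.exp((s_true - marker_cost) * generations + eps)
        out.append(
            CompetitionAssay(
                ratio_initial=ratio_initial,
                ratio_final=float(rt),
                generations=generations,
                mutant=mutant,
                replicate=rep,
                is_marker_control=is_marker_control,
            )
        )
    return out


# ---------------------------------------------------------------------------
# study-shaped bundle
# ---------------------------------------------------------------------------

#: measured per-pathway mutation rates to WS (per cell per generation)
REFERENCE_RATES = {"Wsp": 3.7e-9, "Aws": 6.5e-9, "Mws": 0.74e-9}

#: replicate cultures per pathway in the measured assays
REFERENCE_CULTURES = {"Wsp": 200, "Aws": 200, "Mws": 400}


def paper_like_bundle(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a study-shaped synthetic data bundle and return the file paths.

    Emits one fluctuation TSV per pathway (C = 200/200/400 cultures at the
    measured rates), a no-selection mutation spectrum with an Aws hotspot
    carrying roughly half the pathway's mutants, and a competition table
    with per-gene selection coefficients plus a marker-cost control.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    seeds = iter(s.generate_state(1)[0] % (2**31) for s in ss.spawn(16))
    paths: dict[str, Path] = {}

    for pathway, mu in REFERENCE_RATES.items():
        spec = FluctuationSimSpec(
            mu=mu,
            n_cultures=REFERENCE_CULTURES[pathway],
            seed=int(next(seeds)),
            label=pathway,
        )
        data = simulate_fluctuation_cultures(spec)
        p = outdir / f"fluctuation_{pathway.lower()}.tsv"
        data.to_tsv(p)
        paths[f"fluctuation_{pathway}"] = p

    sites = _hotspot_site_table()
    spectrum = simulate_spectrum(
        SpectrumSimSpec(sites, n_mutants=105, seed=int(next(seeds)))
    )
    p = outdir / "spectrum_no_selection.tsv"
    spectrum.to_tsv(p)
    paths["spectrum"] = p

    # marker-cost control: isogenic marked vs unmarked reference (true s = 0)
    assays = simulate_competition(
        0.0, generations=8.0, noise_sd=0.02, n_replicates=4,
        seed=int(next(seeds)), mutant="reference_control", marker_cost=-0.01,
        is_marker_control=True,
    )
    for mutant, s_true in (
        ("wspF_ref", 0.0), ("wspE", 0.01), ("wspA", -0.05),
        ("wspR", -0.35), ("awsX", -0.12), ("awsR", -0.12), ("mwsR", -0.02),
    ):
        assays += simulate_competition(
            s_true, generations=8.0, noise_sd=0.02, n_replicates=4,
            seed=int(next(seeds)) % (2**31), mutant=mutant, marker_cost=-0.01,
        )
    from .fitness import assays_to_tsv

    p = outdir / "competitions.tsv"
    assays_to_tsv(assays, p)
    paths["competitions"] = p
    return paths


def _hotspot_site_table() -> pd.DataFrame:
    """Site table shaped like the observed spectrum: one strong Aws hotspot
    (the 33-bp awsX deletion), one moderate one (awsR T27P), and uniform
    background sites across all three pathways."""
    rows = [("Aws", "awsX", "dY77-Q87", 20.0), ("Aws", "awsR", "T27P", 9.0)]
    rows += [("Aws", "awsX" if i < 5 else "awsR", f"aws_bg{i}", 1.0) for i in range(12)]
    rows += [("Wsp", "wspA", f"wspA_bg{i}", 1.0) for i in range(15)]
    rows += [("Wsp", "wspF", f"wspF_bg{i}", 1.5) for i in range(10)]
    rows += [("Wsp", "wspE", f"wspE_bg{i}", 1.5) for i in range(10)]
    rows += [("Wsp", "wspC", "wspCD_fusion", 1.0), ("Wsp", "wspR", "wspR_bg0", 1.0)]
    rows += [("Mws", "mwsR", f"mwsR_bg{i}", 1.0) for i in range(12)]
    return pd.DataFrame(rows, columns=["pathway", "gene", "mutation_id", "weight"])
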