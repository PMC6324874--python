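"""Canonical reaction networks for the three mutational pathways to wrinkly spreader.

The wrinkly-spreader (WS) phenotype of *Pseudomonas fluorescens* SBW25 arises
by mutational activation of one of three diguanylate-cyclase (DGC) pathways:

* **Wsp** — a chemotaxis-like phosphorelay (7 genes, 8.4 kb).  The
  methyl-accepting protein WspA (with scaffolds WspB/WspD) controls the
  hybrid kinase WspE, which phosphorylates both the DGC WspR (the WS
  effector) and the methylesterase WspF, a negative regulator that
  demethylates WspA.
* **Aws** — a three-gene operon (2.3 kb).  The outer-membrane sensor AwsO
  sequesters the periplasmic negative regulator AwsX, which otherwise binds
  and inhibits the inner-membrane DGC AwsR; free AwsR dimerises into the
  active form.
* **Mws** — the single gene *mwsR* (3.9 kb), encoding a composite
  DGC/phosphodiesterase protein modelled as interconversion between an
  inactive and an active DGC state.

Each network is a small mass-action ODE system.  The *mutable* reactions
``r1..rn`` are the ones whose rates mutations can raise (enabling change) or
lower (disabling change); every activation or binding product additionally
has a first-order, non-mutable relaxation reaction back to its source (or
degradation, for the open Mws system) so that steady states are
non-degenerate.  The reporter species — phosphorylated WspR, the AwsR dimer,
or the active MwsR DGC state — is the quantity whose increase defines a WS
genotype.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import odeint

__all__ = [
    "SpeciesDef",
    "ReactionDef",
    "ReactionNetwork",
    "ParameterSample",
    "SteadyStateResult",
    "PATHWAY_NAMES",
    "build_pathway",
    "sample_parameters",
    "initial_state",
    "integrate_to_steady_state",
    "simulate_for",
    "classify_reactions",
    "IntegrationError",
    "ClassificationError",
]

PATHWAY_NAMES = ("Wsp", "Aws", "Mws")

#: genomic annotation per pathway: (length in bp, number of genes)
PATHWAY_ANNOTATION = {"Wsp": (8400, 7), "Aws": (2300, 3), "Mws": (3900, 1)}


class IntegrationError(RuntimeError):
    """Raised when the ODE integrator produces an invalid trajectory."""


class ClassificationError(RuntimeError):
    """Raised when a reaction cannot be classified as enabling or disabling."""


@dataclass(frozen=True)
class SpeciesDef:
    """One molecular species of a pathway model.

    ``conserved_group`` ties activated/complexed forms to a shared total;
    ``conserved_weight`` is the number of protomers the species carries
    (2 for the AwsR dimer).
    """

    id: str
    description: str = ""
    is_reporter: bool = False
    conserved_group: str | None = None
    conserved_weight: int = 1


@dataclass(frozen=True)
class ReactionDef:
    """One mass-action reaction.

    ``reactants`` are consumed, ``products`` produced and ``modifiers`` enter
    the rate law without being consumed.  The rate is
    ``constant * prod(reactant conc ** stoich) * prod(modifier conc)``.
    Mutable reactions carry the ids ``r1..rn``; relaxation/degradation
    reactions are never targets of mutation.
    """

    id: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    modifiers: tuple[str, ...] = ()
    mutable: bool = False
    rate_symbol: str = ""


@dataclass(frozen=True)
class ParameterSample:
    """One random draw of rate constants and initial pool sizes."""

    mutable_rates: np.ndarray
    relaxation_rates: np.ndarray
    totals: np.ndarray
    seed: int | None = None


@dataclass(frozen=True)
class SteadyStateResult:
    """Outcome of integrating a network to (approximate) steady state."""

    state: np.ndarray
    t_ss: float
    reporter_level: float
    converged: bool


class ReactionNetwork:
    """A named pathway model with pre-compiled mass-action kinetics."""

    def __init__(
        self,
        name: str,
        species: Sequence[SpeciesDef],
        reactions: Sequence[ReactionDef],
        protein_map: Mapping[str, Iterable[str]],
        bp_length: int,
        gene_count: int,
        pools: Sequence[tuple[str, str]],
    ):
        self.name = name
        self.species = tuple(species)
        self.reactions = tuple(reactions)
        self.protein_map = {p: frozenset(rids) for p, rids in protein_map.items()}
        self.bp_length = int(bp_length)
        self.gene_count = int(gene_count)
        #: ordered (pool label, seeded species id); totals are assigned here
        self.pools = tuple(pools)
        self._compile()

    # -- derived structure -------------------------------------------------
    def _compile(self) -> None:
        self._species_index = {s.id: i for i, s in enumerate(self.species)}
        reporters = [s.id for s in self.species if s.is_reporter]
        if len(reporters) != 1:
            raise ValueError(f"{self.name}: expected exactly one reporter species")
        self.reporter = reporters[0]
        self.reporter_index = self._species_index[self.reporter]

        self.mutable_reactions = tuple(r for r in self.reactions if r.mutable)
        self.relaxation_reactions = tuple(r for r in self.reactions if not r.mutable)
        self.mutable_ids = tuple(r.id for r in self.mutable_reactions)
        covered = set().union(*self.protein_map.values()) if self.protein_map else set()
        if set(self.mutable_ids) - covered:
            raise ValueError(f"{self.name}: protein_map does not cover all mutable reactions")

        n_sp, n_rx = len(self.species), len(self.reactions)
        stoich = np.zeros((n_sp, n_rx))
        factors: list[tuple[int, ...]] = []
        for j, rx in enumerate(self.reactions):
            fac: list[int] = []
            for sid, st in rx.reactants:
                si = self._species_index[sid]
                stoich[si, j] -= st
                fac.extend([si] * st)
            for sid, st in rx.products:
                stoich[self._species_index[sid], j] += st
            for sid in rx.modifiers:
                fac.append(self._species_index[sid])
            factors.append(tuple(fac))
        self._stoich = stoich
        self._factors = tuple(factors)
        self._mutable_cols = np.array(
            [j for j, r in enumerate(self.reactions) if r.mutable], dtype=int
        )
        self._relax_cols = np.array(
            [j for j, r in enumerate(self.reactions) if not r.mutable], dtype=int
        )

        groups: dict[str, list[tuple[int, int]]] = {}
        for i, s in enumerate(self.species):
            if s.conserved_group is not None:
                groups.setdefault(s.conserved_group, []).append((i, s.conserved_weight))
        self.conserved_groups = {g: tuple(m) for g, m in groups.items()}

    @property
    def n_mutable(self) -> int:
        return len(self.mutable_reactions)

    def rate_vector(
        self, params: ParameterSample, rate_multipliers: np.ndarray | None = None
    ) -> np.ndarray:
        """Full per-reaction rate-constant vector, with mutation multipliers applied."""
        mut = np.asarray(params.mutable_rates, dtype=float)
        rel = np.asarray(params.relaxation_rates, dtype=float)
        if mut.shape != (self.n_mutable,) or rel.shape != (len(self._relax_cols),):
            raise ValueError(f"{self.name}: parameter dimensions do not match network")
        if rate_multipliers is not None:
            m = np.asarray(rate_multipliers, dtype=float)
            if m.shape != (self.n_mutable,):
                raise ValueError("rate_multipliers length must equal the mutable count")
            if np.any(m <= 0):
                raise ValueError("rate multipliers must be positive")
            mut = mut * m
        k = np.empty(len(self.reactions))
        k[self._mutable_cols] = mut
        k[self._relax_cols] = rel
        return k

    def rhs(self, k: np.ndarray):
        """Return ``f(y, t)`` computing dy/dt for rate constants ``k``."""
        factors = self._factors
        stoich = self._stoich

        def f(y, t=0.0):
            rates = k.copy()
            for j, fac in enumerate(factors):
                for si in fac:
                    rates[j] *= y[si]
            return stoich @ rates

        return f

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "name": self.name,
            "annotation": {"bp_length": self.bp_length, "gene_count": self.gene_count},
            "species": [
                {
                    "id": s.id,
                    "description": s.description,
                    "is_reporter": s.is_reporter,
                    "conserved_group": s.conserved_group,
                    "conserved_weight": s.conserved_weight,
                }
                for s in self.species
            ],
            "reactions": [
                {
                    "id": r.id,
                    "reactants": [list(x) for x in r.reactants],
                    "products": [list(x) for x in r.products],
                    "modifiers": list(r.modifiers),
                    "mutable": r.mutable,
                    "rate_symbol": r.rate_symbol,
                }
                for r in self.reactions
            ],
            "protein_map": {p: sorted(v) for p, v in self.protein_map.items()},
            "pools": [list(p) for p in self.pools],
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ReactionNetwork":
        doc = json.loads(text)
        species = [SpeciesDef(**s) for s in doc["species"]]
        reactions = [
            ReactionDef(
                id=r["id"],
                reactants=tuple((sid, int(st)) for sid, st in r["reactants"]),
                products=tuple((sid, int(st)) for sid, st in r["products"]),
                modifiers=tuple(r["modifiers"]),
                mutable=r["mutable"],
                rate_symbol=r["rate_symbol"],
            )
            for r in doc["reactions"]
        ]
        return cls(
            name=doc["name"],
            species=species,
            reactions=reactions,
            protein_map=doc["protein_map"],
            bp_length=doc["annotation"]["bp_length"],
            gene_count=doc["annotation"]["gene_count"],
            pools=[tuple(p) for p in doc["pools"]],
        )

    @property
    def annotation(self) -> tuple[int, int]:
        return (self.bp_length, self.gene_count)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<ReactionNetwork {self.name}: {len(self.species)} species, "
            f"{self.n_mutable} mutable reactions, reporter {self.reporter}>"
        )


# ---------------------------------------------------------------------------
# canonical pathway definitions
# ---------------------------------------------------------------------------

def _wsp() -> ReactionNetwork:
    # A/Am: unmethylated/methylated WspA signalling complex; S: active
    # signalling state; E/Ep: WspE kinase and its phosphorylated form;
    # R/Rp: WspR and active (phosphorylated) WspR; F/Fp: WspF and active WspF.
    species = [
        SpeciesDef("A", "unmethylated WspA complex", conserved_group="WspA"),
        SpeciesDef("Am", "methylated WspA complex", conserved_group="WspA"),
        SpeciesDef("S", "active signalling state"),
        SpeciesDef("E", "WspE kinase", conserved_group="WspE"),
        SpeciesDef("Ep", "phosphorylated WspE", conserved_group="WspE"),
        SpeciesDef("R", "WspR diguanylate cyclase", conserved_group="WspR"),
        SpeciesDef("Rp", "activated (phosphorylated) WspR", is_reporter=True,
                   conserved_group="WspR"),
        SpeciesDef("F", "WspF methylesterase", conserved_group="WspF"),
        SpeciesDef("Fp", "activated (phosphorylated) WspF", conserved_group="WspF"),
    ]
    reactions = [
        ReactionDef("r1", (("A", 1),), (("Am", 1),), mutable=True, rate_symbol="k1"),
        ReactionDef("r2", (("Am", 1),), (("A", 1),), modifiers=("Fp",), mutable=True,
                    rate_symbol="k2"),
        ReactionDef("r3", (), (("S", 1),), modifiers=("Am",), mutable=True,
                    rate_symbol="k3"),
        ReactionDef("r4", (("E", 1),), (("Ep", 1),), modifiers=("S",), mutable=True,
                    rate_symbol="k4"),
        ReactionDef("r5", (("Ep", 1), ("R", 1)), (("E", 1), ("Rp", 1)), mutable=True,
                    rate_symbol="k5"),
        ReactionDef("r6", (("Ep", 1), ("F", 1)), (("E", 1), ("Fp", 1)), mutable=True,
                    rate_symbol="k6"),
        ReactionDef("d1", (("Am", 1),), (("A", 1),), rate_symbol="d1"),
        ReactionDef("d2", (("S", 1),), (), rate_symbol="d2"),
        ReactionDef("d3", (("Ep", 1),), (("E", 1),), rate_symbol="d3"),
        ReactionDef("d4", (("Rp", 1),), (("R", 1),), rate_symbol="d4"),
        ReactionDef("d5", (("Fp", 1),), (("F", 1),), rate_symbol="d5"),
    ]
    protein_map = {
        "WspA": {"r1", "r2", "r3", "r4"},
        "WspB": {"r3", "r4"},
        "WspC": {"r1"},
        "WspD": {"r3", "r4"},
        "WspE": {"r4", "r5", "r6"},
        "WspF": {"r2", "r6"},
        "WspR": {"r5"},
    }
    pools = [("WspA", "A"), ("WspE", "E"), ("WspR", "R"), ("WspF", "F")]
    return ReactionNetwork("Wsp", species, reactions, protein_map,
                           *PATHWAY_ANNOTATION["Wsp"], pools=pools)


def _aws() -> ReactionNetwork:
    # O/Op: inactive/activated AwsO sensor; X: free AwsX negative regulator;
    # OX: AwsO-AwsX sequestration complex; R: free AwsR monomer; XR: inhibited
    # AwsX-AwsR complex; RR: active AwsR dimer (two protomers).
    species = [
        SpeciesDef("O", "inactive AwsO", conserved_group="AwsO"),
        SpeciesDef("Op", "activated AwsO", conserved_group="AwsO"),
        SpeciesDef("X", "free AwsX", conserved_group="AwsX"),
        SpeciesDef("OX", "AwsO-AwsX complex", conserved_group="AwsO"),
        SpeciesDef("R", "free AwsR monomer", conserved_group="AwsR"),
        SpeciesDef("XR", "AwsX-AwsR inhibitory complex", conserved_group="AwsR"),
        SpeciesDef("RR", "active AwsR dimer", is_reporter=True,
                   conserved_group="AwsR", conserved_weight=2),
    ]
    # note: OX and XR each belong to two physical pools; for bookkeeping OX is
    # counted in the AwsO group and XR in the AwsR group, with AwsX
    # conservation holding only approximately.  Only one group per species is
    # tracked, so the AwsX pool seeds free X and is not declared conserved.
    reactions = [
        ReactionDef("r1", (("O", 1),), (("Op", 1),), mutable=True, rate_symbol="k1"),
        ReactionDef("r2", (("Op", 1), ("X", 1)), (("OX", 1),), mutable=True,
                    rate_symbol="k2"),
        ReactionDef("r3", (("X", 1), ("R", 1)), (("XR", 1),), mutable=True,
                    rate_symbol="k3"),
        ReactionDef("r4", (("R", 2),), (("RR", 1),), mutable=True, rate_symbol="k4"),
        ReactionDef("d1", (("Op", 1),), (("O", 1),), rate_symbol="d1"),
        ReactionDef("d2", (("OX", 1),), (("Op", 1), ("X", 1)), rate_symbol="d2"),
        ReactionDef("d3", (("XR", 1),), (("X", 1), ("R", 1)), rate_symbol="d3"),
        ReactionDef("d4", (("RR", 1),), (("R", 2),), rate_symbol="d4"),
    ]
    protein_map = {
        "AwsO": {"r1", "r2"},
        "AwsX": {"r2", "r3"},
        "AwsR": {"r3", "r4"},
    }
    pools = [("AwsO", "O"), ("AwsX", "X"), ("AwsR", "R")]
    net = ReactionNetwork("Aws", species, reactions, protein_map,
                          *PATHWAY_ANNOTATION["Aws"], pools=pools)
    # AwsX mass is shared across groups; drop it from strict conservation checks
    net.conserved_groups = {g: m for g, m in net.conserved_groups.items() if g != "AwsX"}
    return net


def _mws() -> ReactionNetwork:
    # M: MwsR with inactive DGC; Dp: active DGC state.  Open system with
    # constitutive production of M and first-order degradation of both forms.
    species = [
        SpeciesDef("M", "MwsR, inactive DGC state"),
        SpeciesDef("Dp", "MwsR, active DGC state", is_reporter=True),
    ]
    reactions = [
        ReactionDef("r1", (("M", 1),), (("Dp", 1),), mutable=True, rate_symbol="k1"),
        ReactionDef("r2", (("Dp", 1),), (("M", 1),), mutable=True, rate_symbol="k2"),
        ReactionDef("r3", (), (("M", 1),), mutable=True, rate_symbol="k3"),
        ReactionDef("d1", (("M", 1),), (), rate_symbol="d1"),
        ReactionDef("d2", (("Dp", 1),), (), rate_symbol="d2"),
    ]
    protein_map = {"MwsR": {"r1", "r2", "r3"}}
    pools = [("MwsR", "M")]
    return ReactionNetwork("Mws", species, reactions, protein_map,
                           *PATHWAY_ANNOTATION["Mws"], pools=pools)


_BUILDERS = {"Wsp": _wsp, "Aws": _aws, "Mws": _mws}


def build_pathway(name: str) -> ReactionNetwork:
    """Build the canonical reaction network for one pathway.

    Parameters
    ----------
    name : {"Wsp", "Aws", "Mws"}
    """
    try:
        builder = _BUILDERS[name]
    except KeyError:
        raise ValueError(
            f"unknown pathway {name!r}; valid pathways are {', '.join(PATHWAY_NAMES)}"
        ) from None
    return builder()


# ---------------------------------------------------------------------------
# sampling, integration, classification
# ---------------------------------------------------------------------------

def sample_parameters(
    network: ReactionNetwork,
    rng: np.random.Generator | int | None = None,
    rate_range: tuple[float, float] = (-2.0, 2.0),
    conc_range: tuple[float, float] = (0.0, 10.0),
) -> ParameterSample:
    """Draw a random parameter set.

    Rate constants (mutable and relaxation alike) are drawn log-uniformly as
    ``10**U[rate_range]``; pool totals / initial concentrations uniformly from
    ``conc_range``.
    """
    seed = rng if isinstance(rng, int) else None
    rng = np.random.default_rng(rng)
    mut = 10.0 ** rng.uniform(*rate_range, size=network.n_mutable)
    rel = 10.0 ** rng.uniform(*rate_range, size=len(network.relaxation_reactions))
    totals = rng.uniform(*conc_range, size=len(network.pools))
    return ParameterSample(mut, rel, totals, seed=seed)


def initial_state(network: ReactionNetwork, totals: np.ndarray) -> np.ndarray:
    """All mass starts in the inactive/free forms named by ``network.pools``."""
    totals = np.asarray(totals, dtype=float)
    if totals.shape != (len(network.pools),):
        raise ValueError("totals length must equal the number of pools")
    if np.any(totals < 0):
        raise ValueError("pool totals must be non-negative")
    y0 = np.zeros(len(network.species))
    for (label, sid), tot in zip(network.pools, totals):
        y0[network._species_index[sid]] = tot
    return y0


_NEG_TOL = 1e-6


def _odeint_step(f, y, t0, t1):
    """One integration segment; returns (state, ok)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out, info = odeint(
            f, y, [t0, t1], rtol=1e-6, atol=1e-9, mxstep=10000, full_output=True
        )
    ok = info["message"] == "Integration successful."
    return out[-1], ok


def _check_negativity(y, network):
    if np.min(y) < -_NEG_TOL:
        raise IntegrationError(
            f"{network.name}: negative concentration beyond solver tolerance "
            f"(min {np.min(y):.3g})"
        )


def integrate_to_steady_state(
    network: ReactionNetwork,
    params: ParameterSample,
    rate_multipliers: np.ndarray | None = None,
    horizon: float = 1e5,
    ss_rtol: float = 1e-6,
) -> SteadyStateResult:
    """Integrate the mass-action ODEs until steady state (or ``horizon``).

    Steady state is declared at the first point of a logarithmic time grid
    where ``max|dy/dt| < ss_rtol * (1 + max|y|)``.  A result with
    ``converged=False`` is returned when the criterion is not met within the
    horizon or the integrator fails; callers sampling parameters discard such
    draws.
    """
    k = network.rate_vector(params, rate_multipliers)
    f = network.rhs(k)
    y = initial_state(network, params.totals)

    def _settled(y, t):
        dy = f(y, t)
        return np.max(np.abs(dy)) < ss_rtol * (1.0 + np.max(np.abs(y)))

    if _settled(y, 0.0):
        return SteadyStateResult(y, 0.0, float(y[network.reporter_index]), True)

    n_grid = int(np.ceil(2 * np.log10(horizon / 1e-2))) + 1
    grid = np.geomspace(1e-2, horizon, n_grid)
    t_prev = 0.0
    for t in grid:
        y, ok = _odeint_step(f, y, t_prev, t)
        if not ok:
            return SteadyStateResult(y, t, float(y[network.reporter_index]), False)
        _check_negativity(y, network)
        np.clip(y, 0.0, None, out=y)
        if _settled(y, t):
            return SteadyStateResult(y, float(t), float(y[network.reporter_index]), True)
        t_prev = t
    return SteadyStateResult(y, float(horizon), float(y[network.reporter_index]), False)


def simulate_for(
    network: ReactionNetwork,
    params: ParameterSample,
    rate_multipliers: np.ndarray | None,
    duration: float,
) -> np.ndarray | None:
    """Integrate for a fixed duration from the standard initial condition.

    Returns the final state, or ``None`` when the integrator fails.  Used to
    run a mutated system for exactly the time its baseline took to settle.
    """
    k = network.rate_vector(params, rate_multipliers)
    f = network.rhs(k)
    y = initial_state(network, params.totals)
    if duration <= 0:
        return y
    y, ok = _odeint_step(f, y, 0.0, duration)
    if not ok:
        return None
    _check_negativity(y, network)
    np.clip(y, 0.0, None, out=y)
    return y


def classify_reactions(
    network: ReactionNetwork,
    n_probe_samples: int = 100,
    seed: int | None = 0,
    probe_factor: float = 10.0,
    rate_range: tuple[float, float] = (-2.0, 2.0),
    conc_range: tuple[float, float] = (0.0, 10.0),
    threshold: float = 1.0 + 1e-9,
) -> tuple[set[str], set[str]]:
    """Classify each mutable reaction as enabling or disabling.

    For every mutable reaction the steady-state reporter is probed under a
    ``probe_factor``-fold increase and decrease of its rate constant across
    ``n_probe_samples`` random parameter draws.  A reaction is *enabling* when
    increasing its rate raises the reporter in a majority of draws and
    *disabling* when decreasing it does; when both directions clear a
    majority, the direction with the larger count wins.

    ``threshold`` is the relative factor the perturbed reporter must exceed;
    the default is a strict increase up to integrator noise — even a 10-fold
    rate change can shift the reporter only marginally when a relaxation
    reaction dominates the perturbed one.
    """
    if n_probe_samples < 1:
        raise ValueError("n_probe_samples must be >= 1")
    rng = np.random.default_rng(seed)
    n = network.n_mutable
    up_wins = np.zeros(n, dtype=int)
    down_wins = np.zeros(n, dtype=int)
    n_used = 0
    for _ in range(n_probe_samples):
        params = sample_parameters(network, rng, rate_range, conc_range)
        base = integrate_to_steady_state(network, params)
        if not base.converged:
            continue
        n_used += 1
        ref = threshold * base.reporter_level + 1e-12
        for j in range(n):
            for direction, wins in ((probe_factor, up_wins), (1.0 / probe_factor, down_wins)):
                mult = np.ones(n)
                mult[j] = direction
                res = integrate_to_steady_state(network, params, mult)
                if res.converged and res.reporter_level > ref:
                    wins[j] += 1
    if n_used == 0:
        raise ClassificationError(f"{network.name}: no parameter draw converged")

    enabling: set[str] = set()
    disabling: set[str] = set()
    ambiguous: list[str] = []
    for j, rid in enumerate(network.mutable_ids):
        up_major = up_wins[j] > n_used / 2
        down_major = down_wins[j] > n_used / 2
        if up_major and (not down_major or up_wins[j] > down_wins[j]):
            enabling.add(rid)
        elif down_major and (not up_major or down_wins[j] > up_wins[j]):
            disabling.add(rid)
        else:
            ambiguous.append(rid)
    if ambiguous:
        raise ClassificationError(
            f"{network.name}: ambiguous classification for {', '.join(ambiguous)} "
            f"(up wins {up_wins.tolist()}, down wins {down_wins.tolist()}, "
            f"n={n_used})"
        )
    return enabling, disabling
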