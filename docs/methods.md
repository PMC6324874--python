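# Methods

This note documents the models, the numerical choices and the design
decisions behind `wsforecast`, and what the synthetic-data-based tests do
and do not establish.

## Pathway models

Each of the three WS pathways is a small mass-action ODE system with a
designated *reporter* species — the activated diguanylate cyclase whose
increase defines a wrinkly spreader.  The reaction structure is a canonical
reconstruction from the pathways' known biology; it is normative for this
package (equivalent published equation systems live in supplementary
material that is not machine-readable, and no token-level match is
attempted).

**Wsp** (reporter: phosphorylated WspR, `Rp`).  Mutable reactions:
r1 methylation A→Am; r2 demethylation Am→A catalysed by active WspF (`Fp`
as modifier); r3 production of the active signalling state S at rate
r3·[Am]; r4 phosphorylation E→Ep with S as modifier; r5 phosphotransfer
Ep+R→E+Rp; r6 phosphotransfer Ep+F→E+Fp.

**Aws** (reporter: AwsR dimer `RR`).  r1 activation O→Op; r2 sequestration
Op+X→OX; r3 inhibition X+R→XR; r4 dimerisation 2R→RR with elementary rate
r4·[R]² (the simplest law consistent with dimer formation).

**Mws** (reporter: active DGC state `Dp`).  r1 activation M→Dp; r2
deactivation Dp→M; r3 constitutive production ∅→M.  The identity of the
third reaction is fixed by the requirement of one disabling and two
enabling reactions for this pathway.

Every activation/binding product has a first-order **non-mutable
relaxation** back to its source (degradation for the open Mws system).
Relaxation constants are drawn from the same 10^U[−2,2] distribution as the
mutable rates but are never multiplied by mutation effects.  This
guarantees non-degenerate steady states and reproduces the published
enabling/disabling structure by construction.  Protein pools (WspA, WspE,
WspR, WspF; AwsO, AwsR) are conserved; AwsX mass is shared between two
complexes and is therefore not tracked as a strict invariant.

### Integration and steady state

Initial conditions place all conserved mass in the inactive/free forms
(Mws starts at M = total, Dp = 0); totals are the sampled "initial
concentrations" U[0,10].  Integration uses LSODA (stiff-safe; rate
constants span four orders of magnitude) with rtol 1e−6 / atol 1e−9.
Steady state is declared at the first point of a logarithmic time grid
(two points per decade, 1e−2 to the horizon, default 1e5) where
`max|dy/dt| < 1e−6 · (1 + max|y|)` — scale-free and cheap.  Draws that do
not settle within the horizon are flagged and discarded by the samplers;
concentrations below −1e−6 raise an error, smaller negative excursions are
clipped to zero.

### Reaction classification

A mutable reaction is *enabling* when a 10-fold rate increase raises the
steady-state reporter in a majority of random parameter draws, *disabling*
when a 10-fold decrease does.  The comparison is a strict increase (up to
integrator noise) rather than a fixed percentage: when a relaxation rate
dominates the perturbed reaction, even a 10-fold change moves the reporter
by far less than 0.1%, yet the direction is still informative.  With 60–100
probe draws the classification is stable across seeds and reproduces
2+4 (Wsp), 1+3 (Aws), 1+2 (Mws) disabling+enabling reactions.

## Model IV

Mutation vectors m ∈ {−1,0,+1}ⁿ are enumerated exhaustively (3ⁿ including
the all-zero baseline).  A vector is **admissible** when some single
protein of the pathway participates in every altered reaction — the
formalization of "requires mutations in two separate genetic components";
the two published Wsp counterexamples (r3 with r5, r3 with r6) fall out of
this rule.  Admissible non-baseline vectors number 108 (Wsp), 20 (Aws) and
26 (Mws).  Inadmissible vectors keep their prior mass but contribute zero
WS probability; priors are *not* renormalized over admissible vectors.

The conditional P(WS | m) is estimated with **common random numbers**: one
set of parameter draws (default 1000; the published procedure stabilizes by
500) is shared by all vectors of a pathway, so ratios between vectors and
pathways are far less noisy than independent sampling at the same cost.
For each converged baseline the mutated system is integrated for exactly
the time t_ss the baseline took to settle, from the same initial condition,
and the draw counts as WS when the mutated reporter exceeds
1.001 × the baseline reporter (the small margin suppresses integrator
noise; the published criterion is simply "increased").  Effect multipliers
are drawn independently per mutated reaction, per draw and per vector;
effect randomness is seeded from (config seed, vector), so results are
bit-reproducible and independent of evaluation order.  A run errors out
when more than 10% of draws are unusable.

Hotspots multiply both p_e and p_d of the flagged reactions in the prior
(the awsX hotspot touches Aws r2 and r3).  The sensitivity suite repeats
the posterior under three perturbed regimes — concentrations U[0,50], rates
10^U[−3,3], and compressed effect sizes 10^U[−1,1] (read as enabling
10^U[0,1], disabling 10^U[−1,0]) — and tabulates the pathway ratios.

### Known deviation

Under this reconstruction the Mws posterior ties with Aws at the
disabling-dominant prior extreme (Mws/Aws ≈ 1.0; ≈ 0.91 at the mirror
extreme) instead of falling to 0.4–0.5: the two-species linear Mws model
responds to essentially every correctly-signed rate change, so its
conditional probabilities are near 1.  The robust statements — Wsp ranks
above both other pathways without a hotspot, a five-fold awsX hotspot
lifts Aws above Wsp, and Wsp/Aws ≈ 1.4–1.6 — are what the acceptance tests
assert; the Aws-over-Mws ordering is asserted separately and documented as
failing at one extreme.

## Fluctuation-test estimation

The Luria–Delbrück pmf uses the Lea–Coulson recursion
p₀ = e^(−m), p_r = (m/r) Σ_{i<r} p_i/(r−i+1) — equivalently a compound
Poisson(m) of clone sizes with P(size = k) = 1/(k(k+1)) — assuming
deterministic growth, no mutant death or phenotypic lag, and complete
plating.  The MLE maximizes the multinomial log-likelihood by bounded
scalar optimization; counts above 150 are pooled into a survivor-probability
tail class so jackpot cultures do not dominate the recursion.  Confidence
intervals use Stewart's log-normal approximation
σ_ln m = 1.225 m^(−0.315)/√C.  Two estimates are compared by a normal test
on ln m; the result carries a caveat flag when final population sizes
differ by more than 10%, where the test's validity is not established.
Note the truncated pmf mass is ~m/(r_max+1) — the heavy tail means
"normalization" checks must account for it analytically.

## Spectrum and fitness analyses

The hotspot resampling null draws N mutations (N = pathway total)
uniformly over the K distinct observed mutation types — the observed-types
null, since the true target set of all possible WS mutations is unknown —
and asks how often the maximum multiplicity reaches the observed one; zero
hits are reported as the rule-of-three bound 3/n_reps.  Rate-adjusted
fractions weight each pathway by its measured mutation rate with the sum
of the three pathway rates (10.94 ×10⁻⁹) as denominator; this reproduces
the published 29%/13% hotspot shares exactly, whereas the wild-type rate
(11.2 ×10⁻⁹) would not.  Selection-vs-no-selection comparisons use
two-sided Fisher exact tests per category with Benjamini–Hochberg
q-values; the published analysis reports no formal test, so the correction
is this package's policy.

Selection coefficients are per generation, s = ln(R(t)/R(0))/t, with
generations from viable counts; marker cost is removed by subtracting the
isogenic marked-vs-unmarked control coefficient, and competitions with >5%
smooth revertant colonies are excluded.  No Malthusian/Wrightian
conversion is offered.

## Synthetic data

The generators emulate the study conditions: fluctuation assays default to
60 cultures (200/200/400 in the bundled "study-shaped" dataset) founded by
~10² cells and grown to N_t = 5×10⁷ — chosen so the expected mutations per
well stay below 0.5 at rates near 10⁻⁹, the regime where mutant-fitness
bias is negligible; spectra are multinomial over a site table whose
hotspot weights mirror the observed 20/41 and 9/41 multiplicities;
competitions run 8 generations with multiplicative log-normal ratio noise
(σ = 0.02) and a small marker-cost offset.  The Lea–Coulson clone-size
sampler (⌊1/U⌋, capped at N_t) matches the estimator's assumptions by
construction; a discrete per-generation binomial simulator provides an
independent cross-check.

Because generator and estimator share their model assumptions, passing
recovery tests demonstrates internal consistency — correct implementation
of both — not robustness to real-data violations (phenotypic lag, partial
plating, mutant-fitness differences, non-exponential growth), which are
out of scope.

## Problem sizes

Default analyses use 200 shared parameter draws per pathway for Model IV
(the published runs used 1000; ratios are stable from a few hundred draws
under common random numbers), 100 probe draws per reaction classification,
10⁶ resampling replicates for the hotspot test (the published analysis
used 10⁷; the conclusion is a zero-hit bound either way), and 200
synthetic assays for estimator-recovery checks.
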