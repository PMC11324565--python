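# Methods

This note documents the models, conventions and numerical choices behind
`pcbdechlor`, in the order the pipeline uses them.

## Congener space and numbering

A PCB congener is a biphenyl with 1–10 chlorines on ring positions 2–6
and 2′–6′. Two substitution patterns are the same compound when related
by the molecule's symmetry group: swap the rings, or flip either ring
about its 1–4 axis (2↔6, 3↔5) — eight images in total. Each congener is
stored as the lexicographically minimal image, which makes equality,
hashing and reaction products well defined. Enumerating orbits of the
2¹⁰ substitution patterns gives the familiar homolog counts
3/12/24/42/46/42/24/12/3/1 (mono→deca), 209 congeners in all; the test
suite re-derives these with an independent brute-force orbit oracle.

Ballschmiter–Zell (BZ) numbers are assigned algorithmically: congeners
sort by chlorine count, then by the locant sequence of their IUPAC-style
name. The name assigns the unprimed ring to the more substituted ring
(ties broken by the lower locant set), and locant sequences compare
elementwise with an unprimed locant ranking below its primed twin — the
rule that puts PCB33 (2′,3,4) after PCB32 (2,4′,6) and PCB122
(2′,3,3′,4,5) after PCB114. The accepted numbering deviates from this
strict ordering only in two historically irregular regions, which a
six-entry override table pins to the literature values: 107–109 (107
and 108 are swapped relative to the strict rule) and 199–201. The table
is validated against 26 published anchor assignments, including every
congener the dechlorination analyses below refer to.

Ortho positions are {2, 6} and their primes, meta {3, 5}, para {4}.
Molecular weights use fixed constants (biphenyl 154.21 g/mol, Cl 35.45,
H 1.008), so each chlorine adds 34.44 g/mol; these are documented
constants, not parameters.

## Dechlorination metrics

All metrics operate on mole-percent congener profiles. Profiles whose
entries sum to 100 ± 0.5 are renormalized to exactly 100 (GC–MS tables
carry rounding drift); larger deviations are hard errors. Congeners
absent from a profile are exact zeros — "not detected", not missing.

* **Average chlorines per biphenyl**: Σ_c x_c·n_Cl(c) with x_c the mole
  fraction. Its decline is the extent of dechlorination.
* **Homolog distribution**: mole percent binned by chlorine count
  (11 bins, conserving the 100% total).
* **Molar concentration**: mass concentration (default 25 mg/L) divided
  by the mole-fraction-weighted mean molecular weight of a reference
  profile, ×1000 → μM. The reference is the profile at the start of the
  metric window. The source data never states its conversion basis;
  this convention is reproducible and consistent across windows (e.g. a
  6.34-Cl mixture at 25 mg/L is 67.1 μM).
* **Dechlorination rate**: (ClAvg(t₀) − ClAvg(t₁)) × molar concentration
  / (t₁ − t₀), in μM Cl⁻ d⁻¹. Fold changes are plain rate ratios.
* **Positional removal**: per class p ∈ {ortho, meta, para}, the
  inventory N_p(t) = Σ_c x_c(t)·n_p(c) and the removal fraction
  1 − N_p(t)/N_p(t₀). A class absent at t₀ is flagged not-applicable
  (None) rather than 0/0. The positional deltas recombine exactly:
  ΔClAvg = ΣΔN_p.

Command-line output rounds rates and fold changes to 2 decimals,
matching how such results are conventionally reported; machine output
(JSON/CSV) keeps full precision.

## Reaction network and process classification

Single-chlorine removal induces a DAG over the 209 congeners plus
biphenyl: one edge per distinct (canonical product, position class),
annotated with the chlorophenyl group of the attacked ring (digit
shorthand such as "245", stored flip-minimal so "256" ≡ "236"), the
removed position, its flanking context (a chlorine is flanked by
chlorines at ring-adjacent positions along 2-3-4-5-6; the ring bond at
position 1 never flanks), and a multiplicity counting
symmetry-equivalent chlorines (PCB153 loses either of two equivalent
meta chlorines to form PCB99, multiplicity 2).

Reachability questions ("can PCB153 yield PCB47 by meta removals
alone?") are breadth-first searches over the network restricted to an
allowed position set; the tests check them against exhaustive path
enumeration. Under a meta-only restriction the terminal (zero
out-degree) congeners reachable from the common hexa/hepta Aroclor 1260
parents all have n_meta = 0 — the network-level counterpart of
tetrachlorobiphenyls being terminal dechlorination products. Note that
two of the commonly cited parents (PCB110 and PCB158) cannot reach any
of PCB47/49/51/53 by meta/para removals at all: both carry their two
ortho chlorines on one ring, while all four tetra products have
2,2′-type patterns, and meta/para removal cannot rearrange ortho
chlorines. The package reports such per-parent facts rather than
asserting any fixed parent list.

Named dechlorination processes are configuration, not code constants:
a `ProcessRule` is a process name plus a set of (chlorophenyl group,
attacked position) pairs. The default table encodes process N as
flanked-meta removal from groups 236/245/2345/2356 and process H/H′ as
para removal from 234/245/2345, the groups classically associated with
those specificities; because group→position assignments vary in the
primary literature, rules are fully overridable from a YAML mapping.

## Kinetic simulator

The synthetic time-course generator emulates congener tables from an
Aroclor 1260-like culture:

* **Starting mixture** (`pseudo_aroclor`): supported on 46 tetra–octa
  congeners prominent in Aroclor 1260 and its dechlorination series,
  with Dirichlet-random weights (homolog prior ≈ tetra 1% / penta 10% /
  hexa 45% / hepta 33% / octa 11%, terminal tetra products held at
  trace level) exponentially tilted in chlorine count so the average
  chlorines per biphenyl hits the requested target (6.34 or 6.4 in the
  study conditions) to < 0.01. Deterministic for a given seed.
* **Dynamics**: first-order kinetics dx/dt = Kx on the reaction
  network. Each edge's rate is base_rate(position class) ×
  process multipliers × multiplicity. Defaults (meta 0.02 d⁻¹, para
  0.004 d⁻¹, ortho 0, lag 15 d) are chosen to qualitatively reproduce
  observed Aroclor 1260 enrichment behaviour — a lag phase, meta-
  dominated removal, tetra/penta accumulation on a 100-day horizon —
  and are not fitted to any measured values.
* **Lag**: a hard delay (K = 0 for t < lag). Cultures show a lag while
  dehalogenator populations grow; the generator does not model growth.
* **Solution**: the state is augmented with one cumulative-chloride
  counter per reaction (the time integral of k_r × parent occupancy)
  and the whole linear system is solved with a matrix exponential, so
  mole conservation, the closed-form exp(−2kt) decay of a pure
  symmetric congener, and the ledger identity ΔClAvg = Σ_r ledger_r
  hold to solver precision (~1e-15, tested at 1e-9/1e-6). The ledger is
  the independent oracle for the rate metrics.
* **Observation model**: multiplicative lognormal noise (σ
  configurable, seed mandatory when σ > 0) and a detection limit
  (default 0.05 mole %, zero-and-renormalize) are applied at
  observation times only — measurement noise, not process noise.

Noise-free trajectories are monotone (average chlorines and every
positional inventory non-increasing), and the generating
meta > para > ortho rate ordering is recoverable from the positional
removal fractions of a single window.

## Abundance generator

The 16S stand-in produces samples × taxa relative abundances. Marginals
are lognormal with per-taxon μ ~ N(0, 1²) and σ ~ U(0.5, 1.5), giving
genus-like spreads over a few orders of magnitude; rows are closed to
sum to 1. Correlated taxon blocks are planted through a Gaussian
copula: block taxa share a latent factor with loading √ρ_lat where
ρ_lat = 2·sin(π·ρ_S/6) converts the target Spearman ρ_S to the latent
Pearson correlation; because the lognormal transform is monotone, rank
correlations survive exactly. Per-taxon ±1 signs plant negative pairs.
Group effects are multiplicative shifts applied before closure. The
default layout is four treatment groups × three replicates.

Closure is not innocuous: dividing by the row sum couples all taxa, and
the more the total is dominated by a few taxa, the more spurious
correlation it induces. With the default μ spread the null generator
(no planted blocks, 24 samples, 120 taxa) yields ≈ 5.7% of pairs
significant at p < 0.05 — near nominal, the excess being the closure
effect. Widening the dominance (μ ~ N(0, 2²)) inflates this to ≈ 9%
with no planted structure at all. This is a known property of
correlation networks on compositional data, and a caveat to carry over
to real tables, which are often more dominated than the generator's
default.

## Co-occurrence networks

The network stage reproduces the standard Gephi-style workflow: filter
taxa by relative abundance (default mean > 0.01% across all samples;
max available as an option), compute pairwise Spearman correlations
with midranks, keep pairs with |r| > 0.7 and p < 0.05. No
multiple-testing correction is applied by default, matching common
practice for these figures; Benjamini–Hochberg is available by flag.
p-values use the t approximation for n > 10 and an exhaustive
permutation null for n ≤ 10, where the approximation is unreliable
(the permutation p has floor 1/n! and is checked against a brute-force
oracle in the tests).

Nodes are taxa with at least one retained edge. Topology metrics: node
and edge counts, positive-edge ratio, average degree, density, average
clustering coefficient, modularity and community count from
deterministic greedy modularity optimization (community *labels* are
algorithm-dependent across tools; the modularity *value* is the
reproducible quantity), number of connected components, and diameter
and average path length on the largest component (the convention most
network tools use, though rarely stated). Nodes are sorted before
community detection so all metrics are invariant to taxon ordering.

## Pipeline and reproducibility

The `pcbdechlor` CLI exposes `enumerate`, `metrics`, `pathways`,
`simulate`, `simulate-abundances`, `network` and a config-driven `run`
that chains stages and writes a JSON report embedding the package
version, the seed and a hash of the effective configuration. All
randomness flows from a single top-level seed; identical config + seed
gives byte-identical reports. Exit codes: 0 success, 2 validation
error, 3 data error.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on generated
data: the full 209-congener network (840 edges), kinetic simulations
over 46-congener starting mixtures on a 112-day grid, abundance tables
of 120 taxa × 24 samples, 200 replicates for the null-calibration
check, and exhaustive 6!-permutation oracles on a 6-sample fixture.

## Known limitations

* The simulator's rate constants are qualitative; the package makes no
  claim that its default kinetics reproduce any measured rate, only
  the structural behaviours listed above.
* First-order kinetics ignore microbial growth, substrate inhibition
  and congener-specific enzyme affinities; the lag is a hard switch.
* The abundance generator plants rank correlation but not the sparsity,
  overdispersion or sequencing-depth artefacts of real amplicon data;
  passing network tests demonstrate correctness of the statistics, not
  robustness to those artefacts.
* Raw Spearman networks on compositional data inherit closure-induced
  correlation (quantified above); interpreting edges as ecological
  interactions requires the same caution as in any such analysis.
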