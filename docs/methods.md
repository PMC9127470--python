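# Methods

## Scope

`bmpscreen` analyzes combinatorial ligand screens for the BMP pathway: all
pairs of a ligand panel are applied across a sweep of concentration ratios to
a reporter cell line, and the package quantifies each pair's interaction,
groups ligands into functional equivalence classes, and explains the observed
behavior with a competitive ligand–receptor equilibrium model.  A synthetic
screen generator produces the full measurement tables from a known ground
truth, so every stage is testable end to end without external data.

## Screen design

A panel of N ligands yields 2N + N(N−1)/2 condition rows: N single-ligand
gradients, N self-pairs (a ligand combined with itself — the built-in control
for saturated additivity), and all N(N−1)/2 distinct pairs.  Each row holds a
zero-dose control plus R dose pairs (default R = 9).  The ratio sweep uses a
trapezoid scheme: for the first ⌈R/2⌉ positions ligand A is held at its top
(saturating) dose while B climbs a geometric dilution ladder from zero to its
top dose; the remaining positions mirror this with B at top.  The center
position has both ligands at top dose, every position keeps at least one
ligand saturating, and the scheme is symmetric under exchanging the two
ligands (swap doses, reverse order).  Gradient rows reuse the same dilution
ladders, so every dose on the saturated flank of a pair row has a matching
single-ligand measurement — this is what lets the interaction stage look up
its single-ligand references exactly.

## Interaction Coefficient

Drug-interaction scales (Loewe, Bliss) assume an additive null that does not
transfer to two ligands feeding one saturable pathway: the non-interacting
expectation spans everything from the stronger individual response (when both
saturate) to the sum of the individual responses (in the linear regime).  The
Interaction Coefficient (IC) therefore places the combined response f(A+B)
against three references — the weaker individual response f(A), the stronger
f(B), and their sum — and normalizes within each regime:

    IC = f(A+B) / (f(A)+f(B))        if f(A+B) ≥ f(A)+f(B)
    IC = f(A+B) / f(B) − 1           if f(A) ≤ f(A+B) < f(A)+f(B)
    IC = f(A+B) / f(A) − 2           if f(A+B) < f(A)

with f(B) ≥ f(A) ≥ 0 by relabeling (negative background-subtracted medians
are clipped to zero first).  IC = 0 is saturated additivity, (0, 1] additive,
1 exact linear additivity, > 1 synergy, [−1, 0) antagonism, and [−2, −1)
suppression (combination weaker than both individual responses).  The scale
is dimensionless, invariant under a global rescaling of responses, and
symmetric in the two ligand labels.  The middle and lower branches meet
discontinuously at f(A+B) = f(A); this is inherited from the definition,
which trades continuity for a bounded, interpretable normalization in each
regime.  The degenerate no-signal case f(A) = f(B) = 0 is defined as IC = 0
and flagged.

### Replicate gating

With only 3–4 biological replicates per condition, classical dispersion
statistics are unreliable, so a nonzero IC is *reported* only when the
replicate ranges separate: the f(A+B) range must be disjoint from the f(B)
range by more than a threshold θ, set per cell context to the maximum
background-subtracted signal divided by 30 (≈3% of dynamic range).  Claims in
the outer regimes need stricter evidence — synergy requires separation from
the replicate-paired sums f(A)+f(B), suppression requires separation from
f(A).  When only the weaker claim is supported the reported value is capped
at the boundary of the best-supported regime (exactly 1 for an unsupported
synergy, −1 for an unsupported suppression); the cap keeps the gated value
continuous across the branch boundaries.  With fewer than two replicates in
any set, gating is impossible and the value is 0 with a warning flag.

A pair's summary IC is its largest-magnitude gated value across the ratio
sweep; ties break toward the ratio nearest 1:1 and then toward the negative
value.  Manual overrides — a data file mapping (context, pair) to a forced
category, ratio index, or IC — replace the automatic call and set a flag, for
the rare conditions where a technical artifact defeats automatic
classification.

## Preprocessing

The corrective chain inverts the screen's nuisance structure:

1. wells with fewer than 500 cells are dropped (exactly 500 is kept);
2. the per-plate background — the median of that plate's zero-dose control
   wells — is subtracted (autofluorescence is additive);
3. each plate is rescaled to a reference plate by the closed-form factor
   α = Σx_ref·x_plate / Σx_plate² minimizing least-squares error over shared
   technical-replicate conditions (plate-to-plate incubation-time differences
   act multiplicatively on accumulated reporter signal);
4. each biological replicate is rescaled to a reference replicate by one
   factor computed the same way over all shared conditions.

The reference plate/replicate defaults to the one sharing the most conditions
with the others, ties to the lowest id.  Negative post-subtraction values are
kept through rescaling (clipping would bias the factors) and clipped only
when ICs are computed.  Rescaling is idempotent and scale-equivariant, and
the background choice (per plate rather than global) makes the correction
robust to plate-specific autofluorescence drift.

## Dose–response and ligand strength

Single-ligand gradients are fit jointly over replicates to a Hill function
with the baseline pinned at zero, y = ymax·cⁿ/(EC50ⁿ + cⁿ), with n bounded
[0.1, 10] and EC50 bounded within 100× of the tested dose range.  The fit is
deterministic: a fixed 3×3 grid of (EC50, n) starts refined by bounded least
squares, best local optimum returned.  Ligands with no positive response are
flagged non-activators with ymax = 0 rather than failing.

Relative Ligand Strength (RLS) is the ligand's median top-dose response
divided by the strongest ligand's, clipped to [0, 1].  It deliberately uses
the measured top-dose value rather than the fitted ymax so that ligands whose
dose–response has not saturated at the highest tested dose still get a
defined (if conservative) strength; when a curve is far from saturation the
two conventions diverge and the measured value is the safer summary.

## Equivalence groups

Each ligand's behavior in one context is summarized by N+1 features: its
summary IC with each of the other N−1 ligands, its self-pair IC, and twice
its RLS.  The doubling calibrates the two scales: a Euclidean distance of 1
then corresponds either to a unit IC difference (one full interaction regime)
or to an RLS difference of 0.5 (a strong vs. a weak activator).  Ligands are
clustered agglomeratively with complete linkage; flat groups merge only
strictly below the distance threshold (default 1), so two ligands exactly one
regime apart stay separate.  Groups are then made *monochromatic*: any group
whose members disagree on the interaction category with some ligand outside
the group is split top-down along its linkage subtree until the predicate
holds.

For the cross-context analysis the per-context feature vectors are
concatenated and the tree is cut at a Euclidean distance of 7 (for seven
contexts), without the monochromaticity constraint — a deliberate relaxation
so that no single pairwise call can separate ligands globally.  The threshold
phrasing is ambiguous between a squared-distance and a Euclidean reading; the
package defaults to the literal Euclidean cut at 7 and exposes the threshold
as a parameter, so the alternative (√7) is one argument away.

### Sequence comparison

Mature-ligand amino-acid sequences are aligned progressively (mafft, default
parameters) unless already of equal length.  Over alignment columns with no
gap in any sequence, the similarity s_ij is the summed BLOSUM50 score;
distance is d_ij = 1 − s_ij / min(s_ii, s_jj), which is zero for identical
sequences and grows past 1 for strongly dissimilar ones.  This normalization
is the package's own choice (the self-score denominator makes the distance
scale-free in sequence length).  Sequences are clustered with average
linkage, and the correlation between sequence distance and
interaction-profile distance is the Pearson r over the off-diagonal pairs,
with an optional seeded sweep over random context subsets reporting each
subset's r and the maximum.

## Equilibrium model

The biochemical model is one-step formation of trimeric signaling complexes:
ligand i, Type I receptor j, and Type II receptor k bind with affinity K_ijk
into complex T_ijk, which phosphorylates SMAD with activity ε_ijk.  Ligand is
held at its reservoir concentration; receptors are conserved:

    T_ijk = K_ijk · L_i0 · A_j · B_k
    A_j0  = A_j + Σ_ik T_ijk,   B_k0 = B_k + Σ_ij T_ijk
    S     = Σ_ijk ε_ijk · T_ijk

Pentameric stoichiometry, stepwise assembly, co-receptors, secreted
inhibitors, inhibitory SMADs, and receptor turnover are all outside the
model; competition through the shared, conserved receptor pools is the single
mechanism, and it suffices to produce synergy, antagonism, suppression, and
their context dependence.

### Solver

The conservation relations are solved on the free-receptor variables: a
damped fixed-point sweep (a_j ← A_j0/(1 + Σ_ik K_ijk L_i b_k), likewise for
b_k; damping 0.5 engages only on oscillation) brings the iterate into the
basin of a batched Newton iteration on the full conservation system, which
converges quadratically; environments where Newton misbehaves fall back to
the pure fixed point, and the single-environment API adds a bounded
least-squares root find as a final fallback.  Convergence is declared at
conservation residual < 1e−12 relative to the receptor totals.  Solutions
are validated against an independent kinetic-relaxation oracle
(dT_ijk/dt = k_off(K_ijk L_i a_j b_k − T_ijk), integrated with LSODA until
stationary): on 200 random instances up to 5 ligands × 3 + 3 receptors the
two methods agree to better than 1e−6 relative.  Uniqueness of the
equilibrium is assumed from the relaxation structure rather than proven;
solver disagreement beyond tolerance is treated as a defect.

### Toy model

A packaged 3-ligand (pink, blue, gold), 2×2-receptor parameter set
demonstrates how redistribution among complexes of differing activity
produces context-dependent interactions.  Pink carries a strong silent
black/black complex, an intermediate silent white/black trap, and a weak but
highly active white/white complex; blue is pink without the trap; gold
dominates white/white but signals weakly through it.  Three behaviors follow
by construction and are asserted in tests: (i) knocking down the black
Type I receptor lowers pink's output even though pink signals through a
complex not containing it (the freed black Type II feeds the trap, which
sequesters white Type I); (ii) gold suppresses pink in the wild-type
(combined output below both individual outputs); (iii) pink and blue combine
saturated-additively in the wild-type but antagonistically after the
knockdown.  The numeric values are package constants; only the topology of
strong/weak and active/silent complexes matters, and the suppression margin
is a few percent — a genuine, if delicate, consequence of the competition
structure rather than a tuned display.

## Parameter fitting

Fitting infers K_ijk, ε_ijk, and per-receptor expression rescalings from
processed responses.  Observations (per-condition replicate medians of
single-ligand and pair conditions) and receptor expressions are normalized to
a maximum of 1, which fixes the otherwise arbitrary units; K and ε are
bounded within [1e−4, 1e2] (six orders of magnitude) and optimized in log
space; each receptor's expression carries a free factor ρ ∈ [1/3, 3]
absorbing fold-scale qPCR uncertainty.  The objective is the plain sum of
squared response errors, minimized by bounded least squares with an analytic
Jacobian obtained from the implicit function theorem on the conservation
relations (an adjoint solve per iteration replaces ~130 finite-difference
perturbations).

The residual landscape is multimodal and individual parameters are
generically non-identifiable — a weak ligand's low output can come from low
affinity or low activity — so the fit runs from many random starts (default
50; the scale of the study this emulates used thousands) and solutions are
filtered by *qualitative* agreement: a competitive residual (within 2× the
best) plus correct predicted interaction categories for a named set of hard
pairs.  Recovery is therefore evaluated in behavior space: response R² and
the fraction of planted interaction categories reproduced, never parameter
values.  The affinity–activity correlation across complexes is reported as a
pattern diagnostic.

## Synthetic data generator

The generator is the package's definition of the study conditions.  Defaults:
10 ligands named for the homodimeric BMP family, top doses 100 ng/mL with
3-fold dilution ladders, 9 ratios per row, 4 biological replicates, rows
assigned round-robin to plates of 6 rows (11 plates for 65 rows), and two
receptor contexts (wild-type and a Type I knockdown at 5% expression).
Measurement noise mirrors the corrective chain in reverse: a per-plate
multiplicative factor uniform in [0.9, 1.1] (incubation times of 20–24 h
around a 22 h nominal, with linear reporter accumulation), a per-replicate
factor uniform in [0.8, 1.2], per-well lognormal noise at 5% CV, additive
background ~30 a.u. (σ = 3), and a reporter gain of 300 mapping model output
onto the arbitrary-unit scale — making background a sub-percent fraction of
the dynamic range, as for a genomically integrated reporter read by flow
cytometry.  Cell counts are Gaussian (mean 5000, σ 1500) with a 2% fraction
of low-count wells that the 500-cell filter should drop.  Every plate carries
triplicate technical-replicate wells of one shared reference condition and of
the no-ligand control; these make the per-plate rescaling identifiable.  A
ground-truth ledger records the noiseless model output and every drawn factor
per well, and identical seeds reproduce both tables bit for bit.

The planted ground truth realizes every interaction class through the
competition mechanism itself: five strong activators sharing one active
complex (mutually saturated-additive, one planted equivalence group), a
BMP9-like ligand mostly sequestered in a silent sink whose release by
II1-grabbing ligands produces synergy, a BMP10-like ligand that dominates the
BMP9 analog's active complex but signals weakly through it (mutual
suppression), two non-activators that antagonize the strong group by
competition, and one inert non-activator.  A design note: one row of screen
arithmetic (65 rows × 10 columns) gives 650 wells per replicate, while the
screen this emulates reports a slightly larger round count per experiment
whose composition is not specified; the generator follows the 65 × 10
arithmetic, plus its explicitly documented shared technical-replicate wells.

What the generator does *not* emulate: per-cell fluorescence distributions
(only well medians), robot scheduling, edge effects, carryover or
cross-contamination, and non-multiplicative drift.  Passing the recovery
tests therefore shows the pipeline inverts the modeled nuisance structure at
realistic noise levels, not that it is robust to every artifact of a real
screen — the manual-override mechanism exists precisely for the residual
cases.

## Numerical and testing choices

Problem sizes in the test suite are chosen to exercise every code path at
interactive runtimes: the end-to-end recovery uses the full 10-ligand,
2-context screen (110 summarized pairs per run), and the fit-recovery
experiment uses 5 ligands × 5 receptors × 4 contexts with 50 starts at 5 of
the 9 ratios.  At zero noise the pipeline's gated summary ICs equal the ICs
computed directly on the ground-truth outputs to 1e−9; at 5% well CV (with
all plate/replicate nuisances active) the recovered interaction categories
match the noiseless truth for ≥95% of pairs across seeds, with the residual
flips concentrated at pairs whose gating margin is inherently close to θ —
most visibly the suppressive pair, whose evidence gap is ~1.5× θ.  Known
limitations: equilibrium uniqueness is assumed, not proven; the IC's
discontinuities make values (not categories) sensitive exactly at branch
boundaries; RLS understates the strength of non-saturating ligands; and the
global-threshold reading (Euclidean 7 vs. squared 7) is a configurable
convention.
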