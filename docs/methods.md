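# Methods

## The model

`tcommit` models the core transcriptional module of early T-cell
specification: four genes — TCF-1 (*Tcf7*), GATA-3 (*Gata3*), BCL11B
(*Bcl11b*) and PU.1 (*Spi1*) — driven by Notch signalling across the
ETP → DN2a → DN2b → DN3a window. Expression levels obey ordinary
differential equations of the Shea–Ackers (thermodynamic occupancy)
form: each gene is produced at a maximal rate `f_X` scaled by
`S/(1+S)`, where the occupancy sum `S` collects weighted activator
terms and the denominator additionally carries repressor terms, minus
linear decay `γ_X·X` that lumps protein degradation and dilution by
cell division:

    dT/dt = f_T (η₁N·ν + η₂T + η₃G) / (1 + η₁N·ν + η₂T + η₃G + η₄P) − γ_T·T
    dG/dt = f_G (δ₁N·ν + δ₂T)      / (1 + δ₁N·ν + δ₂T + δ₃P)        − γ_G·G
    dB/dt = f_B  S_B/(1+S_B)                                          − γ_B·B
    dP/dt = f_P (ρ₁P + u) / (1 + ρ₁P + u + ρ₂T + ρ₃G + ρ₄B)          − γ_P·P

In the TCF-1 and GATA-3 equations every regulator acts as a monomer and
BCL11B is absent (it is not yet expressed when they first activate).
PU.1 has no regulated positive input — only weak self-activation ρ₁ and
an optional constant external drive `u` (e.g. RUNX1), zero by default —
so `P = 0` is an invariant manifold of the dynamics when `u = 0`.

Notch signalling is a nondecreasing sigmoid
`ν(t) = [floor + (N−floor)·logistic((t−t_half)/α)]/N`, normalised to
its maximum `N`. Because a bare weight and the signal amplitude are not
separately identifiable, Notch-coupled weights are stored as the
products `η₁N`, `δ₁N`, `κ₁N`; during bifurcation scans the product is
scaled by `s = notch_level/N ∈ [0, 1]`.

## Combinatorial logic for BCL11B

The BCL11B production term `S_B` is compiled from one of eight AND/OR
gates over {Notch, TCF-1, GATA-3}, each of TCF-1 and GATA-3 acting as a
monomer (Hill exponent 1) or dimer (exponent 2) — 32 configurations in
all, labelled `1a…8d` (letters a–d = valency pairs (1,1), (1,2), (2,1),
(2,2)). A gate is expanded to disjunctive normal form; every OR branch
becomes one minterm `κ_j·Π x_i^{e_i}` with its own kinetic weight.
Minterms are ordered Notch-first (then TCF-1, then GATA-3 presence), so
`κ₁` always multiplies the Notch-containing term, matching the
published parameter tables. Hill exponents apply to the TCF-1 and
GATA-3 factors only, never to Notch.

Two analytic consequences drive the headline results:

* if **every** minterm contains Notch (the pure-AND form 8b), BCL11B
  production is identically zero at `s = 0`, so the committed high-BCL11B
  state cannot survive Notch withdrawal;
* an OR escape (forms 6, 7 with the appropriate valencies) lets the
  accumulated TCF-1/GATA-3 dimer term sustain BCL11B alone, making
  commitment irreversible.

## Stage-to-time mapping and data model

Developmental stages are assigned calendar days via mean transit times:
ETP→0, ETP-DN2a→1, DN2a→2, DN2b→3, DN3a→4 (one-day lags; most ETP cells
are produced near the end of the ~10-day ETP residence, which justifies
the single day between ETP and ETP-DN2a). Expression values carry a
25% coefficient of variation; 95% confidence intervals are
`value·(1 ± 1.96·cv)` on the linear scale with the lower limit clipped
at zero (a lognormal option `value·exp(±1.96·cv)` is available behind
the `scale="log"` flag — linear is the default because it matches how
the error bars are usually drawn and filtered).

Each five-point series is smoothed with a positive four-parameter
curve, baseline + one logistic transition, fitted by least squares
(lmfit). The family was chosen because all four observed profiles are
monotone-then-saturating or monotone-declining; its analytic derivative
feeds the constraint-derivation steps. The smoother is least accurate
at early times for the delayed gene (BCL11B sits near baseline through
day 1), which motivates the "resolved region" rule below.

## Two-leg constrained estimation

The data are five stage means per gene — far too few to fit 15–17
parameters (TGB+Notch subsystem; 14 shared + 1–3 κ) plus 6 (PU.1)
unconstrained. The workflow therefore narrows the space first:

1. **Notch-constraint bounds.** With PU.1 clamped to its smoothed
   profile, each of the T, G and B equations is solved algebraically
   for the implied Notch-coupled term at each time on a 0.1-day grid.
   Requiring that term to be positive everywhere, and to vary by at
   most the fold cap (3.5 between day 0 and day 4), defines a feasible
   set; its Monte Carlo envelope (log-uniform sampling, widened ×5)
   supplies box bounds. Two numerical accommodations: the fold check is
   applied only where the equation's occupancy exceeds 5% of its
   maximum (below that the implied term is a difference of near-zero
   quantities and its fold is meaningless), and when the profiles come
   from noisy data the fold cap in the *feasibility check* is inflated
   by the 95%-band ratio `(1+1.96cv)/(1−1.96cv)`, since a fold measured
   between two noisy values carries that much multiplicative
   uncertainty. Decay-rate sampling is restricted to the half-life
   plausibility window (see below), implementing the "reasonable
   degradation rates" constraint. If no sample is feasible the
   derivation raises a named infeasibility; the pipeline then falls
   back to broad data-scaled bounds (the fold cap still holds by
   construction, below).
2. **TGB leg.** The TCF-1, GATA-3 and BCL11B equations are fitted
   simultaneously with PU.1 clamped. To keep the annealing dimension
   low the search is staged: the TCF-1 equation (which carries the
   Notch shape: α, t_half and the fold) is fitted first with GATA-3 and
   PU.1 clamped to their smoothed profiles, then GATA-3 and BCL11B with
   the signal frozen, then all parameters are polished jointly on the
   coupled system with bounded least squares. Positive parameters are
   searched in log₁₀ space. The Notch signal is parameterised directly
   by its fold increase in [1, 3.5], with the sigmoid floor solved from
   it — the fold cap therefore holds *by construction*, not by
   rejection. Cross-gene weighting is equal; within a gene the
   residuals are relative (per-point), matching the relative confidence
   bands the filter checks; the reported objective uses the
   max-normalised convention so genes with different dynamic ranges
   stay commensurable.
3. **Filters.** A fit is accepted iff (i) the simulated trajectory lies
   inside the 95% band of every observed point for all three genes and
   (ii) every protein half-life falls in the plausibility window,
   default (1, 48) hours ("order of hours"). Half-lives are reported in
   two modes: *intrinsic* `ln2/γ` and *effective* `ln2/(γ − ∂prod/∂X)`
   linearised at the day-4 state; effective is the default because
   printed half-life tables are generally not consistent with a bare
   `ln2/γ` ordering, indicating feedback-corrected values. The window
   comparison carries a 1e-9 relative tolerance because optimal decay
   rates legitimately sit on the bounds implied by the window itself.
4. **PU.1 leg.** With T, G and B clamped, the PU.1 equation is inverted
   for the implied repression term `ρ₄·B(t)`; positivity of that
   expression on the grid rejects infeasible draws, analytic bounds pin
   `γ_P` (derivative positivity) and `f_P` (occupancy < 1), and the
   envelope of the requested number of feasible Monte Carlo samples
   (widened ×2) bounds the rest. Constrained simulated annealing under
   `ρ₄ < min(ρ₂, ρ₃)` — BCL11B represses PU.1 more weakly than TCF-1
   or GATA-3 do, enforced by parameterising ρ₄ as a fraction of that
   minimum — followed by the confidence filter on PU.1 yields an
   ensemble of parameter sets (up to ~10² kept). The ensemble pins the
   PU.1 *trajectory* tightly but leaves `f_P/γ_P` only weakly
   identified (the data end while PU.1 is still declining), so the
   ensemble spread on that ratio is reported, not a point estimate.
5. **Full-network selection.** Each PU.1 set is combined with the best
   TGB parameters, the four-gene system is relaxed to steady state from
   a day-0-like condition at full Notch, and the set is kept iff T, G
   and B reach ≥ 50% of their day-4 reference values while P falls to
   ≤ 10% of its day-0 value.

## Bifurcation analysis and commitment classification

Steady-state branches are continued across the Notch scale
`s ∈ [0, 1]` on a 101-point grid by simulation-based natural-parameter
continuation (relax to steady state from the previous point's state;
relaxation horizon 30/γ_min followed by a Newton root polish in
ceiling-scaled units). Coexisting states are charted by multi-start
root finding (≥ 20 uniform starts in the box `[0, f_X/γ_X]` per gene),
deduplicated at 1e-6 on the ceiling scale; stability comes from the
eigenvalues of a central-difference Jacobian.

Per-gene classification from the downward sweep (committed state at
`s = 1` down to 0):

* **irreversible** — the branch at `s = 0` stays within 50% of the
  committed value (the 50% threshold operationalises "remains high" and
  is exposed as a parameter);
* **reversible** — the branch collapses, with either a discontinuous
  jump along the sweep or a > 5% disagreement with the upward sweep
  somewhere (a bistable region);
* **monostable** — the branch declines smoothly and the two sweeps
  agree everywhere;
* **irreversible-off** — the committed value is already zero and stays
  zero (PU.1 with no external drive, by the invariant-manifold
  argument).

With the packaged mean parameters for the four accepted configurations
and PU.1 clamped at zero (the published parameter table covers the
TGB+Notch subsystem only; full four-gene diagrams are supported when
PU.1 parameters are supplied), BCL11B classifies irreversible in 6d, 7b
and 7d and reversible in 8b — at `s = 0` the all-AND gate's production
is analytically zero. A structural note: with monomer TCF-1/GATA-3
equations, saturating occupancy with linear activation admits no
bistability in the clamped TGB subsystem; the published decay/production
values put the uninduced state in the self-igniting regime
(`f_T·η₂ > γ_T`), so TCF-1/GATA-3 "irreversibility" is of the
self-sustaining kind and the up/down sweeps coincide there. The
hysteresis consistency check is therefore conditional: wherever stable
branches differ, an unstable separatrix is required between them.

The robustness variant with a constant positive PU.1 input (`u > 0`,
e.g. RUNX1) is exposed as a flag; the qualitative claim checked is that
PU.1 still remains low across the sweep.

## Synthetic data generator

No numeric table of the underlying stage-mean profiles is publicly
available (the source figures are graphical), so the generator defines
the study conditions. The packaged day-scale reference model
(configuration 6d; rates per day; ceilings of order 100; half-lives
14–21 h inside the plausibility window; Notch fold 2.7 ≤ 3.5, sigmoid
midpoint day 1.6) was chosen once so that its trajectory from an
ETP-like state (T, G, B at 2% of their ceilings, PU.1 at 50%)
reproduces the qualitative shape of the measured profiles: TCF-1 and
GATA-3 rise from low values beginning at day 0–1 and approach
saturation by day 3–4, BCL11B stays near baseline through day 1 and
then rises steeply (day-1/day-4 ratio < 0.2 — the feed-forward delay),
and PU.1 stays high early and declines after day 1–2. Noise is
multiplicative lognormal with unit mean and CV 25%
(`σ² = ln(1+cv²)`), applied independently per gene and stage —
expression data are positive and the source errors were log-derived.
Deterministic per seed.

What passing tests on these data do **not** show: recovery performance
on microarray-specific artifacts (probe saturation, normalisation
batch effects), on non-lognormal heavy-tailed noise, or on stage
mis-assignment; the generator's five stage means are exactly one draw
per stage, whereas real stage means aggregate many cells and are much
smoother than single lognormal draws — the noisy-recovery results here
are therefore conservative in that respect.

## Numerical choices

* Integration: LSODA in ceiling-scaled units (`u = X/(f/γ)`), rtol 1e-8
  / atol 1e-10 for reported simulations (1e-6 inside optimisation
  loops). Positivity is a model property, not an integrator guarantee:
  scaled undershoots beyond −1e-9 raise; smaller ones are clipped to 0.
* Steady states: long relaxation then `scipy.optimize.root` (hybr) on
  f-normalised residuals; convergence requires residuals < 1e-8.
* Stability: sign of the dominant eigenvalue of the central-difference
  Jacobian; branch dedup at 1e-6 (scaled).
* Optimisation: `scipy.optimize.dual_annealing` (seeded, no local
  search) + `least_squares` (trf) polish; every stochastic step takes a
  mandatory seed and is reproducible.
* Saturated promoters: `S/(1+S)` is clamped to the largest double < 1
  so the ratio stays strictly inside [0, 1) even when `S` overflows.

## Problem sizes used in the shipped tests

The test suite fits the generating configuration on noiseless data (5
optimizer seeds) and on ten CV-25% datasets end to end, runs the
four-configuration bifurcation scans at the full 101-point resolution,
and checks the PU.1 leg with 4 annealing starts; these sizes keep the
whole suite in the tens of minutes on a single core while exercising
every pipeline stage at the same resolution used for the headline
numbers.

## Known limitations

* The exact supplementary rate equations of the source study were not
  available; the equations above are reconstructed from the printed OR
  form, the network diagram and the parameter inventory (6 PU.1
  parameters, no regulated positive PU.1 inputs, one-way BCL11B→PU.1
  repression). The PU.1 numerator/denominator placement is this
  package's design choice satisfying those constraints.
* The time units of the published decay rates are not printed; only
  steady-state structure (which is time-scale invariant) is used from
  them. Transient timing is meaningful only for the day-scale reference
  model.
* The published α is interpreted as the Notch sigmoid steepness; the
  sigmoid midpoint and floor are structural defaults (midpoint day 1,
  floor = N/3.5 so the maximal allowed fold is attainable), fitted per
  run in the estimation leg.
* Parameter identifiability from five points per gene is intrinsically
  weak; beyond the BCL11B decay rate, single-parameter point estimates
  should not be over-interpreted (the tests assert trajectory-level
  recovery and the sharply identified quantities only).
* Formal continuation with fold-point detection (pseudo-arclength) is
  out of scope; the sweep is simulation-based.
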