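# Methods

## The model class

`cfba` implements conditional flux balance analysis: a time-discretized,
resource-constrained linear program that describes the growth of a
metabolic network over one full environmental period (typically a 24 h
light/dark cycle).  The central idea is that metabolism is autocatalytic —
every flux is carried by a catalyst (enzyme, ribosome, pigment) that is
itself a product of metabolism — so the temporal order in which the cell
builds its own machinery co-determines how fast it can grow.

Compounds are partitioned into a **balanced** set `B` (instantaneous mass
balance, as in conventional FBA) and a **dynamic** set `A` whose amounts
`M^k` evolve by an explicit Euler step.  With `n_t` intervals of length
`dt_k` over the period `T`, fluxes `v^k` and amounts `M^k` satisfy

    S_B v^k = 0                                   (steady state)
    M^k = M^{k-1} + dt_k S_A v^k                  (Euler update)
    lb <= v^k <= ub                               (environmental bounds)
    sum_i (1/kcat_ij) gamma_j^k v_i^k <= M_j^{k-1}  (capacity)
    sum_{j in Q} M_j^k >= f_Q * w^T M^k           (quotas)
    sum_i c_i v_i^k >= m * w^T M^{k-1}            (maintenance)
    M^k >= 0
    M^{n_t} >= alpha * M^0                        (cyclic growth)
    w^T M^0 = B0                                  (start biomass)

Biomass is the weighted sum `b = w^T M`.  The objective is the maximal
cyclic growth factor `alpha`; since feasibility is monotone in `alpha`,
the optimum is found by doubling an upper bound until infeasible and
bisecting (relative tolerance `1e-6` by default).  The initial
composition `M^0` is itself a decision variable: the dawn state of the
cell emerges from the optimization.

Design choices where the formulation is genuinely open:

* **Cyclic growth as inequality.** `M^{n_t} >= alpha M^0` componentwise is
  the default; an equality mode exists (`cyclic_equality=True`) but the
  inequality is more robust because compounds without quota or catalytic
  role would otherwise become artificially binding.
* **Start biomass as equality.** `w^T M^0 = B0` (default `B0 = 1`)
  excludes the degenerate all-zero solution that a pure upper bound on
  start biomass would admit; `alpha` is invariant under joint rescaling
  of `B0` and the flux bounds.
* **Left-endpoint capacities.** Flux capacity in interval
  `[t_{k-1}, t_k]` is bounded by the catalyst amount at the interval's
  *start* (`M^{k-1}`): catalysts synthesized within an interval become
  usable only in the next one.
* **Maintenance anchoring.** Biomass-proportional maintenance demands per
  interval are likewise anchored to the interval-start biomass.
* **Dark phases by bounds, not infinities.** Dark intervals force the
  upper bound of light-driven reactions (photon uptake) to zero rather
  than sending the light-harvesting coefficient `gamma` to infinity.

## Representative solution and variability

The flux solution at the optimal `alpha` is not necessarily unique.  The
reported trajectory is selected deterministically by a secondary LP at
the optimal `alpha` minimizing total absolute flux (`sum_k dt_k |v^k|`,
auxiliary variables for reversible reactions).  Uncertainty is quantified
by variability analysis: each flux (per interval) and each amount (per
gridpoint) is minimized and maximized subject to the full LP at fixed
`alpha` — two solves per variable and time step.  Envelopes always
contain the representative trajectory.

## Numerics

LPs are solved with HiGHS through `scipy.optimize.linprog`.  Feasibility
tolerances default to `1e-9`; this matters because capacity constraints
compound multiplicatively over the `n_t` intervals, so loose per-row
slacks would inflate the apparent growth factor.  Exactly at the growth
boundary the LP becomes degenerate and a single algorithm can stall or
return an inconclusive status; all solves therefore run a deterministic
ladder (interior point at `1e-9`, interior point at `1e-8`, then an
iteration-capped dual simplex).  A bisection midpoint on which every rung
is inconclusive is treated conservatively as infeasible — the returned
`alpha` is always a verified feasible point.  All solver settings are
deterministic (fixed iteration caps, no time limits), so identical inputs
give bit-identical results.

On the packaged diurnal model the bisection accuracy was verified against
the closed-form single-autocatalyst oracle: a compound `E` catalyzing its
own synthesis with efficiency `c` has the exact discrete optimum
`alpha = (1 + c dt)^{n_t}`, approaching `exp(cT)` under refinement.

## The packaged diurnal model

The minimal *Synechocystis* sp. PCC 6803 model (52 reactions, 50 cellular
compounds) covers the photosynthetic electron transport chain, a lumped
Calvin-Benson cycle, lumped biomass-component syntheses, per-enzyme
synthesis reactions, glycogen storage, and a TCA/respiration route for
dark metabolism.  Transcription choices that the source tables leave
open are flagged in the model module docstring; the most important:

* **Photon as boundary species.** Light enters through a photon-uptake
  reaction and photons are mass-balanced, but the photon is an
  environmental species, not a cellular compound (`externals`), which is
  the only reading consistent with the stated compound count.
* **Hour time base.** All fluxes are amount/h and the capacity
  coefficients carry their printed numerical values on this time base.
  Reading the same constants on a per-second base makes the model
  provably infeasible: the night maintenance demand would integrate to
  ≈277 biomass-equivalents of ATP while complete respiration of a
  glycogen stock equal to the entire biomass yields only ≈19 — so the
  hour base is the one on which the constants form a growing,
  glycogen-cycling diurnal cell.
* **Capacity row assignment.** The pigment row covers (PSII, PSI) with a
  4:1 coefficient ratio (photons per turnover) and is the only
  light-modulated row; `E_PSI` covers linear and cyclic electron flow
  through PSI; one common ribosomal coefficient covers all 25
  enzyme-synthesis reactions plus ribosome assembly; the remaining 22
  printed coefficients map to the remaining 22 single-reaction enzymes
  in enzyme-list order.
* **Unit biomass weights.** Weights are not printed; every dynamic
  compound has `w = 1` except free amino acids (`w = 0`, and their
  steady amount is consequently zero — a bookkeeping outcome, not a
  concentration estimate).  Weights rescale quota and maintenance
  pressure, so absolute growth factors depend on this choice; the
  qualitative diurnal program does not.

With these defaults the model grows with `alpha ≈ 1.012` per day and
reproduces the expected program: exponential biomass growth in the light;
glycogen accumulated late in the light phase and respired overnight to
meet the maintenance demand; storage respiration (TCA, glycogen
mobilization, NDH) confined to darkness; capacity-saturated operation
under binary light and dawn/dusk sub-saturation under a bell-shaped
light intensity.  Under our coefficient assignment the terminal oxidase
(CytC) additionally carries a small water-water-cycle-like flux during
the day, and inorganic-ion uptake runs at constant rate through the
*light* phase rather than through the night; both behaviours are
sensitive to the unrecoverable assignment of printed capacity
coefficients to catalysts (see the model module docstring).

The toy three-reaction network ships with kcats of 0.3/h for both
catalyzed conversions, a non-binding uptake bound, unit weights and a
start-only product quota of 0.5; these unprinted values were chosen so
that the optimal program is the characteristic bang-bang schedule
(enzyme self-synthesis first, product accumulation after) with a unique
solution.

## Light profiles

Binary light sets `gamma = 1` in every light interval and blocks photon
uptake in the dark.  The bell profile uses
`I(t) = peak * sin^2(pi t / T_L)` on the light phase (a smooth bell with
integral `peak * T_L / 2`); `gamma^k = 1 / I(t_mid)` at interval
midpoints, with zero-intensity intervals treated as dark.  The sin²
shape and the absolute scale of `peak` (default 1, i.e. midday equals
binary light) are package choices; only "approximately bell-shaped" is
prescribed by the underlying problem.

## Calibration

Where users bring their own reference FBA solutions, kcats are estimated
by self-consistency: the catalyst amount accumulated over the reference
period is assumed exactly sufficient to carry the reference fluxes, with
equal catalyst shares per reaction (`kcat_ij = |R_j| v_i / M_j`) and one
common kcat for shared-pool catalysts such as ribosomes.  The packaged
diurnal model ships the printed capacity coefficients directly; the
calibration module does not alter it.  When day and night reference
states are available they are calibrated per call; combining the
estimates (e.g. taking per-reaction maxima) is left to the caller.

## Synthetic generators and what the tests show

`single_autocatalyst_model` has a closed-form optimum and anchors the
optimizer's accuracy; `random_autocatalytic_model` generates small
validated chains (uniform kcats in [0.15, 0.6]/h, one quota compound,
deterministic per seed) for property tests.  These generators emulate
the *structure* of resource-constrained growth — catalysts limited by
catalysts — but not the redox/energy coupling, reversibility patterns or
coefficient heterogeneity of real reconstructions, so green property
tests certify the machinery, not biological realism.

## Problem sizes and runtimes

The default scenario (n_t = 48) solves in ~10 s on one CPU (~25 LPs of
~4200 variables).  The slower analyses in the test suite use documented
reduced sizes: variability on the diurnal model runs on n_t = 12 with
all 52 fluxes at four representative intervals; kcat fold-change scans
use n_t = 24 with a 7-point grid per catalyst; the discretization check
compares n_t = 48 against n_t = 96.  Variability at full size is
available through the API and CLI (`cfba fva`) at a cost of two LPs per
variable per time step.

## Known limitations

* No enzyme degradation or dilution of balanced intermediates; catalysts
  persist until diluted by cyclic growth.
* Uniform grids and explicit Euler only; capacity anchored to interval
  starts makes fine grids mildly conservative.
* Growth factors depend on the unprinted biomass weights (see above);
  comparisons should therefore be made within a weight convention, not
  across them.
* Enzyme-synthesis burst timing is genuinely degenerate when ribosomal
  capacity is slack: per-interval envelopes for those reactions can span
  their full range while every central metabolic flux stays pinned.
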