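# Methods

## The question the package addresses

Kinetic models of central carbon metabolism respond to finite perturbations
of their steady state in a way their linearizations do not predict: some
displacements are transiently *amplified* before the state relaxes back.
`kinresp` provides a controlled, fully synthetic setting for studying which
structural ingredients produce this behavior. It generates random kinetic
models in which two candidate ingredients can be dialed independently —
the sparsity of the backbone reaction network and the fraction of reactions
coupled to a conserved carrier (cofactor) pool — runs the
perturbation-response protocol on them, and quantifies responsiveness.

## Response coefficient

For a model with steady state `x_st`, a trajectory starting from a
perturbed state `x(0)` is scored by

    chi = max_t || ln x(t) - ln x_st ||_2 / || ln x(0) - ln x_st ||_2 .

The maximum includes `t = 0`, so `chi >= 1` always: `chi = 1` means the
log-space distance to the steady state never exceeds its initial value
(weak, essentially monotone relaxation), while `chi >> 1` means the
perturbation is transiently amplified (strong response). The max over time
is evaluated on the stiff solver's own accepted steps *plus* a 512-point
log-spaced refinement grid evaluated on the dense interpolant; this
resolution is validated in the test suite against a 100,000-point uniform
brute-force sweep of a closed-form non-normal linear fixture (agreement to
0.1%).

## Minimal cofactor model

The generator builds, for `N` backbone chemicals and `R` reactions:

1. a linear chain `C1 <=> C2 <=> ... <=> CN` (N-1 uni-uni reactions) plus
   `R-(N-1)` extra uni-uni reactions drawn uniformly without replacement
   from the not-yet-connected species pairs (no self-loops, no duplicates);
2. exchange `D_n (X_n - x_n)` for `Round(0.05 N)` species, always
   including both chain endpoints; the endpoint `C1` is the nutrient with
   external concentration `X = 100`, all other externals are 1;
3. cofactor coupling for `Round(f R)` randomly chosen reactions: two
   distinct forms of a three-form carrier (`A**`, `A*`, `A`; standard
   potentials 1.0, 0.5, 0.0; conserved total 1) are attached with random
   orientation, so a coupled reaction reads `C_a + A_i <=> C_b + A_j`;
4. thermodynamically consistent mass-action kinetics

       J_r = v_r (k_r+ prod_{Sub(r)} x - k_r- prod_{Prd(r)} x),
       v_r = 10^u,  u ~ U(-3.66, 7.13),
       k_r± = min{1, exp(∓ beta Δmu_r)},
       Δmu_r = sum_{Prd} mu - sum_{Sub} mu,  mu_n ~ U(0, 1) (backbone).

   `Round(.)` is half-away-from-zero everywhere, so tie cases such as
   `f R = 31.5` are deterministic. The detailed-balance construction
   guarantees that closed (exchange-free) variants relax to a zero-flux
   equilibrium; this is used as a correctness oracle.

Default inverse temperature is `beta = 10`. The largest admissible
`|Δmu_r|` is 2.0 (backbone span 1 plus the largest cofactor gap 1).

The **catalytic variant** attaches a uniformly drawn catalyst species to
each reaction instead (`C_n + C_l <=> C_m + C_l`, autocatalysis allowed),
has no cofactors, and uses `beta = 20` so that `beta * sup|Δmu|` matches
the cofactor model (the catalyst cancels from `Δmu`, halving the range).
Mirroring the species-count convention of the cofactor model, comparisons
"at matched N and R" use a catalytic variant with `N + 3` species.

## RCRN toy cell

The weak-response baseline is a random catalytic reaction network in which
every metabolite is also a catalyst:

    dx_i/dt = sum_{j,k} x_k (v_ijk x_j - v_jik x_i)
              + D_i x_{T(i)} x_ext_i - mu x_i,
    mu = sum_i D_i x_{T(i)} x_ext_i .

A connected Erdos-Renyi-style edge set (redrawn on disconnection) gets one
uniform catalyst per edge and both directed rate constants from a supplied
pool (default: the same log-uniform distribution as `v_r`). Only species 1
is taken up (`D_1 = 1`, `x_ext = 1`), transported by species `N`. The
catalytic terms cancel pairwise in the total, so `d(sum x)/dt =
mu (1 - sum x)` and growing attractors sit exactly on `sum x = 1`.
Instances also possess washout states (`mu -> 0`); instances whose
attractor screen finds more than one attractor are excluded from response
statistics, with exclusion counts reported.

## Perturbation protocol

Initial states are `x_n(0) = r_n * x_st_n` with `r_n ~ U(1-s, 1+s)` and
default strength `s = 0.4`. The 40% default is deliberately below the
~62% concentration noise ceiling implied by stochastic enzyme expression
(see below); this link is configuration, not computation. Conserved
quantities are restored exactly by the multiplicative projection
`x -> x * exp(P^T lam)` (`P` the integer pool matrix), with `lam` from
Newton iteration on the SPD Gram system. This projection preserves
positivity for arbitrary signed, overlapping pool vectors — generated
networks do produce signed conserved moieties at low `R` — and reduces to
a per-pool uniform rescaling in the common single-pool case. Default
ensemble size is 128 trajectories per model (32 in the desk-scale test
configurations).

## Integration and steady states

Stiff integration uses LSODA with the analytic mass-action Jacobian
(tolerance-tightening and BDF fallbacks on breakdown), dense output, and a
terminal convergence event. A state counts as relaxed when either

* `||dx/dt||_inf < 1e-10 + 1e-6 * max_r |J_r|`, or
* every concentration moves slower than `3e-8` e-folds per unit time,

whichever fires first, with a hard time cap of `1e8` (about a million
exchange timescales; `D = 1`). A state that reaches the cap but has been
numerically frozen over the second half of the horizon (max log change
below 1e-6) also counts as relaxed: slaved coordinates can sit within the
solver's error tolerance of their quasi-equilibrium and carry a residual
the criteria can never see below; genuine creep or oscillation at the cap
remains a loud failure. Two criteria are needed because the rate
constants span ~10.8 decades and `k±` can be as small as `exp(-20)`:
networks routinely contain modes with relaxation times far beyond any
feasible horizon, and in near-chain topologies the largest flux *is* the
slow relaxation flux, so no flux-relative threshold alone can fire. The
residual left by the stopping rule is removed by a Newton polish of the
endpoint in log coordinates (Levenberg-Marquardt with the analytic
Jacobian), solved jointly with the conservation constraints so the root
sits on the exact invariant surface of its initial condition; the polish
is accepted only when it stays within 0.5 log units of the endpoint and
improves the residual. Integration itself lets pool values drift at the
solver tolerance, so endpoints are first projected back onto the pool
surface.

Attractor identity uses a max-log-distance threshold of `1e-4` on polished
endpoints; linear stability is certified on the Jacobian deflated along
conserved-pool directions (they carry exact zero eigenvalues), with
eigenvalues within `1e-8` of zero *relative to the spectral radius*
treated as neutral — polished roots carry ~1e-7 position error, enough to
flip the sign of genuinely-zero slow eigenvalues. Multistability screening
relaxes 32 (configurable) starts drawn log-uniformly from `(1e-3, 1e3)^N`
and clusters the polished endpoints. Default solver tolerances are
`rtol = 1e-6`, `atol = 1e-9`; the chi they produce is oracle-checked at
0.1% as above. Trajectory positivity is enforced by floor-clipping solver
states before RHS evaluation plus a violation check with one
tolerance-tightening retry.

Failed integrations are never dropped silently: trajectories carry a
`failure_reason`, ensembles count `n_failed` and abort beyond 50%
failures, and sweep manifests record all exclusions.

## Clamping

Clamping a species fixes it at its steady-state value and zeroes its
derivative; fluxes still read the frozen value. The scan re-certifies the
attractor's stability under each clamp (clamps can destabilize it — those
species are flagged and carry no rho) and reruns the response protocol
with *identical* perturbation draws as the unclamped reference (frozen
coordinates consume their draws without being displaced), so

    rho+ = (<chi_x> - <chi_ori>) / <chi_ori>   (<chi_x> >= <chi_ori>)
    rho- = (<chi_ori> - <chi_x>) / <chi_ori>   (otherwise)

is free of between-ensemble Monte-Carlo noise and a no-op clamp gives
exactly zero. Ties are reported as `rho+ = 0` by convention. Conserved
pools are recomputed on the reduced stoichiometry (a clamped species drops
out of its pool and acts as a fixed source/sink).

## Network expansion

Extensions add uni-uni reactions between random existing non-cofactor
species (never new species); each is upgraded with probability `p` — by
default the base model's own coupled fraction — to a cofactor-coupled
bi-bi reaction. Rate constants are bootstrap-resampled from the base
model's per-scheme pools; irreversibilities follow from the already-drawn
standard potentials, so extended models stay thermodynamically consistent.
Each extension is screened with 128 (configurable) initial states obtained
by perturbing the base attractor; only extensions with a single attractor
(and a linearly stable one) are measured, with a fresh perturbation set
around the *extended* model's attractor. Duplicate reactant pairs are
permitted. An optional `accept_hook` can impose extra conditions (e.g. a
minimum steady growth rate for models with growth dilution); it is off by
default because generated minimal models have none.

For plug-in models with saturating kinetics the module provides the three
standard enzymatic templates (reversible Michaelis-Menten, ordered bi-bi,
factorized bi-bi) and the elementary reaction decomposition (ERD), which
rewrites a reaction as enzyme binding/conversion/release steps in pure
mass action with a conserved enzyme moiety; its quasi-steady-state flux is
verified against the pseudo-equilibrium closed form at a fast/slow ratio
of 1e8 (agreement ~1e-8, asserted at 1e-4).

## Fluctuation-strength estimate

For the motif `0 ->(P) X ->(Q) 0` with `dx/dt = v p - u q x` and
independent gamma(a, b)-distributed enzyme levels (the stationary law of
bursty expression; `a` is the transcription-to-protein-degradation rate
ratio), the quasi-steady state `x = v p / (u q)` has

    <x>   = (v/u) a/(a-1),
    <x^2> = (v/u)^2 a(a+1) / ((a-1)(a-2)),
    CV    = sqrt((2a-1) / (a(a-2)))          (a > 2).

At the proteomics estimate `a = 6.82` for essential E. coli enzymes the CV
is ~62%, the ceiling under which the 40% default perturbation strength was
chosen. The Monte-Carlo cross-check (1e6 gamma draws per moment) estimates
the four factorizing moments `E[p]`, `E[p^2]`, `E[1/q]`, `E[1/q^2]`
separately, with the inverse moments importance-sampled from a
`gamma(a - s)` proposal (`s = 0.75` and `1.75`). A naive sample of the CV
is unusable exactly in the interesting strong-noise regime: for `a <= 4`
the fourth moment of `x` diverges, the sample CV has infinite variance
and a slowly decaying negative bias, and a "within 3 SE" comparison fails
with constant probability at any sample size. The importance-sampled
estimator has finite variance for all `a > 2.25` and remains a genuine,
non-circular Monte-Carlo check of the closed form.

## What the generator does and does not emulate

The synthetic models capture: mass balance, thermodynamic consistency
(detailed balance), a conserved multi-form carrier coupled to a tunable
fraction of reactions, realistic rate-constant spread (10.8 decades),
sparse connected topologies, and nutrient-driven nonequilibrium steady
states. They deliberately omit: enzyme saturation in the minimal model
(pure mass action), allosteric and substrate-level regulation,
transcriptional control, growth dilution (except in the RCRN), catalytic
activity of the cofactors themselves, and any organism-specific
stoichiometry. Passing tests therefore show that cofactor coupling and
backbone sparsity *suffice* to produce strong responses in thermodynamically
consistent random kinetics — not that real metabolic networks contain no
other contributors.

## Problem sizes used by the test suite

Full-scale study conditions (N = 64 backbone species, 512 networks x 128
trajectories per condition) are exposed through `run_sweep` and the CLI.
The shipped test and acceptance configurations use the desk-scale setting
N = 16, 64 networks x 32 trajectories per condition (8-12 species for
single-model fixtures), which reproduces the direction of every ensemble
effect with comfortable margins; the statistical checks on ensemble
comparisons are one-sided at the 5% level.

## Known limitations

* The stopping rule cannot wait out modes slower than ~1e8 time units;
  such trajectories are either polished onto the root (attractor search)
  or counted as failures (response ensembles). Exclusion fractions are
  reported, mirroring the protocol's treatment of numerically failing
  instances.
* The linearized-response simulator floors non-positive excursions at an
  essentially-zero constant before taking logs; a linear trajectory
  leaving the positive orthant therefore registers an extremely large chi,
  which is itself a diagnostic of linearization breakdown rather than a
  quantitative value.
* `conserved_pools` requires an integer stoichiometry; models without one
  (e.g. the RCRN, whose simplex attraction is dynamical rather than
  structural) report no pools.
* GraphML export flattens multi-substrate reactions to their backbone
  pair; cofactor participation is stored as edge attributes, not edges.
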