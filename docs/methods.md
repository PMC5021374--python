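# Methods

## Poisoning model

A ring of `z` subunits is assembled from a pool containing a fraction `p`
of inactive (arginine-finger mutant) subunits. The ring is inactive once it
contains at least `K` mutants. Two assembly modes are implemented.

**Random assembly.** Subunits enter independently at pool frequency, so the
mutant count is Binomial(z, p) and the active fraction is the cumulative
binomial `A(p) = P(mutants < K)`. This is the classical one-hit poisoning
model used to read stoichiometry off titration curves; for K = 1 it reduces
to `(1 − p)^z`.

**Dimer-seeded assembly.** The ring is one preformed noncovalent dimer plus
`z − 2` independent monomers, reflecting an asymmetric hexamer built from
one dimer and four monomers. Dimers are unordered pairs; with the
arginine-finger donor rule in force, a dimer requires at least one partner
with an intact finger, so the mutant–mutant class is excluded and the pair
distribution renormalizes to WW = (1−p)/(1+p), WM = 2p/(1+p). The finger is
physically directional (donor → acceptor), but pair-composition data cannot
resolve orientation, so it is not a free parameter. Mutant monomers enter
the monomer positions at pool frequency with no further selection, since
there is no evidence of monomer-level exclusion at assembly. For K = 1,
z = 6 the closed form is `[(1−p)/(1+p)] · (1−p)^4`. At p = 1 with the donor
rule no ring can seed; the activity is defined as 0 and a warning is
emitted rather than an error, because an all-mutant pool is a legitimate
titration endpoint.

The mixing ratio is treated as the realized subunit fraction (equal
specific concentrations of the two stocks). `K > z` is accepted as a
degenerate hypothesis with activity identically 1; the fitting grid never
proposes it.

Whether the wild-type member of a WM dimer can still donate its finger
onward into the ring would matter only for interface-level blocking with
K > 1; with the single-poison result it is unobservable and is deliberately
left unmodelled.

## Count model and fitting

Plaque formation is a count process, so replicate counts are modelled as
Poisson with mean `A0 · scale · A(p)`, where `A0` is the expected control
count per unit scale and `scale` a per-replicate volume/dilution factor.
An optional background rate `ε` (default 0) absorbs rare nonzero counts at
A(p) = 0; with ε = 0 such counts give −∞ log-likelihood, which is the
correct verdict on an impossible outcome under the model. A negative
binomial overdispersion hook was considered and left out: the generators
produce exactly Poisson noise, and nothing in the target data constrains a
dispersion parameter.

`fit_stoichiometry` scans the full integer grid z ∈ [z_min, z_max],
K ∈ [1, z], mode ∈ {random, dimer_seeded}. In each cell the baseline has
the closed-form Poisson MLE `A0 = Σ counts / Σ (scale · A(p))` over rows
with positive activity, so no iterative optimization is needed. Cells are
ranked by AIC with two effective parameters each (the baseline plus the
background slot), which makes selection equivalent to maximum likelihood
across the structural grid; an optional `complexity_penalty · (z + K)` term
is available for users who want explicit integer-complexity shrinkage, and
defaults to 0. Ties (e.g. control-only data, where every model fits
identically) break deterministically to the smallest z, then smallest K,
then random mode. `z_max` defaults to 12 — the largest ring plausible for
this motor system, matching its 12-subunit connector.

Display normalization divides by the fitted `A0`, not by the raw p = 0
sample mean, to avoid double-using noisy controls.

**Bootstrap.** Confidence intervals for (z, K) come from case-resampling
the titration *rows* (not individual plaques), respecting the titration
design, stratified into control and non-control strata so that every
replicate retains a p = 0 row and the baseline stays identifiable.
Percentile intervals are reported; integer parameters make degenerate
intervals like [6, 6] common and meaningful (every refit agreed).

## Gradient analysis

Fractions are indexed 1..31 bottom-to-top (31 is the collection default),
so heavier species peak at smaller indices and the calibration slope is
negative. Calibration fits `peak_fraction = a·log10(mass) + b` by least
squares — linear-in-log-mass is the standard rate-zonal behaviour over a
narrow mass range, and with exactly two markers the fit interpolates them
exactly. Anchors are accepted as real-valued fractions even though printed
anchors are integers ("around" a fraction). The subunit mass (~66 kDa for
the eGFP fusion used in the examples) is a parameter, never hard-coded.

Peak detection: moving-average smoothing (odd window, default 3 fractions;
edge-padded), local maxima filtered by prominence expressed as a fraction
of the smoothed maximum (default 0.1; the noisy two-peak analyses in the
tests use 0.2, which separates a 5-fraction-spaced monomer/dimer pair
cleanly at SNR 10 — a window of 5 over-smooths that separation), then
3-point parabolic refinement of each apex. Parabolic refinement was chosen
over Gaussian-mixture deconvolution deliberately: three points around an
apex cannot support a mixture likelihood robustly, and overlapping-species
deconvolution is out of scope.

Oligomer calls: each peak's apparent mass comes from the inverted
calibration; the order is the nearest integer multiple of the subunit mass
within a relative tolerance (default 10%), otherwise the peak is flagged
unassigned — never an error.

## Sequential-ring simulator

The translocation cycle is event-ordered, not time-ordered: no kinetic
rates are published for the per-event chemistry, and the mechanism under
test is a sequence of states. Exactly one subunit engages the DNA. A
wild-type engaged subunit binds ATP (high-affinity state), hydrolyzes on
DNA engagement, advances the cumulative translocation by `step_size` base
pairs (default 1; the true bp-per-ATP value is not fixed by the data this
models, so it is configurable), drops to a low-affinity ADP state and
hands the DNA to the adjacent subunit. Handoff direction is fixed by
convention; results are direction-symmetric. A mutant subunit cannot bind
ATP, so the moment the DNA reaches one the ring stalls permanently — an
absorbing state, not an error. Consequently any ring with at least one
mutant stalls within z handoffs having translocated at most z − 1 steps,
which makes the surviving-ring fraction at a horizon ≥ z identical,
ring-for-ring, to the composition criterion "zero mutants" — the
mechanistic counterpart of K = 1 poisoning. The migrating dimer interface
is represented implicitly by the advancing engagement index; no separate
dimer-position state is tracked. Subunit exchange between a stalled ring
and the free pool is not modelled.

`assemble_rings_mc` is the independent stochastic oracle for the closed
forms: it samples explicit ring compositions (i.i.d. subunits, or a
dimer-class draw plus monomers) and reports the active fraction with its
binomial standard error.

## Synthetic data

`simulate_titration` draws Poisson counts with mean
`control_mean · scale · A(p)` under a stated truth model. Defaults are the
study conditions used throughout: mutant fractions 0–0.9 in steps of 0.1,
3 replicates, control mean 500 counts (plate counts are not published for
the assay this emulates; 500 is a realistic plate-scale count that leaves
the Poisson noise visible), scale 1. `simulate_gradient_profile` sums
Gaussian peaks (common s.d., default 1.2 fractions — a realistic band
width for a 31-fraction gradient) centered at the calibrated fraction of
each species, adds i.i.d. Gaussian noise truncated at zero (the simplest
model consistent with plate-reader fluorescence), and validates that every
species lands inside the gradient.

What the generators do *not* emulate: pipetting error across fractions,
baseline drift, meniscus artefacts, overdispersed plaque counts,
non-Gaussian band shapes, or cross-contamination between fractions. Passing
recovery tests therefore demonstrate correctness of the inference under its
own assumptions, not robustness to real-assay pathologies.

## Problem sizes and numerical choices

Recovery studies use 20 seeded repetitions per condition; Monte-Carlo
cross-checks use 1e5 draws (agreement asserted within 3 binomial standard
errors computed at the closed-form rate, which stays well-defined when the
empirical count is zero); enumeration oracles go exhaustively through all
2^z compositions for z ≤ 10 and are matched to 1e-12. Grid fits cover
z ∈ 1..12, K ∈ 1..z. All randomness flows through
`numpy.random.default_rng` seeds carried in the design objects, so every
dataset, bootstrap and trajectory is exactly reproducible.

Known limitations: the dilution-only control arm of the titration
experiment (buffer titrated instead of mutant) is not modelled — only the
mutant-titration branch is implemented; there is no Bayesian posterior
over (z, K); no svedberg-coefficient physics or shape corrections in the
gradient; no force, geometry, or connector model in the simulator.
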