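# Methods

## Scope

`aktloop` implements a complete in-silico workflow for dissecting acute
negative feedback in insulin/PI3K/Akt signalling: a synthetic-data
generator that encodes the kinetic features of insulin-stimulated Akt
plasma-membrane (PM) recruitment and phosphorylation time courses; a family
of nine ODE network variants differing only in the placement of one
negative-feedback edge; genetic-algorithm (GA) calibration with repeated
resampled runs; model ranking by objective-function optima;
profile-likelihood identifiability analysis; and inhibitor-perturbation
predictions by parameter nulling.

## The model family

All variants share a mass-action backbone on eight conserved moieties (IR,
IRS/PI3K, PIP2+PIP3, PDPK1, Akt, mTORC2, PRAS40, PTEN), each normalised to
a total of 1 so states are dimensionless fractions; time is in seconds and
insulin enters linearly in nM. Insulin activates the receptor; active
receptor activates the lumped IRS/PI3K node; active IRS/PI3K converts PIP2
to PIP3 (`Kf3`) and PTEN reverses it (`Kb3`); PIP3 recruits PDPK1 and Akt
to the membrane; membrane PDPK1 phosphorylates Akt T309 (`Kf6`) and active
mTORC2 phosphorylates S474 (`Kf7`); mTORC2 is activated by PIP3 (`Kf8`) and
by active Akt (SIN1 phosphorylation); active Akt phosphorylates PRAS40
(`Kf11a`/`Kf11b`), the mTORC1-activation surrogate. Only
T309-phosphorylated Akt (singly or doubly phosphorylated) is catalytically
active.

Negative feedback enters in one of two canonical forms: multiplicative
attenuation `1/(1 + sum Ki * [source])` of the IRS/PI3K activation rate, or
multiplicative enhancement `1 + sum Ki * [source]` of PIP3
dephosphorylation (a feedback onto PTEN). Variants 1/2 place the edge from
mTORC1 (read out as phospho-PRAS40) onto IRS/PI3K with strength `Ki2`;
variant 3 has no feedback; variants 4-7 connect PDPK1 or mTORC2 onto
IRS/PI3K or PTEN (`Ki2`); variants 8/9 connect Akt onto PTEN or IRS/PI3K
with separate limb strengths `Ki2a` (pT309-only Akt) and `Ki2b` (doubly
phosphorylated Akt).

A deliberate naming decision: `Ki2a`/`Ki2b` are treated as Akt's catalytic
rate constants wherever active Akt acts. They parameterise the
Akt-dependent SIN1/mTORC2 activation legs in *every* variant, and
additionally the feedback limbs in variants 8/9. Consequently the pan-Akt
inhibitor recipe — nulling `{Ki2a, Ki2b, Kf11a, Kf11b}` — is well defined
for every variant and silences all Akt catalytic output (feedback, mTORC2
activation, PRAS40 phosphorylation) while leaving PIP3-driven membrane
binding of (inactive) Akt intact, which is exactly how an ATP-competitive
Akt inhibitor behaves.

The basal operating point is set by a constitutive ligand equivalent `L0`
(nM, calibrated within [1e-3, 0.5]): serum-starved cells retain basal
receptor activity, and the fold-over-basal normalisation of TIRF data is
only meaningful with a nonzero basal signal. Letting the optimiser place
the basal point proved essential: the data compress a 100-fold ligand
change (basal to 1 nM) into a 2-fold response, which constrains how far
below the low dose the basal state may sit.

### Inhibitors as parameter nulling

rapamycin = `Ki2 -> 0`; pan-Akt inhibition = `{Ki2a, Ki2b, Kf11a, Kf11b} ->
0`; T309A = `Kf6 -> 0`; S474A = `Kf7 -> 0`; wortmannin = `Kf3 -> 0`.
Acute treatments are modelled by nulling at stimulus time over the
unperturbed basal state; the wortmannin washout scenario nulls `Kf3` 10 min
after insulin, once the trace has plateaued.

## Numerics

The inner loop (basal equilibration plus one stiff ODE solve per
stimulation condition, tens of thousands of times per calibration) is
numba-compiled. The stepper is the classic 2(3) L-stable Rosenbrock pair
(ode23s) with a finite-difference Jacobian each step, a hand-rolled LU
factorisation shared by the three stage solves, and the scheme's quadratic
dense-output interpolant so output density never limits the step size.
Reference simulations use rtol 1e-8 / atol 1e-10 (moiety conservation
holds to ~1e-10 relative, comfortably within the 1e-6 invariant);
calibration uses rtol 1e-5 / atol 1e-8 with a 600-step budget per
condition, and solver failures score a large finite penalty (1e12) so the
GA can continue.

The basal steady state is computed by a damped fixed-point cascade: at zero
insulin each moiety's steady state has a closed form given the others (the
four membrane-Akt forms are a 4x4 linear solve), iterated with damping 0.5
to relative tolerance 1e-13. This gives every component full *relative*
precision regardless of magnitude — essential because fold-over-basal
normalisation divides by basal components that can be arbitrarily small,
where any absolute-tolerance solver (Newton or long integration, both kept
as fallbacks) returns noise and silently corrupts the objective landscape.

## Synthetic data

Feature mode encodes the printed kinetics exactly. The overshoot family is
`g(t) = (1-phi) O(t)/O(tp) + phi (1 - exp(-ka t))` with `O(t) = exp(-kd t) -
exp(-ka t)`; given the rise rate `ka`, the peak condition is linear in
`phi`, reducing the two constraints (peak time exactly 75 s; amplitude at
600 s exactly half the peak amplitude) to a bracketed 1-D root find in
`kd`, solved to 1e-14. The default rise rate is `ka = 0.03 /s`: with a
faster rise (1/ka well under the peak time) the family cannot both peak at
75 s and decay to half by 10 min — the achievable steady fraction is
bounded near 0.55 — so 0.03 /s is the fastest round default that leaves
margin for the constraint solver across the tested config range.

The 100 nM curve adds a slow logistic component (midpoint 400 s, width 80
s); its two amplitudes solve a 2x2 linear system pinning the peak amplitude
at exactly four times the 1 nM peak amplitude and the endpoint at 0.95 of
the first peak (the endpoint is not a printed number; 0.95 keeps the
secondary rise below the first peak so the discrete argmax stays at 75 s).
Akt-inhibitor and kinase-dead conditions are saturating exponentials scaled
to exactly 3x and 3.5x the control peak amplitude; rapamycin duplicates the
control; the wortmannin condition rises to a plateau and decays one-phase
at 0.01 /s after 600 s. Immunoblot-style phospho curves use the same
overshoot family with rise rate scaled to the peak time (`ka tp = 2.5`),
peak times 2 min (pT309) and 5 min (pS474), residual fraction 0.6 at the
20-min endpoint, and a saturating pPRAS40; they are expressed as percent of
the 100 nM maximum (basal 2%). The blot sampling grid
{0, 0.5, 1, 2.5, 5, 10, 20} min and the phospho peak times are free
defaults — no printed number pins them.

Noise is Gaussian and homoscedastic per observable, with standard deviation
a fraction (default 0.1) of that observable's dynamic range, applied at
replicate level (default n = 4) so the SEM is computed, not assumed. All
stochastic output is byte-reproducible under a fixed seed.

What the generator does *not* emulate: cell-to-cell heterogeneity,
correlated (time-autocorrelated or multiplicative) measurement error, blot
saturation, or any mechanistic coupling between conditions. Passing tests
therefore certify the pipeline machinery on data with exactly known
properties, not biological fidelity of the curves themselves.

## Calibration

`J(p) = sum_j w_j sum_i ((yD_ji - y_j(t_i, p)) / sigma_ji)^2`, summed over
the eight training series (PM recruitment and the three phospho read-outs
at 1 and 100 nM). Simulations are normalised exactly as the data: fold
over the simulated basal state, and percent of the simulated 100 nM
reference maximum evaluated at the reference series' own sampling times.
Series weights default to 1. Points with sem = 0 (noiseless fixtures) use
a floor of 1e-3 of the observable's dynamic range.

The GA operates in bounds-normalised log10 coordinates (default bounds
[1e-3, 1e3] per rate constant; rates span decades and log-scale mutation is
scale-free). Per generation: the top 5% of individuals pass unchanged;
80% of the remaining offspring come from uniform (scattered) two-parent
crossover with rank-based stochastic-universal-sampling selection; the rest
are Gaussian mutants with the shrinking schedule
`sigma_k = sigma_(k-1) (1 - k/G)`, `sigma_0 = 1`, clipped to bounds.
Repeated runs resample the full starting population (the initial sampling
window within the normalised gene range is configurable); the lowest local
minimum over runs is the global optimum. Named presets: `smoke`
(population 20, 30 generations, 2 runs) for plumbing tests, `reduced`
(60, 150, 5) for desk-scale studies, and `full` (200, 800, 200), the
method's published operating point.

## Identifiability

`chi2_PL(theta_i) = min over theta_{j!=i} of chi2(theta)` on a log-spaced
grid from the optimum out to each bound (default 10 points per direction),
re-optimising the nuisance parameters with warm-started bounded L-BFGS-B
under an evaluation budget; budget-exhausted grid points are flagged. The
CI collects grid-interpolated values whose profile exceeds the optimum by
less than `Delta_alpha = chi2.ppf(alpha, df)` (alpha = 0.95, df = 1
pointwise; computed from the distribution, never hard-coded). Classes:
finite CI on both sides = identifiable; flat in both directions (rise below
0.05 Delta_alpha, a numeric flatness rule the source analysis leaves
unstated) = structurally non-identifiable; any unbounded side otherwise =
practically non-identifiable.

## Reduced problem sizes

Desk-scale presets keep the full pipeline inside single-CPU budgets: the
acceptance script calibrates the mTORC1-feedback variant with population
60, 150 generations, 5 resampled runs and 3 outer seeds (~135k objective
evaluations at ~1-3 ms each); the test suite ranks variants 4-9 with
population 30, 60 generations, 2 runs over 5 seeds, and profiles all 22
free parameters of a calibrated variant 9 at 5 grid points per direction
with a 40-evaluation inner budget. The full preset (200 x 800 x 200 runs
per variant) is exposed in configuration but is orders of magnitude beyond
these budgets.

## Known limitations

* The exact rate equations and best-fit values used in the original
  MATLAB implementation of this workflow are not consumed here; the
  canonical scheme reproduces the qualitative predictions
  (overshoot requires feedback; Akt-site feedback preserves the wortmannin
  dissociation rate while PTEN-site feedback slows it) but not numeric
  best-fit values.
* The magnitude of the rapamycin-perturbation prediction is not identified
  by the training features: any fit that fully reproduces the overshoot
  (amplitude halved between peak and 10 min) needs strong feedback whose
  removal raises the 1 nM peak by far more than the ~25% reported for the
  original mTORC1-feedback fit — a figure consistent with a fit that
  *under*-fits the overshoot. Observed predictions at reduced scale span
  roughly 0-1000% across seeds. At reduced GA scale the calibration lands
  stochastically in a no-overshoot basin (near-zero predicted change) or an
  overshoot basin (large predicted change), so this prediction carries very
  wide seed-to-seed spread.
* At reduced GA scale the ranking of variants 4-9 by global optimum is
  noise-dominated; a stable ordering would require optimisation budgets far
  beyond desk scale.
* The GA is the only calibration engine (no gradient or hybrid refinement),
  matching the method being reimplemented.
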