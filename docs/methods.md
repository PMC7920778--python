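# Methods

## The model

Two species, X and Y, are ecologically neutral: equal per-capita egg
production *r* ≥ 1 (default 25), equal density-dependent mortality *v* > 0
(default 1), and symmetric interspecific resource competition *b* ∈ [0, 1]
(default 0.3).  They differ only in mating behaviour.  With probability *c*
(niche overlap, no default — it is the key experimental dial) a female is
exposed to males of both species and walks a two-stage decision tree:

* **First mating.**  Encounters are conspecific with probability
  f = w_own/(w_X + w_Y), where w_i = a_i·N_i and the activity weights a_i > 0
  (default 1) allow encounter rates to be biased away from raw frequency.
  A virgin accepts a species-j male with probability p_{i|j}; rejected
  encounters are redrawn, so every female eventually mates once (provided
  some acceptance probability is positive — the degenerate all-zero case is
  flagged and returns P = 0).
* **Remating.**  After her first mating a female has m − 1 further encounter
  opportunities (m = `max_matings`, default 2).  Each is a single draw
  accepted with the once-mated probabilities q_{i|j}; an opportunity is
  consumed whether the male is accepted or rejected, reflecting the
  observation that remating opportunities are scarce and rejections forfeit
  them.

Under conspecific sperm precedence a female realises full fecundity *r* as
soon as *any* of her matings is conspecific, regardless of order; otherwise
her matings are wasted.  The probability of at least one conspecific mating
therefore collapses, for m = 2, to

    P_X = (p_XX + p_XY·q_XX·f_Y) · f_X / (f_X·p_XX + f_Y·p_XY),

and for general m to P_first + (1 − P_first)(1 − (1 − f·q_con)^(m−1)) with
P_first = f·p_con/(f·p_con + (1−f)·p_het).  Two consequences the package
tests: P is monotone in m, and P → 1 as m → ∞ whenever f > 0 and q_con > 0 —
with unlimited rematings CSP fully rescues fecundity, which is why
free-spawning marine invertebrates (effectively enormous m) can afford
sympatry while two-shot maters cannot.  The heterospecific remating
probabilities q_XY, q_YX never enter P (a heterospecific remating neither
rescues nor spoils fecundity under CSP); they are carried only for the
individual-based simulator's bookkeeping and default to q_XX, q_YY.

Expected fecundity is E_i = ((1−c) + c·P_i)·r, bounded in [(1−c)r, r], and
densities follow

    dN_X/dt = [E_X − v(N_X + b·N_Y)]·N_X    (mirror for Y).

Mating is assumed fast relative to demography (quasi-stationarity), so P is
evaluated at instantaneous densities.  The *v* coefficient multiplies the
whole competition bracket — this convention reproduces the single-species
equilibrium r/v and is the one the boundary eigenvalues below assume.

### Equilibria and stability

The origin and the two exclusion states B_X = (E_X(alone)/v, 0) = (r/v, 0)
(for p_XX > 0) and B_Y = (0, r/v) always exist; interior equilibria have no
closed form and are found by multi-start root finding (a 20×20 start lattice
over [0, 2r/v]², scipy's hybrid Powell solver on the per-capita growth
system, candidates de-duplicated within 10⁻⁴·r/v and verified to growth
residual < 10⁻⁸·r).  Stability is classified from the eigenvalues of a
central finite-difference Jacobian (step 6·10⁻⁶ × max(density, 0.01·r/v),
which keeps truncation and rounding error below 10⁻⁶ for the tested
magnitudes); real parts within ±10⁻⁸ of zero classify as "marginal".  The
Jacobian at the origin, where frequencies are undefined, is evaluated at an
offset of 10⁻⁸·r along both axes.

At B_X the Jacobian is triangular with eigenvalues {−r, r(1−c−b)}: a rare
Y-invader almost never meets conspecifics (P_Y → 0), earns only (1−c)r, and
suffers competition b·r, so exclusion is locally stable iff **b + c > 1**.
`exclusion_boundary` recovers the critical overlap c* = 1 − b numerically by
bisection (tolerance 10⁻⁹) on the transverse eigenvalue — deliberately
through the finite-difference machinery rather than the formula, so the two
routes check each other.

### Integration and basins

`integrate` uses adaptive LSODA with rtol 10⁻⁹ / atol 10⁻¹², a steady-state
early exit when the derivative norm falls below 10⁻¹⁰, and an extinction
floor: a density crossing 10⁻⁹ from above is set to exactly zero and
integration resumes on the (invariant) axis.  The floor prevents spurious
"atto-population" rescue when a trajectory destined for exclusion hovers at
numerically tiny densities.  Basins of attraction integrate every point of a
lattice (default 50×50) and assign the terminal state to the nearest stable
equilibrium within 10⁻²·r; anything else is reported "unresolved", never
dropped.  Two honest artefacts of the true dynamics: the origin lattice
point is a stationary unstable equilibrium (unresolved), and in the
coexistence regime pure-axis starts converge to the boundary *saddle* —
which is stable within the axis — and are likewise unresolved.

`portrait_export` writes the derivative field, nullcline traces (zero
contours of each growth component via contourpy), the equilibrium table and
optional basin labels as plain CSVs for any plotting tool.

## Signal-detection analysis

For male mating attempts the analysis unit is the session and the correct
signal is a conspecific female; for female rejection the unit is the attempt
and the correct signal is a heterospecific male.  Rates use the log-linear
correction H = (hit+0.5)/(hit+miss+1) applied to *every* cell (not only
degenerate ones) — the documented behaviour of the commonly used d′
implementations, and the variant that reproduces the published male-attempt
indices to ≈3 decimals; because the exact variant used upstream is not
stated, golden comparisons carry a ±0.02 tolerance.  Then d′ = z(H) − z(F),
criterion C = −(z(H)+z(F))/2, and β = exp((z(F)²−z(H)²)/2) = exp(d′·C), an
identity asserted to 10⁻¹⁰.

Binary decisions admit a single ROC point, so the ROC is {(0,0), (f,h),
(1,1)} on *uncorrected* rates and AUC = (1+h−f)/2 (ties one-half).  The
unpaired DeLong test estimates each AUC by midranks, its variance from the
structural components over signal and noise placements, and refers
D = ΔAUC/√(var_A+var_B) to a t distribution with Welch–Satterthwaite
degrees of freedom; a test verifies agreement with pROC's implementation to
10 decimals, and a stratified-bootstrap comparison (10⁴ resamples, normal
reference on the bootstrap SE) serves as a second, independent oracle.
Published female-rejection indices and published AUC/D values are *not*
reproducible from the printed counts (the upstream ROC was evidently fed
covariate-adjusted scores); they are excluded from golden tests, and our
binary-decision AUCs differ from the printed ones by ~0.01–0.02 as expected
under that diagnosis.

## Synthetic data

`simulate_decision_tree` walks the decision tree literally, one replicate
female at a time (vectorised): redraw-until-mated first phase (capped at
10⁴ rounds; replicates still unmated are counted as failures, relevant only
when acceptance probabilities are ~0), then single-draw remating
opportunities with the q probabilities and a mating-count stop.  It shares
no code path with the closed form and is the oracle for it (agreement within
4 SE at 10⁵ replicates across random parameter draws; the test re-estimates
any >4 SE excursion once at 10⁶ replicates with a fresh seed, since a hard
4 SE band over 100 draws fails by chance ~0.6% of the time).

`simulate_sessions` emulates the Petri-dish trials: one female–male pair per
session, one attempt opportunity (matching the session-level "≥1 attempt"
analysis unit), per-cell Bernoulli attempt and rejection probabilities, and
copulation on acceptance or, with a coercion probability, despite rejection.
The default design reproduces the 2014 cell sizes (145/35/87/42 sessions)
and the observed attempt and rejection proportions; coercion defaults to
0.2 — coercive matings are documented upstream but unquantified, so a
moderate value was fixed once.  What the generator does *not* emulate: male
age/size/colour covariates, multiple attempts per session (the long-2015
design), female mating-history effects, and non-independence from reusing
individuals across sessions.  Passing parameter-recovery tests therefore
show correctness of the counting and estimation pipeline, not that real
trials are this clean.

Seeds are explicit arguments everywhere; no generator touches global random
state.  `make_fixtures` writes the packaged reference tables (8 contingency
rows; 24 species pairs) byte-stably.

## Problem sizes in the shipped tests

The default suite runs the full analysis at the sizes reported throughout:
10⁵–10⁶ Monte-Carlo replicates, a 50×50 basin lattice on [0, 30]², 50 random
draws for the eigenvalue closed-form check, 20 scenarios × 10⁴ bootstrap
resamples for the DeLong cross-check, and 2,000 null simulations for the
type-I error of the DeLong test (empirically ≈0.05 at n = 100 per arm).

## Known limitations

* Two species only; no demographic stochasticity, age structure, or hybrid
  offspring accounting (CSP is assumed complete).
* Interior equilibria are found numerically; an exotic equilibrium outside
  the search box or a basin boundary thinner than the lattice spacing would
  be missed.
* The m > 2 remating chain assumes opportunity-limited remating; if real
  females instead redraw rejected remating encounters indefinitely, P for
  m > 2 would differ (the m = 2 headline model is unaffected).
* The DeLong test's t reference is asymptotic; at very small cell counts
  (< ~10 per row) its p-values and the bootstrap's may both be unreliable.
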