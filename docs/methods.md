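# Methods

## Model

Each strategy arm (vesico-amniotic shunting, VAS; conservative
management) is a single decision tree evaluated over a horizon of at
most one year — short enough that no discounting, half-cycle
correction or state-transition machinery is appropriate. Terminals are
the closed set of health states of the clinical pathway: pregnancy
loss before 24 weeks (termination, chorioamnionitis, miscarriage),
death in utero after 24 weeks, death within 24 hours of delivery,
neonatal death (24 h–28 d), infant death between 28 days and 1 year,
and survival to one year with no / mild / moderate / severe renal
impairment. Each terminal carries a cost payoff in GBP (2011 values)
and a binary effect triple (surv28, surv1y, mfs); the ordering
mfs ≤ surv1y ≤ surv28 holds at every terminal and is therefore
preserved by expectation. Rollback computes
E[payoff] = Σ_paths (Π branch probabilities) × payoff; an independent
path-enumeration routine is kept as the test oracle for the rollback
recursion.

Because the published figures describe the tree verbally without
printing branch counts, the shipped structures are reconstructions:
the VAS tree opens on the course of the shunt itself (uncomplicated /
dislodgement with re-insertion / chorioamnionitis ending the
pregnancy), the two non-chorioamnionitis branches leading to
structurally identical pathway subtrees with their own probabilities;
the conservative tree is a single pathway subtree whose early-loss
split retains all three causes. Effects here are per-patient
probabilities in [0, 1]; published tables report effect cells on a
different (tool-specific) scale whose convention is not recoverable,
so cross-arm arithmetic on those printed cells is treated as input
data, not as a rollback target.

## Probability estimation

Branch probabilities come from observed counts at each chance node.

- `mle` (base case): p̂ᵢ = xᵢ/n. A node with n = 0 is unreachable
  under MLE (its parent branch count is 0 by flow conservation) and is
  assigned an inert uniform vector.
- `uniform_prior`: p̂ᵢ = (xᵢ+1)/(n+K), the posterior mean under a flat
  Dirichlet(1,…,1) prior. The point-estimate rule is a package choice
  (the prior is named in the source analysis, the estimator is not);
  the posterior mean is standard, defined at n = 0, and produces the
  expected shrinkage behaviour — e.g. a nonzero conservative-arm
  morbidity-free survival even though no such patient was observed.
  The uniform-prior base case applies to the ITT cohort (configurable).
- `fixed`: explicit probabilities, validated to sum to 1 ± 1e-9.

For probabilistic sensitivity analysis, whole probability vectors are
redrawn per iteration from Dirichlet(α) — Beta being the K = 2 case:
α = counts (`mle_centred`, mean = MLE; undefined and therefore
rejected when any count is 0) or α = counts + 1 (`uniform_prior`).
The pipeline default for MLE base cases is `auto`: mle-centred
wherever all counts are positive, with the add-one fallback at nodes
containing zeros. This keeps PSA means close to the base case — on
the shipped cohort, mean PSA arm costs sit within 1% of the base-case
rollback at 20,000 iterations — while remaining defined at the sparse
nodes a 31-patient trial inevitably produces. With much sparser
subtrees the fallback's prior mass can move PSA means by more
(several percent), which is a property of add-one smoothing, not of
the sampler. Costs stay at base-case values during PSA: no
distributional family for costs is specified by the source analysis,
so only probability uncertainty is propagated.

## Incremental analysis and PSA summaries

ΔC = C_vas − C_cons, ΔE likewise per outcome, ICER = ΔC/ΔE. A
comparison is classified rather than reduced to a ratio: dominant
(ΔC < 0, ΔE > 0), dominated (ΔC > 0, ΔE < 0), equal-effect (ΔE = 0),
otherwise `icer_reported`. Negative ratios are never headline output —
they conflate the two dominance quadrants — but the signed quotient is
retained for report footnotes. The CEAC evaluates, on a £0–£100,000
grid in £500 steps (covering the £20,000 and £40,000 landmarks),
P(λ·ΔE − ΔC > 0); ties count as not cost-effective, affecting at most
1/n_iter. The CE-plane reports per-iteration (ΔE, ΔC) with quadrant
counts under strict inequalities (axis points tallied separately).

## Cohort views and sensitivity scenarios

ITT groups by randomised arm; per-protocol drops post-randomisation
terminations from both arms (the source phrasing does not restrict
the exclusion to one arm); as-treated groups by treatment received.
Deterministic scenarios: DSA1/DSA2 scale the per-insertion shunt
procedure cost (£821.80, itemised bottom-up: device £154.30, scan
£445.50, counselling £80.50, consultant and assistant insertion time
£80.50 + £61.00; summed in integer pence) by 2 and 0.5 — touching
conservative-arm crossovers who received a shunt, so both arms' costs
move; DSA3 replaces each total cost above £50,000 (the threshold is
configurable; £50,000 is the one figure attached to the outliers) with
the same randomised arm's non-outlier mean, implemented by
proportional rescaling of all components so the record invariant
total = Σ components survives; DSA4 re-runs the ITT estimator on the
as-treated grouping.

Terminal cost payoffs are per-terminal means of observed patient
totals. A terminal no patient reaches inherits the nearest ancestor's
subtree mean (ultimately the arm mean): under uniform-prior or `auto`
regimes such terminals carry positive probability, and pricing them at
£0 would bias expected costs downward.

## Synthetic cohort generator

The generator emulates the randomised cohort's published margins
exactly in expectation: arms 16/15; crossovers 3/2 (assigned
deterministically to the first records of each arm so view arithmetic
is exact); per-arm terminal-state tables giving 28-day survival 8/16
and 4/15, 1-year survival 7/16 and 3/15, conservative early losses
3/15, no conservative morbidity-free survivor, and post-randomisation
terminations 1/2 (the last pair back-solved from the per-protocol
effect scaling of the published tables). Intermediate splits (early
loss cause, renal-grade mix, dislodgement probability 2/16) are
fixture choices consistent with those margins — the true per-branch
counts were never published.

Costs are itemised lognormals (log-sd 0.25) with state-specific means,
structural zeros (no delivery or neonatal cost for pregnancy losses),
a deterministic £821.80 per shunt insertion, and an outlier component:
with probability 0.27, a patient randomised to and receiving a shunt
whose pathway includes a neonatal admission has that admission redrawn
as £50,000 plus a lognormal excess — reproducing the observed pattern
of roughly three >£50,000 NICU-driven outliers confined to the shunted
arm. Means were calibrated analytically so expected ITT arm costs land
near £20,851/£9,868 (realised ≈£20.6k/£9.4k over 200 cohorts). These
are calibration targets of the fixture; the generator does not claim
to reproduce the confidential patient data, and passing tests show the
pipeline's correctness on cohorts with this structure, not clinical
conclusions about real patients. Not emulated: gestational-age
dynamics, correlation between crossover status and outcome, centre
effects, and any cost–outcome correlation beyond the state-conditional
means.

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng`; one seed
  per entry point, chance nodes sampled in sorted-id order, so every
  artefact is bit-reproducible under a fixed seed.
- Path probabilities are validated to sum to 1 ± 1e-9; fixed
  probability vectors to 1 ± 1e-9; costs are carried at full precision
  and rounded only at render time (nearest £ in reports, pence in
  patient CSVs).
- Decision nodes are supported only as single-branch pass-throughs: a
  strategy tree has its decision pre-made, and alternatives live in
  separate trees.
- The robustness check of the full pipeline (20 seeded cohorts, ITT
  base case, 2,000-iteration PSA) asserts a dominance-free ΔC > 0,
  ΔE > 0 comparison with an upper-right-modal CE plane in ≥ 90% of
  seeds. Under the generator's own design values the exact probability
  of a cohort realising ΔE(28 d) > 0 is 0.907 — a 31-patient trial is
  simply that noisy — so the 90% bar is intrinsically tight; the
  shipped seed set realises 18/20.
- Problem sizes used by the test suite: 50 random trees (depth ≤ 6)
  for the rollback oracle; 10^5 draws for posterior-mean convergence;
  10,000 patients per arm for generator recovery (tolerance 0.02);
  20,000 PSA iterations for the base-case consistency check.

## Known limitations

- Effects are per-patient probabilities; no QALY weighting or utility
  estimation (none is estimable for infants under 2), only the
  ICER/threshold extrapolation `required_qaly_gain`.
- No confidence intervals or hypothesis tests on relative risks; the
  package reports point summaries, with uncertainty handled by the
  PSA.
- Single-trial, two-strategy comparisons only: no multi-way frontiers,
  no expected value of perfect information, no cost inflation indices,
  no modelling beyond one year (long-term renal morbidity — dialysis,
  transplantation — is exactly where such a model would need to grow).
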