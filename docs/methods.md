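# Methods

This note documents the models, algorithms and design choices behind
`audcheck`, in the spirit of the methods documentation of statsmodels or
msprime: enough detail that a careful reader can re-derive what the code
does and judge what passing tests do and do not establish.

## Model

Each of the J = 11 checklist items is a Bernoulli indicator of one DSM-5
AUD criterion. Conditional on a unidimensional latent severity θ, responses
are independent with the two-parameter logistic (2PL) response function

    P_jg(θ) = 1 / (1 + exp(−a_jg (θ − b_jg))),

in the plain logistic metric (no 1.7 scaling constant). The discrimination
a_jg > 0 sets the slope and the severity b_jg the location, both potentially
group-specific. The latent trait is N(0, 1) in the reference group by
convention — that fixes the scale — and N(μ_F, σ²_F) in the focal group
with both moments free. A parameter may be *shared* (equality-constrained
across groups) or *group-specific*; anchor items are always fully shared,
and at least one fully shared item must exist for μ_F, σ²_F to be
identified.

The metric convention matters for reproducing published parameter values:
with the 1.7 constant the same data yield discriminations smaller by that
factor and a different impact-curve maximum. The plain logistic metric is
what modern IRT software defaults to and is the convention under which the
embedded published item bank reproduces its printed 0.13-criteria headline.

## Estimation

Marginal maximum likelihood via Bock–Aitkin EM.

* **Quadrature.** 61 equally spaced nodes on [−6, 6]; each group's weights
  are its normal density at the nodes, renormalised to sum to one. The
  rectangle rule with Gaussian-decaying integrands converges fast: the
  marginal log-likelihood is stable to < 1e−6 against a 10× finer grid
  (asserted in the tests), and the grid re-weights cheaply each time the
  focal moments update.
* **E step.** Per-respondent posterior weights over nodes, computed from
  log-probabilities with log-sum-exp; expected respondent counts n_gq and
  endorsement counts r_jgq per group, item and node.
* **M step.** Each item solves its expected weighted Bernoulli likelihood
  by Newton's method with step halving, in the parametrisation that keeps
  the subproblem concave where one exists: slope/intercept (a, c) with
  b = −c/a for fully shared or fully free items (pooled across groups when
  shared), common slope with per-group intercepts when only a is shared,
  and a direct (a_ref, a_focal, b) Newton with the full (non-concave)
  Hessian when only b is shared. Discriminations are kept in
  [1e−4, 100] by the line search.
* **Focal moments.** Updated each cycle as the posterior mean and variance
  of θ pooled over focal respondents, then the focal weights are rebuilt.
  This is the standard EM realisation of "freely estimated" group moments;
  on a ±6 grid the truncation term it neglects is O(1e−9), so the observed
  log-likelihood still increases monotonically to numerical precision
  (tests assert no decrease beyond 1e−8).
* **Starting values and convergence.** a = 1, b = 0, moments (0, 1) unless
  warm-started; stop when the log-likelihood improves by < 1e−5 *and* no
  parameter moves by > 1e−4, up to 500 cycles. Non-convergence is flagged,
  never silent; likelihood-ratio machinery refuses non-converged fits.
* **Degenerate inputs.** An item with constant responses in the data that
  estimate one of its parameters (within-group for group-specific
  parameters, pooled otherwise) puts that parameter on the boundary; this
  raises a boundary error naming the item rather than returning a runaway
  estimate.

**Standard errors** are square roots of the diagonal of the inverse
observed information of the *marginal* likelihood: the score is computed
analytically (for item parameters from posterior residual counts, for the
focal moments from the derivative of the renormalised weights) and the
Hessian by central finite differences of that score with per-coordinate
steps 1e−4·(1 + |ψ|). A non-positive-definite information matrix raises an
identification error. Fixed quantities (reference moments, pooled copies)
get no standard-error entry.

## DIF detection

Anchored, iterative likelihood-ratio testing with stepwise purification:

1. Fit the all-shared baseline (anchors and everything else pooled, focal
   moments free).
2. Test every non-anchor, not-yet-freed item against the current model.
3. Free the offending parameter(s) of the most significant item if its
   p-value is at or below the Bonferroni-corrected per-item level
   α = familywise / J (0.05 / 11 ≈ .0045 by default — the divisor is the
   full item count, not the non-anchor count).
4. Refit and repeat until no new item reaches the level. Ties are broken by
   smaller p, then lower item index; the procedure is deterministic given
   the data.

Two testing schemes are provided. The default **parameterwise** scheme
tests each parameter separately: 1-df likelihood ratios for freeing a
alone and b alone, an item being significant when either test is. This
matches the convention of DIF parameter tables that constrain *parameters*
(not whole items) to equality at a stated α, and in simulation it
reproduces severity-only DIF patterns cleanly — b-shifted items are flagged
on b alone — while having more power for single-parameter DIF than a 2-df
test spread over both parameters. The **joint** scheme tests both
parameters at once (2 df) and, when significant, localises with the 1-df
follow-ups, freeing both parameters when neither follow-up is individually
significant. Both schemes keep anchors untested and untouched.

Anchor choice defaults to a user-supplied set (the three-item set of the
published analysis when replicating it). An automatic mode ranks items by
their joint 2-df statistic in an all-shared scan and takes the k smallest
as anchors — a pragmatic all-others-as-anchor purification for datasets
without established anchors.

**What re-detection power means here.** The simulation study treats the
published *estimates* as generating truth. Effects that were near the
significance boundary in the original data are then re-detected with
roughly 50% probability (for example, a severity shift of 0.14 on an item
with a ≈ 2.7 at these group sizes has a 1-df noncentrality near the .0045
critical value of 8.07). Across the 12-replicate study the expected number
of flagged items is therefore close to 3, not the full 4 of the generating
pattern, and the modal flagged count across replicates is typically 3 with
the strongest item (social/interpersonal problems, which differs in both
parameters) flagged essentially always. This is a property of re-simulating
from estimated effect sizes, not of the detector: under a no-DIF generating
bank the procedure's rejection rate is at the nominal level (asserted by a
200-replicate calibration test).

## DIF impact

Expected test score per group, T_g(θ) = Σ_j P_jg(θ), evaluated on a θ grid
over [−4, 4] with step 0.01 (covering > 99.99% of both latent
distributions; the maximum is stable to < 1e−3 under grid refinement). The
headline summary is the unweighted maximum over the grid of
|T_focal(θ) − T_reference(θ)|; a secondary, clearly-labelled extension
reports the mean absolute difference weighted by the focal latent density,
which answers "how big is the gap for a typical online respondent" rather
than "how big can it get". Shared banks give identically zero curves.

## Severity scoring

Criteria counts are plain sums of the 11 binary responses; the DSM-5 rule
maps 0–1 → no AUD, 2–3 → mild, 4–5 → moderate, 6–11 → severe (≥ 2 is the
diagnostic threshold). Tabulations are deliberately *unadjusted* — the
synthetic data carry no demographic covariates, so covariate-adjusted
prevalence modelling is out of scope — with Wilson 95% intervals (well
behaved at boundary proportions, where Wald intervals degenerate) and a
chi-square comparison of the severity distribution when two groups are
present.

## Synthetic data

The generator emulates the analysed study sample: 1603 reference and 1640
focal respondents, reference θ ~ N(0, 1), focal θ ~ N(−0.05, 0.90),
responses drawn from the group-resolved published item bank. Contamination
is optional and applied after response generation: item-wise missingness,
missing completely at random at a per-item rate (default 0.002, chosen so
roughly 2% of checklists have at least one missing item, matching the
order of magnitude of exclusions in the motivating study), and duplicate
checklists per patient at rate 0.02 (the study reports that repeats
occurred but not how often; a few percent is a realistic clinical-workflow
figure). Recovery-focused runs use zero contamination so the analysed
sample sizes are exactly the published ones.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: missingness is independent of severity
(real skipping may be informative), modality is assigned, not self-selected
(the real groups differ demographically), there are no covariates, no
response styles, no local dependence among items, and the latent trait is
exactly normal. The simulation answers "does the pipeline recover known
structure under the model's own assumptions", not "is the checklist
modality-invariant in any particular clinic".

## Problem sizes and seeds

The replicated simulation study uses 12 fixed seeds (1–12) at the published
group sizes — enough replicates to identify the modal detection outcome and
check 3-SE coverage while keeping a full run in minutes on one CPU. Null
calibration of the likelihood-ratio test uses 200 replicates at a reduced
size (two groups of 150, five items), where the nominal-rate check has
binomial standard error 0.015. All randomness flows through explicit
integer seeds; rerunning any stage with the same seed is bit-identical.

## Known limitations

* Two groups only; no polytomous, 1PL/3PL, multidimensional or Bayesian
  variants.
* Equally spaced quadrature with renormalised normal weights (not
  Gauss–Hermite); accurate here, but the node range must cover the latent
  distributions (|mean| + a few SDs well inside ±6).
* The focal-moment M step uses posterior moments of the discretised trait;
  with very coarse grids or extreme moments the neglected renormalisation
  term could bite.
* Likelihood-ratio p-values rely on the χ² asymptotics; at very small n or
  near-boundary discriminations they are approximate.
* The stepwise procedure shares the general caveats of sequential testing:
  the final constraint pattern is data-dependent, and reported standard
  errors do not account for the selection.
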