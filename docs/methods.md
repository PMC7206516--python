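# Methods

This note documents the models, algorithms and design choices behind
`cogbn`, in the order the pipeline runs them, together with the
assumptions of the synthetic study conditions and what the tests do and
do not establish about real cohort data.

## The synthetic cohort and its planted model

The generator (`cogbn.synth`) emulates a community-based cohort of adults
aged 70+ with repeated NP examinations.  Its calibration constants
(`cogbn.variables`) are published cohort characteristics: 4512
examinations of 2091 participants; status counts 3514 HC / 555 AD / 443
NAD; per-group score means and SDs for all 11 tests; prevalences of male
sex, ApoE4 carriage and post-secondary education per group; and each
test's score range and granularity (integers, except half-point PASi).

**Planted graph.**  The default ground truth is a 12-node DAG:

    SIM -> BNT30 -> VRi -> VRd -> Status
    SIM -> VRr  -> VRd
    Status -> LMi -> LMd -> LMr
    Status -> PASi -> PASi_h -> PASd_h

Abstract reasoning, naming and visual function form the upstream chain
into status; verbal memory and paired-associate learning are downstream.
VRr enters VRd as a second, non-adjacent parent.  This collider is a
deliberate design choice: without at least one unshielded v-structure
every orientation of a chain graph is Markov-equivalent and edge
directions would be undecidable from data, making any
direction-sensitive recovery measure arbitrary.

**Planted bins.**  Each test has 4 planted score intervals (fewer than
the up-to-10 intervals the discretizer can fit) with boundaries at
quartiles of the status-mixture score distribution, snapped to the
scoring grid.  Four bins keep exact enumeration over the network cheap
(the largest free-state space in blanket analyses is ~6.5 × 10^4
configurations) while preserving the group separation of the reference
means.  Tests whose range has fewer grid points than requested (VRr,
PASd_h) get singleton-per-value bins.

**CPT construction.**  Each test has a target profile h(bin | status):
the mass a Normal(mean_s, sd_s) places on its intervals.  Direct children
of status use h as their CPT.  Test→test edges use a Gaussian-copula
construction: within each status group the two scores are bivariate
normal with correlation ρ = 0.7 (0.55 on the secondary VRr pathway), and
the CPT is the row-normalised discrete conditional of the π-weighted
mixture of those bivariates (trivariate for VRd's two parents, with the
parents conditionally independent given the child's latent score).  This
gives adjacent tests the strong ordinal coupling that intra-cluster test
pairs show in real batteries (r > 0.6).  The status CPT given VRd starts
from Bayes weights π_s·h_VRd(bin|s) and is calibrated by iterative
proportional fitting so that the *induced* status marginal equals the
target (0.779, 0.123, 0.098) exactly.

Consequences worth knowing: conditional means of tests adjacent to
status track the reference values closely (E[LMd | HC] ≈ 10.6 vs 10.2),
but each extra edge between a test and status shrinks its group
separation toward the pooled mean (E[LMd | AD] ≈ 5.8 vs 3.0), because
information about status passes through a discrete 4-level bottleneck.
The planted model is therefore conservative about downstream group
separation relative to the real cohort.

**Sampling.**  Participants receive Geometric(mean 2.2) examination
counts.  A participant's status is drawn once from the induced marginal
and shared across their examinations; each examination is then an exact
draw from the network conditioned on that status (ancestors of status by
enumeration and Bayes inversion, descendants by forward sampling).
Within-participant scores are otherwise independent — no practice
effects, ageing trajectories or informative dropout are modelled.  A
sampled bin becomes a raw score uniform on the bin's scoring grid
(the least-informative continuous completion).  Scores are masked
missing completely at random at rate 0.05 by default; status and sex are
never missing; ApoE4 and education are missing at the reference rates
(200/4512 and 11/4512).

A second generator, `block_ground_truth`, plants five disconnected
cognitive-function blocks (verbal memory, visual memory, new learning,
reasoning, naming) with ρ = 0.95 star edges and 8 bins; it exists to
test correlation-cluster recovery, where the default chain model —
like any chain — attenuates correlation with graph distance.

## Discretization

`pam_1d` is k-medoids on the line: greedy BUILD initialisation followed
by best-improvement SWAP steps accepted while total absolute deviation
strictly decreases, computed over unique values with multiplicity
weights.  Ties: assignment goes to the lower medoid; equal-cost medoid
sets prefer the lexicographically smaller; equal silhouettes prefer
smaller k.  BUILD+SWAP is a local search; on adversarial value multisets
it can terminate one coordinated double-swap away from the global
optimum (measured ~1.4% of random n ≤ 10 integer fixtures), though on
fixtures with genuine cluster structure it matches brute force.

Mean silhouette width uses (b − a)/max(a, b) with singleton clusters
scored 0; `k` ranges over 2..min(10, #distinct values).  Fitted
intervals span each cluster's observed extremes; on dense integer data
this reproduces the familiar contiguous "(lo,hi), (lo,hi)" published
table shape, while sparse data leave gaps between intervals — a held-out
value falling in a gap is treated as unobserved evidence during
cross-validation rather than an error.

Note a genuine behaviour of silhouette selection on discrete scores:
when a column takes few distinct values with clear frequency structure,
k equal to the number of values (singleton bins, s̄ = 1) is often
optimal, which is why published interval maps contain many singleton
intervals.

## Correlation clusters

Pearson product-moment r on raw scores with pairwise-complete
observations (≥3 required per pair); clusters are connected components
of the graph with edges at r ≥ 0.6 (the signed value by default;
`use_abs` is available).  A Pearson chi-square independence test on the
discretized pair (`chi2_pair`) is reported alongside.  Status
association uses one-way ANOVA per test, Bonferroni factor 11, and
Tukey–Kramer studentized-range contrasts (statsmodels), which handle
unequal group sizes.

## Structure learning

The score is BIC/MDL per family:
`Σ_jk n_jk log(n_jk / n_j) − (log N / 2)·q·(r − 1)`, with q counting
only parent configurations that occur in the data, evaluated on the
jointly complete-case rows so that move deltas are comparable; BDeu and
AIC are available behind a switch.  Hill-climbing applies the best
strictly-improving add/delete/reverse move, with deterministic
lexicographic (source, target, move-type) tie-breaking, family-score
caching, and optional random restarts from perturbed incumbents.  Tabu
search follows the same trajectory while improvements exist, then
accepts the least-worsening non-tabu move, pushing each move's inverse
onto a FIFO list (default length 10, patience 50, aspiration allowed),
and returns the best network visited.

A practical finding that shaped the defaults: with score-equivalent
single-edge additions, deterministic tie-breaking makes hill-climbing
lock chains into tie-preferred orientations that single-move reversals
cannot later fix even with restarts; tabu search escapes these plateaus
and reaches the enumeration optimum on the planted data.  Bootstrap
model averaging (B resamples with replacement, default 500 in the
pipeline config; B = 200 in the recovery analysis) therefore uses tabu
as its default learner in the analysis drivers.  The averaged network
keeps edges with strength ≥ 0.5 oriented by majority direction, breaking
any residual cycle by dropping its weakest edge.

Recovery fidelity depends on the binning of the input: with the planted
4-bin maps, the averaged network attains structural Hamming distance
0–2 to the truth (median 0.5 over 10 seeds at n = 4500); with the
finer fitted maps (up to 10 bins), BIC's larger penalties and the
thinner per-configuration counts cost several edges/orientations
(SHD ≈ 10 in the driver run).  This resolution sensitivity is a real
property of BIC-scored discrete networks, not an artefact.

## Parameters, blanket, inference

CPTs: MLE rows n_jk/n_j with unseen-configuration rows set uniform and
counted in the fit report; Bayesian rows
(n_jk + iss/(rq)) / (n_j + iss/q) with iss = 1 by default.  Inference
consumes the Bayesian fit because MLE zeros would zero out
likelihood-weighting weights.

The Markov blanket is parents ∪ children ∪ co-parents; each node is
reported in a single role (parents take precedence over spouse listing).
Conditional independence uses a stratified Pearson X² with adjusted
degrees of freedom: within each stratum of the conditioning set, zero
rows/columns are dropped and the stratum contributes
(r_x*−1)(r_y*−1) df; empty and degenerate strata contribute nothing,
and total df ≤ 0 yields p = 1 — the mechanism behind the p ≈ 1 pattern
when conditioning on a set that (nearly) determines the target.

Likelihood weighting samples non-evidence nodes ancestrally, clamps
evidence, and weights by the evidence likelihood given sampled parents;
`averaged_inference` averages the posteriors of (default) 100 repeats of
5000 samples, with per-repeat seeds derived from the master seed via
`SeedSequence`, and reports effective-sample-size diagnostics.  The
exact oracle enumerates completions of the evidence (vectorised, chunked;
refuses state spaces above 10^8).  Diagnosis is the posterior argmax
with exact ties resolved HC < NAD < AD and flagged.

## Cross-validation and stratification

Folds are stratified by status over examination rows (the analysis
unit); `group_by_participant` optionally keeps a participant's exams in
one fold.  Per training fold: discretization (scope `fold` by default —
leakage-safe; `global` mimics a fit-once flowchart; `planted` uses the
generator's own bins), bootstrap-averaged structure (B = 25, a
compromise between averaging quality and runtime), Bayesian CPTs, then
per-row diagnosis from the observed, mappable test bins via averaged
likelihood weighting (10 × 500 samples in the driver).  The binary
collapse for sensitivity/specificity is any-dementia vs HC; AD-vs-rest
is available, since a 3-state outcome admits more than one collapse and
published single sensitivity/specificity pairs do not determine which
was used.  Stratified analyses drop rows missing the stratifier (counts
reported) and skip — rather than fail on — strata with fewer than the
fold count of any class.

## Problem sizes and seeds

Analysis drivers default to the reference cohort size (4512
examinations).  The automated checks use: 20 random 12-variable models ×
10 evidence sets at 5000 samples × 20 repeats for the inference oracle;
100 random 3-variable datasets (n = 2000) against enumeration of all 25
DAGs; 10 cohorts of n = 4500 with B = 200 for structure recovery;
100,000 forward samples for parameter recovery; 200 evidence rows for
blanket sufficiency; 500 replicates of n = 10,000 for chi-square
calibration; and one n = 4500 ten-fold cross-validation.  All
randomness flows from explicit integer seeds; the pipeline manifest
records every derived stage seed and artifact hash.

## Known limitations

- The generator's downstream group separations are conservative (see
  above); real-data effect sizes for LMd/LMr/PAS subscores are larger.
- Repeated examinations are exchangeable given status; no progression,
  practice effects, age structure or informative missingness.
- Covariates stratify but are not network nodes, so stratified
  differences in synthetic data arise only from sampling noise unless
  distinct planted models are supplied per stratum.
- PAM is a local search (see Discretization); silhouette-driven k on
  coarse discrete data tends to the singleton-bin solution.
- Structure recovery statements are specific to the planted bins and
  sample sizes stated; passing tests show the machinery is correct and
  calibrated, not that an 11-test battery identifies the true clinical
  dependency graph.
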