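# Methods

`radnet` implements a network-based strategy for nominating driver genes
of acquired radioresistance from a paired radioresistant/radiosensitive
omics contrast, and for testing the nominated drivers as relapse markers
in a patient cohort. This note documents the models, the parameters that
matter, the synthetic data that exercises the pipeline, and the design
choices made where the design was genuinely open.

## The analysis model

**Gene-level copy-number calls.** Segmented aCGH log2-ratio profiles
(SEG records, 1-based inclusive on disk, 0-based half-open internally)
are mapped onto gene coordinates. A gene spanning several segments
receives the overlap-length-weighted mean of their log2-ratios — a
deterministic rule chosen because breakpoint genes are rare and any
weighting is defensible. States are trinary at a symmetric cutoff
(default 0.1 on the log2 scale) with *strict* inequalities, so values at
exactly ±cutoff are `unchanged`; genes with no overlapping segment are
logged and called `unchanged`.

**Differential expression.** Replicate log2-intensity arrays (3 vs 3 by
default) are quantile normalized jointly (classic rank/mean construction
with ties averaged), collapsed to a per-gene average log2-ratio
(resistant minus sensitive), and ordered along chromosomes. A
three-state hidden Markov model with Gaussian emissions — states
underexpressed / unchanged / overexpressed — is trained by Baum–Welch on
the pooled per-chromosome sequences (chromosomes are independent
sequences sharing one parameter set, because positional dependence
cannot span a chromosome end). Initialization: state means −1.25 / 0 /
+1.25, standard deviation 0.5 per state, sticky transitions (0.9 self),
uniform start. The unchanged mean is left free and states are relabelled
by sorted means after training. The M-step is pure maximum likelihood
(no covariance prior), which keeps the log-likelihood exactly
non-decreasing — asserted on every fit; variances that collapse below
1e−4 are floored post-fit with a warning. Genes are assigned by
posterior (forward–backward) decoding with ties broken toward
`unchanged`. Genes whose expression call matches the direction of their
copy-number call (increased & over, or reduced & under) are the
*direct candidates*.

**Network inference.** Each gene's expression across a patient cohort is
modeled as a linear combination of its own copy number and all other
genes' expression. Predictors are standardized to unit variance (the
copy-number term penalized like the rest); the lasso penalty is chosen
at minimum 10-fold cross-validated error, evaluated by interpolating the
piecewise-linear LARS path of each training fold onto a common geometric
grid (capped at 150 path knots — well beyond any penalty the CV ever
selects at desk scale). Each predictor entering the path is scored with
the covariance test: the drop in covariance between the full lasso fit
at the next knot and the fit restricted to the previously active set,
scaled by the noise variance, is asymptotically Exp(1) under the null,
so p = exp(−T). The noise variance comes from OLS residuals when
n > p + 1 and otherwise from the residuals at the CV penalty with the
active-set size as the degrees-of-freedom correction. A predictor is
kept when it is active at the CV penalty *and* its entry p-value is
below the selection cutoff (default 1e−3 — a config knob; the underlying
idea is "keep only links with p approximately zero"). Local regulators —
predictors on the target's chromosome within `local_gene_cutoff`
positions in chromosomal gene order (default 50) — are pruned after the
significance test, because segment-level copy-number alterations make
physical neighbours spuriously co-expressed. Surviving predictors become
signed directed edges (activator iff coefficient > 0), and per-gene
predictive power is the Pearson correlation between model-predicted and
observed expression on data disjoint from training (an independent
validation cohort when available, else a held-out sample split).

*What edge recovery can and cannot mean.* Per-gene sparse regression is
neighborhood selection: it identifies the conditional-dependence
skeleton of the expression distribution. The direction of an edge is not
identifiable from observational Gaussian data — if a regulates b, then a
also helps predict b's residual signal and vice versa, so a true edge
a→b is typically recovered together with its reversal b→a. Recovery is
therefore benchmarked on the undirected skeleton (precision/recall
against planted undirected edges), while the *sign* of every recovered
true directed edge is still required to match the planted sign.

**Propagation impact.** A candidate's observed expression log2-ratio in
the cell-line contrast (the propagated quantity, since candidates are
defined by same-direction expression change) is pushed along all
directed network walks up to `max_path_length` (default 5; "all paths"
is unbounded in cyclic graphs and truncation is the standard
resolution — the norm of the last term is reported as a convergence
diagnostic). Each step multiplies by the edge coefficient and by the
reliability weight of the node entered, where weights are the
predictive-power correlations clipped to [0, 1] (an unpredictable gene
silences paths through it). Computationally this is a sum of powers of
the weighted adjacency matrix; self-impact is excluded; the impact of
candidate a on gene b is the absolute value of the signed walk sum times
|signal(a)|. A candidate's score is its mean absolute impact on the
marker-gene set. The null model is 10 degree-preserving network
permutations (regulator slots exchanged pairwise between target models,
coefficients travelling with the slots, self-loops and duplicate edges
rejected, 10× edge-count attempted swaps); the same 10 permuted networks
are shared across candidates. Per candidate, a one-sided one-sample
t-test asks whether the 10 differences (original − permuted score) are
greater than zero; Benjamini–Hochberg q < 0.01 over the candidate set
defines the nominated drivers. Zero-variance differences are degenerate
for the t-test and resolved by rule: p = 0 if all differences are
positive, else 1 (with a warning).

**Patient transfer.** Drivers are first filtered for sign-consistent
behavior in irradiated patients with an observed relapse: Pearson
correlation (rank correlation available as an option) between
pre-treatment expression and months-to-relapse must be strictly negative
for up-drivers and strictly positive for down-drivers. Each surviving
candidate is screened as a relapse marker on the irradiated subcohort:
candidate cutoffs are midpoints between consecutive sorted unique
expression values, only splits leaving at least `min_group_size`
(default 8) patients on each side are considered, the low group is
expression ≤ cutoff, and the cutoff minimizing the asymptotic log-rank p
is selected (ties to the smaller cutoff; the selected split's p is
reported without selection-bias correction, matching standard
optimal-cutoff practice). The exact permutational log-rank p-value is
the fraction of all C(n, n_low) group-label assignments whose log-rank
chi-square is ≥ the observed one, enumerated exhaustively when that
count is feasible and otherwise estimated by seeded Monte-Carlo
(add-one corrected) with the mode reported. FDR over the screened set is
estimated two ways: Benjamini–Hochberg (conservative) and Storey with
pi0 = #{p > 0.5}/(0.5 m) (liberal; never above the conservative value
when pi0 < 1). A random-gene baseline repeats the screen on uniformly
drawn gene sets and reports the mean count of genes passing p < alpha
with a normal-approximation CI. Cox proportional-hazards models (partial
likelihood, via lifelines) are fitted with and without the candidate
group flag next to age, T-stage, Gleason and PSA.

## The synthetic generator

The generator supplies every input with a recoverable truth. A sparse
signed coefficient matrix W (diagonal zero) is drawn with requested
density and inhibitor fraction, weights uniform in 0.4–0.9 with signs,
then rescaled to a target spectral radius < 1 so the simultaneous linear
model x = (I − Wᵀ)⁻¹(β⊙c + ε) is solvable (cycles allowed). Genes are
placed on chromosomes with strictly increasing coordinates. Patient
copy-number profiles are segment-level: per chromosome, with probability
`segment_prob` one contiguous gene block receives a Normal(0, cna_sd²)
log2-ratio shift. The cell-line contrast plants one focal alteration per
driver (signed by the driver's direction), decoy focal alterations on
non-driver genes, and broad segments over ~15% of the genome, with
per-segment magnitudes drawn from continuous ranges (focal ≈ 0.4–0.6,
broad ≈ 0.2–0.4) so expression shifts form a continuum rather than two
spikes; expression shifts are the dosage effects propagated through W,
plus replicate noise (sd 0.1) on 3 + 3 arrays. Drivers are chosen among
zero-in-degree hubs (so planted shifts cannot be cancelled by incoming
regulation), each driver contributes one of its direct targets to the
marker set, and relapse times are exponential with log-hazard linear in
standardized driver expression (coefficient +1.5 per sd for up-drivers,
−1.5 for down-drivers), administratively censored at the empirical
(1 − censor_frac) quantile. Covariates (age, T-stage, Gleason, PSA) are
simulated independently of the drivers so survival signal is
attributable to the planted hazard alone.

**Problem sizes and coupling.** Two presets are used. The *strong-signal
benchmark* for edge recovery is 100 genes, density 2%, spectral radius
0.7, 400 patients with cna_sd 0.5 and segment_prob 0.4. The *end-to-end
preset* is 300 genes, density 0.6%, spectral radius 0.7, 400 patients
plus a 100-sample independent validation cohort. The lower density at
300 genes is deliberate: with the spectral radius fixed below 1, the
per-edge coefficient scales inversely with connectivity, so a denser
desk-scale network would push every individual edge below the detection
floor of any regression method at these sample sizes; about 1.8
regulators per gene keeps planted coefficients near 0.2–0.5. Local
pruning uses a cutoff of 5 gene positions at desk scale (30 genes per
chromosome) in the end-to-end runs — the library default of 50 is
calibrated to genome-scale annotations of hundreds of genes per
chromosome. Edge-recovery benchmarks disable pruning because the
synthetic truth places edges independently of chromosomal position.

**What the generator does not emulate.** Probe-level microarray
structure, batch effects, realistic clinical covariate distributions,
nonlinear regulation, and measurement platforms differing between cohort
and cell lines. Passing tests on this generator show that the pipeline's
machinery recovers structure it is statistically entitled to recover at
desk scale; they do not certify performance on genome-scale tumor data,
where effect sizes, confounding and multiple-testing burdens are
harsher.

## Numerical choices and degenerate inputs

- Quantile normalization refuses missing values; impute by row median
  first. It assumes arrays share a common distribution — contrasts in
  which a large fraction of the genome shifts violate this and attenuate
  tail values (a reason the generator keeps differential expression
  confined to a minority of genes).
- HMM: EM stops at |Δ log-likelihood| < tol (default 1e−4) or max_iter
  (default 100). A profile shorter than 30 genes is refused.
- Lasso: fits require n ≥ max(30, 3·cv_folds) samples; zero-variance
  targets are errors naming the target. The CV fold split is fixed
  (seeded) so per-target fits are independent of execution order.
- Exact log-rank: exhaustive below 10⁷ assignments (configurable),
  Monte-Carlo otherwise; the constant-statistic case returns p = 1.
  Assignments are compared with a 1e−12 tolerance on the chi-square so
  ties with the observed statistic count as extreme.
- Optimal-cutoff search: cohorts smaller than 2·min_group_size, or
  constant expression, return an explicit infeasible result rather than
  a p-value; censored-only cohorts are likewise infeasible.
- Fisher overlap tests default to one-sided over-representation — this
  choice reproduces published overlap p-values exactly, which settles
  the sidedness ambiguity empirically.
- Pipeline determinism: one global seed is fanned out to per-stage seeds
  via SeedSequence spawn keys; identical config + seed gives
  byte-identical output files.

## Known limitations

- Edge direction is not identifiable (see above); downstream propagation
  treats recovered edges as directed, inheriting reversal noise. In the
  synthetic benchmarks this mainly adds symmetric background that the
  degree-preserving null absorbs.
- The covariance test is applied at each predictor's first entry knot
  with a plug-in noise variance; knots beyond the CV penalty are not
  scored. Exp(1) is an asymptotic null; at desk-scale n it is
  conservative for late entries.
- With only 10 permutations the t-test on impact differences has 9
  degrees of freedom; q < 0.01 over tens of candidates demands
  consistently positive differences, so borderline drivers (weakly
  recovered out-edges) drop out — the price of the small permutation
  budget the method prescribes.
- Optimal-cutoff p-values are reported without selection-bias
  correction; the exact permutational p partially compensates and is the
  honest quantity on small cohorts.
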