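# Methods

## Model and pipeline

The pipeline treats a developmental expression course as the output of a
first-order kinetic system: transcript abundance x_g obeys
dx_g/dt = u_g(t) − λ_g x_g, where u_g is the net transcriptional drive and
λ_g = ln 2 / h_g the decay rate for half-life h_g. Because per-gene
half-lives are unknown, inference assumes a single median half-life h and
reconstructs the drive on each sampling interval by finite differencing:
r_g(k) = Δx_g/Δt_k + λ x_g(t_k). Intervals join consecutive timepoints
within one continuous series only; replicates sharing a (series, time) are
averaged before differencing; the TF predictor for interval k is the TF's
level at the interval start (causal convention). Expression enters
untransformed, since the method consumes normalized abundances (RPKM or
normalized counts) directly; the whole pipeline is invariant to a global
positive rescaling of the input (responses are linear in expression and the
regression standardizes internally).

Candidate regulators are screened by mixed CLR. Mutual information uses
rank transformation, equal-count binning with n_bins = max(2, ⌊√n⌋) and the
plug-in estimator in nats; ranks make it invariant to monotone
normalization differences between platforms, and ties are broken by stable
sort order so the estimate is deterministic. The dynamic matrix holds
MI(r_g, x_tf) over intervals; the static matrix MI(x_tf, x_tf′) over all
samples. z_row corrects each dynamic value against its target's row
(sample standard deviation, n−1); z_col corrects it against the regulator's
column of the static matrix, excluding the self-pair — MI of a TF with
itself is a degenerate maximum, not a draw from the background — and both
are clipped at zero before combining as s = √(z_row² + z_col²). Candidates
are the TFs with s > 0, best-first, up to top_q = 50 (deliberately above
the 30-per-target reporting cap so the regression does the final pruning);
a target is never its own candidate, which structurally excludes
self-regulation from every output.

The fine phase fits, per target, an Elastic Net over the candidate
predictors (ρ = 0.5; 30-point log-spaced α grid from α_max down three
decades; response and predictors standardized internally). Cross-validation
folds are contiguous blocks of intervals rather than random shuffles, to
respect temporal dependence; ties in CV error resolve to the larger α. Each
TF with a nonzero coefficient gets confidence
c_j = sign(β_j)·max(0, R²_full − R²_−j), the variance-explained cost of
removing it at the same α, bounded in [−1, 1]. With repeat > 1 the fit is
re-run on interval resamples (with replacement, seeds seed+i) and |c| is
averaged over all repeats — zero when a TF is not selected in a repeat — so
the ensemble score carries selection stability; the majority sign is kept,
ties resolving positive. The prediction table keeps |c| above the reporting
threshold (default 0), at most 30 ranked regulators per target, ties broken
by TF identifier.

Evaluation matches edges directed and sign-blind; sign accuracy is a
separate top-k statistic over matched edges with known ground-truth sign.
Percentages are rounded half-up to two decimals. Ground-truth curation
removes self-loops, signaling-intermediate rows (flagged in the input, as
the original curation was manual), edges touching unmeasured genes, and
duplicates, in that order; the operation is idempotent. One published cell
is internally inconsistent (a 74/115 comparison printed as 64.53% beside a
miss rate of 35.65%); the evaluator computes from counts and reports 64.35.
The rank-enrichment permutation test asks whether matched edges sit high in
their per-target ranked lists: the statistic is their mean rank, the null
redraws ranks uniformly without replacement within each target's list, and
the p-value uses the add-one correction.

## Synthetic generator

The generator emulates the statistical structure the inference assumes:
signed TF → target regulation, first-order decay, maternal transcripts
present at fertilization and decaying, and count-like multiplicative noise.
Networks draw per-target in-degree ~ Poisson(2) (the density scale of the
curated benchmark networks, ~2 edges per gene), regulators uniformly among
the other TFs, weight magnitudes uniform on [0.5, 2] with random sign, and
half-lives uniform on [3, 15] h — the range explored on real data. Twenty
percent of genes are maternal, starting at a level of 2–5 and decaying;
zygotic genes start near zero. A gene with neither regulators nor a
maternal store would be constant, which cannot occur in a universe defined
by differential-expression filtering, so such genes are flagged maternal.

Dynamics are dx/dt = λ_g (max(0, b_g + Σ_j W_gj σ(x_j)) − x_g) with the
saturating occupancy σ(u) = u²/(1 + u²) (Hill exponent 2, bounding the
drive and providing the nonlinearity that distinguishes MI screening from
plain correlation). Scaling production by λ_g makes the steady state
x* = b + Wσ(x*) independent of decay rate, keeping every gene's level on
the graded region of σ; without this, slow-decaying genes accumulate far
into saturation and the simulated course carries almost no regulatory
signal. The production floor encodes that repression can silence a promoter
but not actively degrade transcript. Integration uses an explicit
exponential-Euler step (exact for the decay part, first-order in the
drive's variation, A-stable for short-half-life genes) at dt = 0.05 h;
measurement noise is unit-mean lognormal with coefficient of variation 0.1
by default, drawn independently per measurement and per duplicate.

Two schedules mirror the real platforms: `sparse10` uses the classic
staging series 0, 10, 18, 24, 30, 40, 48, 56, 64, 72 hpf (single
replicate); `dense2h` samples every 2 h in duplicate, 34 timepoints
(t = 0…66 h, the span of 34 points at 2 h).

What the generator does **not** emulate: spatial (territory-resolved)
averaging, extrinsic signaling inputs, transcriptional bursting, and
platform-specific count distributions. The consequence matters for
interpreting tests: a single autonomous ODE course started from one initial
condition evolves on a low-dimensional manifold, so TF trajectories are far
more mutually correlated than real, territory-averaged embryonic profiles.
Passing tests therefore demonstrate correctness of the machinery, not that
recovery rates transfer to real data — and conversely the recovery ceiling
measured on synthetic data (below) reflects that collinearity, not a defect
of the estimators.

## Study sizes and measured behavior

Synthetic benchmarks use 30 genes / 10 TFs (dense course) and 20 genes /
8 TFs (sparse course); these sizes match the gene counts of the real
benchmark comparisons (30–53 genes) and keep every analysis and the test
suite within minutes on one CPU. The analysis configuration for synthetic
studies uses repeat = 10: with ~9 candidate TFs per target the single-fit
Elastic Net is selection-unstable under collinearity, and the resampling
ensemble roughly doubles the recovered edge set.

Measured on the dense benchmark (seed 1, noise cv 0.1): the full prediction
table recovers ~55% of true edges; the noiseless ceiling is similar (~51%),
and ordinary least squares on the exact noiseless design misattributes
collinear regulators, confirming that the limit is the identifiability of a
single relaxation course (predictor effective rank ≈ 3), not noise or the
estimator. Half-life sweeps on data with a uniform 6 h half-life show the
*shortest* assumed half-life winning (h = 2: ~71%, h = 6: ~59%,
h = 18: ~61%): a large λ makes the response approach λ·x, effectively a
co-expression profile, which on collinear data detects edges more reliably
than derivative reconstruction — consistent with the flat half-life
response reported on real embryonic data.

## Numerical and interface choices

Expression files are gene × sample TSV (17-significant-digit floats, so
write∘read is bitwise identity); predictions are regulator,target,confidence
CSV with 6-significant-digit confidences and ranks rebuilt on read.
Transcript → gene collapse sums abundances (conserves mass). RPKM follows
value / (length/10³) / (library/10⁶). Zero-variance predictors are dropped
with a warning; a constant vector has MI 0 by definition; σ = 0 backgrounds
yield z = 0. The CLI is a thin layer over the library: every output CSV
carries a version/seed/parameter comment header and each stage writes a
JSON manifest with input hashes. All randomness flows from explicit integer
seeds; two runs with the same seed produce identical artifacts.

## Known limitations

Self-interactions are structurally invisible to the response model.
Confidence scores compare variance explained within a target and are only
roughly comparable across targets. The per-gene half-life heterogeneity of
real embryos is reduced to a single median in inference (by design, as in
the original tool), and the sweep shows the result is not sensitive to
matching the true value. The DEG stand-in caller is a max-fold-change rule
for fixtures only and does not emulate any published caller's statistics.
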