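# Methods

## The output model

All pipelines interrogate the same scalar model of "pathway behaviour",
the Sobol g-function

    f(x) = Π_{i=1..d} (|4·x_i − 2| + a_i)/(1 + a_i),  x ∈ [0,1]^d, a_i ≥ 0.

It is non-linear, non-monotone, has mean exactly 1 over the unit cube, and
its ANOVA decomposition is known in closed form: each factor contributes
partial variance `V_i = (1/3)/(1+a_i)²`, the total variance is
`D = Π(1+V_j) − 1`, the first-order index `S_i = V_i/D` and the total index
`T_i = 1 − (Π_{j≠i}(1+V_j) − 1)/D`.  These closed forms serve as the oracle
for every variance-based estimator and are themselves validated once
against brute-force quadrature at d ≤ 2 in the test suite (tolerance 1e-4).
Lower `a_i` means a more important factor.  In the expression pipelines the
coefficient vector `a` is drawn once per run, uniformly on [0,1]^d, from a
recorded seed (`a_seed`); d is 18 for the static panel and 71 for the time
course.  The realised `a` is part of every run log, because the indices of
a run are only interpretable relative to it.

Expression data must be mapped into the g-function's domain, the closed
unit cube.  The static pipeline min–max scales each gene within each
condition group and bootstrap replicate (the experiment segregates by
condition first, and scaling is monotone, so within-replicate ranks are
untouched).  The time-series pipeline has two modes: *scaled* (per-gene
min–max, as in the static case) and *non-scaled*, the mode in which results
are reported, where a single affine map over the whole sample matrix sends
the global minimum to 0 and maximum to 1.  The global map preserves
cross-gene geometry — where a gene's measurement distribution sits relative
to the others and how wide it is — which is exactly the structure a
"non-scaled" analysis is meant to retain; per-gene min–max would erase it
and make every time point look identical.  A consequence worth knowing:
under the multiplicative g-function, a factor whose mapped values sit near
the kink at 0.5 (where |4x−2| ≈ 0) has a large relative effect on the
output, so a gene's influence varies over time with where its fold change
sits in the global range.  That is the mechanism by which per-interval
indices distinguish intervals.

## Weber-law deviations

Bernoulli's logarithmic law γ = b·log(β/α) gives a sensation increment
Δγ = b·log(1 + Δβ/β) that depends on the stimulus only through the
relative step, and inverting it recovers the Weber ratio
k_r = exp(Δγ)^{1/b} − 1 = Δβ/β exactly.  Natural logarithms are used
throughout; the identity is base-invariant, so nothing downstream depends
on that choice.  This is the rationale for the deviation experiment: the
quantity the pathway plausibly responds to is the change in fold change
between consecutive time points, not the level.

## Variance-based estimators

Pick-freeze estimation evaluates the model on two independent n×d sample
matrices A and B and, per factor i, on AB_i (A with column i replaced from
B), at total cost (d+2)·n evaluations.  f(B) and f(AB_i) share exactly
column i, so their covariance estimates the partial variance D_i; f(A) and
f(AB_i) share everything except column i, which yields the complement
variance behind the total index.  The five variants implement the
canonical published forms:

- `sobol1993` / `saltelli2002`: S_i = (mean(f_B·f_AB_i) − f0²)/D,
  T_i = 1 − (mean(f_A·f_AB_i) − f0²)/D, with f0² = (pooled mean)² for the
  1993 form and mean(f_A)·mean(f_B) for the 2002 form;
- `mauntz2007`: S_i = mean(f_B·(f_AB_i − f_A))/D,
  T_i = mean(f_A·(f_A − f_AB_i))/D;
- `jansen`: T_i = mean((f_A − f_AB_i)²)/(2D),
  S_i = 1 − mean((f_B − f_AB_i)²)/(2D);
- `martinez`: S_i = corr(f_B, f_AB_i), T_i = 1 − corr(f_A, f_AB_i).

The model output is centered (pooled A/B mean subtracted) before **every**
variant, not only the 2002 form whose documentation demands it.  The
covariance-form estimators are badly conditioned for non-centered output —
with the g-function's mean of 1 the f0² correction dominates the signal
and roughly doubles the estimator noise (measured: worst-case first-order
error 0.032 vs 0.019 at n=2^14 over 20 seeds) — while the difference-based
jansen/mauntz forms are algebraically unaffected by the shift.  Centering
everything is standard practice in sensitivity-analysis libraries.  Total
variance D is always estimated from the pooled A/B evaluations.  Estimates
may fall slightly outside [0,1] by Monte Carlo noise; they are reported
unclipped with an `out_of_range` flag.

Two caveats the tests document: (i) grouped (closed) indices use the same
pick-freeze scheme with all group columns swapped together, and reduce to
first-order indices for singleton groups; (ii) for an output carrying
exogenous noise (noise not a function of the inputs), first-order indices
correctly read ~0, but pick-freeze **total** indices read ~1, because
f(A) and f(AB_i) necessarily draw fresh noise and the estimator cannot
credit the shared columns.  Total indices are only meaningful for
deterministic models.

When the inputs are data rather than a chosen design, the pipelines draw
the pick-freeze design from the **empirical per-gene marginals** of the
(scaled) sample matrix: each column of A and B is resampled independently,
with replacement, from that gene's observed values, at Monte Carlo size
n = 1000 per evaluation point.  This keeps the factor marginals empirical
while making the columns independent (the assumption behind the variance
decomposition) and the Monte Carlo error ~1/√1000.  The alternative of
splitting the 8–24 data rows into A/B halves leaves the estimates
noise-bound (sd ≈ 1/√12) and was measured to carry no rank information;
`estimate_sobol_from_data` still exposes it for direct use.  Sampling is
plain pseudo-random throughout (no quasi-Monte Carlo).

## HSIC and distance correlation

The biased estimator HSIC_n(X,U) = (1/n²)·Tr(K_X H K_U H) is used as
printed, with H(i,j) = δ_ij − 1/n (implemented via O(n²) double-centering,
verified against the explicit three-term expansion to 1e-10).  Kernels:
rbf exp(−‖x−y‖²/2σ²), laplace exp(−‖x−y‖₁/σ), linear ⟨x,y⟩.  Bandwidths
default to the median heuristic — the median pairwise distance (Euclidean
for rbf, L1 for laplace), falling back to the smallest positive distance
when ties push the median to zero — and may be overridden numerically.
The same kernel family is applied to input and output unless the caller
specifies otherwise.  The reported index is the distance correlation
R = HSIC(X,U)/√(HSIC(X,X)·HSIC(U,U)) ∈ [0,1]; R is what the index scale
0 (no dependence) to 1 (full dependence) refers to.  A permutation test
(re-pairing u against x, Gram matrices cached) is available as a
diagnostic because raw index magnitudes are scale-bound; it never gates
pipeline output.

Since rbf/laplace kernels are translation-invariant and the median
heuristic scales with the data, R is invariant under per-variable affine
rescaling.  This is why scaled and non-scaled pipeline runs rank genes
consistently on the input side; any residual differences come from the
output u being evaluated on differently mapped matrices.

## f-divergence indices

S^F_{X_k} = E[F(1/r)] with r = p_{X_k,U}/(p_{X_k}·p_U), estimated as a
sample mean of F(1/r̂) at the observed pairs (cheaper than numerical
integration and consistent).  F: KL −log t, Hellinger (√t−1)², TV |t−1|,
Pearson t²−1, Neyman (1−t²)/t.  Densities are Gaussian-kernel estimates;
the joint uses a product kernel.  One bandwidth per variable is chosen as
`1.2·min(sd, IQR/1.34)·n^(−1/6)` and shared between the joint and the
marginals.  Two deliberate choices sit in that rule: the n^(−1/6) exponent
is Silverman's rate for a two-dimensional density (the joint is the
accuracy-critical piece), and sharing the bandwidths makes the leading
KDE biases cancel inside the ratio.  The mild oversmoothing constant keeps
the noise of F(1/r) small enough that indices are calibrated near zero
under independence; with the classical 1-D n^(−1/5) rule the
total-variation index reads ~0.08 on independent data at n=5000 purely
from estimation noise.  Calibration was verified against the Gaussian
closed form −½·ln(1−ρ²) for the KL index (within 0.1 nats at n=5000 for
ρ up to 0.9, monotone in ρ).

Estimated ratios are clamped below at 1e-12.  Negative readings of the
non-negative divergences (KL/Hellinger/TV/Pearson) are estimation noise;
they are clamped at zero with the raw value retained in `raw_value` and
flagged.  The density-ratio estimator requires at least 30 paired samples
— below that no bandwidth rule gives a usable 2-D density — which means
f-divergence methods cannot run inside the static bootstrap at subsample
sizes 8–24; the pipeline surfaces this as per-replicate failures and, when
every replicate fails, a pipeline error.  Only scalar factors are
supported (grouped factors belong to the Sobol machinery).

Known limitation: the TV index, whose F is non-smooth at t=1, has a null
noise floor that decays only slowly with n (~0.057 at n=1000, <0.05 at
n=5000 under the default bandwidth).  Smooth divergences (KL, Hellinger,
Pearson, Neyman) are calibrated from n≈1000 up.

## Static pipeline

Per condition (normal/tumor separately, matching the segregation-first
design), per subsample size (defaults 8, 16, 24), 20 replicates are drawn
**without replacement** — "bootstrapping without replicates" read as
subsampling with distinct patients per replicate, since with-replacement
resampling at the full size of 24 would be indistinguishable from ordinary
bootstrap noise.  Each replicate is min–max scaled per gene, the
g-function output evaluated, and every requested method's per-gene index
computed.  Replicate values are aggregated as mean plus percentile
confidence band (default 95%, linear-interpolation quantiles; the band is
widened by at most one ulp to contain the mean when replicates are
identical).  Note that at size 24 the without-replacement subsets are
exhaustive, so all 20 replicates coincide and the bands collapse to
points; bands are informative at the genuinely subsampled sizes.  The
coefficient vector a is drawn once per run, so replicate spread reflects
sampling alone.  Failed replicates are skipped and logged; more than 50%
failures abort the run.

With 24 samples per condition the HSIC index carries reliable rank
information only for strongly separated importances: measured across
independent same-model datasets, full 18-gene HSIC rankings have ~zero
reliability when importances form a gentle ladder, because no gene then
carries more than ~11% of output variance while the biased index at n=24
has a noise floor of similar size.  Concordance between the kernel and
variance routes is therefore a top-of-ranking property (both methods
recover a planted dominant gene), not a full-rank correlation — the tests
assert exactly that.

## Time-series pipeline

For each recorded fold change, a measurement distribution of
n_samples = 1000 draws (configurable) is generated: Normal(value,
sd = 0.005) plus uniform jitter with half-width factor·range/50
(replicating the convention of the standard jitter routine, with
fallbacks factor·|value|/50 for zero range and 0.0002 for an all-zero
value).  The fold-change experiment computes per-gene indices per time
point from these matrices; the deviation experiment forms, per interval
<t_i, t_{i+1}>, the difference of **independent** draws at the two
endpoints (distributions are generated per time snapshot, not with common
random numbers), doubling the measurement variance, and computes indices
per interval.  Sign patterns of the deviations are emitted as strings over
+/−/0 ('0' for exact zeros; typographic minus signs in inputs are
normalised to ASCII).  The two-fold filter retains genes whose |fold
change| exceeds 2 at any time point.  Bar labels t1..t5 map to hours
1, 3, 6, 12, 24; the 0-hour baseline defines fold change and receives no
index.

## Synthetic data

The static generator produces log-normal expression (positive, skewed)
with per-gene baselines drawn once per seed and a per-gene
activation/repression contrast expressed in units of the log-scale sd
(default 0.25); defaults are 24+24 samples and the 18-gene panel.  Zero
contrast yields a null dataset in which the two conditions are
statistically indistinguishable (two-sample t p-values uniform across
seeds, asserted).  The time-course generator builds trajectories
deviation-first so requested sign patterns are realised exactly, then
scales each trajectory so that round(two_fold_fraction·n_genes) genes
exceed the two-fold threshold (fraction default 0.5, scaling positive so
signs survive); defaults are 71 genes on hours 1/3/6/12/24.  What the
generator does *not* emulate: replicate structure and qPCR chemistry,
gene–gene correlation (columns are independent given the seed), and any
real biological co-regulation.  Passing tests therefore demonstrate that
the estimators and pipelines recover planted statistical structure at the
study's sample sizes — not that any specific biological conclusion holds.

## Determinism

Every source of randomness is an explicit seed: dataset seeds, the
coefficient seed `a_seed`, the bootstrap/noise seeds, and per-cell Monte
Carlo streams derived deterministically from them.  Re-running any
pipeline with the same configuration reproduces its tidy table and run log
bit-identically, and each CLI run writes a manifest (config, seeds,
package version, config hash) sufficient to do so.

## Problem sizes

Default experiment sizes are the study's own: 18 genes × (24+24) samples,
sizes 8/16/24 × 20 replicates (static); 71 genes × 5 time points /
4 intervals × 1000 draws (time course).  Estimator benchmarks run at
n = 2^13–2^14 design points; calibration checks at n = 5000 pairs;
recovery rates over 20 (static) and 100 (time-series) seeds.  The full
test suite and the acceptance script each run in a few minutes on one CPU.
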