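# wntgsa

Global sensitivity analysis of Wnt-pathway gene expression: which genes,
and *when*, most influence the behaviour of the signalling pathway.

The package targets two study designs common in colorectal-cancer work on
the Wnt pathway:

- **static**: an expression panel of 18 Wnt-related genes (SFRP, DKK, WIF1
  and DACT family antagonists plus target genes such as *LEF1*, *MYC*,
  *CD44*, *CCND1*) measured in 24 normal-mucosa and 24 tumor samples;
- **time course**: signed fold changes of 71 Wnt-related genes at 1, 3, 6,
  12 and 24 h after WNT3A stimulation, relative to the unstimulated 0-h
  baseline.

Because the pathway responds to *relative* changes (a Weber-law behaviour:
the sensation increment Δγ = b·log(1 + Δβ/β) depends only on Δβ/β), the
time-course analysis is run both on fold changes per time point and on
**deviations in fold change** between consecutive time points.

## The indices

Gene expression profiles enter a common output model, the Sobol g-function

    f(x) = Π_i (|4·x_i − 2| + a_i) / (1 + a_i),   x ∈ [0,1]^d,  a_i ≥ 0,

whose ANOVA decomposition is known exactly (smaller `a_i` = more important
factor), and three families of sensitivity indices measure each gene's
influence on the output:

- **Variance-based (Sobol)** — first-order `S_i = D_i/D` and total
  `T_i = 1 − D_{~i}/D` indices by pick-freeze Monte Carlo, in five
  classical estimator variants (`sobol1993`, `saltelli2002`, `mauntz2007`,
  `jansen`, `martinez`) at a cost of (d+2)·n model evaluations.
- **Kernel-based (HSIC)** — the Hilbert–Schmidt independence criterion
  `HSIC_n = (1/n²)·Tr(K_X H K_U H)` with linear/rbf/laplace kernels and
  median-heuristic bandwidths, reported as the distance correlation
  `R = HSIC(X,U)/√(HSIC(X,X)·HSIC(U,U)) ∈ [0,1]`.
- **Density-based (Csiszár f-divergence)** — `S^F = E[F(1/r)]` with
  `r = p_{X,U}/(p_X·p_U)` estimated by kernel density estimation;
  F ∈ {KL, Hellinger, total variation, Pearson χ², Neyman χ²}.

The two experiment pipelines wrap these: the **static pipeline** segregates
by condition, subsamples without replacement (sizes 8/16/24, 20 replicates)
and reports per-gene index means with 95% percentile bands; the
**time-series pipeline** generates a measurement distribution per recorded
fold change (Normal, sd 0.005, plus jitter) and reports per-gene indices
per time point and per interval `<t_i,t_{i+1}>`, with deviation sign
patterns (e.g. `+-++`) and a more-than-two-fold significance filter.

A synthetic-data module generates both dataset shapes with planted
contrasts, exact deviation sign patterns and a configurable two-fold
fraction, so the full pipeline is testable without any download.

## Worked example

`examples/01_gfunction_sobol_benchmark.py` checks all five estimators
against the exact indices:

```
factor importances a = [ 0.   0.5  3.   9.  99. ]
method        S1=0.587  S2=0.261  S3=0.037  S4=0.006  S5=0.000  (analytic)
sobol1993     S1=0.602  S2=0.272  S3=0.048  S4=0.017  S5=0.014
saltelli2002  S1=0.602  S2=0.272  S3=0.048  S4=0.017  S5=0.014
mauntz2007    S1=0.589  S2=0.258  S3=0.034  S4=0.003  S5=0.000
jansen        S1=0.593  S2=0.270  S3=0.049  S4=0.017  S5=0.014
martinez      S1=0.597  S2=0.271  S3=0.048  S4=0.017  S5=0.014
```

Every estimator reproduces the analytic first-order indices to ~0.02 at
n=2^14; the factor with a=0 dominates and the a=99 factor is inert.

`examples/04_static_experiment.py` runs the full static bootstrap on a
synthetic table with a dominant gene (*DKK1*, a=0 against a background of
a=9, 3-sd expression contrast):

```
normal, size 16, top genes by mean HSIC-rbf index:
  DKK1     mean=0.446  95% band=(0.312, 0.599)
  WIF1     mean=0.242  95% band=(0.050, 0.414)
  SFRP3    mean=0.225  95% band=(0.099, 0.407)
tumor, size 16, top genes by mean HSIC-rbf index:
  DKK1     mean=0.528  95% band=(0.386, 0.696)
  SFRP2    mean=0.282  95% band=(0.133, 0.418)
  CD44     mean=0.251  95% band=(0.132, 0.406)
```

The planted gene tops both conditions and the percentile bands quantify
patient-sampling spread.  The other examples cover kernel dependence
detection (`02`), f-divergence calibration against the Gaussian closed
form (`03`), per-interval deviation indices on the 71-gene time course
(`05`) and the Bernoulli-to-Weber reduction (`06`).

## Command line

A thin CLI wraps the library for shell use:

```bash
wnt-gsa simulate static --seed 3 --out data/
wnt-gsa static --input data/static.csv --methods hsic:rbf,hsic:laplace,jansen \
        --sizes 8,16,24 --nboot 20 --seed 11 --output indices.csv
wnt-gsa simulate timecourse --seed 2 --out data/
wnt-gsa timecourse --input data/timecourse.csv --mode deviation \
        --kernels rbf,laplace,linear --nsamples 1000 --seed 3
wnt-gsa report --input indices.csv
```

Every run writes a manifest (config, seeds, versions) sufficient to
reproduce its outputs bit-identically.  Exit codes: 0 success, 2 input
error, 3 degenerate data, 4 pipeline failure.

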