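# Methods notes

## The model-adequacy procedure

For one gene (× tissue) with per-species mean log-expression z̄ᵢ and
standard error seᵢ on a rooted, ultrametric phylogeny:

1. **Fit** BM, OU, and EB by maximum likelihood. Each model implies a
   species covariance: BM gives σ²·C (C = shared branch length), OU gives
   e^(−2α(T−s))·(σ²/2α)(1−e^(−2αs)) for MRCA depth s on a height-T tree
   (the non-stationary, root-conditioned form), EB gives
   σ₀²(1−e^(−r·s))/r. Measurement error enters as a fixed additive seᵢ²
   on tip i — it is not estimated. The root state z0 is profiled out at
   its GLS estimate; the OU optimum θ is constrained to z0 because the two
   are not separately identifiable from tip data on an ultrametric tree
   (this is the standard single-regime parameterization). Full ML, not
   REML: the root state counts as a parameter, so k = 2 (BM) and 3 (OU,
   EB) and AIC = 2k − 2·lnL.
2. **Select** the lowest-AIC model (ties → fewer parameters, then the
   fixed order BM < EB < OU). Akaike weights are reported alongside.
3. **Rescale** branch lengths to the winner's accrued variance (the *unit
   tree*), adding seᵢ² to terminal branches afterwards — measurement
   variance lives on the data scale, not evolutionary time. Under the
   fitted model the independent contrasts on this tree are i.i.d. N(0,1).
4. **Test** that expectation with five statistics (CV of |PIC|; KS D of
   PICs vs N(0,1); OLS slopes of |PIC| on ancestral estimate, node
   height, and expected contrast variance) against `n_sim` parametric
   bootstrap replicates: BM(σ=1) data simulated on the same unit tree and
   pushed through the *same* statistic kernels (one vectorized code path
   serves observed and simulated data, eliminating code-path bias).
   Two-tailed add-one Monte-Carlo p-values:
   p = 2·min(1+#{null ≤ obs}, 1+#{null ≥ obs})/(n_valid+1), capped at 1,
   so p ∈ (0, 1] always. A gene is *adequate* when every non-NA p ≥ 0.05.

No correction for multiple testing across genes: each gene tests the
single hypothesis that its own fitted model generated its data.

### NA semantics

A slope statistic is NA when its predictor is numerically constant
(sample variance < 1e-12·max(1, mean²)). The practically important case
is `s.hgt` under a strongly-pulling fitted OU: nearly all unit-tree
length ends up in the terminal branches, internal node heights carry
essentially no variance, and no slope is estimable. NA observed
statistics yield NA p-values and are excluded from the adequacy verdict;
low `s.hgt` availability is itself a sign of low phylogenetic signal
(confirmable with `blomberg_k`, which matches phytools' K exactly).

## Numerical choices

- **Likelihood path**: model transform → pruning on the rescaled tree.
  The contrasts factorization equals the dense MVN density to 1e-8 on
  random trees (tested against an independently-coded covariance oracle);
  trees pruned to a clade keep their stem as a root edge, which enters the
  covariance as shared variance and the root-estimate variance in the
  likelihood, so root-to-tip distances survive pruning exactly.
- **Transforms** use `expm1` so OU at α → 0 and EB at r → 0 agree with BM
  to 1e-6 relative at α, r = 1e-9; α = 0 or r = 0 exactly takes the BM
  branch. OU/EB transforms hard-error on non-ultrametric trees rather
  than guessing a convention.
- **Search bounds**, scaled to tree height T: σ² ∈ [1e-8, 1e4]
  (log-scale), α ∈ [1e-8/T, 50/T] (log-scale), r ∈ [0, ln(1e5)/T]
  (linear). BM is a 1-D bounded search plus the closed form σ̂² = Σpic²/n
  when all SEs are zero; OU/EB use L-BFGS-B from 3 stratified random
  starts (deterministic given the seed), with σ² initialized to match the
  BM tip variance at each candidate α or r. A fit whose σ̂² lands on a
  bound is flagged unconverged (constant traits end there by design).
- **Degenerate inputs**: unit-tree branch lengths below 1e-12 are floored
  at 1e-12 before PIC division; an all-zero tree with zero SEs is a
  singular covariance and errors. Genes with < 4 usable species
  (min_tips, configurable — below that OU/EB are unidentifiable) or zero
  trait variance are skipped with a recorded reason, never silently
  dropped.
- **Determinism**: every stochastic step derives from an explicit seed;
  per-gene seeds come from a crc32 hash of gene/tissue ids folded with
  the master seed, so study results are independent of gene order and
  reproducible to the byte.

## The synthetic-data generator

`simulate_dataset` emulates the statistical structure the analysis
assumes: a pure-birth (Yule) ultrametric tree scaled to exact height
(topology realism is irrelevant for calibration, so no birth–death
machinery); per-gene traits evolved by recursive root-to-tip simulation —
for OU with the exact conditional law child = θ + (parent−θ)e^(−αb) +
N(0, (σ²/2α)(1−e^(−2αb))), *not* the unit-tree increments, which are
discounted to the present and would under-disperse deep nodes; Gaussian
replicate noise on the log scale (default sd 0.2 log2 units, triplicates —
typical for bulk RNA-seq biological replicates), so collapsing replicates
yields honest standard errors.

Misspecification fixtures: `BM-2rate` multiplies σ² by a factor (default
8) on a marked clade containing ~⅓ of the tips; `OU-shift` moves θ by 2
log2 units on that clade. Fitting single-regime models to these
reproduces the canonical failure signature: rejections concentrate in
`c.var` and `s.asr`.

What the generator does **not** emulate: count-level sequencing noise
(simulation starts at normalized log expression), unequal replicate
numbers, missing-data structure correlated with the tree, gene-tree
discordance, or non-ultrametric trees. Passing calibration tests
therefore demonstrates the statistical machinery is correct under the
models' own assumptions — not that real expression data satisfy them;
detecting the latter is precisely what the adequacy test is for.

Default generating parameters: σ² log-uniform on [0.5, 2] (log2 units²
per unit tree height), αT log-uniform on [1, 4] (the regime where OU and
BM are distinguishable but not trivially so), rT uniform on [1, 3].

## Problem sizes used by the calibration scripts

The acceptance script simulates 1,000 genes (500 bootstrap draws each) on
a 20-tip tree for the type-I-error check and 200 genes for the unit-tree
whitening check; parameter-recovery tests use a 200-tip tree with 100
replicates. These sizes give Monte-Carlo error comfortably inside the
assertion bands (e.g. the binomial 95% band around 5% at n=1000 is
[3.7%, 6.4%]) while keeping a full run to seconds–minutes on one core.

## Known limitations

- Single-regime models only: no multi-optimum/multi-rate OU, Pagel's λ,
  or white-noise model; no joint estimation of within-species variance.
- The OU fit treats θ = z0; data demanding separate optima will simply
  fail adequacy (by design).
- `s.hgt`'s NA threshold is a numerical convention; fitted α near the
  search bound can leave tiny-but-nonzero node-height variance and a
  wildly unstable (non-NA) slope — the bootstrap null has the same
  instability, so the p-value remains calibrated.
- Polytomies are resolved to zero-length bifurcations (covariance-
  preserving, recorded in run metadata); contrasts at zero-length nodes
  rely on the 1e-12 floor.
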