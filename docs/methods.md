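# Methods

## The analysis problem

`nichecompare` implements the statistical pipeline for comparing
bacterial communities across four oral niches — supragingival plaque,
buccal mucosa, tongue dorsum mucosa and stimulated saliva — sampled
repeatedly from the same dogs. The design is blocked at two levels:
every dog contributes every niche on each of three sampling occasions,
and plaque and buccal mucosa are sampled on both sides of the mouth
(left/right treated as replicates, since there is no hypothesis for a
side effect). Input is an OTU-by-sample read-count table plus sample
metadata (dog, niche, occasion, side) and OTU annotation (taxonomy,
phylum, Gram-stain status, oxygen requirement).

## Preprocessing

* **Sample QC** — samples with a total read count strictly below 1000
  are excluded. The default threshold is configurable.
* **Rare-taxon grouping** — an OTU is pooled into a single `RARE` unit
  if its average proportion is below 0.05% in *every* niche, or if it
  has a nonzero count in fewer than two samples. "Average proportion"
  is the unweighted mean of per-sample proportions within each niche's
  QC-passing samples; a pooled-count-ratio alternative is available via
  `average="pooled"` because the operative definition is ambiguous at
  this level of description. Grouping runs after QC (excluded samples
  cannot contribute averages), conserves column totals, and is
  idempotent (a pre-existing `RARE` row is never regrouped).

## Differential abundance

Each analysis unit (OTU, or a phylum / Gram / oxygen category obtained
by summing member counts; "unknown" annotations are excluded from
category sums but the denominator stays the sample's full read total)
is modelled as a binomial GLMM with a logit link:

    y_i ~ Binomial(n_i, p_i)
    logit(p_i) = beta[niche(i)] + b[dog(i)] + c[occasion(i)]
    b_d ~ N(0, sigma_dog^2),  c_t ~ N(0, sigma_day^2)  (crossed)

where `y_i` is the unit's count out of the sample total `n_i`. Fitting
is maximum likelihood with a Laplace approximation: for a candidate
(sigma_dog, sigma_day) the penalised joint mode in (beta, u) is found
by damped Newton iterations on the standardised-random-effect
parametrisation, and the profile criterion
`loglik(mode) - 0.5 * log|H_uu|` is maximised over the two standard
deviations by Nelder–Mead on |sigma| (so sigma = 0 is an interior
point and boundary fits need no special casing; at zero variance the
fit provably collapses onto ordinary binomial regression, which the
tests verify against an independent IRLS oracle). A weak Gaussian
penalty (sd 10) on the fixed effects guards against separation when a
taxon is entirely absent from a niche; its shrinkage is O(se²/100) and
negligible whenever the data are informative. Wald covariances are
taken conditional on the estimated variance components, the lme4
convention.

Distributional assumptions are then discharged by a **blocked
permutation test**: niche labels are permuted within each dog
(preserving the dog's multiset of labels; left/right replicates are
permuted as individual samples by default, with a `block="pair"` mode
that keeps side pairs together), the model is refitted per permutation,
and all six pairwise Wald statistics are extracted from each refit.
The two-sided permutation p-value uses the add-one estimator
`p = (1 + #{|z_perm| >= |z_obs|}) / (n_perm + 1)`, which is strictly
positive and maintains finite-sample type-I control. Permutation refits
that fail are dropped and counted; more than 20% failures aborts the
unit. Default `n_perm` is 999 and every run takes an explicit seed.

Benjamini–Hochberg adjustment (via statsmodels) is applied across all
units *within* one niche-pair comparison, i.e. six families, matching
how pairwise significance counts are reported "out of 224" units.

## Diversity and ordination

* **Shannon index** per sample, natural log (the index's common form;
  base-2 available). Compared across niches with a Gaussian linear
  mixed model (statsmodels MixedLM, REML) with niche fixed and crossed
  dog/day variance components; niche means, pairwise differences and
  95% Wald intervals are reported.
* **Dog-blocked PCA** — proportions are offset by a pseudocount (half
  the smallest nonzero proportion by default; the minimal-distortion
  convention for log transforms of closed data), log10-transformed, and
  each dog's mean profile is subtracted before the SVD. This
  "multi-group" centering removes between-dog variation so the leading
  components express within-dog (between-niche) structure. Dogs with a
  single sample contribute nothing after centering and trigger a
  warning.
* **Confidence ellipses** — per-niche 95% bivariate normal regions on
  (PC1, PC2): mean center, sample covariance scaled by the chi-square
  quantile with 2 df. Ellipse intersection areas (used to quantify the
  buccal/tongue similarity) are computed from 256-gon polygon
  approximations via shapely.

## Niche sets and core microbiota

* **UpSet membership** — presence in a niche means the niche-mean
  proportion is *strictly greater* than 0.5%; exclusive intersections
  are computed over all 15 non-empty niche combinations.
* **Core microbiota** — an OTU is core at prevalence q when its
  proportion reaches the detection threshold (*inclusive* ≥ 0.5%) in at
  least ⌈q·n⌉ of the QC-passing samples, per niche and for the pooled
  cross-niche set. The strict-vs-inclusive asymmetry between the two
  rules is deliberate: each threshold is honoured exactly as
  conventionally printed. Prevalence counts use the ceiling so that
  "75% of n samples" is attainable with integer samples.

## The synthetic-data generator

Because the underlying sequence data are not publicly deposited, the
generator produces datasets with the statistical structure the pipeline
assumes, plus exported ground truth, so every downstream stage is
testable end to end.

Design defaults reproduce the study bookkeeping exactly: 14 dogs × 3
occasions, duplicate left/right plaque and buccal samples, one
never-collected saliva sample (first occasion), 8 amplification
failures (2 buccal, 6 tongue) and 5 forced sub-1000-read samples
(2 plaque, 1 tongue, 2 saliva) — 251 collected, 243 sequenced, 238
passing QC.

Per sample, a read depth is drawn log-normally (median ≈ 13 000 reads,
matching the reported per-niche medians; non-forced depths are clipped
at the QC threshold so the sub-threshold count is exact), the niche's
expected composition is perturbed on the logit scale by per-dog and
per-occasion Gaussian intercepts (defaults sigma_dog = 0.5,
sigma_day = 0.25 on the logit scale) and any planted effects, a
composition is drawn from a Dirichlet around that mean, and counts are
drawn multinomially. Left/right replicates share the dog/day
intercepts but get independent Dirichlet/multinomial draws. The
logit-normal construction makes the intercepts exactly the random
effects the GLMM estimates, so variance-component recovery is a
well-posed test.

Default niche profiles are deterministic ranked power-law curves,
`w(r) ∝ r^(-γ)`, with decay chosen to reproduce the observed diversity
ordering: plaque γ = 0.75 (flattest, most diverse), buccal = tongue
γ = 1.05, saliva γ = 1.45 (steepest, dominated by few taxa). The
rank-to-OTU assignment makes buccal and tongue near-identical (adjacent
swaps only), plaque distinct (a plaque-specific Gram-positive
Firmicutes/Actinobacteria set interleaved into its top ranks) and
saliva topped by its own facultative Proteobacteria set. Per-niche
Dirichlet concentrations (plaque 2000, buccal/tongue 200, saliva 2)
encode compositional stability; the very low saliva value makes saliva
the most variable niche between dogs — which is also what empties its
100%-prevalence core list, as observed in the real data. No dispersion
estimates exist for the real data, so these values are chosen for
testability, not fidelity.

`null_dataset` shares one profile *and one concentration* across all
four niches (unequal concentrations would break within-dog niche
exchangeability, and the permutation null would not hold). Planted
effects shift one niche's logit for chosen OTUs; the default power
configuration plants log-odds 1.386 (OR 4) on ten mid-rank OTUs of a
60-unit table.

What the generator does **not** emulate: taxonomic correlation
structure (co-occurrence networks), depth/composition dependence,
contamination, chimeras, or any sequence-level artefact. Passing tests
demonstrate the pipeline's correctness and calibration under the
declared generating model, not fidelity of any specific biological
conclusion about real dogs.

## Problem sizes and numerical choices

* The calibration suite runs the full pipeline on a 224-unit null
  table with `n_perm = 99` (rejection rate of raw permutation p at
  alpha = 0.05, expected band 0.03–0.07, plus a KS uniformity check),
  and the power suite on a 60-unit table with ten planted OR = 4
  effects at `n_perm = 199` (expecting ≥ 8/10 BH-significant). These
  sizes keep a full run in a few minutes on one core while leaving the
  Monte-Carlo error well inside the asserted bands.
* Newton inner loop: convergence at gradient max-norm below
  1e-9·(1+|loglik|), with step halving; outer Nelder–Mead with
  xatol = 0.02 (0.03 with warm starts inside permutation loops).
* Ties in permutation statistics count as "at least as extreme",
  the conservative direction.
* Degenerate inputs: all-zero tables, single-niche designs, zero-total
  samples and collinear score clouds raise explicit errors; zero
  estimated variances are valid fits, not failures.

## Known limitations

* Wald intervals are conditional on estimated variance components and
  slightly anti-conservative for small numbers of dogs; the permutation
  p-values, not the Wald intervals, carry the inferential weight.
* The Laplace variance estimate has the usual ML downward bias with 14
  blocks (no REML-type correction); recovery tests budget a 20% band.
* The permutation test assumes within-dog exchangeability of niche
  labels under the null; designs where read depth depends on niche
  would violate it.
* Exact real-study quantities that depend on the non-deposited data
  (pairwise significance counts, PC variance percentages, core lists)
  are out of reach by construction; the pipeline reproduces the
  in-print arithmetic and the qualitative structure instead.
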