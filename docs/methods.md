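# Methods

## Occurrence model

All estimators assume a product-binomial incidence model: each variant `v`
has a per-tumor occurrence probability `p_v` and occurs independently
across tumors and across variants. A cohort of `m` tumors is summarized by
its frequency-of-frequencies vector `(r, N_r)` — `N_r` distinct variants
observed in exactly `r` tumors — at gene, genome-wide, or gene-pair scope.
`r` always counts tumors, never MAF rows: duplicate rows and multi-allelic
records collapse to one incidence per (tumor, variant).

Variants are identified at protein level by default (`GENE:proteinchange`,
e.g. `KRAS:G12D`), matching how hotspots are reported; genomic keying
(chrom/pos/ref/alt) is a config switch. The non-synonymous SNV filter keeps
`Variant_Type == SNP` with classification in {Missense_Mutation,
Nonsense_Mutation, Nonstop_Mutation, Translation_Start_Site, Splice_Site};
the inclusion set is configurable because conventions differ between
annotation pipelines. Samples with zero surviving variants stay in `m` — the
denominator of every per-tumor probability is *profiled* tumors, not
mutated ones.

## Good-Turing estimation

For a variant seen `r ≥ 1` times, `q_GT = (r+1)/(m+1) · S(N_{r+1})/S(N_r)`.
This is the per-tumor (binomial) framing: `q_GT` is the probability that
this specific variant appears in one additional randomly drawn tumor.
Ratio estimators can exceed 1 in tiny scopes; values are clamped to [0, 1]
with a logged warning.

`S` is the smoothing function. Two methods are provided:

- `none`: `S(N_r) = N_r` exactly. An interior empty class (`N_{r+1} = 0`
  with larger classes occupied) makes the ratio undefined and raises an
  explicit "unsmoothable gap" error rather than silently returning 0.
- `simple_good_turing` (default): the Gale–Sampson procedure. Rank-averaged
  counts `Z_r = N_r / (0.5·(t − q))` (with `q`, `t` the neighboring
  non-empty classes) are fit by least squares as `log Z_r = a + b·log r`;
  raw counts are used for small `r` and the fitted power law after the
  first `r` where the raw and fitted turn estimates are within 1.96
  standard deviations of the raw estimate (or where a gap forces the
  switch). The switch stays permanent once made.

The probability that a new tumor carries ≥ 1 hitherto-unseen variant of a
scope is `1 − exp(−N₁/(m+1))`: the Good-Turing missing mass per tumor,
requiring only the singleton count. Its Poisson rate `N₁/(m+1)` is exposed
separately and the two are consistent by construction.

## Good-Toulmin extrapolation

`Δ(t)` is the expected number of new distinct variants found in `t·m`
additional tumors. For `t ≤ 1` the plain alternating series
`Σ (−1)^{r+1} t^r N_r` is evaluated exactly over every observed class (no
truncation). For `t > 1` the plain series diverges; each term is damped by
the binomial tail weight `P(L ≥ r)`, `L ~ Binomial(k, 2/(t+2))` with
`k = ⌈½·log₂(m·t²/(t−1))⌉` — the standard Euler-transform smoothing choice
from the smoothed Good-Toulmin literature, trading a bias of the order of
the estimator's standard deviation for bounded variance. Negative
estimates (possible when high-`r` classes dominate) are truncated to zero
with a warning. The one-new-tumor prediction is `Δ(1/m)`, which agrees with
the Poisson rate `N₁/(m+1)` to first order.

Standard errors come from a tumor-level bootstrap (default B = 200,
seeded): tumors are resampled with replacement, the frequency vector
rebuilt (a tumor drawn twice contributes twice), and `Δ(t)` recomputed; the
SE is the SD across resamples. An analytic SE is deliberately not offered.

## Cohort stratification

Tumors are partitioned into non-hypermutated, APOBEC, Smoking, MMR, UV,
POLE, or excluded. A dominant-signature label in one of the five SBS groups
wins regardless of burden; unlabeled tumors are non-hypermutated when
burden < threshold (strict) and excluded otherwise. The threshold
transfers across sequencing footprints as
`⌈base · median_target/median_reference⌉`; ceiling is used because it is
the rounding that reproduces the published panel threshold (500·4/54 →
38). Mapping SBS exposure vectors to a dominant label is accepted as input;
an argmax helper over a configurable SBS→group map (APOBEC = SBS2/13 by
COSMIC convention) is provided for convenience, since the upstream
dominance rule is a pipeline choice, not something this package fits.

## Tissue specificity (NMI)

A binary event (a specific variant occurring; a gene producing a
hitherto-unseen variant) with per-tissue probabilities `p_c` and tissue
prevalences `w_c` defines the joint `P(T=c, E=1) = w_c·p_c`. The score is
`I(T;E)/H(T)`: zero iff the event is lineage-independent, 1 for a
tissue-deterministic event. The normalizer is switchable (H(T), H(E), min,
sqrt-product) and always reported, because the literature is not uniform;
H(T) is the default so determinism scores 1. For gene-level unseen events
the per-tissue probabilities come from tissue-stratified frequency vectors
(each tissue's own `m_c` and `N₁`). The index-tissue variant binarizes the
label into index-vs-rest, with the rest pooled by prevalence weighting.

Significance is referenced against a permutation null: tissue labels are
reallocated uniformly at random across tumors (preserving every `m_c`),
the per-tissue probabilities recomputed, and the observed NMI compared to
the null's 95th percentile. Under lineage independence the observed score
is exchangeable with the null draws, so it exceeds the cutoff 5% of the
time by construction — the calibration the test suite checks.

## Gene pairs

Pair analysis is gene-level: a gene is mutated in a tumor if the tumor has
any non-synonymous SNV in it. Co-mutation (both mutated) and mutual
exclusivity (exactly one mutated) are disjoint per-tumor events; with
"neither" they exhaust each tumor. Event counts over a pair universe
(default: all pairs within a user-supplied panel, to keep `N_r` classes
populated) form a frequency vector to which `q_GT` applies with the pair's
observed `r`. A pair whose event was never observed is refused — the
missing-mass formula covers the aggregate of unseen pairs, not any
specific one. Pairs with tissue NMI above 0.01 are flagged as a screening
convention in CLI output.

## Validation

Train on one cohort, validate on another: per gene, the predicted
unseen-variant probability (from training `N₁`, `m`) is compared with the
observed fraction of validation tumors carrying a training-unseen variant,
and `Δ(t = m_valid/m_train)` with the count of validation variants absent
from training. Agreement is scored with Lin's concordance correlation
coefficient `ρ_c = 2·cov(x,y)/(var(x)+var(y)+(mean(x)−mean(y))²)` with
population moments; two identical constant vectors score 1. Validation is
restricted to genes present in both cohorts; subgroup-stratified validation
repeats the comparison within each signature subgroup.

## Synthetic cohorts and oracles

The generator draws each tumor's tissue (and optional hypermutation flag)
first, then each variant independently with its tissue- and
multiplier-adjusted probability capped at 1 (a cap firing for >1% of
variant-tumor pairs logs a misspecification warning). Gene pools follow
log-series, Zipf, or hotspot-mixture laws with the per-gene incidence rate
distributed over the pool. Because every `p_v` is retained, the oracles are
exact: the true unseen probability is `1 − Π(1 − p_v)` over pool variants
unseen in training, and the true discovery count in `t·m` future tumors is
`Σ (1 − q_v^{t·m})` with `q_v` the mixture-averaged per-tumor absence
probability. `sample_variant_counts` draws `r_v ~ Binomial(m, p_v)`
directly — marginally equivalent to full simulation within one stratum —
and is the fast path for replicate harnesses.

What the generator emulates: long-tailed per-gene variant distributions
with singleton dominance, hotspots, tissue-dependent rates, hypermutated
subpopulations. What it does not: trinucleotide contexts and realistic
signature spectra (labels are assigned, not derived), inter-variant
correlation (selection, epistasis), panel-vs-exome capture differences,
and calling error. Passing calibration therefore shows the estimators are
correct under the independence model they assume, not that real cohorts
satisfy that model.

## Calibration harness sizes and conventions

The replicate harnesses use 200 log-series genes at m = 2000 over 100
seeded replicates for Good-Toulmin (t ∈ {0.5, 1, 2}) and unseen-probability
calibration, and 100 genes × 1000 permutations at m = 500 across five
tissues for NMI type-I error and power (10× effect in one tissue). The
cross-cohort analogue uses a 5000/5000 split over 200 mixed
hotspot/long-tail genes with pools of 1000–3000 variants, large enough
that singletons dominate at cohort scale as they do in real catalogs —
with small pools the training cohort exhausts the gene and the comparison
degenerates into pure binomial noise. Calibration asserts that estimator
bias stays within three standard errors of a *single replicate* estimate
(the scale of the error bars a practitioner reads); this targets
systematic error while remaining insensitive to Monte-Carlo noise in the
harness itself.

## Numerical choices and degenerate inputs

- Probabilities are clamped to [0, 1] with logged warnings; negative Δ is
  truncated to 0.
- A scope absent from the data yields an empty frequency vector with `m`
  set, not an error; estimators on it return 0.
- NMI with a single tissue is defined as 0; a zero normalizer returns 0.
- `lin_ccc` of two equal constant vectors is 1 (perfect agreement on the
  identity line); unequal constants score 0.
- All stochastic operations (simulation, bootstrap, permutation null) take
  mandatory or defaulted integer seeds and are bit-reproducible.

## Known limitations

- The unseen-event formula is gene-aggregate: it cannot price a *specific*
  unobserved variant.
- Euler-smoothed Δ(t) is usable for moderate t (say t ≤ 5); far
  extrapolation inflates both bias and variance.
- Hypermutated tumors violate the shared-`p_v` assumption; that is why
  stratification precedes estimation, and why ultra-hypermutated
  (POLE-like) subgroups remain over-predicted under this model family.
- NMI comparisons across cohorts with different tissue compositions are
  confounded by `H(T)`; use the same normalizer and comparable mixes.
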