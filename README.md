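# raremut

Rare-variant richness estimation for somatic mutation catalogs.

Most somatic variants in large tumor sequencing cohorts are *singletons* —
observed in exactly one tumor — and a vast number of variants have never
been observed at all. `raremut` treats this as an unseen-species problem:
from the frequency-of-frequencies vector of a sequenced cohort it estimates
the probability that specific variants (seen or hitherto unseen) turn up in
the next tumor, and how many brand-new variants a future cohort will
uncover. Intended users are cancer-genomics analysts working with MAF-style
mutation tables (TCGA-like whole-exome catalogs, targeted panels such as
MSK-IMPACT) who need calibrated probabilities for rare and unseen variants
rather than naive frequency estimates, which assign them probability zero.

## The statistics

Let `m` be the number of sequenced tumors and `N_r` the number of distinct
non-synonymous SNVs observed in exactly `r` tumors. The core estimators are:

- **Good-Turing recurrence probability** for a variant seen `r` times:
  `q_GT = (r+1)/(m+1) · S(N_{r+1})/S(N_r)`, where `S` is a smoothing of the
  frequency-of-frequencies vector (Simple Good-Turing by default).
- **Unseen-variant probability** for a gene: the probability that a new
  tumor carries at least one variant never seen before is
  `1 − exp(−N₁/(m+1))` — driven entirely by the singleton count, with no
  need to know how many unseen variants exist.
- **Good-Toulmin extrapolation** `Δ(t) = Σ_r (−1)^{r+1} t^r N_r`: the
  expected number of new distinct variants discovered if `t·m` more tumors
  are sequenced, with Euler/binomial-tail smoothing for `t > 1` where the
  plain series diverges, and bootstrap standard errors.

Around the estimators the package provides mutational-signature cohort
stratification (six subgroups with a burden threshold that rescales across
sequencing footprints), normalized-mutual-information (NMI) scoring of how
tissue-dependent a variant or gene's unseen-variant probability is
(referenced against a tissue-label permutation null), gene-pair
co-mutation/mutual-exclusivity probabilities, cross-cohort validation
scored with Lin's concordance correlation coefficient, and a synthetic
cohort generator with exact oracles for every estimator.

## Worked example

A hotspot-dominated oncogene versus a long-tailed tumor-suppressor at the
same cohort size. The oncogene's frequency vector has 24 singletons, 3
doubletons and three hotspots seen 142, 120 and 44 times over 6,696 tumors;
the suppressor has 470 singletons:

```python
from raremut import (FrequencyVector, unseen_event_probability,
                     expected_new_variants_in_one_tumor, good_toulmin,
                     scaled_hypermutation_threshold)

kras = FrequencyVector(scope="KRAS", m=6696,
                       counts={1: 24, 2: 3, 142: 1, 120: 1, 44: 1})
print(unseen_event_probability(kras.n1, kras.m))        # 0.00358
print(expected_new_variants_in_one_tumor(kras).delta)   # 0.00358
print(good_toulmin(kras, t=1.0).delta)                  # 18.0

fat1 = FrequencyVector(scope="FAT1", m=6696, counts={1: 470, 2: 15, 3: 5})
print(unseen_event_probability(fat1.n1, fat1.m))        # 0.0678

print(scaled_hypermutation_threshold(500, 4, 54))       # 38
```

Reading the numbers: a new tumor has a 0.36% chance of carrying a
never-seen variant of the hotspot gene — the hotspots soak up most of its
mutation probability — versus 6.8% for the singleton-dominated gene, even
though both are frequently mutated. Doubling the hotspot-gene cohort is
expected to uncover only ~18 new variants in that gene. The last line
rescales a 500-mutation whole-exome hypermutation threshold to a targeted
panel whose median mutation burden is 4 versus the exome cohort's 54,
giving a panel threshold of 38.

The same analyses run from the shell on MAF files:

```bash
raremut simulate --config sim.yaml --seed 42 --out cohort/
raremut stratify --annotations cohort/annotations.tsv --threshold 500 --scale-to 4 54
raremut gt-prob --maf cohort/cohort.maf --gene TAILY --smoothing sgt
raremut unseen-prob --maf cohort/cohort.maf --by-gene --by-tissue
raremut extrapolate --maf cohort/cohort.maf --global --t 1.5 --bootstrap 200 --seed 17
raremut nmi --maf cohort/cohort.maf --annotations cohort/annotations.tsv --seed 7
raremut validate --train train.maf --valid valid.maf
```

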