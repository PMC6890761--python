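"""NMI tissue-specificity scores and the permutation null."""

import math

import numpy as np
import pytest
from scipy import stats

from raremut.synthetic_cohorts import GeneModel, simulate
from raremut.tissue_specificity import (
    gene_unseen_nmi,
    index_tissue_nmi,
    nmi,
    null_nmi_distribution,
    score_gene,
    tissue_unseen_probabilities,
)


def exact_binary_nmi(w, p):
    """Independent 4-cell-per-tissue MI computation, normalized by H(T)."""
    joint = []
    for wc, pc in zip(w, p):
        joint.append((wc * pc, wc * (1 - pc)))
    pe1 = sum(j[0] for j in joint)
    pe0 = sum(j[1] for j in joint)
    mi = 0.0
    for wc, (j1, j0) in zip(w, joint):
        for j, pe in ((j1, pe1), (j0, pe0)):
            if j > 0:
                mi += j * math.log(j / (wc * pe))
    ht = -sum(wc * math.log(wc) for wc in w if wc > 0)
    return mi / ht


class TestNmi:
    def test_lineage_independent_event_scores_zero(self):
        probs = {c: 0.07 for c in "ABCDE"}
        weights = {c: 0.2 for c in "ABCDE"}
        assert nmi(probs, weights) == pytest.approx(0.0, abs=1e-12)

    def test_tissue_deterministic_event_scores_one(self):
        # p=1 in one of two equally weighted tissues: the 2x2 joint is
        # diag(0.5, 0.5), so I(T;E) = H(T) = ln 2 and the ratio is 1
        assert nmi({"A": 1.0, "B": 0.0}, {"A": 0.5, "B": 0.5}) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "w,p",
        [
            ([0.5, 0.5], [0.5, 0.1]),
            ([0.3, 0.7], [0.9, 0.2]),
            ([0.2, 0.3, 0.5], [0.05, 0.4, 0.01]),
        ],
    )
    def test_matches_exact_cellwise_computation(self, w, p):
        tissues = [f"T{i}" for i in range(len(w))]
        got = nmi(dict(zip(tissues, p)), dict(zip(tissues, w)))
        assert got == pytest.approx(exact_binary_nmi(w, p), abs=1e-12)

    def test_single_tissue_defined_as_zero(self):
        assert nmi({"A": 0.3}, {"A": 1.0}) == 0.0

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            nmi({}, {})

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError):
            nmi({"A": 0.1, "B": 0.2}, {"A": 0.7, "B": 0.7})

    def test_bounded_and_relabel_invariant(self):
        w = {"A": 0.25, "B": 0.35, "C": 0.4}
        p = {"A": 0.8, "B": 0.02, "C": 0.3}
        v = nmi(p, w)
        assert 0.0 <= v <= 1.0
        relabeled = nmi(
            {"X": p["A"], "Y": p["B"], "Z": p["C"]},
            {"X": w["A"], "Y": w["B"], "Z": w["C"]},
        )
        assert relabeled == pytest.approx(v, abs=1e-12)

    def test_invariant_to_cohort_duplication(self):
        # doubling every tissue's sample count leaves weights, hence NMI, fixed
        counts = {"A": 40, "B": 60}
        p = {"A": 0.3, "B": 0.05}
        w1 = {c: n / 100 for c, n in counts.items()}
        w2 = {c: 2 * n / 200 for c, n in counts.items()}
        assert nmi(p, w1) == nmi(p, w2)

    def test_normalizers_reportable_and_ordered(self):
        p = {"A": 0.9, "B": 0.1}
        w = {"A": 0.5, "B": 0.5}
        vals = {
            norm: nmi(p, w, normalizer=norm)
            for norm in ("tissue_entropy", "event_entropy", "min", "sqrt_product")
        }
        assert vals["min"] >= vals["sqrt_product"] >= min(vals.values())


class TestIndexTissueNmi:
    def test_equal_probabilities_score_zero(self):
        p = {"A": 0.2, "B": 0.2, "C": 0.2}
        w = {"A": 0.3, "B": 0.3, "C": 0.4}
        assert index_tissue_nmi(p, w, "A") == pytest.approx(0.0, abs=1e-12)

    def test_two_tissues_reduce_to_plain_nmi(self):
        p = {"A": 0.6, "B": 0.1}
        w = {"A": 0.4, "B": 0.6}
        assert index_tissue_nmi(p, w, "A") == pytest.approx(nmi(p, w), abs=1e-12)

    def test_hand_binarized_case(self):
        # index A vs pooled rest: rest probability is the weighted mean
        p = {"A": 0.5, "B": 0.1, "C": 0.3}
        w = {"A": 0.5, "B": 0.25, "C": 0.25}
        p_rest = (0.25 * 0.1 + 0.25 * 0.3) / 0.5
        expected = exact_binary_nmi([0.5, 0.5], [0.5, p_rest])
        assert index_tissue_nmi(p, w, "A") == pytest.approx(expected, abs=1e-12)


@pytest.fixture(scope="module")
def tissue_sim():
    """Four equally likely tissues; G_DEP is 8x enriched in tissue T0."""
    genes = [
        GeneModel(gene="G_IND", law="zipf", pool_size=300, s=1.1, rate=0.2),
        GeneModel(
            gene="G_DEP",
            law="zipf",
            pool_size=300,
            s=1.1,
            rate=0.2,
            tissue_multipliers={"T0": 8.0},
        ),
    ]
    mix = {f"T{i}": 0.25 for i in range(4)}
    return simulate(genes, m=600, tissue_mix=mix, seed=424242)


class TestPermutationNull:
    def test_seeded_null_is_reproducible(self, tissue_sim):
        a, a95 = null_nmi_distribution(tissue_sim.cohort, "G_IND", 100, seed=3)
        b, b95 = null_nmi_distribution(tissue_sim.cohort, "G_IND", 100, seed=3)
        assert np.array_equal(a, b) and a95 == b95

    def test_too_few_permutations_rejected(self, tissue_sim):
        with pytest.raises(ValueError):
            null_nmi_distribution(tissue_sim.cohort, "G_IND", 10, seed=0)

    def test_dependent_gene_exceeds_null_independent_does_not(self, tissue_sim):
        dep = score_gene(tissue_sim.cohort, "G_DEP", n_permutations=200, seed=1)
        assert dep.nmi > dep.null_percentile_95

    def test_stratified_probabilities_use_per_tissue_vectors(self, tissue_sim):
        probs = tissue_unseen_probabilities(tissue_sim.cohort, "G_DEP")
        # enrichment in T0 consumes the pool there: more variants seen in T0
        # means more per-tissue singletons, hence a larger unseen probability
        assert probs["T0"] == max(probs.values())


class TestEffectRanking:
    def test_nmi_ranks_injected_effect_sizes(self):
        """Across simulated genes with graded tissue enrichment, stronger
        effects earn stochastically larger NMI (rank correlation > 0.8)."""
        rng_seed = 777
        effects = np.repeat([1.0, 2.0, 4.0, 8.0, 16.0], 10)
        genes = [
            GeneModel(
                gene=f"G{i:02d}",
                law="zipf",
                pool_size=200,
                s=1.1,
                rate=0.15,
                tissue_multipliers={"T0": float(e)},
            )
            for i, e in enumerate(effects)
        ]
        mix = {f"T{i}": 0.25 for i in range(4)}
        sim = simulate(genes, m=600, tissue_mix=mix, seed=rng_seed)
        nmis = [gene_unseen_nmi(sim.cohort, f"G{i:02d}") for i in range(len(effects))]
        rho = stats.spearmanr(effects, nmis).statistic
        assert rho > 0.8
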