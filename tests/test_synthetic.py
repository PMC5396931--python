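"""Generator tests: penetrance law, class proportions, pedigree genetics."""

import numpy as np
import pytest
from scipy import stats

from phenobma import (
    PhenotypeScheme,
    ValidationError,
    estimate_ibd,
    haldane_recombination_fraction,
    mendelian_errors,
    simulate_mixed_membership,
    simulate_pedigrees,
    simulate_symptoms,
)
from phenobma.datatypes import P1_SYMPTOMS


def test_deterministic_penetrance_gives_indicator_rows(kpd_scheme):
    scheme = PhenotypeScheme.from_labels(
        [("P1", P1_SYMPTOMS), ("unaffected", frozenset())],
        [0.999999, 1e-6],  # essentially everyone in P1
        penetrance_in=1.0,
        penetrance_out=0.0,
    )
    Y, labels = simulate_symptoms(scheme, 50, seed=0)
    indicator = np.zeros(12, dtype=int)
    indicator[[scheme.symptom_labels.index(s) for s in "befh"]] = 1
    for row, lab in zip(Y.values, labels):
        if lab == 0:
            assert np.array_equal(row, indicator)


def test_class_counts_match_population_proportions(kpd_scheme):
    """n=1408 draws reproduce the 184/193/178/853 composition within binomial 99% CI."""
    n = 1408
    Y, labels = simulate_symptoms(kpd_scheme, n, seed=7)
    counts = np.bincount(labels, minlength=4)
    for k, expected in enumerate((184, 193, 178, 853)):
        p = expected / n
        lo, hi = stats.binom.ppf([0.005, 0.995], n, p)
        assert lo <= counts[k] <= hi


def test_background_symptom_frequency(kpd_scheme):
    """Non-class symptoms appear at the background rate (3 SE at n=5000)."""
    Y, labels = simulate_symptoms(kpd_scheme, 5000, seed=11)
    # symptom 'a' (index 0) is background for every class
    freq = Y.values[:, 0].mean()
    se = np.sqrt(0.05 * 0.95 / 5000)
    assert abs(freq - 0.05) < 3 * se


def test_symptom_generation_reproducible(kpd_scheme):
    Y1, l1 = simulate_symptoms(kpd_scheme, 200, seed=3)
    Y2, l2 = simulate_symptoms(kpd_scheme, 200, seed=3)
    assert np.array_equal(Y1.values, Y2.values) and np.array_equal(l1, l2)


def test_scheme_validation():
    with pytest.raises(ValidationError):
        PhenotypeScheme.from_labels(
            [("x", frozenset("ab"))], [1.0], penetrance_in=0.3, penetrance_out=0.5
        )
    with pytest.raises(ValidationError):
        PhenotypeScheme(
            symptom_labels=("a", "b"),
            class_names=("x", "y"),
            class_symptom_sets=(frozenset([0]), frozenset()),
            class_proportions=(0.6, 0.6),
        )


class TestMixedMembership:
    def test_small_concentration_is_near_crisp(self, three_class_scheme):
        Y, g = simulate_mixed_membership(three_class_scheme, 300, concentration=0.01, seed=5)
        assert (g.max(axis=1) > 0.95).mean() > 0.9
        assert g.max(axis=1).mean() > 0.98

    def test_degenerate_profiles_make_membership_irrelevant(self):
        scheme = PhenotypeScheme.from_labels(
            [("A", frozenset("befh")), ("B", frozenset("befh"))],
            [0.5, 0.5],
        )
        Y, g = simulate_mixed_membership(scheme, 4000, concentration=1.0, seed=6)
        lam = scheme.symptom_probabilities()
        # identical profiles: marginal frequency equals the common rate per symptom
        freqs = Y.values.mean(axis=0)
        se = np.sqrt(lam[0] * (1 - lam[0]) / 4000)
        assert np.all(np.abs(freqs - lam[0]) < 4 * se)

    def test_mean_membership_is_symmetric(self, three_class_scheme):
        n, K = 2000, 3
        _, g = simulate_mixed_membership(three_class_scheme, n, concentration=1.0, seed=8)
        # symmetric Dirichlet(1): mean 1/K, var (K-1)/(K^2 (K+1))
        se = np.sqrt((K - 1) / (K**2 * (K + 1)) / n)
        assert np.all(np.abs(g.mean(axis=0) - 1 / K) < 3 * se)

    def test_invalid_concentration(self, three_class_scheme):
        with pytest.raises(ValidationError):
            simulate_mixed_membership(three_class_scheme, 10, concentration=0.0, seed=0)


class TestPedigrees:
    def test_haldane_map_function(self):
        assert haldane_recombination_fraction(7.5) == pytest.approx(0.069646, abs=1e-6)
        assert haldane_recombination_fraction(0.0) == 0.0
        assert haldane_recombination_fraction(1e9) == pytest.approx(0.5)

    def test_mendelian_consistency_and_reproducibility(self, three_class_scheme):
        ped, Y, labels = simulate_pedigrees(30, 3, 6, 7.5, 2, 2.0, three_class_scheme, seed=4)
        assert mendelian_errors(ped) == []
        ped2, Y2, labels2 = simulate_pedigrees(30, 3, 6, 7.5, 2, 2.0, three_class_scheme, seed=4)
        assert np.array_equal(Y.values, Y2.values)
        for ind in ped.genotypes:
            assert np.array_equal(ped.genotypes[ind], ped2.genotypes[ind])

    def test_qtl_marker_out_of_range(self, three_class_scheme):
        with pytest.raises(IndexError):
            simulate_pedigrees(5, 2, 4, 7.5, 4, 1.0, three_class_scheme, seed=0)

    @staticmethod
    def _sharing_and_concordance(ped, labels_by_id, qtl_marker):
        pis, concord = [], []
        for fam in ped.families:
            pi = estimate_ibd(
                ped.genotypes[fam.father_id][qtl_marker],
                ped.genotypes[fam.mother_id][qtl_marker],
                np.array([ped.genotypes[k][qtl_marker] for k in fam.offspring_ids]),
            )
            kids = fam.offspring_ids
            for i in range(len(kids)):
                for j in range(i + 1, len(kids)):
                    pis.append(pi[i, j])
                    concord.append(labels_by_id[kids[i]] == labels_by_id[kids[j]])
        return np.asarray(pis), np.asarray(concord)

    def test_null_effect_gives_no_association(self, three_class_scheme):
        """With qtl_effect=0, affection is independent of allele sharing (alpha=0.01)."""
        ped, Y, labels = simulate_pedigrees(500, 2, 3, 7.5, 1, 0.0, three_class_scheme, seed=17)
        affected = {i: int(l != 2) for i, l in zip(Y.individual_ids, labels)}
        pis, concord = self._sharing_and_concordance(ped, affected, 1)
        table = np.array(
            [[(concord & (pis == v)).sum() for v in (0.0, 0.5, 1.0)],
             [(~concord & (pis == v)).sum() for v in (0.0, 0.5, 1.0)]]
        )
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.01

    def test_strong_effect_links_sharing_to_concordance(self, three_class_scheme):
        """A fully penetrant locus makes allele sharing predict phenotype concordance."""
        ped, Y, labels = simulate_pedigrees(500, 3, 3, 7.5, 1, 8.0, three_class_scheme, seed=18)
        affected = {i: int(l != 2) for i, l in zip(Y.individual_ids, labels)}
        pis, concord = self._sharing_and_concordance(ped, affected, 1)
        assert len(pis) >= 1000
        r = np.corrcoef(pis, concord.astype(float))[0, 1]
        assert r > 0.1
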