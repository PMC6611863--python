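import itertools
import math

import numpy as np
import pytest

from triomosaic.core import AlleleDepths, Person, Tissue
from triomosaic.errors import DegenerateFitError, InvalidInputError
from triomosaic.validation import (
    DeepSeqObservation,
    ValidationOutcome,
    classify_validation,
    compare_group_vafs,
    confusion_metrics,
    tissue_concordance,
)


def deep(person, tissue, alt, depth):
    return DeepSeqObservation(
        person=person, tissue=tissue, depths=AlleleDepths(depth - alt, alt)
    )


def trio(proband_alt, mother_alt, father_alt, depth=100_000):
    return [
        deep(Person.PROBAND, Tissue.SALIVA, proband_alt, depth),
        deep(Person.MOTHER, Tissue.SALIVA, mother_alt, depth),
        deep(Person.FATHER, Tissue.SALIVA, father_alt, depth),
    ]


ERR_ALT = 500  # ~error-rate alt count at depth 100,000 and error 0.005


class TestClassifyValidation:
    def test_constitutive_dnm(self):
        call = classify_validation(trio(50_000, ERR_ALT, ERR_ALT))
        assert call.value is ValidationOutcome.CONSTITUTIVE_DNM

    def test_mosaic_dnm(self):
        call = classify_validation(trio(20_000, ERR_ALT, ERR_ALT))
        assert call.value is ValidationOutcome.MOSAIC_DNM
        assert call.mosaic_person is Person.PROBAND
        assert call.validated_vaf[(Person.PROBAND, Tissue.SALIVA)] == pytest.approx(0.20)

    def test_parent_mosaic(self):
        call = classify_validation(trio(49_800, 8_000, ERR_ALT))
        assert call.value is ValidationOutcome.PARENT_MOSAIC
        assert call.mosaic_person is Person.MOTHER

    def test_constitutive_inherited(self):
        call = classify_validation(trio(50_100, 49_900, ERR_ALT))
        assert call.value is ValidationOutcome.CONSTITUTIVE_INHERITED

    def test_false_positive(self):
        call = classify_validation(trio(ERR_ALT, ERR_ALT, ERR_ALT))
        assert call.value is ValidationOutcome.FALSE_POSITIVE

    def test_shallow_observation_uninformative(self):
        obs = trio(20_000, ERR_ALT, ERR_ALT)
        obs.append(deep(Person.PROBAND, Tissue.BLOOD, 50, 500))
        call = classify_validation(obs, min_informative_depth=1000)
        assert call.value is ValidationOutcome.UNINFORMATIVE

    def test_tissue_conflict_uninformative(self):
        obs = [
            deep(Person.PROBAND, Tissue.SALIVA, 20_000, 100_000),
            deep(Person.PROBAND, Tissue.BLOOD, 510, 100_000),  # absent in blood
            deep(Person.MOTHER, Tissue.SALIVA, ERR_ALT, 100_000),
            deep(Person.FATHER, Tissue.SALIVA, ERR_ALT, 100_000),
        ]
        call = classify_validation(obs)
        assert call.value is ValidationOutcome.UNINFORMATIVE
        assert call.conflict

    def test_requires_proband(self):
        with pytest.raises(InvalidInputError):
            classify_validation([deep(Person.MOTHER, Tissue.SALIVA, 10, 1000)])

    def test_class_recovery_on_simulated_counts(self):
        """>= 99% correct classes over 1,000 simulated ultra-deep trios
        spanning true VAFs 0.01-0.5."""
        rng = np.random.default_rng(42)
        error = 0.003
        n_per = 250
        correct = total = 0
        for true_class in ("constitutive", "mosaic", "parent_mosaic", "fp"):
            for _ in range(n_per):
                if true_class == "constitutive":
                    v_p, v_m, v_f = 0.5, error, error
                    want = ValidationOutcome.CONSTITUTIVE_DNM
                elif true_class == "mosaic":
                    v_p, v_m, v_f = rng.uniform(0.01, 0.40), error, error
                    want = ValidationOutcome.MOSAIC_DNM
                elif true_class == "parent_mosaic":
                    v_p, v_m, v_f = 0.5, rng.uniform(0.01, 0.40), error
                    want = ValidationOutcome.PARENT_MOSAIC
                else:
                    v_p, v_m, v_f = error, error, error
                    want = ValidationOutcome.FALSE_POSITIVE
                obs = []
                for person, v in (
                    (Person.PROBAND, v_p),
                    (Person.MOTHER, v_m),
                    (Person.FATHER, v_f),
                ):
                    depth = int(rng.poisson(100_032))
                    alt = int(rng.binomial(depth, v))
                    obs.append(deep(person, Tissue.SALIVA, alt, depth))
                call = classify_validation(obs, error_rate=error)
                total += 1
                correct += call.value is want
        assert correct / total >= 0.99


# -- confusion metrics ---------------------------------------------------------


def test_confusion_perfect():
    m = confusion_metrics([True] * 5 + [False] * 5, [True] * 5 + [False] * 5)
    assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (1.0, 1.0, 1.0, 1.0)


def test_confusion_undefined_ratio_is_missing_not_zero():
    m = confusion_metrics([True] * 10, [True] * 5 + [False] * 5)
    assert m.tp == 5 and m.fp == 5 and m.fn == 0 and m.tn == 0
    assert m.sensitivity == 1.0
    assert m.ppv == 0.5
    assert m.specificity == 0.0
    assert m.npv is None


def test_confusion_vaf_rule_counts():
    """Identities applied to realistic screen-validation counts."""
    predicted = [True] * 63 + [True] * 32 + [False] * 17 + [False] * 66
    truth = [True] * 63 + [False] * 32 + [True] * 17 + [False] * 66
    m = confusion_metrics(predicted, truth)
    assert m.sensitivity == pytest.approx(63 / 80, abs=1e-12)
    assert m.specificity == pytest.approx(66 / 98, abs=1e-12)
    assert m.ppv == pytest.approx(63 / 95, abs=1e-12)
    assert m.npv == pytest.approx(66 / 83, abs=1e-12)


def test_confusion_counting_oracle():
    rng = np.random.default_rng(0)
    pred = rng.random(200) < 0.4
    tru = rng.random(200) < 0.3
    m = confusion_metrics(pred, tru)
    # naive loop oracle
    tp = sum(p and t for p, t in zip(pred, tru))
    fp = sum(p and not t for p, t in zip(pred, tru))
    fn = sum(t and not p for p, t in zip(pred, tru))
    tn = sum(not p and not t for p, t in zip(pred, tru))
    assert (m.tp, m.fp, m.fn, m.tn) == (tp, fp, fn, tn)


def test_confusion_length_mismatch():
    with pytest.raises(InvalidInputError):
        confusion_metrics([True], [True, False])


# -- Mann-Whitney-Wilcoxon -----------------------------------------------------


def mwu_enumeration_oracle(a, b):
    """Exact two-sided p by enumerating all label assignments."""
    pooled = list(a) + list(b)
    n1 = len(a)

    def u_stat(idx_a):
        ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
        r1 = sum(ranks[pooled[i]] for i in idx_a)
        return r1 - n1 * (n1 + 1) / 2

    u_obs = u_stat(range(n1))
    n = len(pooled)
    us = [u_stat(c) for c in itertools.combinations(range(n), n1)]
    mean_u = n1 * (n - n1) / 2
    extreme = sum(abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12 for u in us)
    return extreme / len(us)


def test_mwu_identical_singletons():
    assert compare_group_vafs([0.2], [0.2]) == 1.0


def test_mwu_exact_small_sample():
    assert compare_group_vafs([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)


@pytest.mark.parametrize(
    "a, b",
    [
        ([1, 2, 3], [4, 5, 6]),
        ([1, 5, 9], [2, 4, 8, 10]),
        ([0.1, 0.9], [0.2, 0.5, 0.7, 0.8]),
        ([3, 1, 4, 1.5, 9], [2.6, 5.3, 5.8]),
    ],
)
def test_mwu_exact_matches_enumeration(a, b):
    """Exact mode equals full enumeration for n1+n2 <= 12, no ties."""
    assert compare_group_vafs(a, b) == pytest.approx(mwu_enumeration_oracle(a, b), abs=1e-12)


def test_mwu_empty_group_rejected():
    with pytest.raises(InvalidInputError):
        compare_group_vafs([], [1.0])


def test_mwu_null_uniformity():
    """Large same-distribution samples give roughly uniform p-values."""
    rng = np.random.default_rng(5)
    ps = [
        compare_group_vafs(rng.normal(size=60), rng.normal(size=60)) for _ in range(200)
    ]
    assert 0.3 < np.mean(ps) < 0.7
    assert min(ps) < 0.2 and max(ps) > 0.8


# -- tissue concordance --------------------------------------------------------


def test_concordance_identity_line():
    pairs = [(v, v, flag) for v in np.linspace(0.05, 0.4, 10) for flag in (False, True)]
    res = tissue_concordance(pairs)
    assert res["slope"] == pytest.approx(1.0, abs=1e-9)
    assert res["r_squared_per_class"][True] == pytest.approx(1.0, abs=1e-9)
    assert res["r_squared_per_class"][False] == pytest.approx(1.0, abs=1e-9)


def test_concordance_noisy_but_concordant():
    rng = np.random.default_rng(8)
    pairs = []
    for flag in (False, True):
        saliva = rng.uniform(0.05, 0.4, size=60)
        blood = saliva + rng.normal(0, 0.03, size=60)
        pairs += [(s, b, flag) for s, b in zip(saliva, blood)]
    res = tissue_concordance(pairs)
    assert res["slope"] == pytest.approx(1.0, abs=0.1)
    assert res["interaction_p"] > 0.01


def test_concordance_discordant_outliers_shift_interaction():
    """Tissue-specific mosaics (saliva >> blood) in one gene class are
    visible in the interaction term."""
    rng = np.random.default_rng(9)
    saliva = rng.uniform(0.05, 0.4, size=40)
    blood = saliva + rng.normal(0, 0.01, size=40)
    pairs = [(s, b, False) for s, b in zip(saliva, blood)]
    # one class with saliva-restricted mosaics: blood far below saliva
    saliva2 = rng.uniform(0.2, 0.4, size=10)
    pairs += [(s, 0.02, True) for s in saliva2]
    res = tissue_concordance(pairs)
    assert res["interaction_p"] < 0.01


def test_concordance_constant_predictor_degenerate():
    with pytest.raises(DegenerateFitError):
        tissue_concordance([(0.2, 0.1, False), (0.2, 0.3, False), (0.2, 0.2, True)])
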