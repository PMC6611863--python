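import math

import numpy as np
import pytest
from scipy.stats import binom

from triomosaic.core import Consequence, GeneClass, Genotype, Person, Sex
from triomosaic.errors import InvalidInputError
from triomosaic.screens import (
    Arm,
    ScreenConfig,
    Strategy,
    calibrate_stringency,
    predict_mosaic_rule,
    screen_child_pzm,
    screen_parent_highlevel,
    screen_parent_lowlevel,
)
from triomosaic.stats import BinomialDeviation, Tail, binomial_deviation_test
from tests.conftest import make_record


# -- child-PZM screen ----------------------------------------------------------


def test_child_screen_empty_input():
    assert screen_child_pzm([]) == []


def test_child_screen_balanced_het_not_selected():
    """A clean 25/50 het among 100 balanced sites has q ~ 1."""
    records = [
        make_record(proband_alt=25, proband_depth=50, site_id=f"s{i}") for i in range(100)
    ]
    assert screen_child_pzm(records) == []


def test_child_screen_selects_strong_deviation():
    """One 8/60 site among 19 balanced sites: p = 2.6e-9, q = 20p << 0.2."""
    records = [
        make_record(proband_alt=30, proband_depth=60, site_id=f"bal{i}") for i in range(19)
    ]
    records.append(make_record(proband_alt=8, proband_depth=60, site_id="mosaic"))
    out = screen_child_pzm(records)
    assert [c.record.site_id for c in out] == ["mosaic"]
    cand = out[0]
    assert cand.arm is Arm.LIKELY_PATHOGENIC
    assert cand.stats.p_value == pytest.approx(binom.cdf(8, 60, 0.5), rel=1e-9)
    assert cand.q_value == pytest.approx(20 * binom.cdf(8, 60, 0.5), rel=1e-6)
    assert cand.predicted_mosaic  # VAF 0.133 inside the (0.1, 0.27) band


def test_child_screen_excludes_sex_chromosomes_in_males():
    rec = make_record(proband_alt=8, proband_depth=60, chrom="X", proband_sex=Sex.M)
    assert screen_child_pzm([rec]) == []
    # same deviation on an autosome in a male is eligible
    rec2 = make_record(proband_alt=8, proband_depth=60, chrom="2", proband_sex=Sex.M)
    assert len(screen_child_pzm([rec2])) == 1


def test_child_screen_vaf_floor():
    rec = make_record(proband_alt=4, proband_depth=50)  # VAF 0.08 <= 0.1
    assert screen_child_pzm([rec]) == []


def test_child_screen_control_arm_separate_threshold():
    """Synonymous non-DDG2P sites go through the control arm at FDR 0.05."""
    records = [
        make_record(
            proband_alt=30,
            proband_depth=60,
            consequence=Consequence.SYNONYMOUS,
            gene_class=GeneClass.NOT_DDG2P,
            site_id=f"bal{i}",
        )
        for i in range(19)
    ]
    records.append(
        make_record(
            proband_alt=8,
            proband_depth=60,
            consequence=Consequence.SYNONYMOUS,
            gene_class=GeneClass.NOT_DDG2P,
            site_id="mosaic",
        )
    )
    out = screen_child_pzm(records)
    assert len(out) == 1
    assert out[0].arm is Arm.CONTROL


def test_child_screen_does_not_mutate_records():
    rec = make_record(proband_alt=8, proband_depth=60)
    import copy

    before = copy.deepcopy(rec.observations)
    screen_child_pzm([rec])
    assert rec.observations == before


# -- low-level parent screen ---------------------------------------------------


@pytest.mark.parametrize(
    "m_alt, f_alt, selected, predicted, parent",
    [
        (0, 0, False, None, None),
        (1, 0, True, False, Person.MOTHER),
        (3, 0, True, True, Person.MOTHER),
        (0, 2, True, True, Person.FATHER),
        (1, 1, False, None, None),  # reads in both parents: excluded
    ],
)
def test_parent_lowlevel_selection(m_alt, f_alt, selected, predicted, parent):
    """Selected iff exactly one parent has >= 1 ALT read; >= 2 reads
    predicts genuine parental mosaicism."""
    rec = make_record(mother_alt=m_alt, father_alt=f_alt)
    out = screen_parent_lowlevel([rec])
    assert bool(out) is selected
    if selected:
        assert out[0].predicted_mosaic is predicted
        assert out[0].mosaic_parent is parent


def test_parent_lowlevel_restricted_to_pathogenic_universe():
    rec = make_record(
        mother_alt=3,
        consequence=Consequence.SYNONYMOUS,
        gene_class=GeneClass.NOT_DDG2P,
    )
    assert screen_parent_lowlevel([rec]) == []


def test_parent_lowlevel_exhaustive_over_alt_grid():
    """Selection matches the definition exhaustively on a small grid."""
    records, expected = [], set()
    i = 0
    for m_alt in range(4):
        for f_alt in range(4):
            sid = f"g{i}"
            records.append(make_record(mother_alt=m_alt, father_alt=f_alt, site_id=sid))
            if (m_alt >= 1 and f_alt == 0) or (f_alt >= 1 and m_alt == 0):
                expected.add(sid)
            i += 1
    got = {c.record.site_id for c in screen_parent_lowlevel(records)}
    assert got == expected


# -- high-level parent screen --------------------------------------------------


def hl_record(
    parent_alt=10,
    parent_depth=60,
    proband_alt=25,
    proband_depth=50,
    consequence=Consequence.LOF,
    carrier=Person.MOTHER,
    **kwargs,
):
    m_alt = parent_alt if carrier is Person.MOTHER else 0
    f_alt = parent_alt if carrier is Person.FATHER else 0
    return make_record(
        proband_alt=proband_alt,
        proband_depth=proband_depth,
        mother_alt=m_alt,
        mother_depth=parent_depth,
        father_alt=f_alt,
        father_depth=parent_depth,
        mother_genotype=Genotype.HET if carrier is Person.MOTHER else Genotype.HOM_REF,
        father_genotype=Genotype.HET if carrier is Person.FATHER else Genotype.HOM_REF,
        consequence=consequence,
        maf=1e-4,
        **kwargs,
    )


def test_highlevel_balanced_carrier_not_selected():
    rec = hl_record(parent_alt=25, parent_depth=50, consequence=Consequence.FUNCTIONAL)
    assert screen_parent_highlevel([rec]) == []


def test_highlevel_lof_low_vaf_selected_by_strategy_b():
    rec = hl_record(parent_alt=10, parent_depth=60, consequence=Consequence.LOF)
    out = screen_parent_highlevel([rec])
    assert len(out) == 1
    assert Strategy.PTV_OR_KNOWN in out[0].strategies
    assert Strategy.FDR in out[0].strategies  # p = 8.1e-8, sole test => q << 0.1
    assert out[0].mosaic_parent is Person.MOTHER
    assert out[0].stats.p_value == pytest.approx(binom.cdf(10, 60, 0.5), rel=1e-9)


def test_highlevel_sib_pair_strategy():
    rec = hl_record(
        parent_alt=18,
        parent_depth=60,
        consequence=Consequence.FUNCTIONAL,
        affected_sibling_shares_variant=True,
    )
    out = screen_parent_highlevel([rec])
    assert out and Strategy.SIB_PAIR in out[0].strategies


def test_highlevel_proband_vaf_window_exclusion():
    """Proband VAF 0.75 is outside [0.3, 0.7]: excluded regardless of parent."""
    rec = hl_record(parent_alt=10, parent_depth=60, proband_alt=45, proband_depth=60)
    assert screen_parent_highlevel([rec]) == []


def test_highlevel_both_parents_with_alt_reads_excluded():
    rec = make_record(
        proband_alt=25,
        mother_alt=10,
        father_alt=3,
        mother_genotype=Genotype.HET,
        consequence=Consequence.LOF,
        maf=1e-4,
    )
    assert screen_parent_highlevel([rec]) == []


def test_highlevel_affected_parent_excluded():
    rec = hl_record(parent_alt=10, parent_depth=60, parent_affected=(True, False))
    assert screen_parent_highlevel([rec]) == []


# -- rule-based predictor ------------------------------------------------------


@pytest.mark.parametrize(
    "alt, depth, expected",
    [
        (10, 50, True),  # VAF 0.20 inside the band
        (25, 50, False),  # constitutive
        (600, 2000, True),  # VAF 0.30 outside band, p = 1.2e-73 < 1e-4
        (1, 10, False),  # VAF 0.10: band open at the boundary, p = 0.011 >= 1e-4
    ],
)
def test_predict_mosaic_rule(alt, depth, expected):
    stats = binomial_deviation_test(alt, depth, 0.5, Tail.LOWER)
    assert predict_mosaic_rule(stats) is expected


def test_vaf_band_open_at_027():
    stats = BinomialDeviation(alt_count=27, depth=100, vaf=0.27, p_value=0.5)
    assert predict_mosaic_rule(stats) is False


# -- stringency calibration ----------------------------------------------------


def syn_records(scores):
    return [
        make_record(
            consequence=Consequence.SYNONYMOUS,
            gene_class=GeneClass.NOT_DDG2P,
            call_quality_score=s,
            site_id=f"syn{i}",
        )
        for i, s in enumerate(scores)
    ]


def test_calibrate_no_filtering_needed():
    assert calibrate_stringency(syn_records([1, 2, 3, 4, 5]), 10) == -math.inf


def test_calibrate_example_threshold():
    assert calibrate_stringency(syn_records([1, 2, 3, 4, 5]), 2) == 4


def test_calibrate_expected_zero_removes_all():
    t = calibrate_stringency(syn_records([1, 2, 3, 4, 5]), 0)
    assert t > 5
    assert t == pytest.approx(5, rel=1e-12)


def test_calibrate_rejects_negative_expectation():
    with pytest.raises(InvalidInputError):
        calibrate_stringency([], -1)


@pytest.mark.parametrize("expected_syn", [0, 1, 2.5, 3, 7])
def test_calibrate_minimal_threshold_by_exhaustive_scan(expected_syn):
    """The returned threshold is the minimal candidate achieving the
    target, and the surviving count is non-increasing in t."""
    scores = [3, 1, 4, 1, 5, 9, 2, 6]
    recs = syn_records(scores)
    t = calibrate_stringency(recs, expected_syn)

    def survivors(thresh):
        return sum(s >= thresh for s in scores)

    assert survivors(t) <= expected_syn
    # minimality: every strictly smaller candidate keeps too many
    for cand in sorted(set(scores)):
        if cand < t:
            assert survivors(cand) > expected_syn
    # monotonicity of the survivor count
    grid = sorted(set(scores)) + [10]
    counts = [survivors(g) for g in grid]
    assert counts == sorted(counts, reverse=True)
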