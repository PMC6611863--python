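"""Candidate-selection screens for postzygotic mosaicism.

Three selection procedures operate on trio variant tables:

* :func:`screen_child_pzm` — candidate mosaic DNMs in the proband,
  selected by BH-FDR on the lower-tail binomial p of the proband VAF
  against 0.5, separately within a likely-pathogenic arm (LOF/functional
  variants in dominant DDG2P context) and a likely-benign control arm
  (synonymous variants outside DDG2P).
* :func:`screen_parent_lowlevel` — apparent DNMs with a few alternative
  reads in exactly one parent, candidate low-level parental mosaics.
* :func:`screen_parent_highlevel` — apparently inherited heterozygous
  variants whose carrier parent's VAF deviates below 0.5, via three
  union-ed strategies (FDR on the parental binomial p; protein-truncating
  or known-pathogenic with parental VAF < 0.4; affected sib pairs with
  parental VAF < 0.4).

Also here: the VAF-band/binomial-p rule-based mosaic predictor and the
stringency calibration that trims a DNM set until observed synonymous
counts match a null mutation-model expectation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from triomosaic.core import (
    Consequence,
    GeneClass,
    Genotype,
    Person,
    Tissue,
    TrioSiteRecord,
    is_dominant_candidate_context,
)
from triomosaic.errors import InvalidInputError
from triomosaic.stats import BinomialDeviation, Tail, bh_fdr, binomial_deviation_test

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenType",
    "Arm",
    "Strategy",
    "ScreenConfig",
    "ScreenCandidate",
    "screen_child_pzm",
    "screen_parent_lowlevel",
    "screen_parent_highlevel",
    "predict_mosaic_rule",
    "calibrate_stringency",
]


class ScreenType(str, Enum):
    CHILD_PZM = "child_pzm"
    PARENT_LOW = "parent_low"
    PARENT_HIGH = "parent_high"


class Arm(str, Enum):
    LIKELY_PATHOGENIC = "likely_pathogenic"
    CONTROL = "control"
    NONE = "none"


class Strategy(str, Enum):
    FDR = "fdr"
    PTV_OR_KNOWN = "ptv_or_known"
    SIB_PAIR = "sib_pair"
    ALT_READS = "alt_reads"
    NONE = "none"


@dataclass
class ScreenConfig:
    """Thresholds for the three screens.

    Defaults mirror the study design: FDR < 0.2 for likely-pathogenic
    child-PZM candidates and < 0.05 for synonymous controls, a proband
    VAF floor of 0.1 (below which WES candidates are dominated by
    sequencing error at ~50X), FDR < 0.1 plus a parental VAF < 0.4 cut
    for high-level parent-PZM, a proband VAF window of [0.3, 0.7] for
    the inherited-variant universe, and the 0.1 < VAF < 0.27 /
    binomial p < 1e-4 rule-based mosaic predictor.
    """

    child_fdr_pathogenic: float = 0.2
    child_fdr_control: float = 0.05
    child_vaf_floor: float = 0.1
    parent_lowlevel_min_alt: int = 1
    parent_lowlevel_predict_alt: int = 2
    highlevel_fdr: float = 0.1
    highlevel_parent_vaf_max: float = 0.4
    highlevel_proband_vaf_window: tuple[float, float] = (0.3, 0.7)
    inherited_maf_max: float = 0.001
    dnm_maf_max: float = 0.01
    predict_vaf_band: tuple[float, float] = (0.1, 0.27)
    predict_binom_p: float = 1e-4
    proband_tissue: Tissue = Tissue.SALIVA

    def __post_init__(self) -> None:
        for name in (
            "child_fdr_pathogenic",
            "child_fdr_control",
            "child_vaf_floor",
            "highlevel_fdr",
            "highlevel_parent_vaf_max",
            "inherited_maf_max",
            "dnm_maf_max",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidInputError(f"{name} must lie in [0, 1]")
        for name in ("highlevel_proband_vaf_window", "predict_vaf_band"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise InvalidInputError(f"{name} must satisfy lo < hi")


@dataclass
class ScreenCandidate:
    """A site selected by a screen, with the statistics that selected it."""

    record: TrioSiteRecord
    screen: ScreenType
    arm: Arm = Arm.NONE
    strategies: tuple[Strategy, ...] = (Strategy.NONE,)
    stats: BinomialDeviation | None = None
    q_value: float = float("nan")
    mosaic_parent: Person | None = None
    predicted_mosaic: bool = False

    @property
    def strategy(self) -> Strategy:
        return self.strategies[0]

    def __post_init__(self) -> None:
        if self.screen in (ScreenType.PARENT_LOW, ScreenType.PARENT_HIGH):
            if self.mosaic_parent not in (Person.MOTHER, Person.FATHER):
                raise InvalidInputError(
                    "parent screens must name exactly one candidate mosaic parent"
                )


def _in_pathogenic_arm(record: TrioSiteRecord) -> bool:
    return record.consequence in (
        Consequence.LOF,
        Consequence.FUNCTIONAL,
    ) and is_dominant_candidate_context(record)


def _in_control_arm(record: TrioSiteRecord) -> bool:
    return (
        record.consequence is Consequence.SYNONYMOUS
        and record.gene_class is GeneClass.NOT_DDG2P
    )


def _dnm_prefilter(
    dnms: Iterable[TrioSiteRecord], config: ScreenConfig
) -> list[tuple[TrioSiteRecord, BinomialDeviation]]:
    """Shared DNM-universe filter: rarity, sex-chromosome exclusion in
    males, proband VAF floor; returns each survivor with its proband
    lower-tail binomial test."""
    kept = []
    for rec in dnms:
        if rec.population_maf >= config.dnm_maf_max:
            continue
        if rec.is_sex_chromosome and rec.proband_sex.value == "M":
            continue
        obs = rec.proband_observation(prefer=config.proband_tissue)
        if obs is None or obs.depths.depth == 0:
            logger.warning("skipping %s: no usable proband depths", rec.site_id)
            continue
        stats = binomial_deviation_test(
            obs.depths.alt_count, obs.depths.depth, 0.5, Tail.LOWER
        )
        if stats.vaf <= config.child_vaf_floor:
            continue
        kept.append((rec, stats))
    return kept


def screen_child_pzm(
    dnms: Sequence[TrioSiteRecord],
    config: ScreenConfig | None = None,
) -> list[ScreenCandidate]:
    """Select candidate mosaic DNMs in the proband.

    BH FDR is applied separately within the likely-pathogenic and the
    control arm: the two arms answer different questions (diagnosis vs
    an unbiased mosaicism-rate estimate) and carry different thresholds.
    """
    config = config or ScreenConfig()
    universe = _dnm_prefilter(dnms, config)

    out: list[ScreenCandidate] = []
    for arm, member, threshold in (
        (Arm.LIKELY_PATHOGENIC, _in_pathogenic_arm, config.child_fdr_pathogenic),
        (Arm.CONTROL, _in_control_arm, config.child_fdr_control),
    ):
        arm_items = [(rec, st) for rec, st in universe if member(rec)]
        if not arm_items:
            continue
        qs = bh_fdr([st.p_value for _, st in arm_items])
        for (rec, st), q in zip(arm_items, qs):
            if q < threshold:
                out.append(
                    ScreenCandidate(
                        record=rec,
                        screen=ScreenType.CHILD_PZM,
                        arm=arm,
                        strategies=(Strategy.FDR,),
                        stats=st,
                        q_value=float(q),
                        predicted_mosaic=predict_mosaic_rule(st, config),
                    )
                )
    return out


def screen_parent_lowlevel(
    dnms: Sequence[TrioSiteRecord],
    config: ScreenConfig | None = None,
) -> list[ScreenCandidate]:
    """Select apparent DNMs with alternative reads in exactly one parent.

    The candidate universe is the likely-pathogenic DNM arm.  A site is
    selected when one parent shows >= ``parent_lowlevel_min_alt``
    alternative reads and the other shows none; the rule-based mosaic
    prediction fires at >= ``parent_lowlevel_predict_alt`` reads, since a
    single parental ALT read is usually sequencing error at ~50X.
    """
    config = config or ScreenConfig()
    universe = _dnm_prefilter(dnms, config)

    out: list[ScreenCandidate] = []
    for rec, proband_stats in universe:
        if not _in_pathogenic_arm(rec):
            continue
        mother = rec.observation(Person.MOTHER)
        father = rec.observation(Person.FATHER)
        if mother is None or father is None:
            continue
        m_alt, f_alt = mother.depths.alt_count, father.depths.alt_count
        if m_alt >= config.parent_lowlevel_min_alt and f_alt == 0:
            carrier, obs = Person.MOTHER, mother
        elif f_alt >= config.parent_lowlevel_min_alt and m_alt == 0:
            carrier, obs = Person.FATHER, father
        else:
            continue  # no parental reads, or reads in both parents
        parent_stats = binomial_deviation_test(
            obs.depths.alt_count, obs.depths.depth, 0.5, Tail.LOWER
        )
        out.append(
            ScreenCandidate(
                record=rec,
                screen=ScreenType.PARENT_LOW,
                arm=Arm.LIKELY_PATHOGENIC,
                strategies=(Strategy.ALT_READS,),
                stats=parent_stats,
                mosaic_parent=carrier,
                predicted_mosaic=obs.depths.alt_count
                >= config.parent_lowlevel_predict_alt,
            )
        )
    return out


def _carrier_parent(rec: TrioSiteRecord) -> Person | None:
    """The single heterozygous-carrier parent, or None if not exactly one.

    Genotype calls decide when present; otherwise a parent with >= 2
    alternative reads counts as a carrier.
    """
    carriers = []
    for person in (Person.MOTHER, Person.FATHER):
        obs = rec.observation(person)
        if obs is None:
            continue
        if obs.genotype_call is not Genotype.MISSING:
            is_carrier = obs.genotype_call in (Genotype.HET, Genotype.HOM_ALT)
        else:
            is_carrier = obs.depths.alt_count >= 2
        if is_carrier:
            carriers.append(person)
    return carriers[0] if len(carriers) == 1 else None


def screen_parent_highlevel(
    inherited: Sequence[TrioSiteRecord],
    config: ScreenConfig | None = None,
) -> list[ScreenCandidate]:
    """Select candidate high-level parental mosaics among inherited variants.

    Universe: rare inherited heterozygous LOF/functional variants in
    dominant DDG2P context with a constitutive-looking proband VAF
    (inside the [0.3, 0.7] window), an unaffected carrier parent, and
    ALT reads in only one parent.  Three strategies are unioned and
    tagged per candidate: (A) BH FDR on the carrier parent's lower-tail
    binomial p; (B) protein-truncating or known-pathogenic with parental
    VAF < 0.4; (C) shared by an affected sibling with parental VAF < 0.4.
    """
    config = config or ScreenConfig()
    lo, hi = config.highlevel_proband_vaf_window

    usable: list[tuple[TrioSiteRecord, Person, BinomialDeviation]] = []
    for rec in inherited:
        if rec.population_maf >= config.inherited_maf_max:
            continue
        if rec.consequence not in (Consequence.LOF, Consequence.FUNCTIONAL):
            continue
        if not is_dominant_candidate_context(rec):
            continue
        if any(rec.parent_affected):
            continue  # affected parents: constitutive inheritance expected
        proband = rec.proband_observation(prefer=config.proband_tissue)
        if proband is None or proband.depths.depth == 0:
            continue
        if proband.genotype_call not in (Genotype.HET, Genotype.MISSING):
            continue
        pvaf = proband.depths.vaf
        if pvaf < lo or pvaf > hi:
            continue
        mother = rec.observation(Person.MOTHER)
        father = rec.observation(Person.FATHER)
        if mother is None or father is None:
            continue
        if mother.depths.alt_count > 0 and father.depths.alt_count > 0:
            continue  # mutant reads in both parents
        carrier = _carrier_parent(rec)
        if carrier is None:
            continue
        obs = rec.observation(carrier)
        if obs.depths.depth == 0:
            continue
        stats = binomial_deviation_test(
            obs.depths.alt_count, obs.depths.depth, 0.5, Tail.LOWER
        )
        usable.append((rec, carrier, stats))

    qs = bh_fdr([st.p_value for _, _, st in usable]) if usable else []
    out: list[ScreenCandidate] = []
    for (rec, carrier, st), q in zip(usable, qs):
        strategies: list[Strategy] = []
        if q < config.highlevel_fdr:
            strategies.append(Strategy.FDR)
        parent_vaf_low = st.vaf < config.highlevel_parent_vaf_max
        if (rec.consequence is Consequence.LOF or rec.known_pathogenic) and parent_vaf_low:
            strategies.append(Strategy.PTV_OR_KNOWN)
        if rec.affected_sibling_shares_variant and parent_vaf_low:
            strategies.append(Strategy.SIB_PAIR)
        if strategies:
            out.append(
                ScreenCandidate(
                    record=rec,
                    screen=ScreenType.PARENT_HIGH,
                    arm=Arm.NONE,
                    strategies=tuple(strategies),
                    stats=st,
                    q_value=float(q),
                    mosaic_parent=carrier,
                    predicted_mosaic=predict_mosaic_rule(st, config),
                )
            )
    return out


def predict_mosaic_rule(
    stats: BinomialDeviation,
    config: ScreenConfig | None = None,
) -> bool:
    """Rule-based high-level mosaic prediction from WES statistics.

    True iff the VAF lies in the open band (0.1, 0.27) or the lower-tail
    binomial p-value is below 1e-4 (defaults).  VAF is sensitive but
    depth-blind; the binomial p adds depth-aware specificity.
    """
    config = config or ScreenConfig()
    lo, hi = config.predict_vaf_band
    return (lo < stats.vaf < hi) or (stats.p_value < config.predict_binom_p)


def calibrate_stringency(
    dnms: Sequence[TrioSiteRecord],
    expected_synonymous: float,
) -> float:
    """Quality-score threshold at which observed synonymous DNMs match a
    null mutation-model expectation.

    Returns the smallest call-quality threshold *t* such that the count
    of synonymous records with score >= *t* is <= ``expected_synonymous``.
    Returns ``-inf`` when no filtering is needed.  Because synonymous
    DNMs are assumed neutral, an excess over the null expectation
    measures the false-positive load, and trimming to the expectation
    yields a high-stringency DNM set.
    """
    if expected_synonymous < 0:
        raise InvalidInputError("expected_synonymous must be >= 0")
    scores = sorted(
        rec.call_quality_score
        for rec in dnms
        if rec.consequence is Consequence.SYNONYMOUS
    )
    n = len(scores)
    if n <= expected_synonymous:
        return -math.inf
    # candidate thresholds: each observed score, then just above the max
    for t in scores:
        if n - np.searchsorted(scores, t, side="left") <= expected_synonymous:
            return float(t)
    return float(np.nextafter(scores[-1], math.inf))
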