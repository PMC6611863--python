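"""Ultra-deep validation classification and downstream comparisons.

Candidate mosaic sites are re-sequenced at ~10^4–10^5x depth in all trio
members.  At that depth the binomial noise on a VAF estimate is ~0.002,
so an exact binomial exceedance test against the per-base error rate
separates real variants from error, and a two-sided test against 0.5
(with an effect-size guard band) separates mosaic from constitutive
carriers.  The classifier combines the per-person outcomes into the
validation categories: mosaic DNM, constitutive DNM, parent-mosaic,
constitutive inherited, false positive, or uninformative.

Also here: 2x2 confusion metrics for screening rules against validation
truth, the Mann–Whitney–Wilcoxon comparison of mosaic-level groups, and
the saliva/blood concordance regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from triomosaic.core import AlleleDepths, Person, Tissue
from triomosaic.errors import DegenerateFitError, InvalidInputError

__all__ = [
    "DeepSeqObservation",
    "ValidationOutcome",
    "ValidationCall",
    "ConfusionMetrics",
    "classify_validation",
    "confusion_metrics",
    "compare_group_vafs",
    "tissue_concordance",
]


@dataclass(frozen=True)
class DeepSeqObservation:
    """Ultra-deep read counts for one trio member in one tissue."""

    person: Person
    tissue: Tissue
    depths: AlleleDepths

    def __post_init__(self) -> None:
        if self.depths.depth <= 0:
            raise InvalidInputError("deep-sequencing observations require depth > 0")


class ValidationOutcome(str, Enum):
    MOSAIC_DNM = "mosaic_dnm"
    CONSTITUTIVE_DNM = "constitutive_dnm"
    PARENT_MOSAIC = "parent_mosaic"
    CONSTITUTIVE_INHERITED = "constitutive_inherited"
    FALSE_POSITIVE = "false_positive"
    UNINFORMATIVE = "uninformative"


@dataclass(frozen=True)
class ValidationCall:
    value: ValidationOutcome
    mosaic_person: Person | None = None
    validated_vaf: dict[tuple[Person, Tissue], float] | None = None
    conflict: bool = False


@dataclass(frozen=True)
class ConfusionMetrics:
    """Standard 2x2 screening metrics; undefined ratios are None."""

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None


def _safe_ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


# -- per-observation evidence --------------------------------------------------


@dataclass(frozen=True)
class _Evidence:
    present: bool
    constitutive_compatible: bool
    vaf: float
    depth: int


def _assess(
    obs: DeepSeqObservation,
    error_rate: float,
    alpha: float,
    constitutive_band: tuple[float, float],
) -> _Evidence:
    alt, depth = obs.depths.alt_count, obs.depths.depth
    present = sps.binomtest(alt, depth, error_rate, alternative="greater").pvalue < alpha
    vaf = alt / depth
    lo, hi = constitutive_band
    # at ultra depth the exact test rejects for trivial deviations from
    # 0.5, so a VAF inside the guard band is still constitutive-compatible
    if lo <= vaf <= hi:
        compatible = True
    else:
        compatible = sps.binomtest(alt, depth, 0.5).pvalue >= alpha
    return _Evidence(present, compatible, vaf, depth)


def classify_validation(
    observations: Sequence[DeepSeqObservation],
    error_rate: float = 0.005,
    alpha: float = 1e-6,
    min_informative_depth: int = 1000,
    constitutive_band: tuple[float, float] = (0.42, 0.58),
) -> ValidationCall:
    """Classify ultra-deep trio read counts into a validation outcome.

    Per person/tissue, a site is PRESENT when the one-sided exact
    binomial test of the alt count against ``error_rate`` rejects at
    ``alpha``, and constitutive-compatible when the two-sided test
    against 0.5 does not reject (or the VAF lies inside
    ``constitutive_band``, guarding against trivially-significant
    deviations at extreme depth).  Outcomes follow the trio logic:
    proband absent -> false positive; proband mosaic with silent parents
    -> mosaic DNM; proband constitutive with silent parents ->
    constitutive DNM; proband constitutive with one sub-constitutive
    parent -> parent-mosaic; both constitutive -> constitutive
    inherited.  Observations at insufficient depth, or proband tissues
    that contradict each other, yield UNINFORMATIVE.
    """
    if not 0.0 < error_rate <= 0.05:
        raise InvalidInputError("error_rate must lie in (0, 0.05]")
    proband_obs = [o for o in observations if o.person is Person.PROBAND]
    if not proband_obs:
        raise InvalidInputError("at least one proband observation is required")

    vafs = {
        (o.person, o.tissue): o.depths.alt_count / o.depths.depth
        for o in observations
    }

    # shallow decisive observations are uninformative
    if any(o.depths.depth < min_informative_depth for o in observations):
        return ValidationCall(ValidationOutcome.UNINFORMATIVE, validated_vaf=vafs)

    prob_ev = [
        _assess(o, error_rate, alpha, constitutive_band) for o in proband_obs
    ]
    # tissue conflict: one tissue shows the variant, the other does not
    if len({ev.present for ev in prob_ev}) > 1:
        return ValidationCall(
            ValidationOutcome.UNINFORMATIVE, validated_vaf=vafs, conflict=True
        )

    proband = prob_ev[0]
    parent_ev: dict[Person, _Evidence] = {
        o.person: _assess(o, error_rate, alpha, constitutive_band)
        for o in observations
        if o.person is not Person.PROBAND
    }
    present_parents = [p for p, ev in parent_ev.items() if ev.present]

    if not proband.present:
        return ValidationCall(ValidationOutcome.FALSE_POSITIVE, validated_vaf=vafs)

    if not present_parents:
        if proband.constitutive_compatible:
            return ValidationCall(ValidationOutcome.CONSTITUTIVE_DNM, validated_vaf=vafs)
        if proband.vaf < 0.5:
            return ValidationCall(
                ValidationOutcome.MOSAIC_DNM,
                mosaic_person=Person.PROBAND,
                validated_vaf=vafs,
            )
        return ValidationCall(ValidationOutcome.UNINFORMATIVE, validated_vaf=vafs)

    if proband.constitutive_compatible and len(present_parents) == 1:
        parent = present_parents[0]
        if not parent_ev[parent].constitutive_compatible and parent_ev[parent].vaf < 0.5:
            return ValidationCall(
                ValidationOutcome.PARENT_MOSAIC,
                mosaic_person=parent,
                validated_vaf=vafs,
            )
        return ValidationCall(
            ValidationOutcome.CONSTITUTIVE_INHERITED, validated_vaf=vafs
        )

    return ValidationCall(ValidationOutcome.UNINFORMATIVE, validated_vaf=vafs)


def confusion_metrics(
    predicted: Sequence[bool], truth: Sequence[bool]
) -> ConfusionMetrics:
    """2x2 confusion metrics of a boolean prediction against truth.

    Uninformative validations must be removed upstream.  Ratios with a
    zero denominator are reported as None, never as 0.
    """
    if len(predicted) != len(truth):
        raise InvalidInputError("predicted and truth must have equal length")
    pred = np.asarray(predicted, dtype=bool)
    tru = np.asarray(truth, dtype=bool)
    tp = int(np.sum(pred & tru))
    fp = int(np.sum(pred & ~tru))
    fn = int(np.sum(~pred & tru))
    tn = int(np.sum(~pred & ~tru))
    return ConfusionMetrics(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        sensitivity=_safe_ratio(tp, tp + fn),
        specificity=_safe_ratio(tn, tn + fp),
        ppv=_safe_ratio(tp, tp + fp),
        npv=_safe_ratio(tn, tn + fn),
    )


def compare_group_vafs(
    group_a: Sequence[float], group_b: Sequence[float]
) -> float:
    """Two-sided Mann–Whitney–Wilcoxon p-value comparing two VAF groups.

    Exact null distribution when the smaller group has <= 8 values and
    there are no ties; normal approximation with tie correction
    otherwise.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidInputError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        return 1.0  # all values identical: no rank information
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


def tissue_concordance(
    pairs: Sequence[tuple[float, float, bool]],
) -> dict:
    """Saliva/blood VAF concordance with gene-class interaction test.

    ``pairs`` are (saliva_vaf, blood_vaf, gene_class_flag) triples, the
    flag marking e.g. DDG2P membership.  Returns the pooled OLS slope
    and intercept of blood on saliva, the per-class R², and the p-value
    of the class x saliva interaction in the joint model — the test of
    whether tissue concordance differs between gene classes.
    """
    df = pd.DataFrame(pairs, columns=["saliva", "blood", "flag"])
    if df.shape[0] < 3:
        raise InvalidInputError("need at least 3 pairs")
    if np.isclose(df["saliva"].var(ddof=0), 0.0):
        raise DegenerateFitError("saliva VAF is constant; slope is undefined")
    df["flag"] = df["flag"].astype(int)

    pooled = smf.ols("blood ~ saliva", data=df).fit()
    r2: dict[bool, float | None] = {}
    for flag, sub in df.groupby("flag"):
        if sub.shape[0] >= 3 and sub["saliva"].var(ddof=0) > 0:
            r2[bool(flag)] = float(smf.ols("blood ~ saliva", data=sub).fit().rsquared)
        else:
            r2[bool(flag)] = None

    interaction_p: float | None = None
    if df["flag"].nunique() > 1:
        joint = smf.ols("blood ~ saliva * flag", data=df).fit()
        interaction_p = float(joint.pvalues["saliva:flag"])

    return {
        "slope": float(pooled.params["saliva"]),
        "intercept": float(pooled.params["Intercept"]),
        "r_squared_per_class": r2,
        "interaction_p": interaction_p,
    }
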