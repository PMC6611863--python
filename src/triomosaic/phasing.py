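"""Read-backed parental-origin phasing of candidate mosaic DNMs.

A candidate DNM lying on the same read pair as a nearby heterozygous
SNV inherited from a single parent can be assigned to the maternal or
paternal haplotype.  A constitutive variant produces two read-pair
haplotype classes; a mosaic variant produces the characteristic
three-haplotype pattern — the mutant allele confined to a *fraction* of
one parental background, with that background also appearing without
the mutant allele.

Downstream summaries: the paired test of DNM VAF against the inherited
allele's VAF (~0.5 expected for the inherited allele), the
paternal:maternal origin ratio with an exact binomial test against the
50:50 expectation for early-embryonic mutations, and the Poisson
regression of per-person mosaic DNM counts on parental age (constitutive
DNMs increase with paternal age; postzygotic ones should not).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from triomosaic.core import Person
from triomosaic.errors import DegenerateFitError, InsufficientDataError, InvalidInputError

__all__ = [
    "Allele",
    "Origin",
    "ReadPairObservation",
    "InformativeSite",
    "PhaseResult",
    "assign_parental_origin",
    "three_haplotype_check",
    "vaf_difference_test",
    "paternal_fraction",
    "parental_age_trend",
]


class Allele(str, Enum):
    REF = "ref"
    ALT = "alt"


class Origin(str, Enum):
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    UNKNOWN = "unknown"


_PARENT_TO_ORIGIN = {Person.MOTHER: Origin.MATERNAL, Person.FATHER: Origin.PATERNAL}
_OTHER_ORIGIN = {Origin.MATERNAL: Origin.PATERNAL, Origin.PATERNAL: Origin.MATERNAL}


@dataclass(frozen=True)
class ReadPairObservation:
    """Co-observation of the DNM allele and the informative-SNV allele on
    one read pair."""

    dnm_allele: Allele
    informative_allele: Allele


@dataclass(frozen=True)
class InformativeSite:
    """A nearby heterozygous SNV whose ALT allele is inherited from
    exactly one parent."""

    parent_of_origin_of_alt: Person
    site_vaf_in_proband: float = 0.5

    def __post_init__(self) -> None:
        if self.parent_of_origin_of_alt not in (Person.MOTHER, Person.FATHER):
            raise InvalidInputError("informative alt must come from one parent")


@dataclass(frozen=True)
class PhaseResult:
    origin: Origin
    n_support: int
    n_conflict: int
    three_haplotype: bool
    inherited_vaf: float


def assign_parental_origin(
    obs: Sequence[ReadPairObservation],
    info: InformativeSite,
    min_support: int = 3,
    max_conflict_fraction: float = 0.2,
) -> PhaseResult:
    """Assign a candidate DNM to the maternal or paternal haplotype.

    Among read pairs carrying the DNM ALT allele, the majority
    informative background decides the origin: if they ride the
    informative ALT, the DNM arose on the haplotype inherited from the
    informative-ALT parent; if they ride REF, on the other parent's
    haplotype.  The call is UNKNOWN with fewer than ``min_support``
    majority pairs or a minority (conflict) fraction above
    ``max_conflict_fraction``.
    """
    if not obs:
        raise InvalidInputError("read-pair observations must be non-empty")
    dnm_alt = [o for o in obs if o.dnm_allele is Allele.ALT]
    inherited_vaf = sum(o.informative_allele is Allele.ALT for o in obs) / len(obs)

    if not dnm_alt:
        return PhaseResult(
            origin=Origin.UNKNOWN,
            n_support=0,
            n_conflict=0,
            three_haplotype=three_haplotype_check(obs, max_conflict_fraction),
            inherited_vaf=inherited_vaf,
        )

    on_alt_bg = sum(o.informative_allele is Allele.ALT for o in dnm_alt)
    on_ref_bg = len(dnm_alt) - on_alt_bg
    alt_parent_origin = _PARENT_TO_ORIGIN[info.parent_of_origin_of_alt]
    if on_alt_bg >= on_ref_bg:
        origin, support, conflict = alt_parent_origin, on_alt_bg, on_ref_bg
    else:
        origin, support, conflict = _OTHER_ORIGIN[alt_parent_origin], on_ref_bg, on_alt_bg

    conflict_fraction = conflict / (support + conflict)
    if support < min_support or conflict_fraction > max_conflict_fraction:
        origin = Origin.UNKNOWN

    return PhaseResult(
        origin=origin,
        n_support=support,
        n_conflict=conflict,
        three_haplotype=three_haplotype_check(obs, max_conflict_fraction),
        inherited_vaf=inherited_vaf,
    )


def three_haplotype_check(
    obs: Sequence[ReadPairObservation],
    max_conflict_fraction: float = 0.2,
) -> bool:
    """Whether read pairs show the three-haplotype pattern of mosaicism.

    Requires at least three distinct (dnm, informative) allele classes,
    the DNM ALT reads confined to a single informative background
    (minority-background fraction <= ``max_conflict_fraction``), and
    both informative backgrounds present among DNM-REF pairs — i.e. the
    mutant allele occupies only part of one parental haplotype.
    """
    if not obs:
        raise InvalidInputError("read-pair observations must be non-empty")
    classes = {(o.dnm_allele, o.informative_allele) for o in obs}
    if len(classes) < 3:
        return False
    dnm_alt = [o for o in obs if o.dnm_allele is Allele.ALT]
    if not dnm_alt:
        return False
    on_alt = sum(o.informative_allele is Allele.ALT for o in dnm_alt)
    minority = min(on_alt, len(dnm_alt) - on_alt)
    if minority / len(dnm_alt) > max_conflict_fraction:
        return False
    ref_backgrounds = {
        o.informative_allele for o in obs if o.dnm_allele is Allele.REF
    }
    return len(ref_backgrounds) == 2


def vaf_difference_test(
    paired: Sequence[tuple[float, float]],
    method: str = "wilcoxon",
) -> float:
    """Paired two-sided test of DNM VAF against the inherited-allele VAF.

    For genuinely mosaic variants the inherited allele sits at ~0.5
    while the DNM VAF is depressed, so the paired differences are
    systematically positive.  Default is the Wilcoxon signed-rank test;
    ``method='t'`` uses a paired t-test instead.
    """
    if len(paired) < 5:
        raise InsufficientDataError("need >= 5 pairs")
    dnm = np.array([p[0] for p in paired], dtype=float)
    inh = np.array([p[1] for p in paired], dtype=float)
    diffs = inh - dnm
    if np.all(diffs == 0):
        return 1.0
    if method == "t":
        return float(sps.ttest_rel(inh, dnm).pvalue)
    if method != "wilcoxon":
        raise InvalidInputError("method must be 'wilcoxon' or 't'")
    return float(sps.wilcoxon(diffs, alternative="two-sided").pvalue)


def paternal_fraction(origins: Sequence[PhaseResult | Origin]) -> dict:
    """Paternal/maternal origin counts with an exact test against 50:50.

    UNKNOWN results are dropped.  Early-embryonic postzygotic mutations
    precede sexual differentiation, so a 50:50 parental-origin ratio is
    the null — in contrast to the paternal excess of gametic DNMs.
    """
    vals = [o.origin if isinstance(o, PhaseResult) else o for o in origins]
    n_pat = sum(v is Origin.PATERNAL for v in vals)
    n_mat = sum(v is Origin.MATERNAL for v in vals)
    n = n_pat + n_mat
    if n == 0:
        raise InvalidInputError("no phased (non-UNKNOWN) results")
    return {
        "n_paternal": n_pat,
        "n_maternal": n_mat,
        "fraction_paternal": n_pat / n,
        "binomial_p_vs_half": float(sps.binomtest(n_pat, n, 0.5).pvalue),
    }


def parental_age_trend(
    per_person: Sequence[tuple[int, float]],
) -> dict:
    """Poisson regression of per-person mosaic DNM counts on parental age.

    Returns the log-link slope per year of age and its Wald p-value.
    Constitutive DNM counts rise with (especially paternal) age;
    postzygotic DNM counts should not.
    """
    if len(per_person) < 10:
        raise InsufficientDataError("need >= 10 persons")
    counts = np.array([p[0] for p in per_person], dtype=float)
    ages = np.array([p[1] for p in per_person], dtype=float)
    if np.any(ages <= 0):
        raise InvalidInputError("ages must be positive")
    if np.isclose(ages.var(ddof=0), 0.0):
        raise DegenerateFitError("age has zero variance")
    X = sm.add_constant(ages)
    fit = sm.GLM(counts, X, family=sm.families.Poisson()).fit()
    return {
        "slope_per_year": float(fit.params[1]),
        "p_value": float(fit.pvalues[1]),
    }
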