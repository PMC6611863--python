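"""VAF-binned enrichment of damaging de novo mutations.

If depressed VAF marks mosaicism, and mosaic variants are less
penetrant, then the enrichment of potentially damaging (LOF +
functional) over synonymous DNMs should fall with decreasing VAF —
most steeply in gene classes where variants are most likely to cause a
dominant monogenic disorder.  The module bins DNMs into six proband-VAF
bins, computes the (LOF+Func)/Syn damaging ratio per bin and gene
class, regresses the ratio on mean bin VAF with a Z-test of the slope
against a flat no-enrichment null, and compares mosaic versus
constitutive enrichment against an externally supplied expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from triomosaic.core import Consequence, GeneClass, TrioSiteRecord
from triomosaic.errors import InsufficientDataError, InvalidInputError
from triomosaic.screens import ScreenConfig

__all__ = [
    "VafBin",
    "ClassCounts",
    "EnrichmentRow",
    "EnrichmentTable",
    "RegressionResult",
    "DEFAULT_BIN_EDGES",
    "REFERENCE_COHORT_BIN_COUNTS",
    "reference_cohort_table",
    "bin_dnms",
    "damaging_ratio",
    "enrichment_regression",
    "mosaic_vs_constitutive_enrichment",
]

#: Six proband-VAF bins: [0.10, 0.15), ..., [0.30, 0.35), [0.35, 1.0].
DEFAULT_BIN_EDGES: tuple[float, ...] = (0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 1.0)

#: Gene-class strata used in the binned table.  Strata are nested, not
#: exclusive: a monoallelic-LOF DDG2P record counts in all three.
STRATA = ("all", "ddg2p", "monolof")


@dataclass(frozen=True)
class VafBin:
    lower: float  # inclusive
    upper: float  # exclusive, except the last bin which closes at 1.0
    mean_vaf: float | None = None

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise InvalidInputError("bin must satisfy lower < upper")


@dataclass(frozen=True)
class ClassCounts:
    functional: int = 0
    lof: int = 0
    synonymous: int = 0

    def __post_init__(self) -> None:
        if min(self.functional, self.lof, self.synonymous) < 0:
            raise InvalidInputError("counts must be non-negative")


@dataclass(frozen=True)
class EnrichmentRow:
    bin: VafBin
    gene_class: str  # one of STRATA
    counts: ClassCounts
    damaging_ratio: float | None


@dataclass
class EnrichmentTable:
    rows: list[EnrichmentRow]
    n_excluded_below_floor: int = 0

    def stratum(self, gene_class: str) -> list[EnrichmentRow]:
        return [r for r in self.rows if r.gene_class == gene_class]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    slope_se: float
    z: float
    p_value: float
    null_slope: float
    null_ratio: float
    intercept_shift_z: float | None = None
    intercept_shift_p: float | None = None


def damaging_ratio(counts: ClassCounts) -> float | None:
    """(LOF + functional) / synonymous; None when no synonymous DNMs."""
    if counts.synonymous == 0:
        return None
    return (counts.functional + counts.lof) / counts.synonymous


def _stratum_member(rec: TrioSiteRecord, stratum: str) -> bool:
    if stratum == "all":
        return True
    if stratum == "ddg2p":
        return rec.gene_class.is_ddg2p_dominant
    if stratum == "monolof":
        return rec.gene_class is GeneClass.DDG2P_MONOALLELIC_LOF
    raise InvalidInputError(f"unknown stratum {stratum!r}")


def bin_dnms(
    dnms: Sequence[TrioSiteRecord],
    edges: Sequence[float] = DEFAULT_BIN_EDGES,
    proband_tissue=None,
) -> EnrichmentTable:
    """Count DNM consequence classes in half-open proband-VAF bins.

    Bins are [lower, upper) with the final bin closed at the last edge.
    Sex-chromosome records in male probands are excluded (hemizygous
    VAFs are not comparable), as are records whose VAF falls below the
    lowest edge (counted in ``n_excluded_below_floor``).
    """
    edges = list(edges)
    if len(edges) < 2 or any(a >= b for a, b in zip(edges, edges[1:])):
        raise InvalidInputError("edges must be strictly increasing")

    nbins = len(edges) - 1
    counts = {
        (i, s): {"functional": 0, "lof": 0, "synonymous": 0}
        for i in range(nbins)
        for s in STRATA
    }
    vaf_sums = np.zeros(nbins)
    vaf_ns = np.zeros(nbins, dtype=int)
    excluded = 0

    for rec in dnms:
        if rec.is_sex_chromosome and rec.proband_sex.value == "M":
            continue
        obs = rec.proband_observation(prefer=proband_tissue) if proband_tissue else rec.proband_observation()
        if obs is None or obs.depths.depth == 0:
            continue
        vaf = obs.depths.vaf
        if vaf < edges[0]:
            excluded += 1
            continue
        if vaf > edges[-1]:
            excluded += 1
            continue
        idx = min(int(np.searchsorted(edges, vaf, side="right")) - 1, nbins - 1)
        vaf_sums[idx] += vaf
        vaf_ns[idx] += 1
        key = {
            Consequence.FUNCTIONAL: "functional",
            Consequence.LOF: "lof",
            Consequence.SYNONYMOUS: "synonymous",
        }.get(rec.consequence)
        if key is None:
            continue
        for s in STRATA:
            if _stratum_member(rec, s):
                counts[(idx, s)][key] += 1

    rows: list[EnrichmentRow] = []
    for i in range(nbins):
        mean_vaf = float(vaf_sums[i] / vaf_ns[i]) if vaf_ns[i] else None
        vbin = VafBin(lower=edges[i], upper=edges[i + 1], mean_vaf=mean_vaf)
        for s in STRATA:
            cc = ClassCounts(**counts[(i, s)])
            rows.append(
                EnrichmentRow(
                    bin=vbin, gene_class=s, counts=cc, damaging_ratio=damaging_ratio(cc)
                )
            )
    return EnrichmentTable(rows=rows, n_excluded_below_floor=excluded)


def enrichment_regression(
    bins: Sequence[tuple[float, float]],
    null_ratio: float,
) -> RegressionResult:
    """OLS of damaging ratio on mean bin VAF, Z-tested against a flat null.

    ``bins`` are (mean_vaf, damaging_ratio) pairs; bins with undefined
    ratios must be dropped by the caller.  Under no enrichment the
    damaging ratio is a flat line at ``null_ratio``: the slope is
    Z-tested against 0, and the fitted intercept is additionally
    Z-tested against ``null_ratio``.
    """
    pts = [(x, y) for x, y in bins if y is not None and np.isfinite(y)]
    if len(pts) < 3:
        raise InsufficientDataError("need >= 3 bins with defined ratios")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    n = x.size
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise InsufficientDataError("mean VAFs are constant; slope undefined")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    dof = n - 2
    sigma2 = float(np.sum(resid**2) / dof) if dof > 0 else 0.0
    slope_se = float(np.sqrt(sigma2 / sxx))
    intercept_se = float(np.sqrt(sigma2 * (1.0 / n + x.mean() ** 2 / sxx)))

    null_slope = 0.0
    if slope_se > 0:
        z = (slope - null_slope) / slope_se
        p = float(2 * sps.norm.sf(abs(z)))
    else:  # perfectly collinear points
        z = math_inf_signed(slope - null_slope)
        p = 0.0 if slope != null_slope else 1.0
    if intercept_se > 0:
        iz = (intercept - null_ratio) / intercept_se
        ip = float(2 * sps.norm.sf(abs(iz)))
    else:
        iz = math_inf_signed(intercept - null_ratio)
        ip = 0.0 if intercept != null_ratio else 1.0

    return RegressionResult(
        slope=slope,
        intercept=intercept,
        slope_se=slope_se,
        z=float(z),
        p_value=p,
        null_slope=null_slope,
        null_ratio=null_ratio,
        intercept_shift_z=float(iz),
        intercept_shift_p=ip,
    )


def math_inf_signed(delta: float) -> float:
    if delta > 0:
        return float("inf")
    if delta < 0:
        return float("-inf")
    return 0.0


def mosaic_vs_constitutive_enrichment(
    counts_mosaic: ClassCounts,
    counts_constitutive: ClassCounts,
    expected: ClassCounts,
) -> dict:
    """Compare damaging-variant enrichment between mosaic and constitutive
    strata, relative to a null expectation.

    ``expected`` carries the null-model expected counts (external input,
    e.g. from a published mutation-rate model).  Enrichment per stratum
    is the observed damaging ratio divided by the expected damaging
    ratio; the p-value is a two-sided Fisher exact test on the 2x2 of
    (damaging, synonymous) across the two strata.
    """
    exp_ratio = damaging_ratio(expected)
    if exp_ratio is None or exp_ratio == 0:
        raise InvalidInputError("expected counts must define a non-zero damaging ratio")
    obs_m = damaging_ratio(counts_mosaic)
    obs_c = damaging_ratio(counts_constitutive)
    if obs_m is None or obs_c is None:
        raise InvalidInputError(
            "both strata need synonymous counts > 0 for a defined ratio"
        )
    enr_m = obs_m / exp_ratio
    enr_c = obs_c / exp_ratio
    table = [
        [counts_mosaic.functional + counts_mosaic.lof, counts_mosaic.synonymous],
        [
            counts_constitutive.functional + counts_constitutive.lof,
            counts_constitutive.synonymous,
        ],
    ]
    _, p = sps.fisher_exact(table, alternative="two-sided")
    return {
        "enrichment_mosaic": enr_m,
        "enrichment_constitutive": enr_c,
        "ratio_of_enrichments": enr_m / enr_c if enr_c != 0 else float("nan"),
        "p_value": float(p),
    }


# ---------------------------------------------------------------------------
# Reference cohort: published per-bin DNM consequence counts from a
# 4,293-trio developmental-disorder study (candidate DNMs binned by
# proband VAF; gene-class strata nested as all / dominant DDG2P /
# monoallelic-LOF DDG2P).  Used by the examples and the acceptance
# script as a fixed published input for ratio arithmetic.
# Each entry: (lower, upper, mean_vaf, {stratum: (func, lof, syn)}).
REFERENCE_COHORT_BIN_COUNTS: tuple = (
    (0.10, 0.15, 0.14, {"all": (10, 1, 7), "ddg2p": (3, 0, 1), "monolof": (1, 0, 0)}),
    (0.15, 0.20, 0.18, {"all": (81, 18, 33), "ddg2p": (5, 3, 3), "monolof": (3, 2, 0)}),
    (0.20, 0.25, 0.22, {"all": (99, 35, 42), "ddg2p": (16, 8, 4), "monolof": (6, 4, 1)}),
    (0.25, 0.30, 0.27, {"all": (135, 58, 53), "ddg2p": (23, 21, 5), "monolof": (7, 15, 2)}),
    (0.30, 0.35, 0.33, {"all": (266, 81, 69), "ddg2p": (54, 31, 10), "monolof": (17, 23, 3)}),
    (0.35, 1.00, 0.49, {"all": (3709, 1224, 1084), "ddg2p": (673, 488, 112), "monolof": (302, 389, 28)}),
)


def reference_cohort_table() -> EnrichmentTable:
    """The published reference-cohort counts as an EnrichmentTable."""
    rows = []
    for lower, upper, mean_vaf, strata in REFERENCE_COHORT_BIN_COUNTS:
        vbin = VafBin(lower=lower, upper=upper, mean_vaf=mean_vaf)
        for s in STRATA:
            func, lof, syn = strata[s]
            cc = ClassCounts(functional=func, lof=lof, synonymous=syn)
            rows.append(
                EnrichmentRow(
                    bin=vbin, gene_class=s, counts=cc, damaging_ratio=damaging_ratio(cc)
                )
            )
    return EnrichmentTable(rows=rows)
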