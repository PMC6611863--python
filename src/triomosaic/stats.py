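"""Core VAF statistics.

A constitutive heterozygous variant generates alternative reads as
Binomial(depth, 0.5); mosaicism in the sequenced tissue depresses the
expected variant allele fraction (VAF) below 0.5, since a variant
present in a cell fraction *f* is sequenced at VAF ≈ *f*/2.  The module
provides the exact binomial deviation test against the constitutive
null, Benjamini–Hochberg FDR over a screen's p-values, a constrained
two-component Gaussian mixture for deconvolving the mosaic VAF component
out of a pooled DNM VAF distribution, and the binomial detection-power
model for a caller that requires a minimum number of alternative reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from triomosaic.errors import InsufficientDataError, InvalidInputError, UndefinedVAFError

__all__ = [
    "Tail",
    "BinomialDeviation",
    "MixtureFit",
    "PowerEstimate",
    "compute_vaf",
    "binomial_deviation_test",
    "bh_fdr",
    "fit_vaf_mixture",
    "detection_power",
]


class Tail(str, Enum):
    LOWER = "lower"
    TWO_SIDED = "two_sided"


@dataclass(frozen=True)
class BinomialDeviation:
    """Exact binomial test of an observed allele count against a null VAF."""

    alt_count: int
    depth: int
    vaf: float
    p_value: float
    null_vaf: float = 0.5
    tail: Tail = Tail.LOWER


@dataclass(frozen=True)
class MixtureFit:
    """Two-component Gaussian mixture fit of a VAF distribution.

    The lower-mean component is the mosaic one by construction
    (``mean_mosaic < mean_constitutive``); ``mosaic_fraction`` is its
    mixture weight among the VAFs above the fitting floor.
    """

    weight_mosaic: float
    weight_constitutive: float
    mean_mosaic: float
    mean_constitutive: float
    sd_mosaic: float
    sd_constitutive: float
    mosaic_fraction: float
    converged: bool
    log_likelihood: float
    n_iterations: int
    n_used: int = 0

    def summary(self) -> dict:
        """JSON-serialisable fit summary."""
        return {
            "weights": [self.weight_mosaic, self.weight_constitutive],
            "means": [self.mean_mosaic, self.mean_constitutive],
            "sds": [self.sd_mosaic, self.sd_constitutive],
            "mosaic_fraction": self.mosaic_fraction,
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "n_used": self.n_used,
        }


@dataclass(frozen=True)
class PowerEstimate:
    depth: float
    vaf: float
    min_alt_reads: int
    power: float


def compute_vaf(alt_count: int, depth: int) -> float:
    """Alternative-allele reads divided by total depth."""
    if depth <= 0:
        raise UndefinedVAFError("VAF undefined at zero depth")
    if alt_count < 0 or alt_count > depth:
        raise InvalidInputError("alt_count must lie in [0, depth]")
    return alt_count / depth


def binomial_deviation_test(
    alt_count: int,
    depth: int,
    null_vaf: float = 0.5,
    tail: Tail = Tail.LOWER,
) -> BinomialDeviation:
    """Exact binomial test of the observed VAF against ``null_vaf``.

    LOWER returns P(X <= alt_count) for X ~ Binomial(depth, null_vaf) —
    the one-sided evidence that the VAF is depressed below the
    constitutive expectation.  TWO_SIDED returns the minimum-likelihood
    exact two-sided p-value.
    """
    if not 0.0 < null_vaf < 1.0:
        raise InvalidInputError("null_vaf must lie in (0, 1)")
    vaf = compute_vaf(alt_count, depth)
    if tail is Tail.LOWER:
        p = float(sps.binom.cdf(alt_count, depth, null_vaf))
    else:
        p = float(sps.binomtest(alt_count, depth, null_vaf).pvalue)
    return BinomialDeviation(
        alt_count=alt_count,
        depth=depth,
        vaf=vaf,
        p_value=min(p, 1.0),
        null_vaf=null_vaf,
        tail=tail,
    )


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order.

    q_i = min over ranks j >= rank(i) of p_(j) * m / j, capped at 1.
    Ties are handled by a stable sort, so the output is deterministic.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _norm_logpdf(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return -0.5 * ((x - mu) / sd) ** 2 - math.log(sd) - 0.5 * math.log(2 * math.pi)


def fit_vaf_mixture(
    vafs: Sequence[float],
    vaf_floor: float = 0.1,
    seed: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
    constitutive_mean_bounds: tuple[float, float] = (0.45, 0.55),
) -> MixtureFit:
    """EM fit of a two-component Gaussian mixture to a VAF distribution.

    Values at or below ``vaf_floor`` are discarded before fitting,
    matching a screen that cannot distinguish very low VAFs from
    sequencing error.  The constitutive component is initialised at mean
    0.5 and its mean is constrained to ``constitutive_mean_bounds``; the
    mosaic component's mean is free in (vaf_floor, 0.45).  This mean
    anchoring fixes component identity, so no post-hoc label switching
    is needed.  The fit is deterministic: initialisation does not depend
    on ``seed`` (accepted for interface uniformity).
    """
    x = np.asarray(list(vafs), dtype=float)
    x = x[x > vaf_floor]
    n = x.size
    if n < 20:
        raise InsufficientDataError(
            f"need >= 20 VAFs above the floor {vaf_floor}, got {n}"
        )

    lo_bound, hi_bound = vaf_floor + 1e-3, 0.45 - 1e-3
    mu1 = min(max(0.5 * (vaf_floor + 0.45), lo_bound), hi_bound)  # mosaic
    mu2 = 0.5  # constitutive
    sd1, sd2 = 0.06, 0.07
    w1 = 0.1

    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_p1 = math.log(max(w1, 1e-300)) + _norm_logpdf(x, mu1, sd1)
        log_p2 = math.log(max(1 - w1, 1e-300)) + _norm_logpdf(x, mu2, sd2)
        log_mix = np.logaddexp(log_p1, log_p2)
        ll = float(log_mix.sum())
        r1 = np.exp(log_p1 - log_mix)  # responsibility of the mosaic component

        n1 = float(r1.sum())
        w1 = n1 / n
        if n1 > 1e-10:
            mu1 = float((r1 * x).sum() / n1)
            sd1 = math.sqrt(max(float((r1 * (x - mu1) ** 2).sum() / n1), 1e-6))
        n2 = n - n1
        if n2 > 1e-10:
            mu2 = float(((1 - r1) * x).sum() / n2)
            sd2 = math.sqrt(max(float(((1 - r1) * (x - mu2) ** 2).sum() / n2), 1e-6))
        mu1 = min(max(mu1, lo_bound), hi_bound)
        mu2 = min(max(mu2, constitutive_mean_bounds[0]), constitutive_mean_bounds[1])

        if abs(ll - ll_prev) < tol:
            converged = True
            ll_prev = ll
            break
        ll_prev = ll

    return MixtureFit(
        weight_mosaic=w1,
        weight_constitutive=1 - w1,
        mean_mosaic=mu1,
        mean_constitutive=mu2,
        sd_mosaic=sd1,
        sd_constitutive=sd2,
        mosaic_fraction=w1,
        converged=converged,
        log_likelihood=ll_prev,
        n_iterations=it,
        n_used=n,
    )


def detection_power(
    depth: int | Sequence[int],
    vaf: float,
    min_alt_reads: int = 3,
) -> PowerEstimate:
    """Probability that at least ``min_alt_reads`` alternative reads appear.

    Models a de novo caller that needs a minimum number of ALT reads:
    power = P(X >= min_alt_reads), X ~ Binomial(depth, vaf).  When
    ``depth`` is a sequence of per-site depths, the mean power over the
    empirical depth distribution is returned.
    """
    if not 0.0 <= vaf <= 1.0:
        raise InvalidInputError("vaf must lie in [0, 1]")
    if min_alt_reads < 1:
        raise InvalidInputError("min_alt_reads must be >= 1")
    depths = np.atleast_1d(np.asarray(depth, dtype=int))
    if depths.size == 0 or np.any(depths <= 0):
        raise InvalidInputError("depth must be positive")
    power = float(np.mean(sps.binom.sf(min_alt_reads - 1, depths, vaf)))
    return PowerEstimate(
        depth=float(np.mean(depths)),
        vaf=vaf,
        min_alt_reads=min_alt_reads,
        power=power,
    )
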