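"""Synthetic trio cohort with ground truth.

The generator emulates a large developmental-disorder trio cohort at
the read-count level: per-site exome depths around 50X, constitutive
heterozygotes sequenced at Binomial(depth, 0.5), mosaic carriers at
Binomial(depth, true VAF), and non-carriers at the per-base error rate.
True mosaic VAFs are drawn uniformly over the validated ranges reported
for each mosaic class (child 0.04–0.39; low-level parent 0.005–0.20;
high-level parent 0.06–0.33).  A separate mixture preset plants a 6%
mosaic component with mean VAF 0.198 among the DNM VAF distribution for
mixture-model recovery.  Ultra-deep validation counts (median ~100,032
reads) and phased read-pair co-observations are generated from the same
ground truth, so every pipeline stage can be tested against what was
planted.

What the generator does *not* model: sequence-context mutation rates,
caller artefacts (strand bias, mapping error), indel realignment, or
relatedness structure.  Tests passing on this cohort show the screens'
decision logic and calibration are correct under binomial read
sampling, not that real-data artefact modes are handled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from triomosaic.core import (
    AlleleDepths,
    Consequence,
    GeneClass,
    Genotype,
    InheritanceMode,
    Person,
    PersonObservation,
    Sex,
    Tissue,
    TrioSiteRecord,
    classify_consequence,
)
from triomosaic.errors import InvalidInputError
from triomosaic.phasing import Allele, InformativeSite, ReadPairObservation
from triomosaic.validation import DeepSeqObservation

__all__ = [
    "SimulationConfig",
    "CohortTruth",
    "TRUE_CLASSES",
    "simulate_trio_cohort",
    "simulate_validation_counts",
    "simulate_read_pairs",
    "simulate_gmm_preset_vafs",
]

TRUE_CLASSES = (
    "constitutive_dnm",
    "child_mosaic",
    "parent_mosaic_low",
    "parent_mosaic_high",
    "false_positive",
    "constitutive_inherited",
)


@dataclass
class SimulationConfig:
    """Cohort-scale generative parameters.

    Defaults follow the emulated study: 4,293 trios contributing ~8,464
    candidate DNMs at ~50X mean coding depth with an Illumina-like
    per-base error rate of 0.005; mosaic VAF ranges per class follow the
    validated ranges; ultra-deep validation depth has median ~100,032
    reads.  ``class_mix`` governs the truth composition of the emitted
    sites; the inherited-variant classes (high-level parent mosaic and
    its constitutive-inherited null background) are included so the
    inherited screen has a meaningful FDR universe.
    """

    n_trios: int = 4293
    n_candidate_dnms: int = 8464
    mean_depth: float = 50.0
    min_depth: int = 10
    error_rate: float = 0.005
    class_mix: dict = field(
        default_factory=lambda: {
            "constitutive_dnm": 0.60,
            "child_mosaic": 0.06,
            "parent_mosaic_low": 0.02,
            "parent_mosaic_high": 0.02,
            "false_positive": 0.05,
            "constitutive_inherited": 0.25,
        }
    )
    child_mosaic_vaf_range: tuple[float, float] = (0.04, 0.39)
    parent_low_vaf_range: tuple[float, float] = (0.005, 0.20)
    parent_high_vaf_range: tuple[float, float] = (0.06, 0.33)
    gmm_mosaic_fraction: float = 0.06
    gmm_mosaic_mean_vaf: float = 0.198
    gmm_mosaic_vaf_sd: float = 0.05
    ultra_depth_median: int = 100_032
    consequence_mix: dict = field(
        default_factory=lambda: {
            "synonymous_variant": 0.30,
            "missense_variant": 0.40,
            "stop_gained": 0.08,
            "frameshift_variant": 0.07,
            "splice_donor_variant": 0.03,
            "inframe_deletion": 0.02,
            "intron_variant": 0.10,
        }
    )
    gene_class_mix: dict = field(
        default_factory=lambda: {
            "not_ddg2p": 0.70,
            "ddg2p_dominant": 0.18,
            "ddg2p_monoallelic_lof": 0.12,
        }
    )
    x_chrom_fraction: float = 0.04
    blood_tissue: bool = True
    saliva_blood_vaf_divergence: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, mix in (
            ("class_mix", self.class_mix),
            ("consequence_mix", self.consequence_mix),
            ("gene_class_mix", self.gene_class_mix),
        ):
            total = sum(mix.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise InvalidInputError(f"{name} proportions must sum to 1, got {total}")
            if any(v < 0 for v in mix.values()):
                raise InvalidInputError(f"{name} proportions must be non-negative")
        if not set(self.class_mix) <= set(TRUE_CLASSES):
            raise InvalidInputError(f"unknown class in class_mix: {set(self.class_mix) - set(TRUE_CLASSES)}")


@dataclass
class CohortTruth:
    """Ground-truth labels for every emitted site, keyed by site_id."""

    table: pd.DataFrame  # columns: site_id, true_class, true_vaf_proband,
    #          true_vaf_mother, true_vaf_father, true_parental_origin,
    #          true_gene_class, true_consequence

    def lookup(self, site_id: str) -> pd.Series:
        return self.table.set_index("site_id").loc[site_id]


def _draw_depth(rng: np.random.Generator, mean_depth: float, min_depth: int) -> int:
    d = int(rng.poisson(mean_depth))
    return max(d, min_depth)


def _genotype_from_truth(true_vaf: float) -> Genotype:
    # emulates a constitutive caller: carriers at appreciable VAF are
    # HET; low-level carriers and non-carriers are called HOM_REF
    if true_vaf >= 0.30:
        return Genotype.HET
    return Genotype.HOM_REF


def simulate_trio_cohort(
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> tuple[list[TrioSiteRecord], CohortTruth]:
    """Generate a trio cohort of candidate sites with ground truth.

    Per site: a true class is drawn from ``class_mix``; per trio member
    a depth is drawn Poisson(mean_depth) truncated at ``min_depth`` and
    an alt count Binomial(depth, v), where v is 0.5 for constitutive
    carriers, the class's true mosaic VAF for the mosaic person, and
    ``error_rate`` for non-carriers and false-positive sites.
    High-level parent-mosaic sites give the child a constitutive 0.5 and
    the mosaic parent their true VAF, with the parental genotype call
    set to HET (these are by definition the sites a standard caller
    genotypes in the parent).  Proband blood observations share the
    saliva true VAF unless ``saliva_blood_vaf_divergence`` is set.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    classes = list(config.class_mix)
    probs = np.array([config.class_mix[c] for c in classes])
    n = config.n_candidate_dnms
    site_classes = rng.choice(classes, size=n, p=probs)

    cons_terms = list(config.consequence_mix)
    cons_probs = np.array([config.consequence_mix[t] for t in cons_terms])
    gene_classes = list(config.gene_class_mix)
    gene_probs = np.array([config.gene_class_mix[g] for g in gene_classes])

    records: list[TrioSiteRecord] = []
    truth_rows: list[dict] = []
    bases = np.array(["A", "C", "G", "T"])

    for i in range(n):
        cls = str(site_classes[i])
        sex = Sex.M if rng.random() < 0.5 else Sex.F
        on_x = rng.random() < config.x_chrom_fraction
        chrom = "X" if on_x else str(int(rng.integers(1, 23)))
        pos = int(rng.integers(1, 100_000_000))
        ref, alt = rng.choice(bases, size=2, replace=False)

        cons_term = str(rng.choice(cons_terms, p=cons_probs))
        gene_cls = GeneClass(str(rng.choice(gene_classes, p=gene_probs)))
        inh = (
            InheritanceMode.X_LINKED_DOMINANT
            if on_x and gene_cls is not GeneClass.NOT_DDG2P
            else InheritanceMode.AUTOSOMAL_DOMINANT
        )

        # true VAF per person (expected fraction of alt reads)
        err = config.error_rate
        origin = None
        if cls == "constitutive_dnm":
            v_prob, v_mo, v_fa = 0.5, err, err
        elif cls == "child_mosaic":
            v_prob = float(rng.uniform(*config.child_mosaic_vaf_range))
            v_mo, v_fa = err, err
            origin = "maternal" if rng.random() < 0.5 else "paternal"
        elif cls == "parent_mosaic_low":
            v_prob = 0.5
            v_parent = float(rng.uniform(*config.parent_low_vaf_range))
            if rng.random() < 0.5:
                v_mo, v_fa, origin = v_parent, err, "maternal"
            else:
                v_mo, v_fa, origin = err, v_parent, "paternal"
        elif cls == "parent_mosaic_high":
            v_prob = 0.5
            v_parent = float(rng.uniform(*config.parent_high_vaf_range))
            if rng.random() < 0.5:
                v_mo, v_fa, origin = v_parent, err, "maternal"
            else:
                v_mo, v_fa, origin = err, v_parent, "paternal"
        elif cls == "false_positive":
            v_prob, v_mo, v_fa = err, err, err
        elif cls == "constitutive_inherited":
            v_prob = 0.5
            if rng.random() < 0.5:
                v_mo, v_fa, origin = 0.5, err, "maternal"
            else:
                v_mo, v_fa, origin = err, 0.5, "paternal"
        else:  # pragma: no cover
            raise InvalidInputError(f"unknown class {cls}")

        observations: list[PersonObservation] = []
        tissue_vafs = {Tissue.SALIVA: v_prob}
        if config.blood_tissue:
            div = config.saliva_blood_vaf_divergence
            tissue_vafs[Tissue.BLOOD] = (
                max(v_prob + float(rng.normal(0.0, div)), 0.0) if div > 0 else v_prob
            )
        for tissue, v in tissue_vafs.items():
            depth = _draw_depth(rng, config.mean_depth, config.min_depth)
            alt_n = int(rng.binomial(depth, min(v, 1.0)))
            gt = _genotype_from_truth(v_prob) if v_prob > 2 * err else Genotype.HOM_REF
            observations.append(
                PersonObservation(
                    person=Person.PROBAND,
                    tissue=tissue,
                    depths=AlleleDepths(ref_count=depth - alt_n, alt_count=alt_n),
                    genotype_call=gt,
                )
            )
        for person, v in ((Person.MOTHER, v_mo), (Person.FATHER, v_fa)):
            depth = _draw_depth(rng, config.mean_depth, config.min_depth)
            alt_n = int(rng.binomial(depth, min(v, 1.0)))
            if cls == "parent_mosaic_high" and v > 2 * err:
                gt = Genotype.HET  # called in the parent by construction
            elif cls == "constitutive_inherited" and v == 0.5:
                gt = Genotype.HET
            else:
                gt = Genotype.HOM_REF
            observations.append(
                PersonObservation(
                    person=person,
                    tissue=Tissue.SALIVA,
                    depths=AlleleDepths(ref_count=depth - alt_n, alt_count=alt_n),
                    genotype_call=gt,
                )
            )

        inherited_like = cls in ("parent_mosaic_high", "constitutive_inherited")
        site_id = f"site{i:06d}"
        rec = TrioSiteRecord(
            chrom=chrom,
            pos=pos,
            ref_allele=str(ref),
            alt_allele=str(alt),
            observations=observations,
            consequence=classify_consequence(cons_term),
            gene=f"GENE{int(rng.integers(0, 2000)):04d}",
            gene_class=gene_cls,
            inheritance_mode=inh,
            population_maf=float(rng.uniform(0, 5e-4)) if inherited_like else 0.0,
            proband_sex=sex,
            parent_affected=(False, False),
            affected_sibling_shares_variant=(
                inherited_like and rng.random() < 0.05
            ),
            known_pathogenic=(
                cls == "parent_mosaic_high" and rng.random() < 0.3
            ),
            call_quality_score=float(
                rng.normal(4.0, 2.0) if cls == "false_positive" else rng.normal(8.0, 1.0)
            ),
            site_id=site_id,
        )
        records.append(rec)
        truth_rows.append(
            {
                "site_id": site_id,
                "true_class": cls,
                "true_vaf_proband": v_prob,
                "true_vaf_mother": v_mo,
                "true_vaf_father": v_fa,
                "true_parental_origin": origin,
                "true_gene_class": gene_cls.value,
                "true_consequence": rec.consequence.value,
            }
        )

    return records, CohortTruth(table=pd.DataFrame(truth_rows))


def simulate_gmm_preset_vafs(
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """DNM VAF distribution with a planted mosaic mixture component.

    Emits ``n_candidate_dnms`` observed proband VAFs: a fraction
    ``gmm_mosaic_fraction`` of sites carry a true mosaic VAF drawn from
    Normal(gmm_mosaic_mean_vaf, gmm_mosaic_vaf_sd) truncated to
    [0.1, 0.39]; the rest are constitutive at 0.5.  Observed VAFs add
    binomial read sampling at Poisson(mean_depth) truncated depth — the
    input for mixture-model recovery of the planted mosaic fraction and
    mean.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_candidate_dnms
    is_mosaic = rng.random(n) < config.gmm_mosaic_fraction
    true_vaf = np.full(n, 0.5)
    n_mos = int(is_mosaic.sum())
    lo, hi = 0.1, 0.39
    draws = np.empty(0)
    while draws.size < n_mos:  # rejection-sampled truncated normal
        cand = rng.normal(config.gmm_mosaic_mean_vaf, config.gmm_mosaic_vaf_sd, size=2 * n_mos + 16)
        draws = np.concatenate([draws, cand[(cand >= lo) & (cand <= hi)]])
    true_vaf[is_mosaic] = draws[:n_mos]
    depths = np.maximum(rng.poisson(config.mean_depth, size=n), config.min_depth)
    alts = rng.binomial(depths, true_vaf)
    return alts / depths


def simulate_validation_counts(
    truth: CohortTruth,
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> dict[str, list[DeepSeqObservation]]:
    """Ultra-deep validation read counts per site, from the same truth.

    Depth per observation is Poisson(ultra_depth_median); alt counts are
    Binomial(depth, true VAF or error rate).  Proband saliva and blood
    share the true VAF; parents are saliva-only.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    out: dict[str, list[DeepSeqObservation]] = {}
    for row in truth.table.itertuples(index=False):
        obs: list[DeepSeqObservation] = []
        specs = [
            (Person.PROBAND, Tissue.SALIVA, row.true_vaf_proband),
            (Person.PROBAND, Tissue.BLOOD, row.true_vaf_proband),
            (Person.MOTHER, Tissue.SALIVA, row.true_vaf_mother),
            (Person.FATHER, Tissue.SALIVA, row.true_vaf_father),
        ]
        for person, tissue, v in specs:
            depth = max(int(rng.poisson(config.ultra_depth_median)), 1)
            alt = int(rng.binomial(depth, min(float(v), 1.0)))
            obs.append(
                DeepSeqObservation(
                    person=person,
                    tissue=tissue,
                    depths=AlleleDepths(ref_count=depth - alt, alt_count=alt),
                )
            )
        out[row.site_id] = obs
    return out


def simulate_read_pairs(
    truth: CohortTruth,
    n_pairs_per_site: int = 20,
    switch_error: float = 0.0,
    seed: int | None = None,
) -> dict[str, tuple[list[ReadPairObservation], InformativeSite]]:
    """Phased read-pair co-observations for sites with a parental origin.

    For each site whose truth carries a parental origin, the informative
    SNV's ALT allele is placed on the origin haplotype.  Each read pair
    samples a haplotype (origin/other, 50:50); pairs on the origin
    haplotype carry the DNM ALT with probability 2 x true VAF (the
    within-haplotype mutant fraction), so a mosaic site shows the
    three-haplotype pattern while a constitutive one shows two.
    ``switch_error`` flips the informative allele independently per pair.
    """
    rng = np.random.default_rng(seed if seed is not None else 0)
    out: dict[str, tuple[list[ReadPairObservation], InformativeSite]] = {}
    for row in truth.table.itertuples(index=False):
        if row.true_parental_origin not in ("maternal", "paternal"):
            continue
        origin_parent = (
            Person.MOTHER if row.true_parental_origin == "maternal" else Person.FATHER
        )
        if row.true_class == "child_mosaic":
            within_hap_rate = min(2.0 * float(row.true_vaf_proband), 1.0)
        elif row.true_vaf_proband >= 0.5:
            within_hap_rate = 1.0  # constitutive carrier: whole haplotype mutant
        else:
            continue
        pairs: list[ReadPairObservation] = []
        for _ in range(n_pairs_per_site):
            on_origin = rng.random() < 0.5
            info_allele = Allele.ALT if on_origin else Allele.REF
            if switch_error > 0 and rng.random() < switch_error:
                info_allele = Allele.REF if info_allele is Allele.ALT else Allele.ALT
            dnm_allele = (
                Allele.ALT
                if (on_origin and rng.random() < within_hap_rate)
                else Allele.REF
            )
            pairs.append(
                ReadPairObservation(dnm_allele=dnm_allele, informative_allele=info_allele)
            )
        out[row.site_id] = (
            pairs,
            InformativeSite(parent_of_origin_of_alt=origin_parent),
        )
    return out
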