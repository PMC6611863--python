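"""Readers, writers and the end-to-end pipeline runner.

The canonical interchange format is a UTF-8 TSV with one row per
person x tissue observation of a site ('.' for missing, no quoting).
A multi-sample VCF with per-sample AD/GT plus a FAM-style pedigree
sidecar is supported read-only as a convenience.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

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
)
from triomosaic.errors import InvalidInputError, SchemaError
from triomosaic.screens import ScreenConfig, screen_child_pzm, screen_parent_highlevel, screen_parent_lowlevel
from triomosaic.simulate import SimulationConfig, simulate_trio_cohort
from triomosaic.stats import fit_vaf_mixture
from triomosaic.enrichment import bin_dnms
from triomosaic.validation import classify_validation

logger = logging.getLogger(__name__)

__all__ = [
    "SITE_TABLE_COLUMNS",
    "ReadReport",
    "write_site_table",
    "read_site_table",
    "read_vcf_trio",
    "candidates_to_frame",
    "PipelineConfig",
    "run_pipeline",
]

SITE_TABLE_COLUMNS = [
    "site_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "person",
    "tissue",
    "ref_count",
    "alt_count",
    "genotype",
    "consequence",
    "gene",
    "gene_class",
    "inheritance_mode",
    "maf",
    "proband_sex",
    "parent_affected_mother",
    "parent_affected_father",
    "sib_shares",
    "known_pathogenic",
    "quality",
]

_MISSING = "."


@dataclass
class ReadReport:
    """Malformed rows are collected here, never silently dropped."""

    n_records: int = 0
    errors: list[str] = field(default_factory=list)


def write_site_table(records: list[TrioSiteRecord], path: str | Path) -> None:
    """Write records to the canonical one-row-per-observation TSV."""
    rows = []
    for rec in records:
        for obs in rec.observations:
            rows.append(
                {
                    "site_id": rec.site_id,
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref_allele,
                    "alt": rec.alt_allele,
                    "person": obs.person.value,
                    "tissue": obs.tissue.value,
                    "ref_count": obs.depths.ref_count,
                    "alt_count": obs.depths.alt_count,
                    "genotype": obs.genotype_call.value,
                    "consequence": rec.consequence.value,
                    "gene": rec.gene,
                    "gene_class": rec.gene_class.value,
                    "inheritance_mode": rec.inheritance_mode.value,
                    "maf": rec.population_maf,
                    "proband_sex": rec.proband_sex.value,
                    "parent_affected_mother": int(rec.parent_affected[0]),
                    "parent_affected_father": int(rec.parent_affected[1]),
                    "sib_shares": int(rec.affected_sibling_shares_variant),
                    "known_pathogenic": int(rec.known_pathogenic),
                    "quality": rec.call_quality_score,
                }
            )
    pd.DataFrame(rows, columns=SITE_TABLE_COLUMNS).to_csv(
        path, sep="\t", index=False, na_rep=_MISSING
    )


def read_site_table(path: str | Path) -> tuple[list[TrioSiteRecord], ReadReport]:
    """Read the canonical TSV back into validated records.

    Rows violating invariants (e.g. negative counts) are reported in the
    :class:`ReadReport`, and the enclosing site is skipped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=[_MISSING], keep_default_na=False)
    missing = [c for c in SITE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"site table missing mandatory column(s): {missing}")

    report = ReadReport()
    records: list[TrioSiteRecord] = []
    for site_id, group in df.groupby("site_id", sort=False):
        try:
            first = group.iloc[0]
            observations = []
            for _, row in group.iterrows():
                observations.append(
                    PersonObservation(
                        person=Person(row["person"]),
                        tissue=Tissue(row["tissue"]),
                        depths=AlleleDepths(
                            ref_count=int(row["ref_count"]),
                            alt_count=int(row["alt_count"]),
                        ),
                        genotype_call=Genotype(row["genotype"]),
                    )
                )
            records.append(
                TrioSiteRecord(
                    chrom=str(first["chrom"]),
                    pos=int(first["pos"]),
                    ref_allele=str(first["ref"]),
                    alt_allele=str(first["alt"]),
                    observations=observations,
                    consequence=Consequence(first["consequence"]),
                    gene=str(first["gene"]),
                    gene_class=GeneClass(first["gene_class"]),
                    inheritance_mode=InheritanceMode(first["inheritance_mode"]),
                    population_maf=float(first["maf"]),
                    proband_sex=Sex(first["proband_sex"]),
                    parent_affected=(
                        bool(int(first["parent_affected_mother"])),
                        bool(int(first["parent_affected_father"])),
                    ),
                    affected_sibling_shares_variant=bool(int(first["sib_shares"])),
                    known_pathogenic=bool(int(first["known_pathogenic"])),
                    call_quality_score=float(first["quality"]),
                    site_id=str(site_id),
                )
            )
        except (ValueError, InvalidInputError) as exc:
            report.errors.append(f"site {site_id}: {exc}")
    report.n_records = len(records)
    return records, report


# -- VCF + pedigree ------------------------------------------------------------


def _read_pedigree(path: str | Path) -> dict[str, dict]:
    """FAM-style pedigree: family, individual, father, mother, sex, affected."""
    roles: dict[str, dict] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise SchemaError("pedigree rows need 6 columns (FAM format)")
            rows.append(parts[:6])
    for fam, iid, father, mother, sex, affected in rows:
        roles[iid] = {
            "family": fam,
            "father": father,
            "mother": mother,
            "sex": Sex.M if sex == "1" else Sex.F,
            "affected": affected == "2",
        }
    return roles


def read_vcf_trio(
    vcf_path: str | Path,
    pedigree_path: str | Path,
    default_gene_class: GeneClass = GeneClass.NOT_DDG2P,
) -> tuple[list[TrioSiteRecord], ReadReport]:
    """Read a multi-sample VCF with AD/GT format fields and a pedigree.

    Per-record annotation (consequence/gene/MAF) is read from the INFO
    keys CSQ_CLASS, GENE and MAF when present.  The proband is the
    pedigree individual whose father and mother are both in the VCF.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    roles = _read_pedigree(pedigree_path)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    proband = next(
        (
            iid
            for iid, info in roles.items()
            if iid in samples and info["father"] in samples and info["mother"] in samples
        ),
        None,
    )
    if proband is None:
        raise SchemaError("pedigree does not define a trio over the VCF samples")
    father, mother = roles[proband]["father"], roles[proband]["mother"]
    idx = {iid: samples.index(iid) for iid in (proband, mother, father)}
    person_of = {proband: Person.PROBAND, mother: Person.MOTHER, father: Person.FATHER}

    report = ReadReport()
    records: list[TrioSiteRecord] = []
    gt_map = {0: Genotype.HOM_REF, 1: Genotype.HET, 2: Genotype.HET, 3: Genotype.HOM_ALT}
    for var in vcf:
        ad = var.format("AD")
        if ad is None:
            raise SchemaError("VCF records must carry per-sample AD (allele depths)")
        try:
            observations = []
            for iid, person in person_of.items():
                j = idx[iid]
                ref_n, alt_n = int(ad[j][0]), int(ad[j][1])
                gt = gt_map.get(var.gt_types[j], Genotype.MISSING)
                observations.append(
                    PersonObservation(
                        person=person,
                        tissue=Tissue.SALIVA,
                        depths=AlleleDepths(ref_count=max(ref_n, 0), alt_count=max(alt_n, 0)),
                        genotype_call=gt,
                    )
                )
            info = dict(var.INFO) if var.INFO else {}
            records.append(
                TrioSiteRecord(
                    chrom=var.CHROM,
                    pos=var.POS,
                    ref_allele=var.REF,
                    alt_allele=var.ALT[0] if var.ALT else "N",
                    observations=observations,
                    consequence=Consequence(info.get("CSQ_CLASS", "other")),
                    gene=str(info.get("GENE", "")),
                    gene_class=GeneClass(info.get("GENE_CLASS", default_gene_class.value)),
                    inheritance_mode=InheritanceMode.AUTOSOMAL_DOMINANT,
                    population_maf=float(info.get("MAF", 0.0)),
                    proband_sex=roles[proband]["sex"],
                    parent_affected=(
                        roles[mother]["affected"] if mother in roles else False,
                        roles[father]["affected"] if father in roles else False,
                    ),
                    call_quality_score=float(var.QUAL or 0.0),
                )
            )
        except (ValueError, InvalidInputError) as exc:
            report.errors.append(f"{var.CHROM}:{var.POS}: {exc}")
    report.n_records = len(records)
    return records, report


def candidates_to_frame(candidates) -> pd.DataFrame:
    """Screen candidates as a flat output table."""
    rows = []
    for c in candidates:
        rows.append(
            {
                "site_id": c.record.site_id,
                "screen": c.screen.value,
                "arm": c.arm.value,
                "strategy": ",".join(s.value for s in c.strategies),
                "person": c.mosaic_parent.value if c.mosaic_parent else "proband",
                "vaf": c.stats.vaf if c.stats else np.nan,
                "p_value": c.stats.p_value if c.stats else np.nan,
                "q_value": c.q_value,
                "predicted_mosaic": int(c.predicted_mosaic),
                "mosaic_parent": c.mosaic_parent.value if c.mosaic_parent else _MISSING,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "site_id",
            "screen",
            "arm",
            "strategy",
            "person",
            "vaf",
            "p_value",
            "q_value",
            "predicted_mosaic",
            "mosaic_parent",
        ],
    )


@dataclass
class PipelineConfig:
    """End-to-end run configuration; the seed is recorded in the manifest."""

    screen: ScreenConfig = field(default_factory=ScreenConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    out_dir: str | Path = "triomosaic_run"
    seed: int = 0
    run_screens: bool = True
    run_mixture: bool = True
    run_enrichment: bool = True


def run_pipeline(config: PipelineConfig) -> dict:
    """simulate -> screens -> mixture/enrichment, with a run manifest.

    Writes per-stage TSV/JSON artefacts under ``out_dir`` and returns
    the manifest (stage input/output counts, config hash, seed).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_text = json.dumps(
        {
            "screen": asdict(config.screen),
            "simulation": asdict(config.simulation),
            "seed": config.seed,
        },
        default=str,
        sort_keys=True,
    )
    manifest: dict = {
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "stages": {},
    }

    records, truth = simulate_trio_cohort(config.simulation, seed=config.seed)
    write_site_table(records, out / "sites.tsv")
    truth.table.to_csv(out / "truth.tsv", sep="\t", index=False)
    manifest["stages"]["simulate"] = {"n_sites": len(records)}
    logger.info("simulate: %d sites", len(records))

    if config.run_screens:
        child = screen_child_pzm(records, config.screen)
        low = screen_parent_lowlevel(records, config.screen)
        high = screen_parent_highlevel(records, config.screen)
        candidates_to_frame(child + low + high).to_csv(
            out / "candidates.tsv", sep="\t", index=False
        )
        manifest["stages"]["screens"] = {
            "child_pzm": len(child),
            "parent_low": len(low),
            "parent_high": len(high),
        }
        logger.info(
            "screens: child=%d parent_low=%d parent_high=%d",
            len(child), len(low), len(high),
        )
    else:
        manifest["stages"]["screens"] = "skipped"

    if config.run_mixture:
        vafs = [
            rec.proband_observation().depths.vaf
            for rec in records
            if rec.proband_observation() is not None
            and rec.proband_observation().depths.depth > 0
        ]
        fit = fit_vaf_mixture(vafs, vaf_floor=config.screen.child_vaf_floor)
        (out / "mixture.json").write_text(json.dumps(fit.summary(), indent=2))
        manifest["stages"]["mixture"] = {
            "mosaic_fraction": fit.mosaic_fraction,
            "converged": fit.converged,
        }
    else:
        manifest["stages"]["mixture"] = "skipped"

    if config.run_enrichment:
        dnm_classes = {"constitutive_dnm", "child_mosaic", "false_positive"}
        truth_by_id = dict(zip(truth.table["site_id"], truth.table["true_class"]))
        dnms = [r for r in records if truth_by_id.get(r.site_id) in dnm_classes]
        table = bin_dnms(dnms)
        rows = [
            {
                "lower": r.bin.lower,
                "upper": r.bin.upper,
                "mean_vaf": r.bin.mean_vaf,
                "gene_class": r.gene_class,
                "functional": r.counts.functional,
                "lof": r.counts.lof,
                "synonymous": r.counts.synonymous,
                "damaging_ratio": r.damaging_ratio,
            }
            for r in table.rows
        ]
        pd.DataFrame(rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        manifest["stages"]["enrichment"] = {"n_bins": len(table.stratum("all"))}
    else:
        manifest["stages"]["enrichment"] = "skipped"

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
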