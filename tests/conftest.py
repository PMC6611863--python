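import pytest

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


def make_record(
    proband_alt=25,
    proband_depth=50,
    mother_alt=0,
    mother_depth=50,
    father_alt=0,
    father_depth=50,
    chrom="1",
    consequence=Consequence.FUNCTIONAL,
    gene_class=GeneClass.DDG2P_DOMINANT,
    inheritance_mode=InheritanceMode.AUTOSOMAL_DOMINANT,
    proband_sex=Sex.F,
    maf=0.0,
    proband_genotype=Genotype.HET,
    mother_genotype=Genotype.HOM_REF,
    father_genotype=Genotype.HOM_REF,
    site_id="",
    **kwargs,
):
    """One trio site with the given read counts; defaults are a clean
    constitutive het DNM in a dominant DDG2P gene."""
    obs = [
        PersonObservation(
            person=Person.PROBAND,
            tissue=Tissue.SALIVA,
            depths=AlleleDepths(proband_depth - proband_alt, proband_alt),
            genotype_call=proband_genotype,
        ),
        PersonObservation(
            person=Person.MOTHER,
            tissue=Tissue.SALIVA,
            depths=AlleleDepths(mother_depth - mother_alt, mother_alt),
            genotype_call=mother_genotype,
        ),
        PersonObservation(
            person=Person.FATHER,
            tissue=Tissue.SALIVA,
            depths=AlleleDepths(father_depth - father_alt, father_alt),
            genotype_call=father_genotype,
        ),
    ]
    return TrioSiteRecord(
        chrom=chrom,
        pos=kwargs.pop("pos", 1000),
        ref_allele="A",
        alt_allele="G",
        observations=obs,
        consequence=consequence,
        gene=kwargs.pop("gene", "GENE1"),
        gene_class=gene_class,
        inheritance_mode=inheritance_mode,
        population_maf=maf,
        proband_sex=proband_sex,
        site_id=site_id,
        **kwargs,
    )


@pytest.fixture
def record_factory():
    return make_record
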