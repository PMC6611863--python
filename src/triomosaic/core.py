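"""Domain types for trio variant data.

One variant site in one family is a :class:`TrioSiteRecord`: per-person
(and, for the proband, per-tissue) allele depths together with the
consequence / gene-class annotation the screens condition on.  The
consequence taxonomy groups annotation terms into loss-of-function
(protein-truncating), functional (protein-altering) and synonymous
classes; gene classes distinguish curated dominant developmental-disorder
genes (DDG2P) — and the monoallelic/LOF-mechanism subset — from all
other genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from triomosaic.errors import InvalidInputError, UndefinedVAFError

__all__ = [
    "Person",
    "Tissue",
    "Genotype",
    "Consequence",
    "GeneClass",
    "InheritanceMode",
    "Sex",
    "AlleleDepths",
    "PersonObservation",
    "TrioSiteRecord",
    "classify_consequence",
    "is_dominant_candidate_context",
]


class Person(str, Enum):
    PROBAND = "proband"
    MOTHER = "mother"
    FATHER = "father"


class Tissue(str, Enum):
    SALIVA = "saliva"
    BLOOD = "blood"


class Genotype(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


class Consequence(str, Enum):
    """Variant consequence class.

    LOF covers protein-truncating terms (splice donor/acceptor, stop
    gained, frameshift, initiator codon); FUNCTIONAL covers
    protein-altering terms (missense, in-frame indels); SYNONYMOUS is
    protein-preserving.  Everything else is OTHER.
    """

    LOF = "lof"
    FUNCTIONAL = "functional"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class GeneClass(str, Enum):
    NOT_DDG2P = "not_ddg2p"
    DDG2P_DOMINANT = "ddg2p_dominant"
    DDG2P_MONOALLELIC_LOF = "ddg2p_monoallelic_lof"

    @property
    def is_ddg2p_dominant(self) -> bool:
        # the monoallelic/LOF-mechanism set is a subset of dominant DDG2P
        return self is not GeneClass.NOT_DDG2P


class InheritanceMode(str, Enum):
    AUTOSOMAL_DOMINANT = "autosomal_dominant"
    X_LINKED_DOMINANT = "x_linked_dominant"
    OTHER = "other"


class Sex(str, Enum):
    M = "M"
    F = "F"


# Consequence term dialects: Sequence-Ontology underscore terms and the
# equivalent prose forms are both accepted, case-insensitively.
_LOF_TERMS = {
    "splice_donor_variant",
    "splice_donor",
    "splice_acceptor_variant",
    "splice_acceptor",
    "stop_gained",
    "frameshift_variant",
    "frameshift",
    "initiator_codon_variant",
    "initiator_codon",
    "start_lost",  # renamed from initiator_codon_variant in later SO releases
}
_FUNCTIONAL_TERMS = {
    "missense_variant",
    "missense",
    "inframe_deletion",
    "in_frame_deletion",
    "inframe_insertion",
    "in_frame_insertion",
}
_SYNONYMOUS_TERMS = {
    "synonymous_variant",
    "synonymous",
}


def classify_consequence(term: str) -> Consequence:
    """Map an annotation consequence term to its class.

    Accepts both underscore- and space-separated dialects,
    case-insensitively.  Unrecognised terms map to
    :attr:`Consequence.OTHER`; an empty term is an error.
    """
    if not isinstance(term, str) or not term.strip():
        raise InvalidInputError("consequence term must be a non-empty string")
    key = term.strip().lower().replace(" ", "_")
    if key in _LOF_TERMS:
        return Consequence.LOF
    if key in _FUNCTIONAL_TERMS:
        return Consequence.FUNCTIONAL
    if key in _SYNONYMOUS_TERMS:
        return Consequence.SYNONYMOUS
    return Consequence.OTHER


@dataclass(frozen=True)
class AlleleDepths:
    """Reference and alternative read counts at one site for one sample."""

    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise InvalidInputError("read counts must be non-negative")

    @property
    def depth(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def vaf(self) -> float:
        """Alternative reads over total depth; undefined at depth 0."""
        if self.depth == 0:
            raise UndefinedVAFError("VAF undefined at zero depth")
        return self.alt_count / self.depth


@dataclass(frozen=True)
class PersonObservation:
    """One sequencing observation of one trio member in one tissue.

    Parents are saliva-only: blood DNA is available for probands only.
    """

    person: Person
    tissue: Tissue
    depths: AlleleDepths
    genotype_call: Genotype = Genotype.MISSING

    def __post_init__(self) -> None:
        if self.person is not Person.PROBAND and self.tissue is not Tissue.SALIVA:
            raise InvalidInputError(
                f"{self.person.value} observations must be saliva (parents are saliva-only)"
            )


_SEX_CHROMS = {"X": "X", "CHRX": "X", "Y": "Y", "CHRY": "Y"}


def normalise_chrom(chrom: str) -> str:
    """Strip a 'chr' prefix and upper-case sex chromosomes."""
    c = chrom.strip()
    return _SEX_CHROMS.get(c.upper(), c[3:] if c.lower().startswith("chr") else c)


@dataclass
class TrioSiteRecord:
    """One candidate variant site in one trio.

    The atom every screen consumes: biallelic site coordinates, per-person
    allele depths, the consequence and gene-class annotation, and the
    family metadata the selection strategies condition on.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    observations: list[PersonObservation]
    consequence: Consequence
    gene: str
    gene_class: GeneClass
    inheritance_mode: InheritanceMode
    population_maf: float
    proband_sex: Sex
    parent_affected: tuple[bool, bool] = (False, False)  # (mother, father)
    affected_sibling_shares_variant: bool = False
    known_pathogenic: bool = False
    call_quality_score: float = 0.0
    site_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InvalidInputError("pos is 1-based and must be >= 1")
        if not self.ref_allele or not self.alt_allele:
            raise InvalidInputError("alleles must be non-empty")
        if not 0.0 <= self.population_maf <= 1.0:
            raise InvalidInputError("population_maf must lie in [0, 1]")
        seen: set[tuple[Person, Tissue]] = set()
        for obs in self.observations:
            key = (obs.person, obs.tissue)
            if key in seen:
                raise InvalidInputError(
                    f"duplicate observation for {obs.person.value}/{obs.tissue.value}"
                )
            seen.add(key)
        if not self.site_id:
            self.site_id = f"{self.chrom}:{self.pos}:{self.ref_allele}:{self.alt_allele}"

    # -- observation accessors -------------------------------------------------

    def observation(self, person: Person, tissue: Tissue | None = None) -> PersonObservation | None:
        """Return the observation for *person* (preferring *tissue* if given)."""
        matches = [o for o in self.observations if o.person is person]
        if not matches:
            return None
        if tissue is not None:
            for o in matches:
                if o.tissue is tissue:
                    return o
            return None
        return matches[0]

    def proband_observation(self, prefer: Tissue = Tissue.SALIVA) -> PersonObservation | None:
        """Proband observation, preferring *prefer* but falling back to any tissue."""
        obs = self.observation(Person.PROBAND, prefer)
        if obs is None:
            obs = self.observation(Person.PROBAND)
        return obs

    @property
    def is_sex_chromosome(self) -> bool:
        return normalise_chrom(self.chrom) in ("X", "Y")


def is_dominant_candidate_context(record: TrioSiteRecord) -> bool:
    """Whether a record sits in the dominant diagnostic context.

    True iff the gene is dominant DDG2P and the variant could act as a
    dominant diploid allele in this proband: autosomal-dominant genes on
    autosomes always qualify; X-linked-dominant genes qualify only in
    female probands (X sites are hemizygous in males); Y never qualifies.
    """
    if not record.gene_class.is_ddg2p_dominant:
        return False
    chrom = normalise_chrom(record.chrom)
    if chrom == "Y":
        return False
    if chrom == "X" and record.proband_sex is not Sex.F:
        return False
    if record.inheritance_mode is InheritanceMode.AUTOSOMAL_DOMINANT:
        return True
    if record.inheritance_mode is InheritanceMode.X_LINKED_DOMINANT:
        return record.proband_sex is Sex.F
    return False
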