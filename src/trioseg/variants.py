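"""Core data model for case-parent trio exome analysis.

A *trio* is an affected child plus both unaffected parents. Every variant
site is held as a biallelic :class:`TrioVariantRecord` (multi-allelic sites
are split upstream) carrying per-sample genotype evidence (GT/AD/DP/GQ/PL),
transcript-level functional annotations and population/in-silico scores.

Coordinates are 1-based VCF positions throughout; no internal conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Tuple

# Closed consequence vocabulary, ordered most- to least-severe. Unknown
# annotation terms collapse to "other"; ranking decides which annotation
# represents a multi-transcript variant.
CONSEQUENCES: Tuple[str, ...] = (
    "stop_gained",
    "frameshift",
    "splice_site",
    "start_lost",
    "stop_lost",
    "missense",
    "inframe_insertion",
    "inframe_deletion",
    "synonymous",
    "other",
)

_SEVERITY = {c: i for i, c in enumerate(CONSEQUENCES)}

# Sequence-Ontology-style terms (SnpEff ANN / VEP CSQ) -> vocabulary above.
SO_TERM_MAP = {
    "missense_variant": "missense",
    "stop_gained": "stop_gained",
    "nonsense": "stop_gained",
    "frameshift_variant": "frameshift",
    "inframe_insertion": "inframe_insertion",
    "conservative_inframe_insertion": "inframe_insertion",
    "disruptive_inframe_insertion": "inframe_insertion",
    "inframe_deletion": "inframe_deletion",
    "conservative_inframe_deletion": "inframe_deletion",
    "disruptive_inframe_deletion": "inframe_deletion",
    "splice_acceptor_variant": "splice_site",
    "splice_donor_variant": "splice_site",
    "splice_region_variant": "splice_site",
    "start_lost": "start_lost",
    "initiator_codon_variant": "start_lost",
    "stop_lost": "stop_lost",
    "synonymous_variant": "synonymous",
    "stop_retained_variant": "synonymous",
}


def severity_rank(consequence: str) -> int:
    """Rank of a consequence; lower is more severe."""
    return _SEVERITY.get(consequence, _SEVERITY["other"])


def map_so_term(term: str) -> str:
    """Map a (possibly '&'-joined) SO-style effect string into the vocabulary.

    Multi-effect entries keep the most severe mapped term; anything
    unrecognised becomes ``other``.
    """
    best = "other"
    for part in term.split("&"):
        mapped = SO_TERM_MAP.get(part.strip(), "other")
        if severity_rank(mapped) < severity_rank(best):
            best = mapped
    return best


@dataclass(frozen=True)
class PedigreeTrio:
    """One affected child and its two parents, as declared in a PED file."""

    family_id: str
    child_id: str
    father_id: str
    mother_id: str
    child_affected: bool = True
    child_sex: str = "unknown"  # {male, female, unknown}

    def __post_init__(self) -> None:
        ids = {self.child_id, self.father_id, self.mother_id}
        if len(ids) != 3:
            raise ValueError(
                f"trio {self.family_id}: child/father/mother ids must be distinct"
            )

    @property
    def sample_ids(self) -> Tuple[str, str, str]:
        return (self.child_id, self.father_id, self.mother_id)


@dataclass(frozen=True)
class SampleGenotype:
    """Genotype evidence for one sample at one biallelic site.

    ``alleles`` is an ordered pair of allele indices (0=ref, 1=alt) or
    ``None`` for a missing call. ``pl`` is the phred-scaled genotype
    likelihood triple (ref/ref, ref/alt, alt/alt), normalised so
    ``min(pl) == 0`` when present.
    """

    alleles: Optional[Tuple[int, int]]
    ad_ref: int = 0
    ad_alt: int = 0
    depth: int = 0
    gq: Optional[float] = None
    pl: Optional[Tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        if self.ad_ref < 0 or self.ad_alt < 0 or self.depth < 0:
            raise ValueError("read counts must be non-negative")
        if self.ad_ref > self.depth or self.ad_alt > self.depth:
            raise ValueError("allele depth cannot exceed total depth")

    @property
    def is_missing(self) -> bool:
        return self.alleles is None

    @property
    def dosage(self) -> Optional[int]:
        """Alternate-allele count (0, 1, 2) or None for a missing call."""
        if self.alleles is None:
            return None
        return int(self.alleles[0] != 0) + int(self.alleles[1] != 0)

    @property
    def is_het(self) -> bool:
        return self.dosage == 1

    @property
    def is_hom_ref(self) -> bool:
        return self.dosage == 0

    @property
    def is_hom_alt(self) -> bool:
        return self.dosage == 2


@dataclass(frozen=True)
class TranscriptAnnotation:
    """Functional annotation of a variant on one transcript."""

    gene_symbol: str
    transcript_id: str = ""
    consequence: str = "other"
    hgvs_c: str = ""
    hgvs_p: str = ""

    def __post_init__(self) -> None:
        if self.consequence not in _SEVERITY:
            raise ValueError(f"unknown consequence {self.consequence!r}")


@dataclass(frozen=True)
class VariantScores:
    """Population frequency and in-silico deleteriousness scores.

    Raw SIFT/PolyPhen-2 lie in [0,1]; CADD is phred-scaled (>=0); the
    ``*_rank`` fields are dbNSFP-style percentile rank scores in [0,1];
    ``maf`` is an ExAC-style minor allele frequency. Any field may be
    missing (None).
    """

    sift: Optional[float] = None
    polyphen: Optional[float] = None
    cadd_phred: Optional[float] = None
    sift_rank: Optional[float] = None
    polyphen_rank: Optional[float] = None
    cadd_rank: Optional[float] = None
    maf: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("sift", "polyphen", "sift_rank", "polyphen_rank",
                     "cadd_rank", "maf"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError("cadd_phred must be >= 0")


EMPTY_SCORES = VariantScores()


@dataclass
class TrioVariantRecord:
    """One biallelic VCF site with genotype evidence for pipeline samples.

    ``genotypes`` maps sample id -> :class:`SampleGenotype` and covers at
    least the three members of every trio under analysis (calls may be
    missing, samples may not).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float = 0.0
    genotypes: Mapping[str, SampleGenotype] = field(default_factory=dict)
    annotations: Sequence[TranscriptAnnotation] = field(default_factory=list)
    scores: VariantScores = EMPTY_SCORES

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    def genotype(self, sample_id: str) -> Optional[SampleGenotype]:
        return self.genotypes.get(sample_id)


def most_severe_annotation(
    annotations: Iterable[TranscriptAnnotation],
) -> Optional[TranscriptAnnotation]:
    """The most severe annotation; ties broken by gene symbol, then transcript."""
    anns = list(annotations)
    if not anns:
        return None
    return min(
        anns,
        key=lambda a: (severity_rank(a.consequence), a.gene_symbol, a.transcript_id),
    )
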