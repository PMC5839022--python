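"""Per-trio inheritance classification and compound-heterozygote detection.

Each filtered biallelic variant is assigned exactly one inheritance class
per trio from the genotype triple (child, father, mother):

==================  =======================================================
de_novo             child het, both parents hom-ref
recessive_hom       child hom-alt, both parents het carriers
het_paternal        child het, only the father carries the alternate
het_maternal        child het, only the mother carries the alternate
het_biparental      child het, both parents carry (phase unresolvable)
mendelian_error     triple impossible under mu=0 Mendelian transmission
                    (other than the de novo configuration above)
inherited_other     any remaining Mendelian-consistent configuration
uncalled            any member's genotype missing
==================  =======================================================

Compound heterozygotes are phased by transmission only: a (trio, gene)
pair with at least one het_paternal and one het_maternal variant yields
one :class:`CompHetPair`; biparental hets are excluded from pairing.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .filters import (
    DeNovoPrior,
    FilterThresholds,
    member_passes,
    passes_genotype_filters,
    trio_genotype_posterior,
)
from .variants import (
    PedigreeTrio,
    SampleGenotype,
    TrioVariantRecord,
    most_severe_annotation,
)

logger = logging.getLogger("trioseg")

SEG_CLASSES = (
    "de_novo",
    "recessive_hom",
    "het_paternal",
    "het_maternal",
    "het_biparental",
    "inherited_other",
    "mendelian_error",
    "uncalled",
)


@dataclass(frozen=True)
class SegregationCall:
    """Inheritance class of one variant within one trio."""

    trio_id: str
    key: str  # chrom:pos:ref:alt
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: Optional[str]
    consequence: Optional[str]
    seg_class: str
    child_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.seg_class not in SEG_CLASSES:
            raise ValueError(f"unknown segregation class {self.seg_class!r}")


@dataclass(frozen=True)
class CompHetPair:
    """Transmission-phased compound heterozygote in one gene and trio."""

    trio_id: str
    gene_symbol: str
    paternal_variants: Tuple[str, ...]
    maternal_variants: Tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.paternal_variants or not self.maternal_variants:
            raise ValueError("both paternal and maternal sides must be non-empty")
        if set(self.paternal_variants) & set(self.maternal_variants):
            raise ValueError("paternal and maternal variant sets must be disjoint")

    @property
    def variant_keys(self) -> Tuple[str, ...]:
        return self.paternal_variants + self.maternal_variants


def _dosage(g) -> Optional[int]:
    if g is None:
        return None
    if isinstance(g, SampleGenotype):
        return g.dosage
    return int(g)


def mendelian_consistent(child: int, father: int, mother: int) -> bool:
    """True when the child triple is reachable without mutation.

    The child genotype must be composable from one allele of each parent
    (dosages 0/1/2 on a biallelic site).
    """
    alleles = {0: (0,), 1: (0, 1), 2: (1,)}
    return any(a + b == child for a in alleles[father] for b in alleles[mother])


def classify_trio_genotype(child, father, mother) -> str:
    """Inheritance class from the (child, father, mother) genotypes.

    Accepts :class:`SampleGenotype` objects or plain dosages (0/1/2,
    None = missing). Total: every triple maps to exactly one class.
    """
    c, f, m = _dosage(child), _dosage(father), _dosage(mother)
    if c is None or f is None or m is None:
        return "uncalled"
    if c == 1 and f == 0 and m == 0:
        return "de_novo"
    if not mendelian_consistent(c, f, m):
        return "mendelian_error"
    if c == 1:
        if f > 0 and m == 0:
            return "het_paternal"
        if m > 0 and f == 0:
            return "het_maternal"
        return "het_biparental"  # both parents carry; phase unresolvable
    if c == 2 and f == 1 and m == 1:
        return "recessive_hom"
    return "inherited_other"


@dataclass
class SegregationSummary:
    """Per-trio class counts plus consequence tallies."""

    class_counts: Dict[str, Counter] = field(default_factory=dict)
    n_records: int = 0

    def total(self, seg_class: str) -> int:
        return sum(c.get(seg_class, 0) for c in self.class_counts.values())


def _call_gene_consequence(record: TrioVariantRecord):
    ann = most_severe_annotation(record.annotations)
    if ann is None:
        return None, None
    return ann.gene_symbol, ann.consequence


def segregate_all(
    records: Iterable[TrioVariantRecord],
    trios: Sequence[PedigreeTrio],
    thresholds: FilterThresholds = FilterThresholds(),
    prior: DeNovoPrior = DeNovoPrior(),
    use_posterior: bool = True,
    ab_on_parents: bool = True,
    denovo_requires_parent_ref_reads: bool = False,
) -> Tuple[List[SegregationCall], SegregationSummary]:
    """Filter and classify every record for every trio.

    For each (record, trio): the hard filters are evaluated first; when
    all three members carry PLs and ``use_posterior`` is set, the child's
    genotype and GQ are then reassigned from the pedigree-informed
    posterior and the reassigned GQ (and allele balance, if the
    reassigned call is het) is re-checked against the thresholds.
    Records failing the filters for a trio produce no call for that trio.

    ``denovo_requires_parent_ref_reads`` additionally demotes a de novo
    call to inherited_other when either parent shows any alternate reads.
    """
    calls: List[SegregationCall] = []
    summary = SegregationSummary(
        class_counts={t.family_id: Counter() for t in trios}
    )
    posterior_fallbacks = 0
    for record in records:
        summary.n_records += 1
        gene, consequence = _call_gene_consequence(record)
        for trio in trios:
            child = record.genotype(trio.child_id)
            father = record.genotype(trio.father_id)
            mother = record.genotype(trio.mother_id)
            if child is None or father is None or mother is None:
                continue

            decision = passes_genotype_filters(
                record, trio, thresholds, ab_on_parents=ab_on_parents
            )
            if not decision.record_pass:
                continue

            child_eff = child
            if use_posterior:
                post = trio_genotype_posterior(record, trio, prior)
                if post is None:
                    posterior_fallbacks += 1
                else:
                    child_eff = SampleGenotype(
                        alleles=post.reassigned_child_gt,
                        ad_ref=child.ad_ref,
                        ad_alt=child.ad_alt,
                        depth=child.depth,
                        gq=post.reassigned_child_gq,
                        pl=child.pl,
                    )
                    if not member_passes(child_eff, thresholds, apply_ab=True):
                        continue

            seg_class = classify_trio_genotype(child_eff, father, mother)
            if (
                seg_class == "de_novo"
                and denovo_requires_parent_ref_reads
                and (father.ad_alt > 0 or mother.ad_alt > 0)
            ):
                seg_class = "inherited_other"

            calls.append(
                SegregationCall(
                    trio_id=trio.family_id,
                    key=record.key,
                    chrom=record.chrom,
                    pos=record.pos,
                    ref=record.ref,
                    alt=record.alt,
                    gene=gene,
                    consequence=consequence,
                    seg_class=seg_class,
                    child_id=trio.child_id,
                )
            )
            summary.class_counts[trio.family_id][seg_class] += 1
    if posterior_fallbacks:
        logger.info(
            "%d record/trio pairs lacked complete PLs; hard-filter path used",
            posterior_fallbacks,
        )
    return calls, summary


def find_compound_hets(calls: Iterable[SegregationCall]) -> List[CompHetPair]:
    """Pair transmission-phased hets per (trio, gene).

    Emits one :class:`CompHetPair` for every (trio, gene) holding at
    least one het_paternal and one het_maternal call. Variants without a
    gene assignment and biparental hets never pair. Output is sorted by
    (trio, gene); variant lists by (chrom, pos).
    """
    sides: Dict[Tuple[str, str], Dict[str, List[SegregationCall]]] = defaultdict(
        lambda: {"het_paternal": [], "het_maternal": []}
    )
    for call in calls:
        if call.seg_class in ("het_paternal", "het_maternal") and call.gene:
            sides[(call.trio_id, call.gene)][call.seg_class].append(call)

    pairs: List[CompHetPair] = []
    for (trio_id, gene) in sorted(sides):
        group = sides[(trio_id, gene)]
        pat, mat = group["het_paternal"], group["het_maternal"]
        if pat and mat:
            order = lambda c: (c.chrom, c.pos, c.ref, c.alt)
            pairs.append(
                CompHetPair(
                    trio_id=trio_id,
                    gene_symbol=gene,
                    paternal_variants=tuple(c.key for c in sorted(pat, key=order)),
                    maternal_variants=tuple(c.key for c in sorted(mat, key=order)),
                )
            )
    return pairs
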