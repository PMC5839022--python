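"""Cross-family recurrence of recessive and compound-heterozygous variants.

Per-trio segregation calls are intersected across families into three
categories:

* **A** — the *same* variant (chrom,pos,ref,alt) homozygous-recessive in
  at least two trios;
* **B** — genes hit by homozygous-recessive variants in at least two
  trios but at different intragenic positions (genes already qualifying
  through category A are excluded);
* **C** — genes with transmission-phased compound-heterozygote pairs in
  at least two trios (may overlap B, since the underlying variants
  differ).

A separate single-trio view restricts homozygous-recessive calls private
to one family to rare alleles (MAF below a threshold; a missing MAF
counts as rare by default).
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple, Union

from .segregation import CompHetPair, SegregationCall
from .variants import VariantScores

logger = logging.getLogger("trioseg")


def _pos_key(key: str) -> Tuple[str, int]:
    chrom, pos, _ref, _alt = key.split(":")
    return (chrom, int(pos))


@dataclass(frozen=True)
class SharedVariant:
    """Category-A entry: one variant recessive in several trios."""

    key: str
    gene: Optional[str]
    trios: Tuple[str, ...]


@dataclass(frozen=True)
class GeneRecurrence:
    """Category-B/C entry: one gene with per-trio variant lists."""

    gene: str
    trios: Tuple[str, ...]
    variants: Tuple[Tuple[str, str], ...]  # (trio_id, variant key)

    @property
    def variant_keys(self) -> Tuple[str, ...]:
        return tuple(dict.fromkeys(k for _t, k in self.variants))


@dataclass
class RecurrenceReport:
    category_a: List[SharedVariant] = field(default_factory=list)
    category_b: List[GeneRecurrence] = field(default_factory=list)
    category_c: List[GeneRecurrence] = field(default_factory=list)
    totals: Dict[str, int] = field(default_factory=dict)

    def compute_totals(self) -> None:
        a_vars = len(self.category_a)
        b_vars = sum(len(g.variant_keys) for g in self.category_b)
        c_vars = sum(len(g.variant_keys) for g in self.category_c)
        self.totals = {
            "A_variants": a_vars,
            "A_genes": len({v.gene for v in self.category_a if v.gene}),
            "B_genes": len(self.category_b),
            "B_variants": b_vars,
            "C_genes": len(self.category_c),
            "C_variants": c_vars,
            "total_variants": a_vars + b_vars + c_vars,
        }


def cross_trio_recurrence(
    per_trio_calls: Iterable[SegregationCall],
    comp_het_pairs: Iterable[CompHetPair] = (),
) -> RecurrenceReport:
    """Intersect segregation calls across trios into categories A/B/C.

    Ordering is deterministic: genes alphabetically, variants by
    (chrom, pos). With fewer than two trios present the report is empty
    (warned).
    """
    calls = list(per_trio_calls)
    pairs = list(comp_het_pairs)
    report = RecurrenceReport()
    trios_seen = sorted({c.trio_id for c in calls} | {p.trio_id for p in pairs})
    if len(trios_seen) < 2:
        logger.warning("recurrence needs >= 2 trios; report is empty")
        report.compute_totals()
        return report

    recessive = [c for c in calls if c.seg_class == "recessive_hom"]

    # Category A: identical variant recessive in >= 2 trios.
    by_key: Dict[str, List[SegregationCall]] = defaultdict(list)
    for c in recessive:
        by_key[c.key].append(c)
    a_genes: set = set()
    for key in sorted(by_key, key=_pos_key):
        group = by_key[key]
        trios = tuple(sorted({c.trio_id for c in group}))
        if len(trios) >= 2:
            gene = group[0].gene
            report.category_a.append(SharedVariant(key=key, gene=gene, trios=trios))
            if gene:
                a_genes.add(gene)

    # Category B: gene recessive in >= 2 trios at non-identical positions.
    by_gene: Dict[str, List[SegregationCall]] = defaultdict(list)
    for c in recessive:
        if c.gene:
            by_gene[c.gene].append(c)
    for gene in sorted(by_gene):
        if gene in a_genes:
            continue
        group = by_gene[gene]
        trios = tuple(sorted({c.trio_id for c in group}))
        if len(trios) < 2:
            continue
        variants = tuple(
            (c.trio_id, c.key)
            for c in sorted(group, key=lambda c: (c.chrom, c.pos, c.trio_id))
        )
        report.category_b.append(
            GeneRecurrence(gene=gene, trios=trios, variants=variants)
        )

    # Category C: compound-het gene in >= 2 trios.
    pairs_by_gene: Dict[str, List[CompHetPair]] = defaultdict(list)
    for p in pairs:
        pairs_by_gene[p.gene_symbol].append(p)
    for gene in sorted(pairs_by_gene):
        group = pairs_by_gene[gene]
        trios = tuple(sorted({p.trio_id for p in group}))
        if len(trios) < 2:
            continue
        variants = tuple(
            (p.trio_id, key)
            for p in sorted(group, key=lambda p: p.trio_id)
            for key in sorted(p.variant_keys, key=_pos_key)
        )
        report.category_c.append(
            GeneRecurrence(gene=gene, trios=trios, variants=variants)
        )

    report.compute_totals()
    return report


ScoreLike = Union[VariantScores, float, None]


def _maf_of(score: ScoreLike) -> Optional[float]:
    if score is None:
        return None
    if isinstance(score, VariantScores):
        return score.maf
    return float(score)


def single_trio_rare_recessive(
    per_trio_calls: Iterable[SegregationCall],
    scores: Mapping[str, ScoreLike],
    maf_threshold: float = 0.01,
    missing_is_rare: bool = True,
) -> List[SegregationCall]:
    """Rare recessive calls private to a single trio.

    Keeps homozygous-recessive calls whose variant occurs in exactly one
    trio and whose MAF is below ``maf_threshold`` (strict); a missing MAF
    is treated as rare when ``missing_is_rare``.
    """
    recessive = [c for c in per_trio_calls if c.seg_class == "recessive_hom"]
    trios_per_key: Dict[str, set] = defaultdict(set)
    for c in recessive:
        trios_per_key[c.key].add(c.trio_id)

    kept: List[SegregationCall] = []
    for c in recessive:
        if len(trios_per_key[c.key]) != 1:
            continue
        maf = _maf_of(scores.get(c.key))
        if maf is None:
            if missing_is_rare:
                kept.append(c)
        elif maf < maf_threshold:
            kept.append(c)
    kept.sort(key=lambda c: (c.chrom, c.pos, c.trio_id))
    return kept
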