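"""Variant prioritization, consequence tallies, rank tests and ORA.

Pathogenicity flagging follows the common in-silico conventions: SIFT at
or below 0.05 ("deleterious"), PolyPhen-2 at or above 0.446 (the
"possibly damaging" lower bound), or any loss-of-function consequence.
Score-distribution comparisons use the Wilcoxon/Mann-Whitney rank-sum
test (exact for small untied samples, tie-corrected normal approximation
otherwise) and gene-set over-representation uses the upper hypergeometric
tail with Benjamini-Hochberg FDR across sets.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats as sps

from .segregation import SegregationCall
from .variants import VariantScores

LOF_CONSEQUENCES = frozenset(
    {"stop_gained", "frameshift", "splice_site", "start_lost", "stop_lost"}
)


@dataclass(frozen=True)
class PathogenicityRule:
    sift_max: float = 0.05
    polyphen_min: float = 0.446
    lof_consequences: frozenset = LOF_CONSEQUENCES

    def __post_init__(self) -> None:
        if not (0.0 <= self.sift_max <= 1.0 and 0.0 <= self.polyphen_min <= 1.0):
            raise ValueError("thresholds must lie in [0, 1]")


DEFAULT_RULE = PathogenicityRule()


def pathogenicity_flag(
    scores: Optional[VariantScores],
    consequences: Iterable[str] = (),
    rule: PathogenicityRule = DEFAULT_RULE,
) -> Tuple[bool, Tuple[str, ...]]:
    """Flag a variant as putatively pathogenic in silico.

    True when SIFT <= sift_max, PolyPhen >= polyphen_min, or any
    consequence is loss-of-function; the returned reasons list the
    triggering criteria. With no usable inputs the flag is False with
    reason ``unscored``.
    """
    reasons: List[str] = []
    cons = list(consequences)
    sift = scores.sift if scores else None
    polyphen = scores.polyphen if scores else None
    if sift is None and polyphen is None and not cons:
        return False, ("unscored",)
    if sift is not None and sift <= rule.sift_max:
        reasons.append(f"sift<={rule.sift_max:g}")
    if polyphen is not None and polyphen >= rule.polyphen_min:
        reasons.append(f"polyphen>={rule.polyphen_min:g}")
    lof = sorted(set(cons) & rule.lof_consequences)
    if lof:
        reasons.append("lof:" + ",".join(lof))
    return bool(reasons), tuple(reasons)


def consequence_tally(calls: Iterable[SegregationCall]) -> Dict[str, int]:
    """Count calls by most-severe consequence; includes a ``total`` key.

    Each variant call counts exactly once (under the consequence already
    attached to it by segregation); the total equals the number of calls.
    """
    counter: Counter = Counter()
    total = 0
    for c in calls:
        counter[c.consequence or "other"] += 1
        total += 1
    out = dict(sorted(counter.items()))
    out["total"] = total
    return out


@dataclass(frozen=True)
class RankTestResult:
    u_statistic: float
    z_value: float
    p_two_sided: float
    method: str  # {"exact", "normal"}


def rank_sum_test(
    scores_prioritized: Sequence[float],
    scores_other: Sequence[float],
) -> RankTestResult:
    """Two-sided Wilcoxon/Mann-Whitney test between two score groups.

    U is computed with midranks for ties. The p-value is exact (full
    enumeration) when both groups have at most 12 observations and there
    are no ties; otherwise the tie-corrected normal approximation with
    continuity correction is used. The reported z is always the
    tie-corrected normal deviate of U.
    """
    a = np.asarray(scores_prioritized, dtype=float)
    b = np.asarray(scores_other, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    u1 = float(sps.mannwhitneyu(a, b, alternative="two-sided",
                                method="asymptotic").statistic)
    z = _tie_corrected_z(u1, n1, n2, tie_counts)

    if n1 <= 12 and n2 <= 12 and not has_ties:
        p = float(sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method="exact").pvalue)
        method = "exact"
    else:
        p = min(2.0 * sps.norm.sf(abs(z)), 1.0)
        method = "normal"
    return RankTestResult(u_statistic=u1, z_value=z, p_two_sided=p, method=method)


def _tie_corrected_z(u: float, n1: int, n2: int, tie_counts: np.ndarray) -> float:
    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0
    cc = 0.5 * np.sign(u - mu)  # continuity correction toward the null
    return float((u - mu - cc) / np.sqrt(var))


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap_count: int
    set_size: int
    query_size: int
    universe_size: int
    p_hypergeometric: float
    fdr_bh: float = field(default=1.0, compare=False)


def ora_enrichment(
    query_genes: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe_genes: Iterable[str],
) -> List[EnrichmentResult]:
    """Hypergeometric over-representation of query genes in gene sets.

    For each set S (intersected with the universe first):
    p = P(X >= |S ∩ query|) with X hypergeometric(population=|universe|,
    successes=|S|, draws=|query|). Benjamini-Hochberg FDR is applied
    across all tested sets; results are sorted by p then name.
    """
    universe: Set[str] = set(universe_genes)
    query: Set[str] = set(query_genes)
    if not query or not universe:
        raise ValueError("query and universe must be non-empty")
    if not query <= universe:
        extra = sorted(query - universe)[:5]
        raise ValueError(f"query genes outside universe, e.g. {extra}")

    results: List[EnrichmentResult] = []
    pvals: List[float] = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe
        overlap = len(members & query)
        p = float(sps.hypergeom.sf(overlap - 1, len(universe), len(members),
                                   len(query)))
        p = min(p, 1.0)
        results.append(
            EnrichmentResult(
                set_name=name,
                overlap_count=overlap,
                set_size=len(members),
                query_size=len(query),
                universe_size=len(universe),
                p_hypergeometric=p,
            )
        )
        pvals.append(p)

    if results:
        fdr = sps.false_discovery_control(np.asarray(pvals), method="bh")
        results = [
            EnrichmentResult(
                set_name=r.set_name,
                overlap_count=r.overlap_count,
                set_size=r.set_size,
                query_size=r.query_size,
                universe_size=r.universe_size,
                p_hypergeometric=r.p_hypergeometric,
                fdr_bh=float(min(q, 1.0)),
            )
            for r, q in zip(results, fdr)
        ]
    results.sort(key=lambda r: (r.p_hypergeometric, r.set_name))
    return results


def rank_score_groups(
    prioritized_keys: Iterable[str],
    calls: Iterable[SegregationCall],
    scores: Mapping[str, VariantScores],
    score: str = "sift",
    per_gene_mean: bool = False,
) -> Tuple[List[float], List[float]]:
    """Build the two score groups for the rank-sum comparison.

    Prioritized variants are compared against the *other* variants lying
    in the same genes. dbNSFP-style rank scores are used when present,
    raw scores otherwise. ``per_gene_mean`` averages scores per gene
    before testing instead of testing per-variant values.
    """
    prioritized = set(prioritized_keys)
    rank_field = f"{score}_rank"

    def value(key: str) -> Optional[float]:
        s = scores.get(key)
        if s is None:
            return None
        v = getattr(s, rank_field, None)
        if v is None:
            v = getattr(s, score, None)
        return v

    genes = {c.gene for c in calls if c.key in prioritized and c.gene}
    group_a: Dict[str, List[float]] = {}
    group_b: Dict[str, List[float]] = {}
    seen = set()
    for c in calls:
        if not c.gene or c.gene not in genes or c.key in seen:
            continue
        seen.add(c.key)
        v = value(c.key)
        if v is None:
            continue
        (group_a if c.key in prioritized else group_b).setdefault(
            c.gene, []
        ).append(v)

    def flatten(groups: Dict[str, List[float]]) -> List[float]:
        if per_gene_mean:
            return [float(np.mean(vs)) for _g, vs in sorted(groups.items())]
        return [v for _g, vs in sorted(groups.items()) for v in vs]

    return flatten(group_a), flatten(group_b)
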