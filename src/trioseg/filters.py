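"""Genotype-level filters and pedigree-informed genotype posteriors.

Two layers run before segregation:

1. *Hard filters* — genotype quality strictly greater than ``gq_min``
   (default 20) for every trio member, and for heterozygous calls an
   allele balance (alternate-read fraction) within ``[ab_min, ab_max]``
   (default [0.35, 0.65], bounds inclusive). Homozygous calls are
   AB-exempt; a missing GQ fails conservatively.

2. *Posterior reassignment* — when PL triples are available for all
   three members, the joint posterior over the 27 (child, father,
   mother) genotype triples is computed from the PL likelihoods, a
   Hardy-Weinberg prior on the parents, and a Mendelian transmission
   model in which each transmitted allele mutates independently with
   probability ``mu``. The child's genotype is reassigned to the
   posterior-marginal argmax and its GQ to the phred of the residual
   probability, then re-checked against ``gq_min``. Without PLs only
   the hard filters apply; likelihoods are never fabricated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .variants import PedigreeTrio, SampleGenotype, TrioVariantRecord

GENOTYPES: Tuple[Tuple[int, int], ...] = ((0, 0), (0, 1), (1, 1))


@dataclass(frozen=True)
class FilterThresholds:
    """genoFilter-style genotype-level thresholds."""

    ab_min: float = 0.35
    ab_max: float = 0.65
    gq_min: float = 20.0   # strict: a member passes only with GQ > gq_min
    min_depth: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ab_min <= 0.5 <= self.ab_max <= 1.0):
            raise ValueError("require 0 <= ab_min <= 0.5 <= ab_max <= 1")
        if self.gq_min < 0 or self.min_depth < 0:
            raise ValueError("gq_min and min_depth must be >= 0")


@dataclass(frozen=True)
class DeNovoPrior:
    """Per-allele de novo mutation probability used in transmission."""

    mu: float = 1e-6

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu <= 1e-3):
            raise ValueError("mu must lie in [0, 1e-3]")


@dataclass
class TrioGenotypePosterior:
    """Joint genotype posterior for one trio at one site.

    ``joint[c, f, m]`` indexes child, father, mother genotypes in the
    order hom-ref, het, hom-alt; it sums to 1. ``child_marginal`` is the
    exact child marginal, ``reassigned_child_gt`` its argmax and
    ``reassigned_child_gq`` the phred of (1 - max marginal), capped at 99.
    """

    joint: np.ndarray
    child_marginal: np.ndarray = field(init=False)
    reassigned_child_gt: Tuple[int, int] = field(init=False)
    reassigned_child_gq: float = field(init=False)

    def __post_init__(self) -> None:
        total = float(self.joint.sum())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError("joint posterior must sum to 1")
        self.child_marginal = self.joint.sum(axis=(1, 2))
        best = int(np.argmax(self.child_marginal))
        self.reassigned_child_gt = GENOTYPES[best]
        residual = max(1.0 - float(self.child_marginal[best]), 0.0)
        if residual <= 0.0:
            self.reassigned_child_gq = 99.0
        else:
            self.reassigned_child_gq = min(-10.0 * np.log10(residual), 99.0)


def allele_balance(genotype: SampleGenotype) -> Optional[float]:
    """Alternate-read fraction of a heterozygous call, or None.

    Defined only for heterozygous calls with at least one informative
    read at the two alleles; homozygous or missing calls return None.
    """
    if not genotype.is_het:
        return None
    total = genotype.ad_ref + genotype.ad_alt
    if total <= 0:
        return None
    return genotype.ad_alt / total


def member_passes(
    genotype: Optional[SampleGenotype],
    thresholds: FilterThresholds,
    apply_ab: bool = True,
) -> bool:
    """Hard-filter decision for one member's genotype."""
    if genotype is None or genotype.is_missing:
        return False
    if genotype.gq is None or genotype.gq <= thresholds.gq_min:
        return False
    if genotype.depth < thresholds.min_depth:
        return False
    if apply_ab and genotype.is_het:
        ab = allele_balance(genotype)
        if ab is None or not (thresholds.ab_min <= ab <= thresholds.ab_max):
            return False
    return True


@dataclass(frozen=True)
class FilterDecision:
    member_pass: Dict[str, bool]
    record_pass: bool


def passes_genotype_filters(
    record: TrioVariantRecord,
    trio: PedigreeTrio,
    thresholds: FilterThresholds = FilterThresholds(),
    ab_on_parents: bool = True,
) -> FilterDecision:
    """Evaluate the hard filters for all three trio members.

    The record passes only when child, father and mother all pass. The
    allele-balance window always applies to the child's heterozygous
    calls; ``ab_on_parents`` extends it to the parents (default on).
    """
    flags: Dict[str, bool] = {}
    for sid in trio.sample_ids:
        apply_ab = ab_on_parents or sid == trio.child_id
        flags[sid] = member_passes(record.genotype(sid), thresholds, apply_ab)
    return FilterDecision(member_pass=flags, record_pass=all(flags.values()))


def transmission_table(mu: float) -> np.ndarray:
    """T[f, m, c]: probability of child genotype c given parents (f, m).

    Each parent transmits one of its two alleles uniformly at random and
    the transmitted allele mutates (flips) independently with probability
    ``mu``. With ``mu = 0`` this is exact Mendelian transmission.
    """
    p_alt = np.array([mu, 0.5, 1.0 - mu])  # P(transmit alt | parent genotype)
    T = np.empty((3, 3, 3))
    for f in range(3):
        for m in range(3):
            pf, pm = p_alt[f], p_alt[m]
            T[f, m, 0] = (1 - pf) * (1 - pm)
            T[f, m, 1] = pf * (1 - pm) + (1 - pf) * pm
            T[f, m, 2] = pf * pm
    return T


def hwe_prior(q: float) -> np.ndarray:
    """Hardy-Weinberg genotype prior at alternate-allele frequency q."""
    if not (0.0 < q < 1.0):
        raise ValueError("allele frequency must lie strictly in (0, 1)")
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])


def likelihoods_from_pl(pl: Sequence[float]) -> np.ndarray:
    l = np.power(10.0, -np.asarray(pl, dtype=float) / 10.0)
    return l / l.sum()


def genotype_posterior_from_pls(
    pl_child: Sequence[float],
    pl_father: Sequence[float],
    pl_mother: Sequence[float],
    mu: float = 1e-6,
    pop_alt_freq: float = 0.01,
) -> TrioGenotypePosterior:
    """Joint trio genotype posterior from phred-scaled likelihood triples.

    joint(c,f,m) ∝ L_c(c) L_f(f) L_m(m) T(c|f,m; mu) H(f) H(m) with H the
    HWE prior at ``pop_alt_freq`` and T the mutation-aware transmission
    probability; normalised over the 27 triples.
    """
    Lc = likelihoods_from_pl(pl_child)
    Lf = likelihoods_from_pl(pl_father)
    Lm = likelihoods_from_pl(pl_mother)
    H = hwe_prior(pop_alt_freq)
    T = transmission_table(mu)  # [f, m, c]
    joint = (
        Lc[None, None, :] * Lf[:, None, None] * Lm[None, :, None]
        * T * H[:, None, None] * H[None, :, None]
    )
    # reorder to [c, f, m]
    joint = np.transpose(joint, (2, 0, 1))
    total = joint.sum()
    if total <= 0:
        raise ValueError("degenerate posterior: zero total mass")
    return TrioGenotypePosterior(joint=joint / total)


def trio_genotype_posterior(
    record: TrioVariantRecord,
    trio: PedigreeTrio,
    prior: DeNovoPrior = DeNovoPrior(),
    pop_alt_freq: Optional[float] = None,
) -> Optional[TrioGenotypePosterior]:
    """Posterior for one record/trio, or None when any PL is missing.

    The parental HWE prior uses the variant's MAF when annotated,
    otherwise ``pop_alt_freq`` (default 0.01). Records without complete
    PLs fall back to the hard-filter-only path (a note is logged by the
    segregation driver).
    """
    pls = [record.genotype(s).pl if record.genotype(s) else None
           for s in trio.sample_ids]
    if any(p is None for p in pls):
        return None
    q = pop_alt_freq
    if q is None:
        q = record.scores.maf if record.scores.maf is not None else 0.01
    q = min(max(q, 1e-6), 1.0 - 1e-6)
    return genotype_posterior_from_pls(pls[0], pls[1], pls[2], prior.mu, q)
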