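"""Synthetic trio exome data with known ground truth.

Generates annotated multi-trio VCFs with the statistical structure the
downstream analysis assumes: parental genotypes drawn at Hardy-Weinberg
equilibrium from a Beta-distributed site frequency spectrum, children by
Mendelian transmission, injected de novo / homozygous-recessive /
compound-heterozygote events in chosen genes, binomial allele-depth
noise at exome-scale coverage and PL/GQ derived from the binomial read
likelihoods. Every run is reproducible from its seed and ships a truth
table for recovery tests.

Also simulates genotypes along a marker panel under the two-state
autozygosity HMM (known inbreeding coefficient f and IBD tracts) for
the inbreeding estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .inbreeding import HET, HOM_ALT, HOM_REF, MarkerPanel
from .segregation import classify_trio_genotype
from .variants import VariantScores

# VCF consequence terms emitted for each vocabulary entry.
_SO_OUT = {
    "missense": "missense_variant",
    "stop_gained": "stop_gained",
    "frameshift": "frameshift_variant",
    "inframe_insertion": "inframe_insertion",
    "inframe_deletion": "inframe_deletion",
    "splice_site": "splice_donor_variant",
    "start_lost": "start_lost",
    "stop_lost": "stop_lost",
    "synonymous": "synonymous_variant",
    "other": "intergenic_region",
}

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class SimConfig:
    """Study-condition defaults for the trio simulator.

    ``mean_depth`` of 100 reflects exome coverage on the order of the
    per-variant depths the analysis targets; the alternate-allele
    frequency spectrum is Beta(0.5, 5) truncated to (0.001, 0.5).
    Injected genes are reserved for injections (background variants get
    their own gene universe) so truth labels stay unambiguous.
    """

    n_trios: int = 3
    n_variants: int = 1000
    n_denovo: int = 2
    recessive_genes: Mapping[str, Sequence[str]] = field(default_factory=dict)
    recessive_consequences: Optional[Mapping[str, Sequence[str]]] = None
    comphet_genes: Mapping[str, Sequence[str]] = field(default_factory=dict)
    shared_recessive: Sequence[Tuple[str, Tuple[str, ...]]] = ()
    alt_freq_beta: Tuple[float, float] = (0.5, 5.0)
    alt_freq_bounds: Tuple[float, float] = (0.001, 0.5)
    mean_depth: int = 100
    base_error: float = 0.001
    allele_depth_noise: bool = True
    background_mode: str = "hwe"  # or "single_carrier" (decoys only)
    seed: int = 0

    def trio_ids(self) -> List[str]:
        return [f"T{i + 1}" for i in range(self.n_trios)]


@dataclass
class TruthTable:
    """Ground truth of a simulated dataset.

    ``classes`` maps (trio_id, variant key) to the true segregation
    class; compound-het membership is recorded for variants whose phase
    is resolvable by transmission (exactly one carrier parent), the
    definition the pipeline itself uses.
    """

    classes: Dict[Tuple[str, str], str] = field(default_factory=dict)
    comp_het_genes: Dict[str, set] = field(default_factory=dict)  # trio -> genes
    child_f: Dict[str, float] = field(default_factory=dict)

    def of_class(self, seg_class: str) -> set:
        return {tk for tk, c in self.classes.items() if c == seg_class}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"trio": t, "key": k, "true_class": c}
            for (t, k), c in sorted(self.classes.items())
        ]
        return pd.DataFrame(rows, columns=["trio", "key", "true_class"])


@dataclass
class SimulatedDataset:
    vcf: Path
    ped: Path
    scores: Path
    truth_path: Path
    truth: TruthTable
    trio_ids: List[str]
    n_sites: int


@dataclass
class _Site:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    freq: Optional[float]           # None -> MAF missing in the score table
    genotypes: Dict[str, int]       # sample -> dosage
    scores: VariantScores = VariantScores()
    qual: Optional[float] = None    # overrides the derived site quality
    depth: Optional[int] = None     # overrides mean_depth for this site


def _sample_ids(trio_ids: Sequence[str]) -> List[str]:
    out = []
    for t in trio_ids:
        out += [f"{t}c", f"{t}p", f"{t}m"]
    return out


def _transmit(rng: np.random.Generator, father: int, mother: int) -> int:
    pf = (rng.random() < father / 2.0) if father in (1,) else father // 2
    pm = (rng.random() < mother / 2.0) if mother in (1,) else mother // 2
    return int(pf) + int(pm)


def _genotype_field(
    dosage: int,
    rng: np.random.Generator,
    mean_depth: int,
    base_error: float,
    noise: bool,
) -> str:
    """GT:AD:DP:GQ:PL string for one sample from its true genotype."""
    p_alt = (base_error, 0.5, 1.0 - base_error)[dosage]
    if noise:
        depth = max(int(rng.poisson(mean_depth)), 10)
        ad_alt = int(rng.binomial(depth, p_alt))
    else:
        depth = int(mean_depth)
        ad_alt = {0: 0, 1: depth // 2, 2: depth}[dosage]
    ad_ref = depth - ad_alt
    # binomial read likelihoods per candidate genotype
    lls = []
    for g in range(3):
        p = (base_error, 0.5, 1.0 - base_error)[g]
        lls.append(ad_alt * math.log10(p) + ad_ref * math.log10(1.0 - p))
    pls = [min(round(-10.0 * (ll - max(lls))), 9999) for ll in lls]
    sorted_pl = sorted(pls)
    gq = min(sorted_pl[1] - sorted_pl[0], 99)
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}[dosage]
    return f"{gt}:{ad_ref},{ad_alt}:{depth}:{gq}:{pls[0]},{pls[1]},{pls[2]}"


def write_vcf(sites: Sequence[_Site], samples: Sequence[str], path,
              rng: np.random.Generator, mean_depth: int, base_error: float,
              noise: bool) -> None:
    """Write sites as a plain-text VCF 4.2 with GT/AD/DP/GQ/PL and ANN."""
    chroms = list(dict.fromkeys(s.chrom for s in sites))
    lines = ["##fileformat=VCFv4.2", "##source=trioseg-simulator"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines += [
        '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: '
        "'Allele|Annotation|Annotation_Impact|Gene_Name|Gene_ID|Feature_Type|"
        "Feature_ID|Transcript_BioType|Rank|HGVS.c|HGVS.p'\">",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred likelihoods">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    for s in sites:
        ann = (
            f"{s.alt}|{_SO_OUT[s.consequence]}|MODERATE|{s.gene}|{s.gene}|"
            f"transcript|{s.gene}.t1|protein_coding|1/1|c.1A>G|p.X1Y"
        )
        site_depth = s.depth if s.depth is not None else mean_depth
        fields = [
            _genotype_field(s.genotypes.get(sid, 0), rng, site_depth,
                            base_error, noise)
            for sid in samples
        ]
        qual = f"{s.qual:g}" if s.qual is not None else f"{1000 + (s.pos % 9000)}"
        lines.append(
            f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t{qual}\tPASS\t"
            f"ANN={ann}\tGT:AD:DP:GQ:PL\t" + "\t".join(fields)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_ped(trio_ids: Sequence[str], path) -> None:
    lines = []
    for t in trio_ids:
        lines.append(f"{t}\t{t}c\t{t}p\t{t}m\t2\t2")
        lines.append(f"{t}\t{t}p\t0\t0\t1\t1")
        lines.append(f"{t}\t{t}m\t0\t0\t2\t1")
    Path(path).write_text("\n".join(lines) + "\n")


def _truncated_beta(rng, a, b, lo, hi):
    while True:
        x = rng.beta(a, b)
        if lo <= x <= hi:
            return x


def _draw_hwe(rng, q: float) -> int:
    u = rng.random()
    p0 = (1 - q) ** 2
    p1 = p0 + 2 * q * (1 - q)
    return 0 if u < p0 else (1 if u < p1 else 2)


def simulate_trio_dataset(config: SimConfig, outdir) -> SimulatedDataset:
    """Generate a multi-trio VCF + score table + pedigree + truth table.

    Background sites: parents at HWE (or a single het carrier in
    ``single_carrier`` decoy mode), children by Mendelian transmission;
    injected sites override the affected trio's genotypes (other trios
    keep background behaviour, except de novo sites which stay hom-ref
    elsewhere and carry no population MAF). Truth classes are derived
    from the true genotypes, so chance events (e.g. a background variant
    that happens to be recessive in some trio) are labelled truthfully.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    trio_ids = config.trio_ids()
    samples = _sample_ids(trio_ids)

    sites: List[_Site] = []
    injected_genes: List[Tuple[str, str, Optional[str], object]] = []
    # (kind, gene, consequence, payload)
    for t in trio_ids:
        for i in range(config.n_denovo):
            injected_genes.append(("denovo", f"DNV_{t}_{i + 1}", "missense", t))
        rec = list(config.recessive_genes.get(t, ()))
        cons = None
        if config.recessive_consequences:
            cons = list(config.recessive_consequences.get(t, ()))
        for i, gene in enumerate(rec):
            c = cons[i] if cons and i < len(cons) else "missense"
            injected_genes.append(("recessive", gene, c, (t,)))
        for gene in config.comphet_genes.get(t, ()):
            injected_genes.append(("comphet", gene, "missense", t))
    for gene, trios in config.shared_recessive:
        injected_genes.append(("recessive", gene, "missense", tuple(trios)))

    n_background_genes = max(config.n_variants // 4, 1)
    background_genes = [f"BG{i + 1:05d}" for i in range(n_background_genes)]

    # lay sites down chromosome by chromosome with deterministic spacing
    pos_counter = {c: 10_000 for c in range(1, 23)}

    def next_pos(i: int) -> Tuple[str, int]:
        c = (i % 22) + 1
        pos_counter[c] += int(rng.integers(200, 5000))
        return f"chr{c}", pos_counter[c]

    site_index = 0

    def base_pair(rng) -> Tuple[str, str]:
        ref = _BASES[rng.integers(0, 4)]
        alt = _BASES[(rng.integers(1, 4) + _BASES.index(ref)) % 4]
        return ref, alt

    # background sites
    for _ in range(config.n_variants):
        chrom, pos = next_pos(site_index)
        site_index += 1
        ref, alt = base_pair(rng)
        q = _truncated_beta(rng, *config.alt_freq_beta, *config.alt_freq_bounds)
        gene = background_genes[int(rng.integers(0, n_background_genes))]
        consequence = "missense" if rng.random() < 0.85 else "synonymous"
        genotypes: Dict[str, int] = {}
        for t in trio_ids:
            if config.background_mode == "single_carrier":
                father = int(rng.random() < 0.5)
                mother = father ^ 1 if father else int(rng.random() < 0.5)
                father, mother = (father, 0) if father else (0, mother)
            else:
                father = _draw_hwe(rng, q)
                mother = _draw_hwe(rng, q)
            child = _transmit(rng, father, mother)
            genotypes[f"{t}c"] = child
            genotypes[f"{t}p"] = father
            genotypes[f"{t}m"] = mother
        sites.append(
            _Site(chrom, pos, ref, alt, gene, consequence, q, genotypes,
                  _random_scores(rng, q))
        )

    # injected sites
    for kind, gene, consequence, payload in injected_genes:
        if kind == "comphet":
            specs = [("paternal",), ("maternal",)]
        else:
            specs = [(None,)]
        for (side,) in specs:
            chrom, pos = next_pos(site_index)
            site_index += 1
            ref, alt = base_pair(rng)
            q = _truncated_beta(rng, *config.alt_freq_beta,
                                *config.alt_freq_bounds)
            genotypes = {}
            target_trios = payload if isinstance(payload, tuple) else (payload,)
            for t in trio_ids:
                if kind == "denovo":
                    if t == payload:
                        genotypes[f"{t}c"], genotypes[f"{t}p"], genotypes[f"{t}m"] = 1, 0, 0
                    else:
                        genotypes[f"{t}c"] = genotypes[f"{t}p"] = genotypes[f"{t}m"] = 0
                elif kind == "recessive":
                    if t in target_trios:
                        genotypes[f"{t}c"], genotypes[f"{t}p"], genotypes[f"{t}m"] = 2, 1, 1
                    else:
                        genotypes[f"{t}c"] = genotypes[f"{t}p"] = genotypes[f"{t}m"] = 0
                else:  # comphet
                    if t == payload:
                        if side == "paternal":
                            genotypes[f"{t}c"], genotypes[f"{t}p"], genotypes[f"{t}m"] = 1, 1, 0
                        else:
                            genotypes[f"{t}c"], genotypes[f"{t}p"], genotypes[f"{t}m"] = 1, 0, 1
                    else:
                        genotypes[f"{t}c"] = genotypes[f"{t}p"] = genotypes[f"{t}m"] = 0
            freq = None if kind == "denovo" else q
            sites.append(
                _Site(chrom, pos, ref, alt, gene, consequence, freq, genotypes,
                      _random_scores(rng, freq))
            )

    sites.sort(key=lambda s: (int(s.chrom[3:]), s.pos))

    # ground truth from true genotypes
    truth = TruthTable()
    for s in sites:
        for t in trio_ids:
            c = classify_trio_genotype(
                s.genotypes[f"{t}c"], s.genotypes[f"{t}p"], s.genotypes[f"{t}m"]
            )
            collapsed = c if c in ("de_novo", "recessive_hom") else "inherited_other"
            truth.classes[(t, f"{s.chrom}:{s.pos}:{s.ref}:{s.alt}")] = collapsed
            if c in ("het_paternal", "het_maternal"):
                truth.comp_het_genes.setdefault(t, set())
    # phase-resolvable compound hets: both parental sides present in a gene
    sided: Dict[Tuple[str, str], set] = {}
    for s in sites:
        for t in trio_ids:
            c = classify_trio_genotype(
                s.genotypes[f"{t}c"], s.genotypes[f"{t}p"], s.genotypes[f"{t}m"]
            )
            if c in ("het_paternal", "het_maternal"):
                sided.setdefault((t, s.gene), set()).add(c)
    for (t, gene), kinds in sided.items():
        if {"het_paternal", "het_maternal"} <= kinds:
            truth.comp_het_genes.setdefault(t, set()).add(gene)
            for s in sites:
                if s.gene != gene:
                    continue
                c = classify_trio_genotype(
                    s.genotypes[f"{t}c"], s.genotypes[f"{t}p"],
                    s.genotypes[f"{t}m"],
                )
                if c in ("het_paternal", "het_maternal"):
                    truth.classes[(t, f"{s.chrom}:{s.pos}:{s.ref}:{s.alt}")] = \
                        "comp_het_member"

    vcf_path = outdir / "trios.vcf"
    ped_path = outdir / "trios.ped"
    scores_path = outdir / "scores.tsv"
    truth_path = outdir / "truth.tsv"
    write_vcf(sites, samples, vcf_path, rng, config.mean_depth,
              config.base_error, config.allele_depth_noise)
    write_ped(trio_ids, ped_path)
    _write_scores(sites, scores_path)
    truth.to_frame().to_csv(truth_path, sep="\t", index=False)
    return SimulatedDataset(
        vcf=vcf_path, ped=ped_path, scores=scores_path, truth_path=truth_path,
        truth=truth, trio_ids=trio_ids, n_sites=len(sites),
    )


def _random_scores(rng, freq: Optional[float]) -> VariantScores:
    return VariantScores(
        sift=round(float(rng.random()), 3),
        polyphen=round(float(rng.random()), 3),
        cadd_phred=round(float(rng.random() * 40), 2),
        sift_rank=round(float(rng.random()), 4),
        polyphen_rank=round(float(rng.random()), 4),
        cadd_rank=round(float(rng.random()), 4),
        maf=None if freq is None else round(float(freq), 5),
    )


def _write_scores(sites: Sequence[_Site], path) -> None:
    from .io import write_score_table

    write_score_table(
        {f"{s.chrom}:{s.pos}:{s.ref}:{s.alt}": s.scores for s in sites}, path
    )


# ---------------------------------------------------------------------------
# autozygosity simulation


def make_marker_panel(
    n_markers: int = 3900,
    n_chrom: int = 22,
    total_length_cm: float = 3500.0,
    q_range: Tuple[float, float] = (0.05, 0.5),
    seed: Optional[int] = None,
) -> MarkerPanel:
    """Synthetic genome-wide marker panel with an exponential genetic map.

    Markers are spread over ``n_chrom`` chromosomes totalling
    ``total_length_cm`` of genetic map (human-genome scale by default),
    with exponential inter-marker spacing and common alternate-allele
    frequencies drawn uniformly from ``q_range``.
    """
    rng = np.random.default_rng(seed)
    per_chrom = np.full(n_chrom, n_markers // n_chrom)
    per_chrom[: n_markers % n_chrom] += 1
    mean_spacing = total_length_cm / n_markers
    chroms, poss, qs, cms = [], [], [], []
    for c in range(n_chrom):
        n = int(per_chrom[c])
        gaps = rng.exponential(mean_spacing, size=n)
        cm = np.cumsum(gaps)
        chroms += [f"chr{c + 1}"] * n
        poss += list((cm * 1e4).astype(np.int64) + 1)
        qs += list(rng.uniform(*q_range, size=n))
        cms += list(cm)
    return MarkerPanel(chroms, poss, qs, cms)


def simulate_inbred_genotypes(
    panel: MarkerPanel,
    f: float,
    a: float,
    seed: Optional[int] = None,
    eps: float = 0.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Genotypes for one individual with autozygous (IBD) tracts.

    Hidden IBD states follow the two-state chain (stationary start
    (f, 1-f), chromosomes independent); genotypes come from the
    state-conditional emissions. Returns (genotype codes, IBD mask).
    """
    gt, ibd = simulate_inbred_genotypes_many(panel, f, a, 1, seed, eps)
    return gt[0], ibd[0]


def simulate_inbred_genotypes_many(
    panel: MarkerPanel,
    f: float,
    a: float,
    n: int,
    seed: Optional[int] = None,
    eps: float = 0.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorised replicate simulation: (n, markers) genotypes + IBD masks."""
    if not (0.0 <= f < 1.0) or a <= 0:
        raise ValueError("require 0 <= f < 1 and a > 0")
    rng = np.random.default_rng(seed)
    m = len(panel)
    ibd = np.zeros((n, m), dtype=bool)
    u_state = rng.random((n, m))
    state = u_state[:, 0] < f
    ibd[:, 0] = state
    for i in range(1, m):
        d = panel.d[i]
        r = math.exp(-a * d) if np.isfinite(d) else 0.0
        p_ibd = np.where(state, r + (1 - r) * f, (1 - r) * f)
        state = u_state[:, i] < p_ibd
        ibd[:, i] = state

    q = panel.q[None, :]
    u1 = rng.random((n, m))
    u2 = rng.random((n, m))
    hom_alt_ibd = u1 < q
    gt_ibd = np.where(hom_alt_ibd, HOM_ALT, HOM_REF)
    p0 = (1 - q) ** 2
    p1 = p0 + 2 * q * (1 - q)
    gt_out = np.where(u1 < p0, HOM_REF, np.where(u1 < p1, HET, HOM_ALT))
    gt = np.where(ibd, gt_ibd, gt_out)
    if eps > 0:
        flip = u2 < eps
        gt = np.where(flip & ibd, gt_out, gt)
    return gt.astype(np.int8), ibd
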