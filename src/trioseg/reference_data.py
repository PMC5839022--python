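"""Deterministic synthetic fixtures for the bundled T1-T3 reference study.

These builders emit small, fully synthetic multi-trio VCFs (plus score
tables, pedigree and a JSON manifest of expected counts) whose variant
content encodes the published per-trio result structure of a three-family
pediatric-sarcoidosis exome study: six de novo variants (two per trio),
nine rare (MAF < 0.01) single-trio homozygous-recessive variants with
two common decoys, the cross-family recurrence sets (9 shared recessive
variants, 12 shared-gene recessive genes / 26 variants, 11 compound-het
genes / 44 variants, 79 variants in all, 58 of them flagged pathogenic
in silico) and the per-consequence composition of the trios' recessive
variant loads. All genotype evidence is generated noise-free so expected
counts are exact; these are validation fixtures, not real data.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np

from .simulate import SimConfig, _Site, simulate_trio_dataset, write_ped, write_vcf
from .variants import VariantScores

TRIO_IDS = ("T1", "T2", "T3")

# scores given to invented (non-printed) variants
_FLAGGED = (0.01, 0.95)    # sift, polyphen -> passes the in-silico rule
_BENIGN = (0.55, 0.12)     # fails the rule

# --------------------------------------------------------------------------
# de novo table: gene, trio, chrom, pos, ref, alt, consequence, qual, depth,
#                sift, polyphen, maf
DENOVO_ROWS = (
    ("IGSF3", "T1", "chr1", 117122285, "A", "AGGA", "inframe_insertion",
     14580, 191, None, None, 0.25),
    ("SPICE1", "T1", "chr3", 113172543, "T", "G", "missense",
     3572, 291, None, None, None),
    ("ZNF717", "T2", "chr3", 75781257, "A", "C", "missense",
     106499, 580, 0.06, 0.0, None),
    ("CTNND2", "T2", "chr5", 10981914, "G", "A", "missense",
     299, 111, None, None, None),
    ("NPHS2", "T3", "chr1", 179526340, "T", "C", "missense",
     6106, 530, None, None, None),
    ("PRSS55", "T3", "chr8", 10390473, "G", "C", "missense",
     3426, 172, None, None, None),
)

# rare single-trio recessive table: trio, gene, chrom, pos, ref, alt,
#                consequence, qual, depth, sift, polyphen, maf
RARE_RECESSIVE_ROWS = (
    ("T1", "ZNF717", "chr3", 75787726, "C", "T", "missense",
     221913, 1345, 0.14, 0.689, None),
    ("T1", "WNT2", "chr7", 116963030, "T", "G", "missense",
     7083, 305, 0.39, 0.063, 0.0011),
    ("T1", "COG6", "chr13", 40254100, "T", "TT", "frameshift",
     4954, 228, None, None, None),
    ("T1", "BEGAIN", "chr14", 101036074, "G", "C", "splice_site",
     20030, 273, None, None, None),
    ("T1", "NDUFV3", "chr21", 44317156, "A", "C", "missense",
     8515, 341, 0.01, 0.927, 0.0051),
    ("T2", "SHROOM1", "chr5", 132161699, "C", "A", "missense",
     13112, 130, 0.02, 0.274, 0.0065),
    ("T2", "FMNL1", "chr17", 43320554, "G", "A", "missense",
     7318, 194, 0.12, 1.0, 0.0019),
    ("T3", "DCP1B", "chr12", 2062323, "A", "AGCA", "inframe_insertion",
     65685, 295, None, None, 0.00784),
    ("T3", "CHRNA3", "chr15", 78913067, "TCTG", "T", "inframe_deletion",
     27072, 105, None, None, 0.00138),
)

# common recessive decoys (also category-A members of the recurrence set):
# gene, chrom, pos, ref, alt, trios, sift, polyphen, maf
_SEC16A = ("Sec16A", "chr9", 139368953, "C", "T", ("T1", "T2"),
           0.14, 0.689, 0.21)
_AP5B1 = ("AP5B1", "chr11", 65547333, "C", "T", ("T1", "T3"),
          0.0, 0.999, 0.29)

# Category A: identical recessive variant in >= 2 trios.
# gene, chrom, pos, ref, alt, trios, sift, polyphen, maf  (invented scores
# keyed by the pathogenic flag the aggregate requires)
CATEGORY_A_ROWS = (
    _SEC16A,
    ("ADGRV1", "chr5", 90011342, "G", "A", ("T1", "T2"), *_BENIGN, 0.12),
    ("RHBDL2", "chr1", 39351277, "C", "T", ("T1", "T3"), *_FLAGGED, 0.08),
    ("ZNF804A", "chr2", 185800931, "A", "G", ("T1", "T3"), *_FLAGGED, 0.17),
    _AP5B1,
    ("TYR", "chr11", 88911044, "G", "A", ("T1", "T3"), *_BENIGN, 0.31),
    ("CPAMD8", "chr19", 17001523, "T", "C", ("T1", "T3"), *_FLAGGED, 0.22),
    ("PRSS48", "chr4", 152200684, "C", "G", ("T2", "T3"), *_FLAGGED, 0.19),
    ("OR11G2", "chr14", 20402217, "A", "T", ("T1", "T2", "T3"), *_FLAGGED, 0.26),
)

# Category B: shared gene, different recessive positions per trio.
# gene, chrom, {trio: (pos, ref, alt, sift, polyphen, maf)}
CATEGORY_B_ROWS = (
    ("ASPN", "chr9", {
        "T1": (95218411, "C", "T", *_FLAGGED, 0.11),
        "T2": (95219630, "G", "A", *_BENIGN, 0.09),
    }),
    ("WFDC3", "chr20", {
        "T1": (44023108, "A", "G", *_BENIGN, 0.21),
        "T2": (44024751, "C", "T", *_FLAGGED, 0.14),
    }),
    ("CCT6B", "chr17", {
        "T1": (33243870, "G", "C", *_FLAGGED, 0.07),
        "T2": (33245991, "T", "C", *_BENIGN, 0.18),
    }),
    ("OBSCN", "chr1", {
        "T1": (228505204, "G", "A", 0.0, 0.91, 0.26),
        "T3": (228494790, "G", "A", 0.01, 0.939, 0.41),
    }),
    ("SLC16A8", "chr22", {
        "T1": (38477104, "C", "T", *_FLAGGED, 0.13),
        "T3": (38478990, "G", "T", *_BENIGN, 0.24),
    }),
    ("AFAP1", "chr4", {
        "T2": (7862115, "A", "C", *_BENIGN, 0.16),
        "T3": (7864208, "G", "A", *_FLAGGED, 0.05),
    }),
    ("HSD17B4", "chr5", {
        "T2": (118811509, "T", "C", *_FLAGGED, 0.10),   # c.1606T>C
        "T3": (118790403, "G", "A", *_BENIGN, 0.20),    # c.392G>A
    }),
    ("DNAH11", "chr7", {
        "T2": (21752217, "C", "T", *_BENIGN, 0.15),
        "T3": (21759984, "A", "G", *_FLAGGED, 0.09),
    }),
    ("CNGB1", "chr16", {
        "T2": (57930126, "G", "A", *_FLAGGED, 0.12),
        "T3": (57942873, "C", "T", *_BENIGN, 0.23),
    }),
    ("MARCH10", "chr17", {
        "T2": (60602904, "T", "G", *_BENIGN, 0.08),
        "T3": (60611450, "C", "A", *_FLAGGED, 0.11),
    }),
    ("RHBG", "chr1", {
        "T1": (156334201, "C", "T", *_FLAGGED, 0.14),
        "T2": (156336450, "G", "A", *_BENIGN, 0.17),
        "T3": (156338112, "A", "G", *_FLAGGED, 0.06),
    }),
    ("KNL1", "chr15", {
        "T1": (40916237, "A", "G", 0.05, 0.058, 0.32),  # c.3853A>G
        "T2": (40915190, "A", "G", 1.0, 0.0, 0.24),     # c.2806A>G
        "T3": (40914177, "T", "C", 0.01, 0.006, 0.39),  # c.1793T>C
    }),
)

# Category C: transmission-phased compound heterozygotes in >= 2 trios.
# gene, chrom, [(trio, side, pos, ref, alt, consequence, sift, polyphen, maf)]
CATEGORY_C_ROWS = (
    ("CMYA5", "chr5", (
        ("T1", "p", 78985102, "C", "T", "missense", *_BENIGN, 0.13),
        ("T1", "m", 78990341, "G", "A", "missense", *_FLAGGED, 0.19),
        ("T2", "p", 78987265, "A", "G", "missense", *_FLAGGED, 0.09),
        ("T2", "m", 78995414, "T", "C", "missense", *_FLAGGED, 0.21),
    )),
    ("PCDHB16", "chr5", (
        ("T1", "p", 140602311, "G", "A", "missense", *_FLAGGED, 0.11),
        ("T1", "m", 140603492, "C", "T", "missense", *_FLAGGED, 0.07),
        ("T2", "p", 140602877, "A", "C", "missense", *_FLAGGED, 0.15),
        ("T2", "m", 140604105, "T", "G", "missense", *_BENIGN, 0.23),
    )),
    ("RREB1", "chr6", (
        ("T1", "p", 7231843, "G", "A", "missense", 0.0, 0.999, 0.11),
        ("T1", "m", 7246998, "G", "A", "missense", 0.12, 0.0, 0.27),
        ("T2", "p", 7230680, "G", "T", "missense", 0.06, 0.156, 0.44),
        ("T2", "m", 7247344, "C", "A", "missense", 0.01, 0.025, 0.14),
    )),
    ("AIM1L", "chr1", (
        ("T1", "p", 26703814, "C", "T", "missense", *_FLAGGED, 0.12),
        ("T1", "m", 26705992, "G", "A", "missense", *_FLAGGED, 0.18),
        ("T3", "p", 26704427, "A", "G", "missense", *_BENIGN, 0.25),
        ("T3", "m", 26706531, "T", "C", "missense", *_FLAGGED, 0.08),
    )),
    ("IDO2", "chr8", (
        ("T1", "p", 39862881, "C", "T", "missense", 0.0, 1.0, 0.48),
        ("T1", "m", 39873053, "G", "A", "missense", 0.57, 0.024, 0.06),
        ("T3", "p", 39872935, "T", "A", "stop_gained", None, None, 0.226),
        ("T3", "m", 39862893, "T", "A", "missense", 0.02, 0.444, 0.02),
    )),
    ("KIR3DL1", "chr19", (
        ("T1", "p", 55316723, "G", "C", "missense", *_FLAGGED, 0.16),
        ("T1", "m", 55318940, "A", "G", "missense", *_BENIGN, 0.22),
        ("T3", "p", 55317801, "C", "T", "missense", *_FLAGGED, 0.10),
        ("T3", "m", 55319574, "G", "A", "missense", *_FLAGGED, 0.14),
    )),
    ("TDRD5", "chr1", (
        ("T2", "p", 179603212, "A", "G", "missense", *_FLAGGED, 0.09),
        ("T2", "m", 179609457, "C", "T", "missense", *_FLAGGED, 0.17),
        ("T3", "p", 179605338, "G", "A", "missense", *_FLAGGED, 0.12),
        ("T3", "m", 179611820, "T", "C", "missense", *_FLAGGED, 0.20),
    )),
    ("DNAH11", "chr7", (
        ("T2", "p", 21893993, "G", "T", "missense", 0.02, 0.611, 0.43),
        ("T2", "m", 21584693, "G", "T", "missense", 0.0, 0.601, 0.012),
        ("T3", "p", 21628242, "C", "G", "missense", 0.67, 0.02, 0.13),
        ("T3", "m", 21678643, "A", "G", "missense", 0.0, 0.783, 0.045),
    )),
    ("PIEZO1", "chr16", (
        ("T2", "p", 88782416, "C", "T", "missense", *_FLAGGED, 0.11),
        ("T2", "m", 88786103, "G", "A", "missense", *_FLAGGED, 0.19),
        ("T3", "p", 88783525, "A", "G", "missense", *_FLAGGED, 0.07),
        ("T3", "m", 88787934, "T", "C", "missense", *_FLAGGED, 0.15),
    )),
    ("FCGBP", "chr19", (
        ("T2", "p", 40354310, "G", "A", "missense", *_FLAGGED, 0.13),
        ("T2", "m", 40357026, "C", "T", "missense", *_FLAGGED, 0.09),
        ("T3", "p", 40355492, "T", "C", "missense", *_FLAGGED, 0.18),
        ("T3", "m", 40358743, "A", "G", "missense", *_FLAGGED, 0.24),
    )),
    ("PCNT", "chr21", (
        ("T2", "p", 47741934, "C", "T", "missense", *_FLAGGED, 0.10),
        ("T2", "m", 47745126, "G", "A", "missense", *_FLAGGED, 0.16),
        ("T3", "p", 47743057, "A", "G", "missense", *_FLAGGED, 0.12),
        ("T3", "m", 47746689, "T", "C", "missense", *_FLAGGED, 0.21),
    )),
)

# per-consequence recessive composition of the two consequence fixtures
CONSEQUENCE_MIXES: Dict[str, Dict[str, int]] = {
    "trio1": {
        "missense": 404,
        "frameshift": 3,
        "inframe_insertion": 6,
        "splice_site": 14,
        "start_lost": 2,
        "stop_lost": 2,
    },
    "trio3": {
        "missense": 478,
        "stop_gained": 4,
        "frameshift": 8,
        "inframe_deletion": 6,
        "inframe_insertion": 6,
        "splice_site": 12,
        "stop_lost": 1,
    },
}


def _scores(sift, polyphen, maf) -> VariantScores:
    return VariantScores(sift=sift, polyphen=polyphen, maf=maf)


def _genotypes(per_trio: Dict[str, Tuple[int, int, int]]) -> Dict[str, int]:
    gts: Dict[str, int] = {}
    for t in TRIO_IDS:
        c, p, m = per_trio.get(t, (0, 0, 0))
        gts[f"{t}c"], gts[f"{t}p"], gts[f"{t}m"] = c, p, m
    return gts


def _emit(sites: List[_Site], outdir: Path, stem: str) -> Dict[str, Path]:
    samples = [f"{t}{s}" for t in TRIO_IDS for s in ("c", "p", "m")]
    sites = sorted(sites, key=lambda s: (int(s.chrom[3:]), s.pos))
    rng = np.random.default_rng(0)  # unused: fixtures are noise-free
    vcf = outdir / f"{stem}.vcf"
    write_vcf(sites, samples, vcf, rng, mean_depth=300, base_error=0.001,
              noise=False)
    scores_path = outdir / f"{stem}_scores.tsv"
    from .io import write_score_table

    write_score_table(
        {f"{s.chrom}:{s.pos}:{s.ref}:{s.alt}": s.scores for s in sites},
        scores_path,
    )
    return {"vcf": vcf, "scores": scores_path}


def make_denovo_fixture(outdir) -> Dict[str, Path]:
    """Six de novo variants (two per trio) plus inherited decoys."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sites: List[_Site] = []
    for gene, trio, chrom, pos, ref, alt, cons, qual, depth, sift, pp, maf in \
            DENOVO_ROWS:
        sites.append(
            _Site(chrom, pos, ref, alt, gene, cons, maf,
                  _genotypes({trio: (1, 0, 0)}), _scores(sift, pp, maf),
                  qual=qual, depth=depth)
        )
    # inherited decoys: transmitted hets and one all-reference site
    decoys = (
        ("DECOY1", "chr2", 40101210, "A", "G", {"T1": (1, 1, 0)}),
        ("DECOY2", "chr6", 30202321, "C", "T", {"T2": (1, 0, 1)}),
        ("DECOY3", "chr10", 50404432, "G", "A", {"T3": (1, 1, 1)}),
        ("DECOY4", "chr12", 60505143, "T", "C", {}),
    )
    for gene, chrom, pos, ref, alt, gts in decoys:
        sites.append(
            _Site(chrom, pos, ref, alt, gene, "missense", 0.3,
                  _genotypes(gts), _scores(0.5, 0.2, 0.3))
        )
    return _emit(sites, outdir, "denovo")


def make_rare_recessive_fixture(outdir) -> Dict[str, Path]:
    """Nine rare single-trio recessive variants plus common decoys."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sites: List[_Site] = []
    for trio, gene, chrom, pos, ref, alt, cons, qual, depth, sift, pp, maf in \
            RARE_RECESSIVE_ROWS:
        sites.append(
            _Site(chrom, pos, ref, alt, gene, cons, maf,
                  _genotypes({trio: (2, 1, 1)}), _scores(sift, pp, maf),
                  qual=qual, depth=depth)
        )
    for gene, chrom, pos, ref, alt, trios, sift, pp, maf in (_SEC16A, _AP5B1):
        sites.append(
            _Site(chrom, pos, ref, alt, gene, "missense", maf,
                  _genotypes({t: (2, 1, 1) for t in trios}),
                  _scores(sift, pp, maf))
        )
    return _emit(sites, outdir, "rare_recessive")


def make_recurrence_fixture(outdir) -> Dict[str, Path]:
    """The three cross-family recurrence categories (79 variants)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sites: List[_Site] = []
    for gene, chrom, pos, ref, alt, trios, sift, pp, maf in CATEGORY_A_ROWS:
        sites.append(
            _Site(chrom, pos, ref, alt, gene, "missense", maf,
                  _genotypes({t: (2, 1, 1) for t in trios}),
                  _scores(sift, pp, maf))
        )
    for gene, chrom, per_trio in CATEGORY_B_ROWS:
        for trio, (pos, ref, alt, sift, pp, maf) in per_trio.items():
            sites.append(
                _Site(chrom, pos, ref, alt, gene, "missense", maf,
                      _genotypes({trio: (2, 1, 1)}), _scores(sift, pp, maf))
            )
    for gene, chrom, entries in CATEGORY_C_ROWS:
        for trio, side, pos, ref, alt, cons, sift, pp, maf in entries:
            gts = (1, 1, 0) if side == "p" else (1, 0, 1)
            sites.append(
                _Site(chrom, pos, ref, alt, gene, cons, maf,
                      _genotypes({trio: gts}), _scores(sift, pp, maf))
            )
    return _emit(sites, outdir, "recurrence")


def make_consequence_fixture(mix: str, outdir, seed: int = 0):
    """One trio whose recessive variant load follows a stated consequence mix.

    ``mix`` is a key of :data:`CONSEQUENCE_MIXES`. Built through the trio
    simulator in its deterministic (noise-free) mode with non-recessive
    decoy background so the recessive tally is exact by construction.
    """
    counts = CONSEQUENCE_MIXES[mix]
    genes: List[str] = []
    consequences: List[str] = []
    i = 0
    for cons, n in counts.items():
        for _ in range(n):
            i += 1
            genes.append(f"REC_{mix.upper()}_{i:04d}")
            consequences.append(cons)
    config = SimConfig(
        n_trios=1,
        n_variants=100,
        n_denovo=0,
        recessive_genes={"T1": genes},
        recessive_consequences={"T1": consequences},
        allele_depth_noise=False,
        background_mode="single_carrier",
        seed=seed,
    )
    return simulate_trio_dataset(config, outdir)


def make_reference_fixtures(outdir) -> Dict[str, object]:
    """Emit all reference fixtures plus a manifest of expected counts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_ped(TRIO_IDS, outdir / "trios.ped")
    paths: Dict[str, object] = {"ped": outdir / "trios.ped"}
    paths["denovo"] = make_denovo_fixture(outdir)
    paths["rare_recessive"] = make_rare_recessive_fixture(outdir)
    paths["recurrence"] = make_recurrence_fixture(outdir)
    paths["consequence_trio1"] = make_consequence_fixture(
        "trio1", outdir / "consequence_trio1"
    )
    paths["consequence_trio3"] = make_consequence_fixture(
        "trio3", outdir / "consequence_trio3"
    )
    manifest = expected_counts()
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    paths["manifest"] = manifest_path
    return paths


def expected_counts() -> Dict[str, object]:
    """Expected analysis counts encoded by the fixtures."""
    n_flagged = _count_flagged()
    total = (
        len(CATEGORY_A_ROWS)
        + sum(len(pt) for _g, _c, pt in CATEGORY_B_ROWS)
        + sum(len(e) for _g, _c, e in CATEGORY_C_ROWS)
    )
    return {
        "denovo": {
            "total": len(DENOVO_ROWS),
            "per_trio": {t: sum(1 for r in DENOVO_ROWS if r[1] == t)
                         for t in TRIO_IDS},
        },
        "rare_recessive": {"retained_at_maf_0.01": len(RARE_RECESSIVE_ROWS)},
        "recurrence": {
            "A_variants": len(CATEGORY_A_ROWS),
            "B_genes": len(CATEGORY_B_ROWS),
            "B_variants": sum(len(pt) for _g, _c, pt in CATEGORY_B_ROWS),
            "C_genes": len(CATEGORY_C_ROWS),
            "C_variants": sum(len(e) for _g, _c, e in CATEGORY_C_ROWS),
            "total_variants": total,
            "flagged_pathogenic": n_flagged,
            "flagged_fraction_pct": round(100.0 * n_flagged / total, 1),
        },
        "consequence": {
            mix: {**counts, "total": sum(counts.values())}
            for mix, counts in CONSEQUENCE_MIXES.items()
        },
    }


def _count_flagged() -> int:
    from .stats import pathogenicity_flag

    n = 0
    for _g, _c, pos, _r, _a, _t, sift, pp, maf in CATEGORY_A_ROWS:
        n += pathogenicity_flag(_scores(sift, pp, maf), ("missense",))[0]
    for _g, _c, per_trio in CATEGORY_B_ROWS:
        for pos, ref, alt, sift, pp, maf in per_trio.values():
            n += pathogenicity_flag(_scores(sift, pp, maf), ("missense",))[0]
    for _g, _c, entries in CATEGORY_C_ROWS:
        for _t, _s, pos, ref, alt, cons, sift, pp, maf in entries:
            n += pathogenicity_flag(_scores(sift, pp, maf), (cons,))[0]
    return n
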