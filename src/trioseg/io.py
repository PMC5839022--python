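"""Readers and writers: PED pedigrees, multi-sample VCFs, score tables, GMT.

VCF parsing is delegated to :mod:`cyvcf2`; multi-allelic sites are split
into biallelic records here (one record per alternate allele, with AD and
PL subset accordingly) before any filtering happens downstream.
"""

from __future__ import annotations

import logging
import math
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from cyvcf2 import VCF

from .variants import (
    PedigreeTrio,
    SampleGenotype,
    TranscriptAnnotation,
    TrioVariantRecord,
    VariantScores,
    map_so_term,
)

logger = logging.getLogger("trioseg")

_SEX = {"1": "male", "2": "female"}

# Column layout of the tab-delimited per-variant score / MAF side table.
SCORE_COLUMNS = (
    "chrom", "pos", "ref", "alt",
    "sift", "polyphen", "cadd_phred",
    "sift_rank", "polyphen_rank", "cadd_rank", "maf",
)

# Output layout of write_variant_table (one row per segregation call).
TABLE_COLUMNS = (
    "gene", "trio", "chrom", "pos", "ref", "alt", "qual", "depth",
    "consequence", "sift", "polyphen", "maf", "class",
)


def read_pedigree(path) -> List[PedigreeTrio]:
    """Parse a 6-column PED file into analysis trios.

    Returns one :class:`PedigreeTrio` per affected child (phenotype 2)
    whose father and mother rows are both present, preserving family
    order. A child that names a parent absent from the file, or a
    duplicated sample id, is a hard error.
    """
    rows = []
    seen = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: expected >= 6 columns")
            fam, iid, fid, mid, sex, pheno = parts[:6]
            if iid in seen:
                raise ValueError(f"{path}:{ln}: duplicate sample id {iid!r}")
            seen.add(iid)
            rows.append((fam, iid, fid, mid, sex, pheno))

    trios: List[PedigreeTrio] = []
    for fam, iid, fid, mid, sex, pheno in rows:
        if pheno != "2":
            continue
        for parent, role in ((fid, "father"), (mid, "mother")):
            if parent != "0" and parent not in seen:
                raise ValueError(
                    f"affected child {iid!r} references absent {role} {parent!r}"
                )
        if fid == "0" or mid == "0":
            continue  # not a complete trio
        trios.append(
            PedigreeTrio(
                family_id=fam,
                child_id=iid,
                father_id=fid,
                mother_id=mid,
                child_affected=True,
                child_sex=_SEX.get(sex, "unknown"),
            )
        )
    return trios


def parse_annotations(info_text: str, dialect: str) -> List[TranscriptAnnotation]:
    """Parse a SnpEff-ANN or VEP-CSQ INFO string into annotations.

    ``dialect`` is ``"ANN"`` or ``"CSQ"``. Effect terms outside the closed
    vocabulary map to ``other``; malformed entries are skipped with a
    warning rather than aborting the record.
    """
    if dialect not in ("ANN", "CSQ"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    out: List[TranscriptAnnotation] = []
    for entry in str(info_text).split(","):
        fields = entry.split("|")
        try:
            if dialect == "ANN":
                # Allele|Annotation|Impact|Gene_Name|Gene_ID|Feature_Type|
                # Feature_ID|BioType|Rank|HGVS.c|HGVS.p|...
                consequence = map_so_term(fields[1])
                gene = fields[3]
                tx = fields[6] if len(fields) > 6 else ""
                hgvs_c = fields[9] if len(fields) > 9 else ""
                hgvs_p = fields[10] if len(fields) > 10 else ""
            else:
                # Allele|Consequence|IMPACT|SYMBOL|Gene|Feature_type|Feature|
                # BIOTYPE|EXON|INTRON|HGVSc|HGVSp|...
                consequence = map_so_term(fields[1])
                gene = fields[3]
                tx = fields[6] if len(fields) > 6 else ""
                hgvs_c = fields[10] if len(fields) > 10 else ""
                hgvs_p = fields[11] if len(fields) > 11 else ""
            if not gene:
                raise IndexError("empty gene field")
        except IndexError:
            logger.warning("skipping malformed %s entry: %r", dialect, entry)
            continue
        out.append(
            TranscriptAnnotation(
                gene_symbol=gene,
                transcript_id=tx,
                consequence=consequence,
                hgvs_c=hgvs_c,
                hgvs_p=hgvs_p,
            )
        )
    return out


def qual_to_chance_prob(qual: float) -> float:
    """Probability that a variant observation is a chance artifact.

    Convention: for a site quality ``QUAL = n`` the chance-observation
    probability is ``1/n``.
    """
    if qual <= 0:
        raise ValueError("qual must be > 0")
    return 1.0 / qual


def _none_if_missing(x) -> Optional[float]:
    if x is None:
        return None
    x = float(x)
    if math.isnan(x) or x < 0:
        return None
    return x


def read_score_table(path) -> Dict[str, VariantScores]:
    """Read the tab-delimited side table of scores/MAFs keyed chrom:pos:ref:alt.

    Empty cells and the tokens ``na``/``nd``/``nan``/``.`` are missing.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"", "na", "nd", "nan", "."}
    out: Dict[str, VariantScores] = {}
    for row in df.itertuples(index=False):
        d = {c: getattr(row, c) for c in df.columns}
        key = f"{d['chrom']}:{d['pos']}:{d['ref']}:{d['alt']}"

        def val(col: str) -> Optional[float]:
            raw = str(d.get(col, "")).strip().lower()
            return None if raw in missing else float(raw)

        out[key] = VariantScores(
            sift=val("sift"),
            polyphen=val("polyphen"),
            cadd_phred=val("cadd_phred"),
            sift_rank=val("sift_rank"),
            polyphen_rank=val("polyphen_rank"),
            cadd_rank=val("cadd_rank"),
            maf=val("maf"),
        )
    return out


def write_score_table(scores: Mapping[str, VariantScores], path) -> None:
    rows = []
    for key, s in scores.items():
        chrom, pos, ref, alt = key.split(":")
        rows.append(
            {
                "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                "sift": _fmt(s.sift), "polyphen": _fmt(s.polyphen),
                "cadd_phred": _fmt(s.cadd_phred), "sift_rank": _fmt(s.sift_rank),
                "polyphen_rank": _fmt(s.polyphen_rank),
                "cadd_rank": _fmt(s.cadd_rank), "maf": _fmt(s.maf),
            }
        )
    pd.DataFrame(rows, columns=list(SCORE_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def _pl_subset_indices(alt_index: int) -> Tuple[int, int, int]:
    # Diploid PL ordering: index of genotype (j,k) is k*(k+1)/2 + j.
    k = alt_index
    return (0, k * (k + 1) // 2, k * (k + 1) // 2 + k)


def _detect_dialect(vcf: VCF) -> Optional[str]:
    for dialect in ("ANN", "CSQ"):
        try:
            vcf.get_header_type(dialect)
            return dialect
        except KeyError:
            continue
    return None


def read_trio_vcf(
    path,
    trios: Sequence[PedigreeTrio],
    score_table: Optional[Mapping[str, VariantScores]] = None,
    info_score_keys: Optional[Mapping[str, str]] = None,
) -> Iterator[TrioVariantRecord]:
    """Stream biallelic :class:`TrioVariantRecord` objects from a VCF.

    Multi-allelic sites are split into one record per alternate allele;
    AD and PL are subset per allele (allele indices for non-focal
    alternates are collapsed onto the reference so that each record is
    strictly biallelic, their reads contributing to depth only). Records
    are emitted in file order with VCF 1-based positions unchanged.

    Scores come from ``score_table`` (keyed chrom:pos:ref:alt) when
    provided; otherwise from INFO keys named in ``info_score_keys``
    (mapping VariantScores field -> INFO key). The side table wins on
    conflict. A sample column missing from the VCF is a hard error; a
    missing FORMAT field leaves the corresponding evidence unset.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    index = {s: i for i, s in enumerate(samples)}
    needed = [s for t in trios for s in t.sample_ids]
    for s in needed:
        if s not in index:
            raise ValueError(f"sample {s!r} absent from VCF {path}")
    dialect = _detect_dialect(vcf)
    warned: set = set()

    for variant in vcf:
        n_alleles = 1 + len(variant.ALT)
        ad = _format_or_none(variant, "AD", warned)
        dp = _format_or_none(variant, "DP", warned)
        gq = _format_or_none(variant, "GQ", warned)
        pl = _format_or_none(variant, "PL", warned)
        ann_text = None
        if dialect is not None:
            ann_text = variant.INFO.get(dialect)

        for k, alt in enumerate(variant.ALT, start=1):
            genotypes: Dict[str, SampleGenotype] = {}
            i0, i1, i2 = _pl_subset_indices(k)
            for s in set(needed):
                i = index[s]
                gt = variant.genotypes[i]
                a, b = gt[0], gt[1]
                if a < 0 or b < 0:
                    alleles = None
                else:
                    # collapse non-focal alternates onto the reference
                    alleles = (int(a == k), int(b == k))
                ad_ref = ad_alt = 0
                if ad is not None:
                    row = ad[i]
                    ad_ref = max(int(row[0]), 0)
                    if len(row) > k:
                        ad_alt = max(int(row[k]), 0)
                depth = 0
                if dp is not None:
                    depth = max(int(_first(dp[i])), 0)
                elif ad is not None:
                    depth = max(sum(max(int(x), 0) for x in ad[i]), 0)
                depth = max(depth, ad_ref + ad_alt)
                gq_val = None
                if gq is not None:
                    g = float(_first(gq[i]))
                    gq_val = g if g >= 0 else None
                pl_val = None
                if pl is not None:
                    row = pl[i]
                    if len(row) >= n_alleles * (n_alleles + 1) // 2:
                        trip = (float(row[i0]), float(row[i1]), float(row[i2]))
                        if all(p >= 0 for p in trip):
                            m = min(trip)
                            pl_val = tuple(p - m for p in trip)
                genotypes[s] = SampleGenotype(
                    alleles=alleles, ad_ref=ad_ref, ad_alt=ad_alt,
                    depth=depth, gq=gq_val, pl=pl_val,
                )

            annotations: List[TranscriptAnnotation] = []
            if ann_text:
                annotations = parse_annotations(ann_text, dialect)
                if len(variant.ALT) > 1:
                    keep = [
                        a for e, a in zip(str(ann_text).split(","), annotations)
                        if e.split("|", 1)[0] == alt
                    ]
                    if keep:
                        annotations = keep

            key = f"{variant.CHROM}:{variant.POS}:{variant.REF}:{alt}"
            scores = VariantScores()
            if info_score_keys:
                scores = _scores_from_info(variant, info_score_keys)
            if score_table is not None and key in score_table:
                scores = score_table[key]

            yield TrioVariantRecord(
                chrom=variant.CHROM,
                pos=variant.POS,
                ref=variant.REF,
                alt=alt,
                qual=float(variant.QUAL) if variant.QUAL is not None else 0.0,
                genotypes=genotypes,
                annotations=annotations,
                scores=scores,
            )


def _format_or_none(variant, field: str, warned: set):
    try:
        arr = variant.format(field)
    except KeyError:
        arr = None
    if arr is None and field not in warned:
        logger.warning("FORMAT field %s absent at %s:%s; continuing with it missing",
                       field, variant.CHROM, variant.POS)
        warned.add(field)
    return arr


def _first(x):
    try:
        return x[0]
    except (TypeError, IndexError):
        return x


def _scores_from_info(variant, keys: Mapping[str, str]) -> VariantScores:
    vals = {}
    for field_name, info_key in keys.items():
        raw = variant.INFO.get(info_key)
        if raw is None:
            continue
        if isinstance(raw, (tuple, list)):
            # mean over transcripts when the annotation is per-transcript
            nums = [float(x) for x in raw if x is not None]
            vals[field_name] = sum(nums) / len(nums) if nums else None
        else:
            try:
                vals[field_name] = float(raw)
            except (TypeError, ValueError):
                continue
    return VariantScores(**vals)


def _fmt(x) -> str:
    if x is None:
        return "nd"
    if isinstance(x, float) and x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return f"{x:.6g}"


def write_variant_table(records, calls, path) -> None:
    """Write segregation calls joined to their records as a TSV.

    One row per call, deterministic column order (:data:`TABLE_COLUMNS`)
    and row order (chrom, pos, trio). ``depth`` is the child's read depth
    for that trio. The written file round-trips byte-identically through
    :func:`read_variant_table` / :func:`write_table_df`.
    """
    by_key = {r.key: r for r in records}
    rows = []
    for call in calls:
        rec = by_key.get(call.key)
        if rec is None:
            raise ValueError(f"call references unknown record {call.key}")
        child_gt = None
        if call.child_id is not None:
            child_gt = rec.genotype(call.child_id)
        rows.append(
            {
                "gene": call.gene or "",
                "trio": call.trio_id,
                "chrom": rec.chrom,
                "pos": str(rec.pos),
                "ref": rec.ref,
                "alt": rec.alt,
                "qual": _fmt(rec.qual),
                "depth": str(child_gt.depth) if child_gt else "0",
                "consequence": call.consequence or "other",
                "sift": _fmt(rec.scores.sift),
                "polyphen": _fmt(rec.scores.polyphen),
                "maf": _fmt(rec.scores.maf),
                "class": call.seg_class,
            }
        )
    df = pd.DataFrame(rows, columns=list(TABLE_COLUMNS))
    if len(df):
        df = df.sort_values(
            ["chrom", "pos", "trio"],
            key=lambda s: s.astype(int) if s.name == "pos" else s,
            kind="mergesort",
        )
    write_table_df(df, path)


def write_table_df(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_variant_table(path) -> pd.DataFrame:
    """Read a variant table as written by :func:`write_variant_table`.

    Cells are kept as strings so that a re-write is byte-identical.
    """
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def read_gmt(path) -> Dict[str, set]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: Dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets
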