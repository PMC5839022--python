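"""End-to-end pipeline: filter -> segregate -> recurrence -> prioritize ->
inbreeding -> enrichment, with a JSON summary mirroring per-trio counts.

All outputs are deterministic given the configuration (fixed seed,
stable sort orders), so re-running an identical configuration yields
byte-identical TSV/JSON files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .filters import DeNovoPrior, FilterThresholds
from .inbreeding import HOM_ALT, HOM_REF, HET, MISSING, InbreedingHMM, MarkerPanel
from .recurrence import cross_trio_recurrence, single_trio_rare_recessive
from .segregation import find_compound_hets, segregate_all
from .stats import (
    PathogenicityRule,
    ora_enrichment,
    pathogenicity_flag,
    rank_score_groups,
    rank_sum_test,
)

logger = logging.getLogger("trioseg")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths, thresholds and settings for one pipeline run."""

    vcf: str
    ped: str
    outdir: str
    scores: Optional[str] = None
    panel: Optional[str] = None
    gmt: Optional[str] = None
    ab_min: float = 0.35
    ab_max: float = 0.65
    gq_min: float = 20.0
    min_depth: int = 0
    ab_on_parents: bool = True
    use_posterior: bool = True
    denovo_prior: float = 1e-6
    sift_max: float = 0.05
    polyphen_min: float = 0.446
    maf_threshold: float = 0.01
    missing_maf_rare: bool = True
    inbreeding_subsamples: int = 100
    inbreeding_subsample_size: int = 3900
    inbreeding_eps: float = 1e-3
    seed: int = 0

    def thresholds(self) -> FilterThresholds:
        return FilterThresholds(ab_min=self.ab_min, ab_max=self.ab_max,
                                gq_min=self.gq_min, min_depth=self.min_depth)

    def prior(self) -> DeNovoPrior:
        return DeNovoPrior(mu=self.denovo_prior)

    def rule(self) -> PathogenicityRule:
        return PathogenicityRule(sift_max=self.sift_max,
                                 polyphen_min=self.polyphen_min)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise PipelineError(name, exc) from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> Dict:
    """Run every stage and write TSV/JSON reports under ``config.outdir``.

    Returns the summary dict (also written to ``summary.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info(
        "pipeline start: ab=[%.2f,%.2f] gq>%.0f mu=%g maf<%g seed=%d",
        config.ab_min, config.ab_max, config.gq_min, config.denovo_prior,
        config.maf_threshold, config.seed,
    )

    trios = _stage("pedigree")(tio.read_pedigree)(config.ped)
    score_table = {}
    if config.scores:
        score_table = _stage("scores")(tio.read_score_table)(config.scores)
    records = _stage("vcf")(lambda: list(
        tio.read_trio_vcf(config.vcf, trios, score_table=score_table or None)
    ))()

    calls, seg_summary = _stage("segregate")(segregate_all)(
        records, trios,
        thresholds=config.thresholds(),
        prior=config.prior(),
        use_posterior=config.use_posterior,
        ab_on_parents=config.ab_on_parents,
    )
    pairs = _stage("comp_het")(find_compound_hets)(calls)
    report = _stage("recurrence")(cross_trio_recurrence)(calls, pairs)
    key_scores = {r.key: r.scores for r in records}
    rare_single = _stage("rare_single")(single_trio_rare_recessive)(
        calls, key_scores,
        maf_threshold=config.maf_threshold,
        missing_is_rare=config.missing_maf_rare,
    )

    # prioritized = the recurrent set (categories A, B, C)
    recurrent_entries: List[tuple] = []
    for v in report.category_a:
        for t in v.trios:
            recurrent_entries.append((t, v.key, v.gene))
    for g in report.category_b + report.category_c:
        for t, k in g.variants:
            recurrent_entries.append((t, k, g.gene))
    recurrent_keys = list(dict.fromkeys(k for _t, k, _g in recurrent_entries))

    cons_by_key = {c.key: c.consequence for c in calls if c.consequence}
    rule = config.rule()
    flags = {
        k: pathogenicity_flag(
            key_scores.get(k), (cons_by_key.get(k, "other"),), rule
        )
        for k in recurrent_keys
    }
    n_flagged = sum(1 for f, _r in flags.values() if f)
    frac = 100.0 * n_flagged / len(recurrent_keys) if recurrent_keys else 0.0

    rank_result = None
    if recurrent_keys:
        a, b = rank_score_groups(recurrent_keys, calls, key_scores, "sift")
        if a and b:
            rank_result = _stage("rank_test")(rank_sum_test)(a, b)

    enrichment = []
    if config.gmt and recurrent_keys:
        gene_sets = _stage("gmt")(tio.read_gmt)(config.gmt)
        universe = sorted({c.gene for c in calls if c.gene})
        query = sorted({g for _t, k, g in recurrent_entries
                        if g and flags.get(k, (False,))[0]})
        if query and universe:
            enrichment = _stage("enrichment")(ora_enrichment)(
                query, gene_sets, universe
            )

    inbreeding = {}
    if config.panel:
        panel = _stage("panel")(MarkerPanel.read)(config.panel)
        for trio in trios:
            gts = _panel_genotypes(records, panel, trio.child_id)
            model = InbreedingHMM(gts, panel, eps=config.inbreeding_eps)
            try:
                res = _stage("inbreeding")(model.fit_subsampled)(
                    n_subsamples=config.inbreeding_subsamples,
                    subsample_size=config.inbreeding_subsample_size,
                    seed=config.seed,
                )
            except PipelineError:
                raise
            inbreeding[trio.child_id] = {
                "f_hat": res.f_hat,
                "f_median": res.f_median,
                "lrt": res.lrt_statistic,
                "p_value": res.p_value,
                "n_markers": res.n_markers,
            }

    # ------------------------------------------------------------------ write
    tio.write_variant_table(records, calls, outdir / "calls.tsv")
    _write_comp_hets(pairs, outdir / "comp_het.tsv")
    _write_recurrence(report, outdir)
    tio.write_variant_table(records, rare_single, outdir / "rare_single_trio.tsv")
    _write_flags(flags, outdir / "pathogenic_flags.tsv")
    if enrichment:
        _write_enrichment(enrichment, outdir / "enrichment.tsv")

    summary = {
        "n_records": seg_summary.n_records,
        "per_trio_classes": {
            t: dict(sorted(c.items())) for t, c in seg_summary.class_counts.items()
        },
        "de_novo": seg_summary.total("de_novo"),
        "recessive_hom": seg_summary.total("recessive_hom"),
        "comp_het_pairs": len(pairs),
        "recurrence": report.totals,
        "rare_single_trio": len(rare_single),
        "pathogenic_flagged": n_flagged,
        "pathogenic_flagged_pct": round(frac, 1),
        "rank_test": None if rank_result is None else {
            "u": rank_result.u_statistic,
            "z": rank_result.z_value,
            "p": rank_result.p_two_sided,
            "method": rank_result.method,
        },
        "enrichment_sets_tested": len(enrichment),
        "inbreeding": inbreeding,
        "settings": dataclasses.asdict(config),
    }
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary


def _panel_genotypes(records, panel: MarkerPanel, sample_id: str) -> np.ndarray:
    by_site = {}
    for r in records:
        g = r.genotype(sample_id)
        if g is not None and not g.is_missing:
            by_site[(r.chrom, r.pos)] = {0: HOM_REF, 1: HET, 2: HOM_ALT}[g.dosage]
    return np.array(
        [by_site.get((c, p), MISSING)
         for c, p in zip(panel.chrom, panel.pos)],
        dtype=np.int8,
    )


def _write_comp_hets(pairs, path) -> None:
    rows = [
        {
            "trio": p.trio_id,
            "gene": p.gene_symbol,
            "paternal": ",".join(p.paternal_variants),
            "maternal": ",".join(p.maternal_variants),
        }
        for p in pairs
    ]
    tio.write_table_df(
        pd.DataFrame(rows, columns=["trio", "gene", "paternal", "maternal"]),
        path,
    )


def _write_recurrence(report, outdir: Path) -> None:
    tio.write_table_df(
        pd.DataFrame(
            [{"key": v.key, "gene": v.gene or "", "trios": ",".join(v.trios)}
             for v in report.category_a],
            columns=["key", "gene", "trios"],
        ),
        outdir / "recurrence_A.tsv",
    )
    for name, groups in (("B", report.category_b), ("C", report.category_c)):
        tio.write_table_df(
            pd.DataFrame(
                [{"gene": g.gene, "trio": t, "key": k}
                 for g in groups for t, k in g.variants],
                columns=["gene", "trio", "key"],
            ),
            outdir / f"recurrence_{name}.tsv",
        )
    (outdir / "recurrence_totals.json").write_text(
        json.dumps(report.totals, indent=2, sort_keys=True) + "\n"
    )


def _write_flags(flags, path) -> None:
    rows = [
        {"key": k, "flagged": str(int(f)), "reasons": ";".join(r)}
        for k, (f, r) in sorted(flags.items())
    ]
    tio.write_table_df(
        pd.DataFrame(rows, columns=["key", "flagged", "reasons"]), path
    )


def _write_enrichment(results, path) -> None:
    rows = [
        {
            "set": r.set_name,
            "overlap": r.overlap_count,
            "set_size": r.set_size,
            "query_size": r.query_size,
            "universe_size": r.universe_size,
            "p": f"{r.p_hypergeometric:.6g}",
            "fdr_bh": f"{r.fdr_bh:.6g}",
        }
        for r in results
    ]
    tio.write_table_df(
        pd.DataFrame(
            rows,
            columns=["set", "overlap", "set_size", "query_size",
                     "universe_size", "p", "fdr_bh"],
        ),
        path,
    )
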