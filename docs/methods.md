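# Methods

This note documents the models and procedures `trioseg` implements, the
defaults it ships, what the synthetic data do and do not emulate, and
the numerical choices a maintainer would want recorded.

## Genotype filtering

A trio member passes the hard filters when its genotype quality is
**strictly** greater than `gq_min` (default 20; "superior to 20" is
read literally, so GQ = 20 fails), its depth is at least `min_depth`
(default 0), and — for heterozygous calls only — its allele balance
AB = AD_alt / (AD_ref + AD_alt) lies in `[ab_min, ab_max]` (default
[0.35, 0.65], **bounds inclusive**, so the printed bound is itself
admissible). A record passes for a trio only when all three members
pass. Choices worth noting:

* AB is undefined for homozygous calls; they are AB-exempt so that a
  hom-alt call with AB ≈ 1 is not discarded.
* A missing GQ fails conservatively; missing AD gives no AB and fails
  only the het case.
* Whether AB also applies to parents is genuinely open; the default
  applies it to all three members, and `ab_on_parents=False` restricts
  it to the child.

## Pedigree-informed genotype posterior

When all three members carry PL triples, the joint posterior over the
27 (child, father, mother) genotype combinations is

    joint(c,p,m) ∝ L_c(c) L_p(p) L_m(m) T(c | p, m; μ) H(p) H(m)

with L the renormalised 10^(−PL/10) likelihoods, H the Hardy–Weinberg
prior at the variant's population alternate-allele frequency (its
annotated MAF when present, else `pop_alt_freq` = 0.01), and T the
transmission kernel in which each parent transmits one allele uniformly
and the transmitted allele flips with probability μ (`DeNovoPrior.mu`,
default 10⁻⁶, the conventional per-site germline mutation scale).
μ = 0 recovers exact Mendelian transmission and puts zero posterior
mass on every Mendelian-inconsistent triple.

The child's genotype is reassigned to the argmax of its exact marginal
and its GQ to −10·log₁₀(1 − max marginal), capped at 99. Order of
operations: hard filters run first on the recorded genotypes; the
reassigned child call is then re-checked against `gq_min` (and AB if
still het). Records without complete PLs take the hard-filter-only
path — likelihoods are never fabricated.

## Segregation classes and compound heterozygotes

Each (record, trio) maps to exactly one class; the partition is total
and symmetric under parent swap up to the paternal/maternal label. Two
deliberate conventions: a child 1/1 with a 1/1 parent is
`inherited_other`, not recessive — the design targets unaffected
carrier parents, so "recessive" demands both parents strictly 0/1; and
the de novo configuration (0/1 from 0/0 × 0/0), although Mendelian-
impossible at μ = 0, is named `de_novo` rather than `mendelian_error`
because it is the event class of interest. An optional stricter rule
(`denovo_requires_parent_ref_reads`) additionally vetoes de novo calls
when a parent shows any alternate reads; it is off by default because
the genotype-level definition is the documented behaviour.

Compound heterozygotes are phased **by transmission only**: within a
(trio, gene), at least one `het_paternal` and one `het_maternal`
variant form a pair. Hets with both parents carrying
(`het_biparental`) are phase-unresolvable without statistical phasing
and never pair. Gene assignment uses the most severe annotation
(severity order: stop_gained > frameshift > splice_site > start_lost >
stop_lost > missense > in-frame indel > synonymous > other; ties break
lexicographically). X-chromosome sites are processed autosomally —
hemizygous logic is not modelled.

## Recurrence and the rare single-trio view

Variant identity is the exact (chrom, pos, ref, alt) tuple; HGVS
strings are never compared. Genes qualifying for category A (identical
recessive variant in ≥ 2 trios) are excluded from category B, keeping
the two lists disjoint; category C (compound-het genes in ≥ 2 trios)
may overlap B because the underlying variants differ. The single-trio
view keeps recessive calls private to one family with MAF strictly
below `maf_threshold` (default 0.01); a missing MAF counts as rare by
default (`missing_is_rare`), since absence from a population reference
is itself evidence of rarity.

## Prioritization and statistics

The in-silico pathogenicity rule flags SIFT ≤ 0.05 (the standard
"deleterious" cutoff), PolyPhen-2 ≥ 0.446 (the "possibly damaging"
lower bound), or any loss-of-function consequence. The rank-sum
comparison takes dbNSFP-style rank scores when available (raw scores as
fallback), per-variant by default with a per-gene-mean mode exposed;
the exact null distribution is used when both groups have ≤ 12
untied observations, otherwise the tie-corrected normal approximation
with continuity correction. Over-representation is the upper
hypergeometric tail of the query/set overlap within the universe of
all variant-carrying genes seen in the run, with Benjamini–Hochberg
FDR across sets. Gene sets are user-supplied GMT files; no pathway
database is bundled or downloaded.

## Autozygosity HMM

States are (IBD, non-IBD) with stationary distribution (f, 1 − f).
Over genetic distance d (Morgans), P(IBD→IBD) = e^(−a·d) +
(1 − e^(−a·d))·f and P(non→IBD) = (1 − e^(−a·d))·f; chromosome
boundaries are treated as d = ∞, so chromosomes are independent chains
started at stationarity (this also makes the likelihood invariant to
chromosome ordering). Emissions are Hardy–Weinberg at the marker's
allele frequency q outside IBD and (1−q, 0, q) inside, mixed with a
genotyping-error weight ε (default 10⁻³) so a stray heterozygote
inside a tract does not zero the likelihood; missing genotypes are
uninformative.

(f, a) are fitted jointly by a batched nested grid search: 4 rounds of
an 11 × 7 grid over f ∈ [0, 0.5] and log a, a ∈ [0.01, 10] per Morgan,
each round shrinking the window around the incumbent by a factor 0.35.
f = 0 is always a grid point, so the boundary is exactly reachable and
the final f-resolution (~10⁻³) is far inside the ±0.03 validation
band. The null f = 0 has the closed-form log-likelihood Σ log HWE, and
the LRT p-value uses the boundary mixture ½χ²₀ + ½χ²₁ (p = 1 exactly
when f̂ = 0). The subsample protocol draws `n_subsamples` = 100 marker
subsets of exactly 3,900 (genomic order preserved, without
replacement) and reports the median f̂ alongside the full-panel fit.
LD pruning is the caller's responsibility; the panel loader only warns
on zero adjacent genetic distance.

The scaled forward pass is vectorised across parameter grids and
replicates (`estimate_f_many`), which is what makes the 200-replicate
× 3,900-marker recovery study run in tens of seconds on one CPU.

## Synthetic data

The simulator emulates the statistical structure the analysis assumes:
a Beta(0.5, 5) site-frequency spectrum truncated to (0.001, 0.5),
Hardy–Weinberg parents, Mendelian children, injected de novo /
recessive / compound-het / shared-recessive events in reserved genes,
Poisson depth around `mean_depth` = 100 (exome scale), binomial
allele-depth noise, and PL/GQ derived from binomial read likelihoods
with base error 10⁻³. Injected de novo sites carry no population MAF,
matching how genuinely new alleles appear in frequency references. Two
deterministic modes exist for exact-count validation: noise-free
evidence (exact depth split) and a carrier-free decoy background (at
most one het parent, so no background site can be recessive or de
novo). Truth tables label compound-het membership only where the
parental phase is transmission-resolvable — the same definition the
detector uses — so round-trip recall/precision 1.0 is a sharp
contract.

What the simulator does **not** emulate: linkage between exome sites,
haplotype structure, mapping or capture artefacts, multi-allelic
sites, indel realignment errors, or joint-calling batch effects.
Passing recovery tests therefore validates the segregation logic and
evidence handling, not robustness to upstream calling artefacts.

The bundled reference fixtures (`trioseg.reference_data`) encode the
per-trio result structure of the three-family study this pipeline
models — the printed variant coordinates, qualities, depths,
SIFT/PolyPhen/MAF values and category memberships — as noise-free
synthetic VCFs. Where the source tables print no per-variant score,
fixtures assign deterministic scores consistent with the study's
aggregate flagged fraction. A JSON manifest records every expected
count.

## Numerical and degenerate-input choices

* Multi-allelic sites are split to biallelic records before filtering;
  per-alt AD/PL are subset (PL renormalised to min 0) and non-focal
  alternate alleles collapse onto the reference, contributing to depth
  only.
* Positions are 1-based VCF coordinates end to end.
* Posterior computation normalises over all 27 triples; a degenerate
  all-zero mass raises rather than returning NaNs.
* The forward recursion rescales per marker; chains hitting zero mass
  (impossible under ε > 0 grids) propagate −∞ log-likelihood, and the
  fitter raises on non-finite optima.
* Fewer than 100 informative markers is an error for `fit()`; a panel
  smaller than the subsample size falls back to one full-panel fit
  with a warning.
* Empty inputs (no records, no calls, < 2 trios) produce empty
  reports, not errors; empty test groups and empty ORA queries raise.
* All outputs sort deterministically (gene, then chrom:pos, then
  trio), so identical configurations reproduce byte-identical files.

## Validation design

Each operation is checked against an independent oracle: the trio
posterior against a literal 27-state triple loop; the forward
algorithm against exhaustive 2ⁿ hidden-path enumeration on ≤ 12
markers; the rank test against full-enumeration exact p-values and a
100,000-permutation oracle under ties; ORA against explicit binomial-
coefficient tail sums; the classifier's Mendelian-error set against
the μ = 0 transmission table; and the estimator against parameter
recovery (bias within ±0.03 at f ∈ {0, 0.0625, 0.25}, 200 replicates
of 3,900 markers, true a = 5 per Morgan). Problem sizes — a few
hundred variants per simulated dataset, 200 replicates, 3,900-marker
panels — were chosen as the smallest scales at which these properties
are sharply testable.
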