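"""Maximum-likelihood inbreeding estimation under a two-state autozygosity HMM.

The hidden state at each marker is autozygous (IBD, both alleles copies
of one ancestral allele) or not. The chain is parameterised by the
inbreeding coefficient ``f`` (stationary IBD probability) and a rate
``a`` (per Morgan) governing IBD-tract length: over a genetic distance
``d`` the transition probabilities are

    P(IBD -> IBD)    = e^(-a d) + (1 - e^(-a d)) f
    P(nonIBD -> IBD) =            (1 - e^(-a d)) f

so the stationary distribution is (f, 1 - f) and chromosomes (distance
reset to infinity) start at stationarity and contribute independent
chains. Emissions at a marker with alternate-allele frequency q are
Hardy-Weinberg in the non-IBD state and allele-frequency homozygote
probabilities in the IBD state, mixed with a small genotyping-error
weight ``eps`` so that stray heterozygotes do not zero the likelihood.

``f`` and ``a`` are fitted jointly by a nested grid search (coarse grid
refined around the incumbent), the null ``f = 0`` has the closed-form
log-likelihood sum of per-marker HWE terms, and the boundary LRT p-value
uses the half-chi-square mixture ½·χ²₀ + ½·χ²₁.

The interface is statsmodels-flavoured: an :class:`InbreedingHMM` model
is built from genotypes + panel and ``fit()`` (or ``fit_subsampled()``
for the 100-subsample median protocol) returns an
:class:`InbreedingResults` with estimates, the LRT and ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("trioseg")

# genotype codes
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, 3

PANEL_COLUMNS = ("chrom", "pos", "q", "cm")


@dataclass(frozen=True)
class HMMParams:
    """Autozygosity HMM parameters."""

    f: float        # inbreeding coefficient, stationary IBD mass
    a: float        # rate per Morgan governing IBD-tract length
    eps: float = 0.0  # genotyping-error mixing weight

    def __post_init__(self) -> None:
        if not (0.0 <= self.f < 1.0):
            raise ValueError("f must lie in [0, 1)")
        if self.a <= 0:
            raise ValueError("a must be > 0")
        if not (0.0 <= self.eps <= 0.05):
            raise ValueError("eps must lie in [0, 0.05]")


class MarkerPanel:
    """Genotyping panel: positions, allele frequencies, genetic map.

    Markers must be sorted by (chromosome block, position); ``cm`` is the
    cumulative genetic position within its chromosome in centimorgans.
    Inter-marker distances (in Morgans) reset to infinity across
    chromosome boundaries, which makes chromosomes independent chains
    started at the stationary distribution.
    """

    def __init__(self, chrom, pos, q, cm):
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.q = np.asarray(q, dtype=float)
        self.cm = np.asarray(cm, dtype=float)
        n = self.pos.size
        if not (self.chrom.size == self.q.size == self.cm.size == n):
            raise ValueError("panel columns must have equal length")
        if np.any((self.q <= 0) | (self.q >= 1)):
            raise ValueError("allele frequencies must lie strictly in (0, 1)")
        for arr in (self.pos, self.cm):
            same = self.chrom[1:] == self.chrom[:-1]
            if np.any(same & (arr[1:] < arr[:-1])):
                raise ValueError("markers must be sorted within chromosomes")
        self.d = self._chain_distances()
        if np.any(self.d[np.isfinite(self.d)] == 0.0):
            logger.warning(
                "panel contains adjacent markers at zero genetic distance; "
                "estimates assume markers in minimal linkage disequilibrium"
            )

    def _chain_distances(self) -> np.ndarray:
        d = np.full(self.pos.size, np.inf)
        if self.pos.size > 1:
            same = self.chrom[1:] == self.chrom[:-1]
            d[1:][same] = (self.cm[1:][same] - self.cm[:-1][same]) / 100.0
        return d

    def __len__(self) -> int:
        return int(self.pos.size)

    def subset(self, idx: Sequence[int]) -> "MarkerPanel":
        idx = np.sort(np.asarray(idx, dtype=np.int64))  # preserve genomic order
        return MarkerPanel(self.chrom[idx], self.pos[idx], self.q[idx], self.cm[idx])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MarkerPanel":
        return cls(df["chrom"].to_numpy(), df["pos"].to_numpy(),
                   df["q"].to_numpy(), df["cm"].to_numpy())

    @classmethod
    def read(cls, path) -> "MarkerPanel":
        return cls.from_dataframe(pd.read_csv(path, sep="\t"))

    def write(self, path) -> None:
        pd.DataFrame(
            {"chrom": self.chrom, "pos": self.pos, "q": self.q, "cm": self.cm}
        ).to_csv(path, sep="\t", index=False)


def transition_matrix(params: HMMParams, d: float) -> np.ndarray:
    """2x2 transition probabilities over genetic distance d (Morgans).

    State order (IBD, non-IBD); rows sum to 1; d = 0 gives the identity
    and d -> inf the stationary rows (f, 1 - f).
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    r = np.exp(-params.a * d)
    f = params.f
    return np.array(
        [
            [r + (1 - r) * f, (1 - r) * (1 - f)],
            [(1 - r) * f, r + (1 - r) * (1 - f)],
        ]
    )


def emission_probs(genotype: int, q: float, eps: float = 0.0) -> np.ndarray:
    """Emission probability of a genotype in the (IBD, non-IBD) states.

    Non-IBD: Hardy-Weinberg at q. IBD: (1-eps)*(1-q, 0, q) + eps*HWE.
    A missing genotype is uninformative (1, 1).
    """
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie strictly in (0, 1)")
    if genotype == MISSING:
        return np.ones(2)
    hwe = [(1 - q) ** 2, 2 * q * (1 - q), q ** 2]
    ibd = [(1 - q), 0.0, q]
    g = int(genotype)
    return np.array([(1 - eps) * ibd[g] + eps * hwe[g], hwe[g]])


def _emissions(gt: np.ndarray, q: np.ndarray, eps: float):
    """e_ibd, e_non with shape gt.shape (gt codes 0/1/2, else missing)."""
    codes = np.where((gt >= 0) & (gt <= 2), gt, 3).astype(np.int64)
    hwe_rows = np.stack([(1 - q) ** 2, 2 * q * (1 - q), q ** 2, np.ones_like(q)])
    ibd_rows = np.stack([1 - q, np.zeros_like(q), q, np.ones_like(q)])
    mix_rows = (1 - eps) * ibd_rows + eps * hwe_rows
    mix_rows[3] = 1.0
    n = q.size
    e_ibd = mix_rows[codes, np.arange(n)] if codes.ndim == 1 else \
        mix_rows[codes, np.arange(n)[None, :]]
    e_non = hwe_rows[codes, np.arange(n)] if codes.ndim == 1 else \
        hwe_rows[codes, np.arange(n)[None, :]]
    return e_ibd, e_non


def _forward_batch(
    e_ibd: np.ndarray,
    e_non: np.ndarray,
    d: np.ndarray,
    f: np.ndarray,
    a: np.ndarray,
) -> np.ndarray:
    """Scaled forward log-likelihood, broadcast over parameter arrays.

    ``e_ibd``/``e_non`` have shape (..., n) broadcastable against the
    shape of ``f``/``a`` (e.g. replicates x grid); returns log-likelihood
    with the broadcast shape. ``d[0]`` must be inf so the first marker
    starts each chain at the stationary distribution.
    """
    f = np.asarray(f, dtype=float)
    a = np.asarray(a, dtype=float)
    shape = np.broadcast_shapes(f.shape, a.shape, e_ibd.shape[:-1])
    alpha0 = np.zeros(shape)
    alpha1 = np.ones(shape)
    ll = np.zeros(shape)
    n = d.size
    with np.errstate(divide="ignore", invalid="ignore", under="ignore"):
        for i in range(n):
            r = np.exp(-a * d[i]) if np.isfinite(d[i]) else 0.0
            t_ii = r + (1 - r) * f
            t_ni = (1 - r) * f
            n0 = (alpha0 * t_ii + alpha1 * t_ni) * e_ibd[..., i]
            n1 = (alpha0 * (1 - t_ii) + alpha1 * (1 - t_ni)) * e_non[..., i]
            s = n0 + n1
            ok = s > 0
            ll = np.where(ok, ll + np.log(np.where(ok, s, 1.0)), -np.inf)
            safe = np.where(ok, s, 1.0)
            alpha0 = np.where(ok, n0 / safe, 0.0)
            alpha1 = np.where(ok, n1 / safe, 1.0)
    return ll


def forward_loglik(
    genotypes: Sequence[int], panel: MarkerPanel, params: HMMParams
) -> float:
    """Log-likelihood of one individual's panel genotypes."""
    gt = np.asarray(genotypes)
    if gt.size != len(panel):
        raise ValueError("genotype vector length must match panel size")
    e_ibd, e_non = _emissions(gt, panel.q, params.eps)
    return float(
        _forward_batch(e_ibd, e_non, panel.d, np.float64(params.f),
                       np.float64(params.a))
    )


def null_loglik(genotypes: Sequence[int], panel: MarkerPanel) -> float:
    """Closed-form log-likelihood at f = 0 (pure Hardy-Weinberg)."""
    gt = np.asarray(genotypes)
    _e_ibd, e_non = _emissions(gt, panel.q, 0.0)
    with np.errstate(divide="ignore"):
        terms = np.log(e_non)
    return float(terms.sum())


@dataclass
class InbreedingResults:
    """Fitted autozygosity HMM: estimates, LRT, subsample protocol."""

    f_hat: float
    a_hat: float
    loglik_hat: float
    loglik_f0: float
    lrt_statistic: float
    p_value: float
    n_markers: int
    eps: float
    subsample_estimates: List[float] = field(default_factory=list)
    f_median: Optional[float] = None

    def summary(self) -> str:
        lines = [
            "Autozygosity HMM inbreeding estimate",
            "=" * 44,
            f"markers used          {self.n_markers:>12d}",
            f"f_hat                 {self.f_hat:>12.5f}",
            f"a_hat (per Morgan)    {self.a_hat:>12.4f}",
            f"eps                   {self.eps:>12.4g}",
            f"log-likelihood        {self.loglik_hat:>12.3f}",
            f"log-likelihood (f=0)  {self.loglik_f0:>12.3f}",
            f"LRT statistic         {self.lrt_statistic:>12.4f}",
            f"p (0.5*chi2_0 + 0.5*chi2_1)  {self.p_value:>12.6f}",
        ]
        if self.f_median is not None:
            lines += [
                f"subsamples            {len(self.subsample_estimates):>12d}",
                f"f median              {self.f_median:>12.5f}",
            ]
        return "\n".join(lines)


def _boundary_p(lrt: float) -> float:
    # f on its boundary: T ~ 0.5*chi2_0 + 0.5*chi2_1 under H0.
    if lrt <= 0:
        return 1.0
    return float(0.5 * sps.chi2.sf(lrt, df=1))


class InbreedingHMM:
    """Two-state autozygosity HMM for one individual.

    Parameters
    ----------
    genotypes : sequence of int
        Genotype codes aligned to the panel markers (0 hom-ref, 1 het,
        2 hom-alt, anything else missing).
    panel : MarkerPanel
    eps : float
        Genotyping-error mixing weight (default 1e-3).
    """

    F_MAX = 0.5
    A_BOUNDS = (0.01, 10.0)

    def __init__(self, genotypes, panel: MarkerPanel, eps: float = 1e-3):
        self.genotypes = np.asarray(genotypes)
        if self.genotypes.size != len(panel):
            raise ValueError("genotype vector length must match panel size")
        self.panel = panel
        self.eps = float(eps)
        self.n_informative = int(
            ((self.genotypes >= 0) & (self.genotypes <= 2)).sum()
        )

    def loglike(self, f: float, a: float) -> float:
        return forward_loglik(
            self.genotypes, self.panel, HMMParams(f=f, a=a, eps=self.eps)
        )

    def fit(self, min_informative: int = 100) -> InbreedingResults:
        """Joint (f, a) maximum likelihood via nested grid refinement."""
        if self.n_informative < min_informative:
            raise ValueError(
                f"need >= {min_informative} informative markers, "
                f"have {self.n_informative}"
            )
        e_ibd, e_non = _emissions(self.genotypes, self.panel.q, self.eps)
        f_hat, a_hat, ll_hat = _grid_fit(
            e_ibd[None, :], e_non[None, :], self.panel.d,
            self.F_MAX, self.A_BOUNDS,
        )
        ll_hat = float(ll_hat[0])
        ll0 = null_loglik(self.genotypes, self.panel)
        if not np.isfinite(ll_hat) or not np.isfinite(ll0):
            raise RuntimeError(
                "likelihood optimisation failed: non-finite log-likelihood "
                f"(ll_hat={ll_hat}, ll0={ll0})"
            )
        ll_hat = max(ll_hat, ll0)  # f=0 is in the parameter space
        lrt = max(2.0 * (ll_hat - ll0), 0.0)
        return InbreedingResults(
            f_hat=float(f_hat[0]),
            a_hat=float(a_hat[0]),
            loglik_hat=float(ll_hat),
            loglik_f0=float(ll0),
            lrt_statistic=float(lrt),
            p_value=_boundary_p(lrt),
            n_markers=self.n_informative,
            eps=self.eps,
        )

    def fit_subsampled(
        self,
        n_subsamples: int = 100,
        subsample_size: int = 3900,
        seed: Optional[int] = None,
    ) -> InbreedingResults:
        """Median-of-subsamples protocol on top of the full-panel fit.

        ``n_subsamples`` random marker subsets of ``subsample_size`` are
        drawn without replacement (genomic order preserved); f is fitted
        on each and the median reported alongside the full-panel fit.
        Reproducible given ``seed``. A panel smaller than the subsample
        size falls back to the full panel once, with a warning.
        """
        full = self.fit()
        n = len(self.panel)
        if n < subsample_size:
            logger.warning(
                "panel (%d markers) smaller than subsample size %d; "
                "using the full panel once", n, subsample_size,
            )
            full.subsample_estimates = [full.f_hat]
            full.f_median = full.f_hat
            return full
        rng = np.random.default_rng(seed)
        estimates: List[float] = []
        for _ in range(n_subsamples):
            idx = rng.choice(n, size=subsample_size, replace=False)
            sub_panel = self.panel.subset(idx)
            sub = InbreedingHMM(
                self.genotypes[np.sort(idx)], sub_panel, eps=self.eps
            ).fit()
            estimates.append(sub.f_hat)
        full.subsample_estimates = estimates
        full.f_median = float(np.median(estimates))
        return full


def _grid_fit(
    e_ibd: np.ndarray,
    e_non: np.ndarray,
    d: np.ndarray,
    f_max: float,
    a_bounds: Tuple[float, float],
    n_refine: int = 4,
    n_f: int = 11,
    n_a: int = 7,
):
    """Batched nested grid search over (f, log a) for R replicates.

    ``e_ibd``/``e_non`` have shape (R, n). Returns (f_hat, a_hat, ll_hat)
    arrays of length R. Each refinement round shrinks the search window
    around the incumbent by a factor 0.35 (log-space for a), clipped to
    the bounds; f = 0 is always a candidate so the boundary is exactly
    reachable.
    """
    R = e_ibd.shape[0]
    f_lo = np.zeros(R)
    f_hi = np.full(R, f_max)
    la_lo = np.full(R, np.log(a_bounds[0]))
    la_hi = np.full(R, np.log(a_bounds[1]))
    best_f = np.zeros(R)
    best_a = np.full(R, np.exp(0.5 * (la_lo + la_hi)))
    best_ll = np.full(R, -np.inf)

    for _ in range(n_refine):
        f_offsets = np.linspace(0.0, 1.0, n_f)
        a_offsets = np.linspace(0.0, 1.0, n_a)
        f_grid = f_lo[:, None] + (f_hi - f_lo)[:, None] * f_offsets[None, :]
        la_grid = la_lo[:, None] + (la_hi - la_lo)[:, None] * a_offsets[None, :]
        # cartesian product per replicate -> (R, n_f*n_a)
        ff = np.repeat(f_grid, n_a, axis=1)
        aa = np.exp(np.tile(la_grid, (1, n_f)))
        ll = _forward_batch(e_ibd[:, None, :], e_non[:, None, :], d, ff, aa)
        arg = np.argmax(ll, axis=1)
        take = np.arange(R)
        improved = ll[take, arg] > best_ll
        best_f = np.where(improved, ff[take, arg], best_f)
        best_a = np.where(improved, aa[take, arg], best_a)
        best_ll = np.where(improved, ll[take, arg], best_ll)
        # shrink windows around the incumbent
        f_span = (f_hi - f_lo) * 0.35
        la_span = (la_hi - la_lo) * 0.35
        f_lo = np.clip(best_f - f_span / 2, 0.0, f_max)
        f_hi = np.clip(best_f + f_span / 2, 0.0, f_max)
        la_lo_new = np.clip(np.log(best_a) - la_span / 2,
                            np.log(a_bounds[0]), np.log(a_bounds[1]))
        la_hi_new = np.clip(np.log(best_a) + la_span / 2,
                            np.log(a_bounds[0]), np.log(a_bounds[1]))
        la_lo, la_hi = la_lo_new, la_hi_new
    return best_f, best_a, best_ll


def estimate_f(
    genotypes, panel: MarkerPanel, eps: float = 1e-3
) -> InbreedingResults:
    """Single-panel maximum-likelihood fit (functional wrapper)."""
    return InbreedingHMM(genotypes, panel, eps=eps).fit()


def subsample_median_estimate(
    genotypes,
    panel: MarkerPanel,
    n_subsamples: int = 100,
    subsample_size: int = 3900,
    seed: Optional[int] = None,
    eps: float = 1e-3,
) -> InbreedingResults:
    """Median-of-subsamples estimate (functional wrapper)."""
    return InbreedingHMM(genotypes, panel, eps=eps).fit_subsampled(
        n_subsamples=n_subsamples, subsample_size=subsample_size, seed=seed
    )


def estimate_f_many(
    genotype_matrix: np.ndarray, panel: MarkerPanel, eps: float = 1e-3
):
    """Fit many individuals that share one panel in a single batched pass.

    ``genotype_matrix`` has shape (replicates, n_markers). Returns
    (f_hat, a_hat, lrt, p) arrays. Used for simulation studies where
    per-replicate model objects would be needlessly slow.
    """
    gt = np.asarray(genotype_matrix)
    if gt.ndim != 2 or gt.shape[1] != len(panel):
        raise ValueError("genotype matrix must be (replicates, n_markers)")
    e_ibd, e_non = _emissions(gt, panel.q, eps)
    f_hat, a_hat, ll_hat = _grid_fit(
        e_ibd, e_non, panel.d, InbreedingHMM.F_MAX, InbreedingHMM.A_BOUNDS
    )
    _e0, e_non0 = _emissions(gt, panel.q, 0.0)
    with np.errstate(divide="ignore"):
        ll0 = np.log(e_non0).sum(axis=1)
    ll_hat = np.maximum(ll_hat, ll0)
    lrt = np.maximum(2.0 * (ll_hat - ll0), 0.0)
    p = np.where(lrt <= 0, 1.0, 0.5 * sps.chi2.sf(lrt, df=1))
    return f_hat, a_hat, lrt, p
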