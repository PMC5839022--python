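"""Autozygosity HMM: transitions, emissions, forward algorithm, fitting."""

import itertools

import numpy as np
import pytest

from trioseg.inbreeding import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    HMMParams,
    MarkerPanel,
    emission_probs,
    estimate_f,
    estimate_f_many,
    forward_loglik,
    null_loglik,
    subsample_median_estimate,
    transition_matrix,
)
from trioseg.simulate import (
    make_marker_panel,
    simulate_inbred_genotypes,
    simulate_inbred_genotypes_many,
)


class TestTransitionMatrix:
    def test_zero_distance_identity(self):
        P = transition_matrix(HMMParams(f=0.2, a=3.0), 0.0)
        np.testing.assert_allclose(P, np.eye(2))

    def test_large_distance_reaches_stationarity(self):
        f = 0.3
        P = transition_matrix(HMMParams(f=f, a=2.0), 1e6)
        np.testing.assert_allclose(P, [[f, 1 - f], [f, 1 - f]], atol=1e-12)

    def test_f_zero_only_persistence_enters_ibd(self):
        P = transition_matrix(HMMParams(f=0.0, a=2.0), 0.5)
        assert P[1, 0] == 0.0
        assert P[0, 0] == pytest.approx(np.exp(-1.0))

    def test_rows_sum_to_one(self):
        for f, a, d in [(0.1, 0.5, 0.01), (0.4, 8.0, 2.0), (0.0, 1.0, 0.3)]:
            P = transition_matrix(HMMParams(f=f, a=a), d)
            np.testing.assert_allclose(P.sum(axis=1), [1.0, 1.0])


class TestEmissions:
    def test_het_impossible_under_ibd_without_error(self):
        e = emission_probs(HET, q=0.3, eps=0.0)
        assert e[0] == 0.0
        assert e[1] == pytest.approx(2 * 0.3 * 0.7)

    def test_hom_alt_closed_form(self):
        e = emission_probs(HOM_ALT, q=0.5, eps=0.0)
        np.testing.assert_allclose(e, [0.5, 0.25])

    def test_states_normalise_over_genotypes(self):
        for q in (0.05, 0.3, 0.49):
            for eps in (0.0, 1e-3, 0.02):
                sums = sum(
                    emission_probs(g, q, eps) for g in (HOM_REF, HET, HOM_ALT)
                )
                np.testing.assert_allclose(sums, [1.0, 1.0])

    def test_missing_uninformative_and_bad_q_rejected(self):
        np.testing.assert_allclose(emission_probs(MISSING, 0.2), [1.0, 1.0])
        with pytest.raises(ValueError):
            emission_probs(HET, 0.0)


def exhaustive_loglik(gt, panel, params):
    """Sum over all 2^n hidden paths (oracle for the forward algorithm)."""
    n = len(panel)
    total = 0.0
    for path in itertools.product([0, 1], repeat=n):
        p = 1.0
        for i, s in enumerate(path):
            d = panel.d[i]
            if not np.isfinite(d):
                prior = params.f if s == 0 else 1.0 - params.f
            else:
                prior = transition_matrix(params, d)[path[i - 1], s]
            p *= prior * emission_probs(int(gt[i]), panel.q[i], params.eps)[s]
        total += p
    return np.log(total)


class TestForward:
    def test_matches_exhaustive_path_enumeration(self):
        panel = make_marker_panel(n_markers=12, n_chrom=3,
                                  total_length_cm=60, seed=1)
        rng = np.random.default_rng(2)
        gt = rng.integers(0, 3, size=12)
        gt[4] = MISSING
        for f, a, eps in [(0.0, 1.0, 0.0), (0.25, 5.0, 1e-3),
                          (0.45, 0.2, 0.02)]:
            params = HMMParams(f=f, a=a, eps=eps)
            assert forward_loglik(gt, panel, params) == pytest.approx(
                exhaustive_loglik(gt, panel, params), abs=1e-10
            )

    def test_f_zero_equals_hwe_closed_form(self):
        panel = make_marker_panel(n_markers=200, seed=3)
        gt = np.random.default_rng(4).integers(0, 3, size=200)
        ll = forward_loglik(gt, panel, HMMParams(f=0.0, a=1.0, eps=0.0))
        hwe = null_loglik(gt, panel)
        assert ll == pytest.approx(hwe, abs=1e-9)

    def test_all_het_individual_penalises_positive_f(self):
        panel = make_marker_panel(n_markers=300, seed=5)
        gt = np.full(300, HET)
        ll0 = null_loglik(gt, panel)
        for f in (0.05, 0.2, 0.45):
            assert forward_loglik(
                gt, panel, HMMParams(f=f, a=1.0, eps=0.0)
            ) < ll0

    def test_invariant_to_chromosome_order(self):
        panel = make_marker_panel(n_markers=60, n_chrom=4,
                                  total_length_cm=200, seed=6)
        gt = np.random.default_rng(7).integers(0, 3, size=60)
        params = HMMParams(f=0.2, a=2.0, eps=1e-3)
        base = forward_loglik(gt, panel, params)
        # rotate whole chromosome blocks
        order = []
        for c in ["chr3", "chr1", "chr4", "chr2"]:
            order += list(np.where(panel.chrom == c)[0])
        permuted = MarkerPanel(panel.chrom[order], panel.pos[order],
                               panel.q[order], panel.cm[order])
        assert forward_loglik(gt[order], permuted, params) == pytest.approx(
            base, abs=1e-9
        )

    def test_length_mismatch_rejected(self):
        panel = make_marker_panel(n_markers=10, n_chrom=2,
                                  total_length_cm=10, seed=1)
        with pytest.raises(ValueError):
            forward_loglik([0, 1], panel, HMMParams(f=0.1, a=1.0))


class TestEstimation:
    def test_recovers_first_cousin_scale_f(self):
        panel = make_marker_panel(n_markers=3900, seed=11)
        gt, _ibd = simulate_inbred_genotypes(panel, f=0.25, a=5.0, seed=12)
        res = estimate_f(gt, panel)
        assert res.f_hat == pytest.approx(0.25, abs=0.05)
        assert res.p_value < 1e-6
        assert res.lrt_statistic >= 0.0
        assert "f_hat" in res.summary()

    def test_outbred_individual_fits_to_boundary(self):
        panel = make_marker_panel(n_markers=3900, seed=13)
        gt, ibd = simulate_inbred_genotypes(panel, f=0.0, a=5.0, seed=14)
        assert ibd.sum() == 0
        res = estimate_f(gt, panel)
        assert res.f_hat <= 0.01
        assert res.p_value > 0.05
        if res.f_hat == 0.0:
            assert res.lrt_statistic == 0.0 and res.p_value == 1.0

    def test_too_few_informative_markers_rejected(self):
        panel = make_marker_panel(n_markers=50, n_chrom=2,
                                  total_length_cm=100, seed=15)
        with pytest.raises(ValueError, match="informative"):
            estimate_f(np.zeros(50, dtype=int), panel)

    def test_subsample_protocol_deterministic(self):
        panel = make_marker_panel(n_markers=1200, seed=16)
        gt, _ = simulate_inbred_genotypes(panel, f=0.25, a=5.0, seed=17)
        r1 = subsample_median_estimate(gt, panel, n_subsamples=8,
                                       subsample_size=600, seed=42)
        r2 = subsample_median_estimate(gt, panel, n_subsamples=8,
                                       subsample_size=600, seed=42)
        assert r1.subsample_estimates == r2.subsample_estimates
        assert r1.f_median == np.median(r1.subsample_estimates)
        assert len(r1.subsample_estimates) == 8

    def test_subsample_larger_than_panel_falls_back(self):
        panel = make_marker_panel(n_markers=400, seed=18)
        gt, _ = simulate_inbred_genotypes(panel, f=0.1, a=5.0, seed=19)
        res = subsample_median_estimate(gt, panel, n_subsamples=5,
                                        subsample_size=5000, seed=1)
        assert res.subsample_estimates == [res.f_hat]
        assert res.f_median == res.f_hat


class TestSimulatedAutozygosity:
    def test_outbred_has_no_ibd_and_hwe_het_rate(self):
        panel = make_marker_panel(n_markers=10_000, seed=21)
        gt, ibd = simulate_inbred_genotypes(panel, f=0.0, a=5.0, seed=22)
        assert not ibd.any()
        expected = np.mean(2 * panel.q * (1 - panel.q))
        se = np.sqrt(expected * (1 - expected) / len(panel))
        assert abs((gt == HET).mean() - expected) < 3 * se

    def test_stationary_ibd_mass(self):
        panel = make_marker_panel(n_markers=10_000, seed=23)
        _gt, ibd = simulate_inbred_genotypes_many(panel, 0.25, 5.0, 20, seed=24)
        assert abs(ibd.mean() - 0.25) < 0.03

    def test_ibd_markers_never_heterozygous_without_error(self):
        panel = make_marker_panel(n_markers=5_000, seed=25)
        gt, ibd = simulate_inbred_genotypes(panel, f=0.3, a=5.0, seed=26)
        assert not (gt[ibd] == HET).any()

    def test_batched_fit_matches_single_fit(self):
        panel = make_marker_panel(n_markers=1500, seed=27)
        gts, _ = simulate_inbred_genotypes_many(panel, 0.25, 5.0, 3, seed=28)
        f_many, a_many, lrt_many, _p = estimate_f_many(gts, panel)
        for i in range(3):
            single = estimate_f(gts[i], panel)
            assert f_many[i] == pytest.approx(single.f_hat, abs=1e-9)
            assert lrt_many[i] == pytest.approx(single.lrt_statistic, abs=1e-6)
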