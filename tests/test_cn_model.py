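"""Integer CN inference: prior, theta, candidates, likelihood, selection."""

import numpy as np
import pandas as pd
import pytest

from clonecn import cn_model
from clonecn.segmentation import Segmentation


def make_segments(ratios, w=None, chrom="chr1"):
    """Minimal Segmentation with given ratios and genomic fractions."""
    ratios = np.asarray(ratios, dtype=float)
    if w is None:
        w = np.full(len(ratios), 1.0 / len(ratios))
    w = np.asarray(w, dtype=float)
    length = (w * 3e8).astype(np.int64)
    start = np.concatenate([[0], np.cumsum(length)[:-1]])
    table = pd.DataFrame(
        {
            "chrom": [chrom] * len(ratios),
            "start": start,
            "end": start + length,
            "win_first": np.arange(len(ratios)),
            "win_last": np.arange(len(ratios)) + 1,
            "n_windows": np.ones(len(ratios), dtype=int),
            "ratio": ratios,
            "length": length,
            "w": w,
        }
    )
    return Segmentation(table)


class TestPriorProb:
    def test_zero_theta_gives_uniform(self):
        p = cn_model.prior_prob(np.zeros(5), np.array([0.3, 0.7]))
        assert np.allclose(p, 0.2)

    def test_hand_computed_three_state_prior(self):
        # Q={1,2,3}, theta=(1,1,1), w=0.5: softmax of (-0.5,-1.0,-1.5)
        p = cn_model.prior_prob(np.ones(3), np.array([0.5]))[0]
        assert np.allclose(p, [0.50648, 0.30720, 0.18632], atol=1e-4)

    def test_rows_normalize_for_random_parameters(self, rng):
        theta = rng.uniform(0, 3, size=8)
        w = rng.dirichlet(np.ones(12))
        p = cn_model.prior_prob(theta, w)
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_large_theta_does_not_overflow(self):
        p = cn_model.prior_prob(np.array([500.0, 1000.0]), np.array([1.0]))
        assert np.isfinite(p).all()


class TestEstimateTheta:
    def test_beats_dense_grid_for_single_segment_two_states(self):
        w = np.array([1.0])
        Q = np.array([1, 2])
        theta_hat, loss = cn_model.estimate_theta(w, Q)
        grid = np.linspace(0, 5, 200)
        gx, gy = np.meshgrid(grid, grid)
        best_grid = min(
            cn_model._theta_loss(np.array([a, b]), w)
            for a, b in zip(gx.ravel(), gy.ravel())
        )
        assert loss <= best_grid + 1e-9

    def test_deterministic_across_runs(self):
        w = np.array([0.5, 0.3, 0.2])
        Q = np.arange(1, 7)
        t1, l1 = cn_model.estimate_theta(w, Q)
        t2, l2 = cn_model.estimate_theta(w, Q)
        assert np.array_equal(t1, t2)
        assert l1 == l2

    def test_no_worse_than_random_multistart(self, rng):
        w = rng.dirichlet(np.ones(10))
        Q = np.arange(1, 7)
        _, loss = cn_model.estimate_theta(w, Q)
        restarts = min(
            cn_model._theta_loss(rng.uniform(0, 2, size=6), w)
            for _ in range(1000)
        )
        assert loss <= restarts + 1e-9


class TestBuildCandidates:
    def test_half_unit_ladder_from_half_unit_modes(self):
        segs = make_segments(
            [0.5, 0.5, 1.0, 1.0, 1.0, 1.5, 1.5],
        )
        cands = cn_model.build_candidates(segs.ratios, segs.w)
        assert any(
            c.delta == pytest.approx(0.5, abs=0.02)
            and c.mu1 == pytest.approx(0.5, abs=0.02)
            for c in cands
        )

    def test_unimodal_profile_falls_back_with_diploid_anchor(self):
        segs = make_segments([1.0, 1.0, 1.0, 1.0])
        cands = cn_model.build_candidates(segs.ratios, segs.w)
        assert any(c.delta == pytest.approx(0.5) for c in cands)
        assert any(
            c.delta == pytest.approx(0.5) and c.mu1 == pytest.approx(0.5)
            for c in cands
        )

    def test_quarter_spacing_from_close_modes(self):
        ratios = np.array([0.75] * 4 + [1.0] * 6 + [1.25] * 4)
        w = np.full(len(ratios), 1.0 / len(ratios))
        modes = cn_model.density_modes(ratios, w)
        gaps = np.diff(np.sort(modes))
        # explicit mode-distance oracle: some adjacent gap ~0.25
        assert any(abs(g - 0.25) < 0.05 for g in gaps)
        cands = cn_model.build_candidates(ratios, w)
        assert any(abs(c.delta - 0.25) < 0.05 for c in cands)

    def test_all_deltas_below_one(self, rng):
        ratios = rng.uniform(0.4, 3.5, size=20)
        w = rng.dirichlet(np.ones(20))
        for c in cn_model.build_candidates(ratios, w):
            assert 0 < c.delta < 1


class TestFitAndSelect:
    def test_perfect_fit_hits_sigma_floor_and_wins(self):
        segs = make_segments([0.5, 1.0, 1.5], w=[0.2, 0.5, 0.3])
        theta, _ = cn_model.estimate_theta(segs.w, np.arange(1, 9), segs.ratios)
        cands = cn_model.build_candidates(segs.ratios, segs.w)
        fits = [cn_model.fit_model(segs, c, theta) for c in cands]
        best = cn_model.select_by_aic(fits, segs)
        # the half-unit ladder wins, drives sigma^2 to its floor, and its
        # log-likelihood is maximal across all fitted candidates
        assert best.candidate.delta == pytest.approx(0.5, abs=0.01)
        assert best.candidate.mu1 == pytest.approx(0.5, abs=0.01)
        assert best.sigma2 <= 10 * cn_model.SIGMA2_FLOOR
        assert best.logL == pytest.approx(max(f.logL for f in fits), abs=1e-6)

    def test_optimum_beats_random_sigma_draws(self, rng):
        segs = make_segments(
            [0.52, 0.98, 1.49, 1.03, 1.55], w=[0.1, 0.3, 0.2, 0.3, 0.1]
        )
        theta, _ = cn_model.estimate_theta(segs.w, np.arange(1, 9), segs.ratios)
        cand = cn_model.Candidate(0.5, 0.5)
        fit = cn_model.fit_model(segs, cand, theta, refine_mu1=False)
        for _ in range(500):
            s2 = rng.uniform(1e-6, 0.5)
            ll = cn_model._log_lik(
                segs.ratios, segs.w, cand.mu(8), s2, theta
            )
            assert fit.logL >= ll - 1e-6

    def test_single_segment_diploid_anchor_calls_cn2(self):
        segs = make_segments([1.0])
        theta, _ = cn_model.estimate_theta(segs.w, np.arange(1, 9), segs.ratios)
        fit = cn_model.fit_model(segs, cn_model.Candidate(0.5, 0.5), theta)
        prof = cn_model.posterior_cn(fit, segs)
        assert prof.cn[0] == 2
        assert prof.posterior[0, 1] == prof.posterior[0].max()

    def test_aic_ordering_equal_complexity(self):
        a = cn_model.CNModel(
            Q=np.arange(1, 9), theta=np.zeros(8), mu=np.arange(1, 9) * 0.5,
            sigma2=0.01, candidate=cn_model.Candidate(0.5, 0.5),
            logL=-10.0, aic=2 * 10 - 2 * -10.0, n_params=10,
        )
        b = cn_model.CNModel(
            Q=np.arange(1, 9), theta=np.zeros(8), mu=np.arange(1, 9) * 0.4,
            sigma2=0.01, candidate=cn_model.Candidate(0.4, 0.4),
            logL=-12.0, aic=2 * 10 - 2 * -12.0, n_params=10,
        )
        assert cn_model.select_by_aic([a, b]) is a

    def test_single_candidate_returned_unchanged(self):
        only = cn_model.CNModel(
            Q=np.arange(1, 9), theta=np.zeros(8), mu=np.arange(1, 9) * 0.5,
            sigma2=0.01, candidate=cn_model.Candidate(0.5, 0.5),
            logL=-1.0, aic=22.0, n_params=10,
        )
        assert cn_model.select_by_aic([only]) is only

    def test_true_spacing_beats_wrong_spacing_on_noiseless_levels(self):
        segs = make_segments(
            [0.5, 1.0, 1.5, 1.0, 0.5, 1.5], w=[0.1, 0.3, 0.1, 0.3, 0.1, 0.1]
        )
        theta, _ = cn_model.estimate_theta(segs.w, np.arange(1, 9), segs.ratios)
        good = cn_model.fit_model(segs, cn_model.Candidate(0.5, 0.5), theta)
        bad = cn_model.fit_model(segs, cn_model.Candidate(0.75, 0.25), theta)
        assert good.aic < bad.aic


class TestPosteriorAndPloidy:
    def test_ratio_at_state_mean_with_uniform_prior(self):
        segs = make_segments([1.0])
        fit = cn_model.CNModel(
            Q=np.arange(1, 9), theta=np.zeros(8),
            mu=np.arange(1, 9) * 0.5, sigma2=0.01,
            candidate=cn_model.Candidate(0.5, 0.5),
            logL=0.0, aic=0.0, n_params=10,
        )
        prof = cn_model.posterior_cn(fit, segs)
        assert prof.cn[0] == 2

    def test_hand_computed_posterior_with_skewed_prior(self):
        # Q={1,2,3}, mu=(0.5,1.0,1.5), sigma2=0.04, R midway between mu2,mu3
        # prior from theta=(1,1,1), w=0.5 favors q=2
        segs = make_segments([1.25], w=[0.5])
        segs.table["w"] = [0.5]
        fit = cn_model.CNModel(
            Q=np.array([1, 2, 3]), theta=np.ones(3),
            mu=np.array([0.5, 1.0, 1.5]), sigma2=0.04,
            candidate=cn_model.Candidate(0.5, 0.5),
            logL=0.0, aic=0.0, n_params=5,
        )
        prof = cn_model.posterior_cn(fit, segs)
        prior = cn_model.prior_prob(np.ones(3), np.array([0.5]))[0]
        lik = np.exp(-0.5 * (1.25 - fit.mu) ** 2 / 0.04)
        expected = prior * lik / np.sum(prior * lik)
        assert np.allclose(prof.posterior[0], expected, atol=1e-9)
        assert prof.cn[0] == 2

    def test_posterior_rows_sum_to_one(self, rng):
        segs = make_segments(rng.uniform(0.4, 2.5, size=12))
        theta, _ = cn_model.estimate_theta(segs.w, np.arange(1, 9), segs.ratios)
        fit = cn_model.fit_model(segs, cn_model.Candidate(0.5, 0.5), theta)
        prof = cn_model.posterior_cn(fit, segs)
        assert np.allclose(prof.posterior.sum(axis=1), 1.0)

    def test_ploidy_hand_sums(self):
        assert cn_model.compute_ploidy([2, 2], [0.5, 0.5]) == 2.0
        assert cn_model.compute_ploidy([2, 4], [0.5, 0.5]) == 3.0

    def test_ploidy_matches_brute_force(self, rng):
        cn = rng.integers(1, 9, size=20)
        w = rng.dirichlet(np.ones(20))
        expected = sum(float(a) * float(b) for a, b in zip(w, cn))
        assert cn_model.compute_ploidy(cn, w) == pytest.approx(expected)


class TestReliabilityScore:
    def _perfect(self, delta=0.5):
        segs = make_segments(
            [delta, 2 * delta, 3 * delta], w=[0.2, 0.6, 0.2]
        )
        model = cn_model.CNModel(
            Q=np.arange(1, 9), theta=np.zeros(8),
            mu=np.arange(1, 9) * delta, sigma2=1e-6,
            candidate=cn_model.Candidate(delta, delta),
            logL=0.0, aic=0.0, n_params=10,
        )
        prof = cn_model.posterior_cn(model, segs)
        return prof, model, segs

    def test_perfect_diploid_fit_scores_one(self):
        prof, model, segs = self._perfect(0.5)
        assert cn_model.reliability_score(prof, model, segs) == pytest.approx(1.0)

    def test_tiny_spacing_penalized(self):
        good = cn_model.reliability_score(*self._perfect(0.5))
        tight = cn_model.reliability_score(*self._perfect(0.1))
        assert tight < good

    def test_monotone_decreasing_along_noise_ladder(self, rng):
        base = np.array([0.5, 1.0, 1.0, 1.5, 1.0, 0.5])
        w = np.full(6, 1 / 6)
        scores = []
        for noise in (0.0, 0.05, 0.12, 0.2):
            ratios = base + rng.normal(0, 1, size=6) * 0 + noise * np.array(
                [1, -1, 1, -1, 1, -1]
            )
            segs = make_segments(ratios, w=w)
            model = cn_model.CNModel(
                Q=np.arange(1, 9), theta=np.zeros(8),
                mu=np.arange(1, 9) * 0.5, sigma2=0.01,
                candidate=cn_model.Candidate(0.5, 0.5),
                logL=0.0, aic=0.0, n_params=10,
            )
            prof = cn_model.posterior_cn(model, segs)
            scores.append(cn_model.reliability_score(prof, model, segs))
        assert scores == sorted(scores, reverse=True)
        assert scores[0] > scores[-1]


class TestFullInference:
    @pytest.mark.parametrize("delta", [0.25, 1.0 / 3.0, 0.5])
    def test_noiseless_exact_recovery(self, delta):
        """Planted diploid-anchored ladders are recovered with zero error."""
        mu1 = 1.0 - delta
        planted = np.array([1, 2, 3, 2, 4, 2, 1, 2])
        ratios = mu1 + (planted - 1) * delta
        w = np.array([0.05, 0.3, 0.1, 0.25, 0.05, 0.15, 0.05, 0.05])
        segs = make_segments(ratios, w=w)
        model, prof = cn_model.infer_clone_cn(segs)
        assert np.array_equal(prof.cn, planted)
        assert prof.ploidy == pytest.approx(float(np.sum(w * planted)))

    def test_scale_consistency_of_assignments(self):
        segs = make_segments([0.5, 1.0, 1.5, 1.0], w=[0.2, 0.4, 0.2, 0.2])
        model, prof = cn_model.infer_clone_cn(segs)
        scale = 1.3
        segs2 = make_segments(
            np.array([0.5, 1.0, 1.5, 1.0]) * scale, w=[0.2, 0.4, 0.2, 0.2]
        )
        model2, prof2 = cn_model.infer_clone_cn(segs2)
        assert np.array_equal(prof.cn, prof2.cn)

    def test_selected_model_comes_from_candidate_enumeration(self):
        segs = make_segments(
            [0.5, 1.0, 1.5, 1.0, 2.0], w=[0.1, 0.4, 0.2, 0.2, 0.1]
        )
        theta, _ = cn_model.estimate_theta(segs.w, np.arange(1, 9), segs.ratios)
        cands = cn_model.build_candidates(segs.ratios, segs.w)
        fits = [cn_model.fit_model(segs, c, theta) for c in cands]
        chosen = cn_model.select_by_aic(fits, segs)
        model, _ = cn_model.infer_clone_cn(segs)
        assert model.aic == pytest.approx(chosen.aic)
        assert model.candidate.delta == pytest.approx(chosen.candidate.delta)
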