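"""Cut-count matrix construction and the mixture-model footprint caller:
strand-frame correctness, EM behaviour against a brute-force Bayes oracle,
and occupancy profiles."""

import warnings

import numpy as np
import pytest
from scipy import stats

from thymoatac import footprinting as fp
from thymoatac import simulate as sim
from thymoatac.core import CutSiteTrack, GenomicInterval, PeakSet
from thymoatac.motif_scan import MotifOccurrence

L = 20  # small window for construction tests


def occ(start, strand="+", width=10, score=10.0, chrom="chr1"):
    return MotifOccurrence("m", GenomicInterval(chrom, start, start + width, strand),
                           score, 1e-5)


def track_from_dense(plus, minus, chrom="chr1"):
    return CutSiteTrack.from_dense("s", {chrom: (np.asarray(plus), np.asarray(minus))})


class TestBuildCutMatrix:
    def test_empty_track_all_zero(self):
        track = track_from_dense(np.zeros(500, int), np.zeros(500, int))
        mat = fp.build_cut_matrix([occ(100)], track, L=L)
        assert mat.counts.sum() == 0
        assert mat.counts.shape == (1, 2 * (2 * L + 1))

    def test_single_insertion_at_center_plus(self):
        plus = np.zeros(500, int)
        center = 100 + 10 // 2  # motif start 100, width 10
        plus[center] = 1
        track = track_from_dense(plus, np.zeros(500, int))
        mat = fp.build_cut_matrix([occ(100)], track, L=L)
        assert mat.counts[0, L] == 1  # forward-strand center column
        assert mat.counts.sum() == 1

    def test_minus_occurrence_strand_flip_oracle(self, rng):
        """A '-' occurrence over the mirrored (reverse-complemented) track
        yields the identical row.  Odd width keeps the center anchor exactly
        symmetric under mirroring."""
        width, n = 11, 1000
        plus = rng.poisson(0.5, n)
        minus = rng.poisson(0.5, n)
        track = track_from_dense(plus, minus)
        row_plus = fp.build_cut_matrix([occ(100, "+", width=width)], track,
                                       L=L).counts[0]
        # mirrored track: reverse coordinates, swap strands
        track_rc = track_from_dense(minus[::-1].copy(), plus[::-1].copy())
        start_rc = n - (100 + width)
        row_minus = fp.build_cut_matrix([occ(start_rc, "-", width=width)],
                                        track_rc, L=L).counts[0]
        np.testing.assert_array_equal(row_plus, row_minus)

    def test_edge_occurrences_dropped_with_warning(self):
        track = track_from_dense(np.zeros(60, int), np.zeros(60, int))
        with pytest.warns(UserWarning, match="dropped"):
            mat = fp.build_cut_matrix([occ(2), occ(30)], track, L=L)
        assert len(mat.occurrences) == 1

    def test_invalid_L_rejected(self):
        track = track_from_dense(np.zeros(10, int), np.zeros(10, int))
        with pytest.raises(ValueError):
            fp.build_cut_matrix([occ(5)], track, L=0)


def bayes_oracle(counts, scores, fit):
    """Independent posterior computation at the fitted parameters using
    scipy distributions and explicit per-row loops."""
    n, S = counts.shape
    post = np.zeros(n)
    for i in range(n):
        r = counts[i].sum()
        # NegBin(mu, phi) == scipy nbinom(n=phi, p=phi/(phi+mu))
        def lognb(mu, phi):
            return stats.nbinom.logpmf(r, phi, phi / (phi + mu))

        l1 = lognb(fit.mu1, fit.phi1) + np.sum(counts[i] * np.log(fit.tau))
        l0 = lognb(fit.mu0, fit.phi0) - r * np.log(S)
        eta = fit.beta[0] + fit.beta[1] * scores[i]
        log_prior_odds = eta
        post[i] = 1.0 / (1.0 + np.exp(-(log_prior_odds + l1 - l0)))
    return post


def _sim_matrix(n_bound, n_unbound, seed, **kw):
    shape = kw.pop("shape", sim.FootprintShape(depletion_depth=0.4))
    counts, is_bound, scores, prof = sim.simulate_cut_matrix(
        n_bound, n_unbound, shape,
        kw.pop("mu1", 200), kw.pop("phi1", 10),
        kw.pop("mu0", 20), kw.pop("phi0", 10), seed=seed)
    occs = [occ(1000 + 500 * i, width=14) for i in range(len(scores))]
    mat = fp.CutCountMatrix("m", occs, counts, shape.window_halfwidth)
    return mat, is_bound, scores, prof


class TestFitCentipede:
    def test_identical_rows_equal_posteriors(self):
        counts = np.tile(np.ones(402, dtype=int), (30, 1))
        occs = [occ(1000 + 500 * i, width=14) for i in range(30)]
        mat = fp.CutCountMatrix("m", occs, counts, 100)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fp.fit_centipede(mat, covariates=np.full(30, 10.0), seed=0)
        assert np.allclose(fit.posterior, fit.posterior[0])

    def test_posteriors_match_bayes_oracle(self):
        mat, _, scores, _ = _sim_matrix(25, 25, seed=3)
        fit = fp.fit_centipede(mat, covariates=scores, seed=0)
        oracle = bayes_oracle(mat.counts, scores, fit)
        np.testing.assert_allclose(fit.posterior, oracle, atol=1e-10)

    def test_loglik_trace_non_decreasing(self):
        mat, _, scores, _ = _sim_matrix(100, 100, seed=4)
        fit = fp.fit_centipede(mat, covariates=scores, seed=0)
        tr = np.array(fit.loglik_trace)
        assert np.all(np.diff(tr) >= -1e-8 * np.abs(tr[:-1]))

    def test_row_permutation_invariance(self):
        mat, _, scores, _ = _sim_matrix(40, 40, seed=5)
        fit = fp.fit_centipede(mat, covariates=scores, seed=0)
        perm = np.random.default_rng(1).permutation(80)
        mat2 = fp.CutCountMatrix("m", [mat.occurrences[i] for i in perm],
                                 mat.counts[perm], mat.L)
        fit2 = fp.fit_centipede(mat2, covariates=scores[perm], seed=0)
        np.testing.assert_allclose(fit2.posterior, fit.posterior[perm], atol=1e-8)

    def test_component_identifiability(self):
        mat, _, scores, _ = _sim_matrix(100, 100, seed=6)
        fit = fp.fit_centipede(mat, covariates=scores, seed=0)
        assert fit.mu1 >= fit.mu0
        assert fit.tau.sum() == pytest.approx(1.0, abs=1e-12)

    def test_recovery_of_bound_labels_and_profile(self):
        from sklearn.metrics import roc_auc_score

        mat, is_bound, scores, prof = _sim_matrix(150, 150, seed=7)
        fit = fp.fit_centipede(mat, covariates=scores, seed=0)
        assert roc_auc_score(is_bound, fit.posterior) >= 0.99
        assert np.corrcoef(fit.tau, prof)[0, 1] >= 0.9

    def test_all_zero_matrix_rejected(self):
        occs = [occ(1000 + 500 * i, width=14) for i in range(30)]
        mat = fp.CutCountMatrix("m", occs, np.zeros((30, 402), int), 100)
        with pytest.raises(ValueError, match="signal"):
            fp.fit_centipede(mat, covariates=np.full(30, 10.0), seed=0)

    def test_too_few_occurrences_rejected(self):
        occs = [occ(1000 + 500 * i, width=14) for i in range(5)]
        mat = fp.CutCountMatrix("m", occs, np.ones((5, 402), int), 100)
        with pytest.raises(ValueError, match="20"):
            fp.fit_centipede(mat, covariates=np.full(5, 10.0), seed=0)


class TestCallFootprints:
    def _fit_stub(self, posteriors):
        return fp.CentipedeFit(tau=np.full(402, 1 / 402), mu1=200, phi1=10,
                               mu0=20, phi0=10, beta=np.zeros(2),
                               posterior=np.asarray(posteriors),
                               loglik_trace=[0.0], converged=True, n_iter=1)

    def _mat(self, occs):
        return fp.CutCountMatrix("m", occs, np.zeros((len(occs), 402), int), 100)

    def test_threshold_and_containment(self):
        peaks = PeakSet([GenomicInterval("chr1", 990, 1200)])
        occs = [occ(1000), occ(1195), occ(1050)]  # 1195+10 ends outside peak
        calls = fp.call_footprints(self._fit_stub([0.995, 0.995, 0.5]),
                                   self._mat(occs), peaks)
        assert [c.bound for c in calls] == [True, False, False]
        assert calls[0].containing_peak == GenomicInterval("chr1", 990, 1200)

    def test_posterior_exactly_at_threshold_not_bound(self):
        peaks = PeakSet([GenomicInterval("chr1", 990, 1200)])
        calls = fp.call_footprints(self._fit_stub([0.99]), self._mat([occ(1000)]),
                                   peaks)
        assert not calls[0].bound  # strict inequality


class TestOccupancy:
    def test_flat_when_bound_equals_unbound(self):
        # two bound-like and two unbound occurrences with identical rows
        counts = np.tile(np.full(402, 5, dtype=int), (40, 1))
        occs = ([occ(1000 + 300 * i) for i in range(20)]        # in peaks
                + [occ(50_000 + 300 * i) for i in range(20)])   # off peaks
        mat = fp.CutCountMatrix("m", occs, counts, 100)
        posts = np.array([1.0] * 20 + [0.0] * 20)
        fit = fp.CentipedeFit(tau=np.full(402, 1 / 402), mu1=2000, phi1=10,
                              mu0=2000, phi0=10, beta=np.zeros(2),
                              posterior=posts, loglik_trace=[0.0],
                              converged=True, n_iter=1)
        peaks = PeakSet([GenomicInterval("chr1", 900, 7500)])
        prof = fp.occupancy_profile(mat, fit, peaks, seed=0)
        assert prof.n_bound == prof.n_unbound == 20
        np.testing.assert_allclose(prof.signal, 1.0)

    def test_shape_recovered_from_synthetic_bound_sites(self):
        shape = sim.FootprintShape(depletion_depth=0.4, flank_boost=1.8)
        counts, is_bound, scores, prof_true = sim.simulate_cut_matrix(
            60, 60, shape, 200, 10, 20, 10, seed=9)
        # bound occurrences inside the peak, unbound outside
        occs, k_in, k_out = [], 0, 0
        for b in is_bound:
            if b:
                occs.append(occ(1000 + 300 * k_in, width=14))
                k_in += 1
            else:
                occs.append(occ(100_000 + 300 * k_out, width=14))
                k_out += 1
        mat = fp.CutCountMatrix("m", occs, counts, 100)
        fit = fp.fit_centipede(mat, covariates=scores, seed=0)
        peaks = PeakSet([GenomicInterval("chr1", 500, 1000 + 300 * k_in + 500)])
        prof = fp.occupancy_profile(mat, fit, peaks, seed=1)
        assert prof.n_bound > 0
        # dips over the motif, rises at the flanks, mirroring the planted shape
        rel = np.arange(-100, 101)
        in_motif = (rel >= -7) & (rel <= 6)
        in_flank = (~in_motif) & (np.abs(rel) <= 19)
        half = prof.signal[:201] + prof.signal[201:]
        assert half[in_motif].mean() < half[in_flank].mean()
        assert half[in_flank].mean() > 2 * half[np.abs(rel) > 60].mean() / 2

    def test_empty_bound_set_is_not_an_error(self):
        counts = np.random.default_rng(0).poisson(1.0, (30, 402))
        occs = [occ(100_000 + 300 * i) for i in range(30)]
        mat = fp.CutCountMatrix("m", occs, counts, 100)
        fit = fp.CentipedeFit(tau=np.full(402, 1 / 402), mu1=200, phi1=10,
                              mu0=20, phi0=10, beta=np.zeros(2),
                              posterior=np.full(30, 0.1), loglik_trace=[0.0],
                              converged=True, n_iter=1)
        peaks = PeakSet([GenomicInterval("chr1", 900, 1500)])
        prof = fp.occupancy_profile(mat, fit, peaks, seed=0)
        assert prof.n_bound == 0
        np.testing.assert_allclose(prof.signal, 1.0)
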