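"""Core model layer: classifier, likelihood, BIC, information measures."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcoin.models import (
    MotifModel,
    SitePredictionSet,
    bic,
    ic_per_col,
    jensen_shannon,
    log_likelihood,
    log_odds_matrix,
    predict_sites,
    score_model,
    score_subsequence,
)


class TestLogOdds:
    @pytest.mark.parametrize(
        "lam,expected_t",
        [(0.5, 0.0), (0.25, math.log(3.0)), (0.1, math.log(9.0))],
    )
    def test_threshold_from_prior(self, lam, expected_t):
        model = MotifModel(
            theta1=np.full((2, 4), 0.25), theta0=np.full(4, 0.25), lam=lam
        )
        clf = log_odds_matrix(model)
        assert clf.threshold == pytest.approx(expected_t, abs=1e-12)

    def test_uniform_column_gives_zero_row(self, uniform_model):
        clf = log_odds_matrix(uniform_model)
        assert np.allclose(clf.lo, 0.0)

    def test_zero_frequency_raises_with_column_named(self):
        theta1 = np.array([[0.5, 0.5, 0.0, 0.0], [0.25] * 4])
        model = MotifModel(theta1=theta1, theta0=np.full(4, 0.25), lam=0.1)
        with pytest.raises(ValueError, match=r"column\(s\) \[0\]"):
            log_odds_matrix(model)


class TestScoring:
    def test_consensus_scores_positive(self, conserved_model):
        clf = log_odds_matrix(conserved_model)
        s = score_subsequence(clf, "ACGT")
        assert s == pytest.approx(4 * math.log((1 - 3 * 0.001) / 0.25))
        assert s > clf.threshold

    def test_uniform_model_scores_zero(self, uniform_model):
        clf = log_odds_matrix(uniform_model)
        assert score_subsequence(clf, "GTAC") == pytest.approx(0.0)

    def test_score_is_sum_of_matrix_entries(self, uniform_model):
        clf = log_odds_matrix(uniform_model)
        lo = clf.lo.copy()
        lo[0, 0] = 1.0
        lo[1, 1] = 1.0
        clf2 = type(clf)(lo=lo[:2], threshold=0.0)
        assert score_subsequence(clf2, "AC") == pytest.approx(2.0)

    def test_ambiguous_base_rejected(self, conserved_model):
        clf = log_odds_matrix(conserved_model)
        with pytest.raises(ValueError, match="ambiguous"):
            score_subsequence(clf, "ANGT")


class TestPredictSites:
    def test_perfect_motif_recovers_every_site(self, perfect_dataset):
        sm = score_model(
            MotifModel(
                theta1=_alignment_pwm(perfect_dataset.occurrences),
                theta0=np.full(4, 0.25),
                lam=20 / 3780,
            ),
            perfect_dataset.sequences,
        )
        starts = {(s.seq_index, s.start) for s in sm.predictions.sites}
        assert set(perfect_dataset.true_sites) <= starts

    def test_extreme_prior_empties_predictions(self, conserved_model):
        model = MotifModel(
            theta1=conserved_model.theta1, theta0=conserved_model.theta0, lam=1e-12
        )
        pred = predict_sites(model, ["ACGTACGT"])
        assert pred.n_pred == 0

    def test_overlap_resolved_by_score(self):
        # consensus AAAA: the window of four A's wins over any overlapping shift
        eps = 0.01
        theta1 = np.full((4, 4), eps)
        theta1[:, 0] = 1 - 3 * eps
        model = MotifModel(theta1=theta1, theta0=np.full(4, 0.25), lam=0.05)
        pred = predict_sites(model, ["CCAAAACC"])
        assert [(s.seq_index, s.start) for s in pred.sites] == [(0, 2)]

    def test_no_overlapping_sites_on_random_models(self, rng, random_pwm):
        for _ in range(10):
            w = int(rng.integers(3, 8))
            model = MotifModel(
                theta1=random_pwm(rng, w), theta0=np.full(4, 0.25), lam=0.2
            )
            seqs = [
                "".join("ACGT"[k] for k in rng.integers(0, 4, size=60))
                for _ in range(5)
            ]
            pred = predict_sites(model, seqs)
            by_seq = {}
            for s in pred.sites:
                by_seq.setdefault(s.seq_index, []).append(s.start)
            for starts in by_seq.values():
                starts.sort()
                assert all(b - a >= w for a, b in zip(starts, starts[1:]))


class TestLikelihoodBic:
    def test_loglik_matches_naive_loop(self, rng, weak_dataset, random_pwm):
        model = MotifModel(
            theta1=random_pwm(rng, 6), theta0=np.full(4, 0.25), lam=0.05
        )
        pred = predict_sites(model, weak_dataset.sequences)
        if pred.n_pred == 0:
            pytest.skip("no predictions for this random model")
        ll = log_likelihood(model, pred, weak_dataset.sequences)
        # independent naive evaluation, site by site and letter by letter
        total = 0.0
        for occ in pred.occurrences(weak_dataset.sequences):
            p1 = p0 = 1.0
            for j, base in enumerate(occ):
                k = "ACGT".index(base)
                p1 *= model.theta1[j, k]
                p0 *= model.theta0[k]
            total += math.log(p1 * model.lam + p0 * (1 - model.lam))
        assert ll == pytest.approx(total, abs=1e-10)

    def test_lam_one_limit(self):
        # with theta1 uniform the mixture term is 0.25^w regardless of lam
        model = MotifModel(
            theta1=np.full((3, 4), 0.25), theta0=np.full(4, 0.25), lam=0.999999
        )
        pred = SitePredictionSet(width=3)
        from mcoin.models import Site

        pred.sites.append(Site(0, 0, "+", 0.0, 0.5))
        ll = log_likelihood(model, pred, ["ACG"])
        assert ll == pytest.approx(3 * math.log(0.25), abs=1e-5)

    def test_bic_direct_substitution(self):
        assert bic(-50.0, 12, 10) == pytest.approx(100 + 39 * math.log(10))

    def test_bic_penalty_vanishes_at_single_site(self):
        assert bic(-7.5, 9, 1) == pytest.approx(15.0)

    def test_bic_monotone_in_width_and_loglik(self):
        assert bic(-50, 13, 20) - bic(-50, 12, 20) == pytest.approx(
            3 * math.log(20)
        )
        assert bic(-60, 12, 20) > bic(-50, 12, 20)

    def test_bic_requires_sites(self):
        with pytest.raises(ValueError):
            bic(-10.0, 5, 0)


class TestInformation:
    def test_perfectly_conserved_is_two_bits(self, conserved_model):
        assert ic_per_col(conserved_model) == pytest.approx(2.0, abs=0.05)

    def test_half_half_column_is_one_bit(self):
        model = MotifModel(
            theta1=np.array([[0.5, 0.5, 0.0, 0.0]]),
            theta0=np.full(4, 0.25),
            lam=0.1,
        )
        assert ic_per_col(model) == pytest.approx(1.0)

    def test_uniform_is_zero_bits(self, uniform_model):
        assert ic_per_col(uniform_model) == pytest.approx(0.0)


class TestJensenShannon:
    def test_identity_and_disjoint_bounds(self):
        assert jensen_shannon([0.25] * 4, [0.25] * 4) == pytest.approx(0.0)
        assert jensen_shannon([1, 0, 0, 0], [0, 1, 0, 0]) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        js = jensen_shannon([0.5, 0.5, 0, 0], [0.25] * 4)
        assert js == pytest.approx(0.3112781, abs=1e-6)

    def test_rejects_unnormalised(self):
        with pytest.raises(ValueError):
            jensen_shannon([0.5, 0.5, 0.5, 0.5], [0.25] * 4)

    @settings(max_examples=200, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_symmetry_bounds_identity(self, seed):
        r = np.random.default_rng(seed)
        p = r.dirichlet(np.ones(4))
        q = r.dirichlet(np.ones(4))
        js_pq = jensen_shannon(p, q)
        assert js_pq == pytest.approx(jensen_shannon(q, p), abs=1e-12)
        assert 0.0 <= js_pq <= 1.0 + 1e-12
        assert jensen_shannon(p, p) == pytest.approx(0.0, abs=1e-12)


def _alignment_pwm(occurrences):
    idx = np.array([["ACGT".index(b) for b in occ] for occ in occurrences])
    counts = np.stack([(idx == k).sum(axis=0) for k in range(4)], axis=1) + 0.01
    return counts / counts.sum(axis=1, keepdims=True)
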