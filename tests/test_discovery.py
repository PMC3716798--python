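"""EM discovery core and ground-truth candidate construction."""

import numpy as np
import pytest

from mcoin.discovery import (
    CandidateModelSet,
    EMConfig,
    best_subwindow,
    construct_perfect_models,
    em_fit_tcm,
    run_over_widths,
)
from mcoin.models import MotifModel, encode_sequence, score_model
from mcoin.synthetic import DatasetSpec, generate_dataset


class TestEM:
    def test_loglik_monotone_nondecreasing(self, perfect_dataset):
        sm = em_fit_tcm(
            perfect_dataset.sequences, 12, EMConfig(n_starts=2, seed=0)
        )
        hist = np.asarray(sm.em_history)
        assert hist.size >= 2
        assert np.all(np.diff(hist) >= -1e-6)

    def test_recovers_fully_conserved_motif(self, perfect_dataset):
        sm = em_fit_tcm(
            perfect_dataset.sequences, 12, EMConfig(n_starts=5, seed=3)
        )
        # discovered consensus matches the planted one at some shift
        found = sm.model.consensus()
        truth = perfect_dataset.consensus
        overlaps = [
            sum(a == b for a, b in zip(found[k:], truth))
            for k in range(6)
        ] + [sum(a == b for a, b in zip(found, truth[k:])) for k in range(6)]
        assert max(overlaps) >= 8

    def test_determinism_under_seed(self, weak_dataset):
        a = em_fit_tcm(weak_dataset.sequences, 10, EMConfig(n_starts=2, seed=11))
        b = em_fit_tcm(weak_dataset.sequences, 10, EMConfig(n_starts=2, seed=11))
        assert np.array_equal(a.model.theta1, b.model.theta1)
        assert a.em_history == b.em_history

    def test_config_validation(self):
        with pytest.raises(ValueError):
            EMConfig(tol=0.0)
        with pytest.raises(ValueError):
            EMConfig(max_iterations=0)


class TestRunOverWidths:
    def test_width_range_and_keys(self, perfect_dataset):
        cs = run_over_widths(
            perfect_dataset.sequences, 10, 14, EMConfig(n_starts=1, seed=0)
        )
        assert cs.widths == [10, 11, 12, 13, 14]
        for w in cs.widths:
            assert cs[w].width == w

    def test_singleton_range(self, perfect_dataset):
        cs = run_over_widths(
            perfect_dataset.sequences, 12, 12, EMConfig(n_starts=1, seed=0)
        )
        assert cs.widths == [12]

    def test_invalid_ranges_rejected(self, perfect_dataset):
        with pytest.raises(ValueError):
            run_over_widths(perfect_dataset.sequences, 1, 5)
        with pytest.raises(ValueError):
            run_over_widths(perfect_dataset.sequences, 8, 500)


class TestPerfectModels:
    def test_true_width_model_is_fully_conserved(self, perfect_dataset):
        cs = construct_perfect_models(perfect_dataset, 8, 16)
        assert cs[12].ic_per_col == pytest.approx(2.0, abs=0.05)
        assert cs[12].model.consensus() == perfect_dataset.consensus

    def test_sub_and_super_widths_dilute_information(self, perfect_dataset):
        cs = construct_perfect_models(perfect_dataset, 8, 16)
        # trimmed models keep full conservation; extended ones dilute it
        assert cs[10].ic_per_col == pytest.approx(2.0, abs=0.05)
        assert cs[13].ic_per_col < cs[12].ic_per_col
        assert cs[13].ic_per_col == pytest.approx(2.0 * 12 / 13, abs=0.15)

    def test_trimmed_model_is_slice_of_true_alignment(self, weak_dataset):
        cs = construct_perfect_models(weak_dataset, 8, 16)
        full = cs[12].model.theta1
        for w in (9, 11):
            offset = (12 - w) // 2
            assert np.allclose(cs[w].model.theta1, full[offset : offset + w])

    def test_candidate_sites_are_planted_sites(self, weak_dataset):
        cs = construct_perfect_models(weak_dataset, 8, 16)
        pred = {(s.seq_index, s.start) for s in cs[12].predictions.sites}
        assert pred == set(weak_dataset.true_sites)
        assert cs[12].n_pred == 20

    def test_extension_respects_boundaries(self):
        ds = generate_dataset(DatasetSpec(target_ic=2.0, seed=12345))
        cs = construct_perfect_models(ds, 8, 16)
        for s in cs[16].predictions.sites:
            assert 0 <= s.start <= len(ds.sequences[s.seq_index]) - 16

    def test_width_out_of_range_rejected(self, perfect_dataset):
        with pytest.raises(ValueError):
            construct_perfect_models(perfect_dataset, 13, 16)


class TestBestSubwindow:
    def test_matches_exhaustive_offset_oracle(self, rng):
        for _ in range(20):
            idx = rng.integers(0, 4, size=(12, 10))
            w = int(rng.integers(2, 9))
            got = best_subwindow(idx, w)
            # brute force over offsets with an independent IC evaluation
            def window_ic(off):
                total = 0.0
                for j in range(off, off + w):
                    col = idx[:, j]
                    for k in range(4):
                        f = (col == k).mean()
                        if f > 0:
                            total += f * np.log2(4 * f)
                return total
            scores = np.array([window_ic(o) for o in range(10 - w + 1)])
            assert window_ic(got) == pytest.approx(scores.max())
            assert got == int(np.argmax(scores >= scores.max() - 1e-9))


def test_candidate_set_contiguity_enforced(perfect_dataset):
    model = MotifModel(
        theta1=np.full((5, 4), 0.25), theta0=np.full(4, 0.25), lam=0.01
    )
    sm = score_model(model, perfect_dataset.sequences)
    with pytest.raises(ValueError):
        CandidateModelSet(models={5: sm, 7: sm}, w_min=5, w_max=7)
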