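"""Design, schedule, BOLD, embedding and ratings generators."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from socialmap import synth
from socialmap.volume import default_grid


class TestConceptSet:
    def test_2x2_design(self, concept_set):
        assert len(concept_set) == 36
        cells = concept_set.groupby(["affect", "desirability"]).size()
        assert len(cells) == 4 and (cells == 9).all()
        # orthogonal, balanced factors
        assert (concept_set["affect"] == "high").sum() == 18
        assert (concept_set["desirability"] == "high").sum() == 18

    def test_unique_ids(self, concept_set):
        assert concept_set["concept_id"].nunique() == 36


class TestItis:
    def test_sampled_proportions(self):
        itis = synth.draw_itis(10_000, seed=0, mode="sampled")
        props = pd.Series(itis).value_counts(normalize=True)
        for val, target in [(6.0, 0.5), (6.5, 0.25), (7.0, 0.125)]:
            assert props[val] == pytest.approx(target, abs=0.02)

    def test_deterministic_allocation_exact(self):
        itis = synth.draw_itis(10_000, seed=0, mode="deterministic")
        counts = pd.Series(itis).value_counts()
        assert counts[6.0] == 5000
        assert counts[6.5] == 2500
        assert counts[7.0] == 1250
        assert counts[7.5] == 625
        assert counts[8.0] == 625

    def test_distribution_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            synth.draw_itis(10, iti_spec={6.0: 0.5, 6.5: 0.4})


class TestSchedule:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_onsets_increasing_with_jittered_gaps(self, concept_set, seed):
        for ev in synth.make_event_schedule(concept_set, n_runs=2, seed=seed):
            onsets = ev["onset"].to_numpy()
            assert (np.diff(onsets) > 0).all()
            gaps = onsets[1:] - (onsets[:-1] + ev["duration"].to_numpy()[:-1])
            assert (gaps >= 6.0 - 1e-9).all() and (gaps <= 8.0 + 1e-9).all()
            # spacing between onsets >= stimulus length + minimum ITI
            assert (np.diff(onsets) >= ev["duration"].iloc[0] + 6.0 - 1e-9).all()

    def test_each_concept_once_per_run(self, concept_set):
        schedule = synth.make_event_schedule(concept_set, n_runs=8, seed=3)
        assert sum(len(ev) for ev in schedule) == 288
        for ev in schedule:
            assert sorted(ev["concept_id"]) == list(range(36))

    def test_order_randomized_between_runs(self, concept_set):
        r0, r1 = synth.make_event_schedule(concept_set, n_runs=2, seed=4)
        assert list(r0["concept_id"]) != list(r1["concept_id"])

    def test_overrun_refused(self, concept_set):
        with pytest.raises(ValueError, match="schedule needs"):
            synth.make_event_schedule(concept_set, n_runs=1, seed=0, run_duration=120.0)

    def test_default_fits_standard_run(self, concept_set):
        # 36 trials must fit the 537-volume x 0.85 s acquisition
        for ev in synth.make_event_schedule(
            concept_set, n_runs=8, seed=0, run_duration=537 * 0.85
        ):
            assert ev["onset"].max() + 10.5 <= 537 * 0.85


class TestSimulateBold:
    def test_zero_signal_is_constant_baseline(self, concept_set):
        grid = default_grid(8)
        ev = synth.make_event_schedule(concept_set, n_runs=1, seed=0)[0]
        spec = synth.SignalSpec(rois=[], effect_scale=0.0, noise_sd=0.0, baseline=50.0)
        run = synth.simulate_bold(ev, grid, spec, n_volumes=synth.required_volumes(ev, 0.85))
        assert np.allclose(run.data[grid.mask], 50.0)
        assert np.allclose(run.data[~grid.mask], 0.0)

    def test_single_event_matches_discrete_convolution_oracle(self):
        """One event, one voxel, amplitude 1, no noise: the voxel time course
        equals a brute-force discrete convolution of the boxcar with the HRF
        at TR resolution."""
        grid = default_grid(8)
        vox = grid.mask_indices()[0]
        tr, n_vol = 0.85, 80
        onset = 17.0  # TR-aligned: 17.0 = 20 * 0.85
        ev = pd.DataFrame(
            {"onset": [onset], "duration": [3.4], "concept_id": [0], "run_id": [0]}
        )
        patterns = np.zeros((36, 1))
        patterns[0, 0] = 1.0
        roi = synth.RoiPattern("single", vox[None, :], patterns)
        spec = synth.SignalSpec(rois=[roi], effect_scale=1.0, noise_sd=0.0, baseline=0.0)
        run = synth.simulate_bold(ev, grid, spec, n_volumes=n_vol, tr=tr, oversample=1)
        course = run.data[tuple(vox)]

        box = np.zeros(n_vol)
        i0, i1 = round(onset / tr), round((onset + 3.4) / tr)
        box[i0:i1] = 1.0
        hrf = synth.double_gamma_hrf(np.arange(0, 32.0, tr))
        oracle = np.convolve(box, hrf)[:n_vol]
        np.testing.assert_allclose(course, oracle, atol=1e-12)
        # peak of the response ~6 s after stimulus midpoint region
        assert course.argmax() == oracle.argmax()

    def test_roi_outside_mask_refused(self, concept_set):
        grid = default_grid(8)
        ev = synth.make_event_schedule(concept_set, n_runs=1, seed=0)[0]
        roi = synth.RoiPattern("bad", np.array([[0, 0, 0]]), np.zeros((36, 1)))
        spec = synth.SignalSpec(rois=[roi])
        with pytest.raises(ValueError, match="outside the brain mask"):
            synth.simulate_bold(ev, grid, spec, n_volumes=synth.required_volumes(ev, 0.85))

    def test_seed_reproducibility(self, concept_set):
        grid = default_grid(8)
        ev = synth.make_event_schedule(concept_set, n_runs=1, seed=0)[0]
        spec = synth.SignalSpec(rois=[], noise_sd=1.0)
        nv = synth.required_volumes(ev, 0.85)
        a = synth.simulate_bold(ev, grid, spec, n_volumes=nv, seed=42)
        b = synth.simulate_bold(ev, grid, spec, n_volumes=nv, seed=42)
        np.testing.assert_array_equal(a.data, b.data)


class TestEmbeddings:
    def test_default_row_length_is_16128(self, concept_set):
        emb = synth.simulate_embeddings(concept_set, seed=0)
        assert emb.matrix.shape == (36, 16_128)
        assert emb.n_features == 21 * 768

    def test_padding_tails_are_zero(self, concept_set):
        emb = synth.simulate_embeddings(concept_set, max_tokens=6, width=8, seed=1)
        for i, c in enumerate(emb.token_counts):
            assert np.all(emb.matrix[i, c * 8 :] == 0.0)
            assert np.any(emb.matrix[i, : c * 8] != 0.0)

    def test_large_class_effect_separates_nearest_centroid(self, concept_set):
        """With a big class shift, an independent nearest-centroid rule on
        token-mean features separates the classes perfectly."""
        emb = synth.simulate_embeddings(concept_set, max_tokens=4, width=16, class_effect=8.0, seed=2)
        y = (concept_set["affect"] == "high").to_numpy()
        # token-mean to undo padding dilution
        feats = np.stack(
            [emb.matrix[i, : c * 16].reshape(c, 16).mean(0) for i, c in enumerate(emb.token_counts)]
        )
        correct = 0
        for i in range(36):
            rest = np.delete(np.arange(36), i)
            mu1 = feats[rest][y[rest]].mean(0)
            mu0 = feats[rest][~y[rest]].mean(0)
            pred = np.linalg.norm(feats[i] - mu1) < np.linalg.norm(feats[i] - mu0)
            correct += pred == y[i]
        assert correct == 36

    def test_null_class_effect_not_linearly_separated(self, concept_set):
        from socialmap.lmfeat import pair_holdout_decode

        aucs = []
        for seed in range(4):
            emb = synth.simulate_embeddings(concept_set, max_tokens=3, width=8, class_effect=0.0, seed=seed)
            y = (concept_set["affect"] == "high").astype(int).to_numpy()
            aucs.append(pair_holdout_decode(emb, y))
        assert abs(np.mean(aucs) - 0.5) < 0.12


class TestRatings:
    def test_bounded_and_complete(self, concept_set):
        df = synth.simulate_ratings(concept_set, n_subjects=3, seed=0)
        assert df["rating"].between(0, 100).all()
        assert len(df) == 3 * 36 * 2 * 2  # subjects x concepts x dimensions x sessions

    def test_zero_noise_gives_perfect_retest(self, concept_set):
        from socialmap.behav import icc_testretest

        df = synth.simulate_ratings(concept_set, n_subjects=3, noise_sd=0.0, seed=1)
        piv = df[df["dimension"] == "affect"].pivot_table(
            index=["subject_id", "concept_id"], columns="session", values="rating"
        )
        res = icc_testretest(piv["pre"].to_numpy(), piv["post"].to_numpy())
        assert res.icc == pytest.approx(1.0, abs=1e-9)

    def test_icc_recovers_target_reliability(self, concept_set):
        """Variance mix targeting ICC 0.9.  True-score variance = cell-mean
        spread ((60-50)^2 = 100 for means 60/40) + between_subject_sd^2;
        target 0.9 = T/(T + noise^2) with noise_sd = 6 needs T = 324, i.e.
        between_subject_sd = sqrt(224)."""
        from socialmap.behav import icc_testretest

        means = {"affect": {"high": 60.0, "low": 40.0}, "desirability": {"high": 60.0, "low": 40.0}}
        df = synth.simulate_ratings(
            concept_set, n_subjects=6, mean_by_cell=means,
            between_subject_sd=np.sqrt(224.0), noise_sd=6.0, seed=2,
        )
        piv = df[df["dimension"] == "affect"].pivot_table(
            index=["subject_id", "concept_id"], columns="session", values="rating"
        )
        res = icc_testretest(piv["pre"].to_numpy(), piv["post"].to_numpy())
        assert res.icc == pytest.approx(0.9, abs=0.05)


@given(st.integers(0, 1000))
def test_schedule_invariants_any_seed(seed):
    cs = synth.make_concept_set()
    ev = synth.make_event_schedule(cs, n_runs=1, seed=seed)[0]
    onsets = ev["onset"].to_numpy()
    assert (np.diff(onsets) >= 3.5 + 6.0 - 1e-9).all()
    assert sorted(ev["concept_id"]) == list(range(36))
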