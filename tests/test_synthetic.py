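"""Stimulus generator and ROI response simulator: factorial structure,
determinism, split bookkeeping, the linear noise model, and IO round-trips."""

import numpy as np
import pytest

import facerecon as fr
from facerecon.features import N_EXPRESSIONS
from facerecon.synthetic import (
    EncodingSpec,
    generate_stimulus_set,
    indicator_features,
    load_responses,
    load_stimulus_set,
    save_responses,
    save_stimulus_set,
    simulate_roi_responses,
    split_dataset,
)
from facerecon.utils import ConfigurationError


class TestGenerateStimulusSet:
    def test_full_factorial_size(self):
        sset = generate_stimulus_set(136, image_size=(16, 16), seed=0)
        assert len(sset) == 952
        pairs = {(s.identity_id, s.expression_id) for s in sset.stimuli}
        assert len(pairs) == 952

    def test_minimal_case_labels(self):
        sset = generate_stimulus_set(1, n_expressions=1, image_size=(16, 16), seed=0)
        assert len(sset) == 1
        s = sset.stimuli[0]
        assert (s.identity_id, s.expression_id) == (0, 0)
        assert s.gender_id in (0, 1)

    def test_bit_reproducible(self):
        a = generate_stimulus_set(3, image_size=(32, 32), seed=7)
        b = generate_stimulus_set(3, image_size=(32, 32), seed=7)
        assert all(np.array_equal(x.image, y.image) for x, y in zip(a.stimuli, b.stimuli))

    def test_seed_changes_pixels(self):
        a = generate_stimulus_set(3, image_size=(32, 32), seed=7)
        b = generate_stimulus_set(3, image_size=(32, 32), seed=8)
        assert not all(np.array_equal(x.image, y.image) for x, y in zip(a.stimuli, b.stimuli))

    def test_label_invariants(self, glyph_set):
        for s in glyph_set.stimuli:
            assert 0 <= s.expression_id < N_EXPRESSIONS
            assert s.gender_id in (0, 1)
            assert s.image.dtype == np.uint8

    def test_expression_and_gender_change_pixels(self):
        sset = generate_stimulus_set(2, image_size=(64, 64), seed=0, genders=[0, 1])
        by_key = {(s.identity_id, s.expression_id): s.image for s in sset.stimuli}
        assert not np.array_equal(by_key[(0, 0)], by_key[(0, 6)])
        assert not np.array_equal(by_key[(0, 3)], by_key[(1, 3)])

    @pytest.mark.parametrize("bad", [dict(n_identities=0), dict(n_identities=2, n_expressions=8),
                                     dict(n_identities=2, image_size=(8, 8))])
    def test_invalid_arguments(self, bad):
        kwargs = dict(n_identities=2, image_size=(32, 32), seed=0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            generate_stimulus_set(**kwargs)


class TestSplitDataset:
    def test_exact_counts_and_partition(self, glyph_set):
        split = split_dataset(glyph_set, (49, 14, 7), seed=3)
        tags = [s.split for s in split.stimuli]
        assert tags.count("train") == 49
        assert tags.count("val_fit") == 14
        assert tags.count("val_predict") == 7
        assert all(t is not None for t in tags)

    def test_bad_counts_raise(self, glyph_set):
        with pytest.raises(ValueError):
            split_dataset(glyph_set, (1, 1, 1), seed=0)

    def test_degenerate_all_train_warns(self, glyph_set):
        with pytest.warns(UserWarning):
            split = split_dataset(glyph_set, (len(glyph_set), 0, 0), seed=0)
        assert all(s.split == "train" for s in split.stimuli)

    def test_identity_disjoint_open_set(self, glyph_set):
        split = split_dataset(glyph_set, (49, 14, 7), seed=3, identity_disjoint=True)
        train_ids = {s.identity_id for s in split.stimuli if s.split == "train"}
        val_ids = {s.identity_id for s in split.stimuli if s.split != "train"}
        assert train_ids.isdisjoint(val_ids)


class TestSimulateResponses:
    def test_shapes(self, desk_assets):
        _sset, _feats, spec, rset = desk_assets
        assert rset.n_runs == 5
        for roi in spec.roi_names:
            assert rset.get(0, roi).shape == (140, 56)

    def test_noiseless_responses_deterministic_per_identity_block(self):
        sset = fr.generate_stimulus_set(4, image_size=(32, 32), seed=0, genders=[0, 0, 1, 1])
        feats = indicator_features(sset)
        spec = EncodingSpec.default(feats.block_dims, noise_sd=0.0, seed=1)
        rset = simulate_roi_responses(feats, spec, n_runs=2, seed=2)
        # FFA is identity/gender selective: two expressions of one identity
        # share identity and gender blocks, hence identical voxel vectors
        idx = [i for i, s in enumerate(sset.stimuli) if s.identity_id == 0]
        resp = rset.get(0, "FFA")
        assert np.allclose(resp[idx[0]], resp[idx[1]])

    def test_noiseless_responses_lie_in_feature_rowspace(self):
        sset = fr.generate_stimulus_set(6, image_size=(32, 32), seed=0)
        feats = indicator_features(sset)
        spec = EncodingSpec.default(feats.block_dims, noise_sd=0.0, seed=1)
        rset = simulate_roi_responses(feats, spec, n_runs=1, seed=2)
        for roi in ("V1", "pSTS"):
            resp = rset.get(0, roi)
            coef = np.linalg.lstsq(feats.z, resp, rcond=None)[0]
            assert np.allclose(resp, feats.z @ coef, atol=1e-8)

    def test_run_noise_variance_matches_model(self):
        """Across many runs the per-voxel sample variance approaches noise_sd^2."""
        sset = fr.generate_stimulus_set(2, image_size=(32, 32), seed=0)
        feats = indicator_features(sset)
        sd = 0.7
        spec = EncodingSpec.default(feats.block_dims, voxels_per_roi=8, noise_sd=sd, seed=1)
        rset = simulate_roi_responses(feats, spec, n_runs=200, seed=2)
        stack = np.stack([rset.get(r, "V1") for r in range(200)])
        var = stack.var(axis=0, ddof=1)
        assert abs(var.mean() - sd**2) < 3 * sd**2 * np.sqrt(2 / 199)

    def test_selectivity_zero_weights(self, desk_assets):
        _sset, feats, spec, _rset = desk_assets
        id_dim = feats.block_dims["identity"]
        for roi in ("pSTS", "amygdala"):
            assert np.all(spec.weights[roi][:id_dim] == 0)  # identity rows zero
            assert np.all(spec.weights[roi][-2:] == 0)  # gender rows zero
        for roi in ("FFA", "aIT"):
            exp_rows = spec.weights[roi][id_dim : id_dim + N_EXPRESSIONS]
            assert np.all(exp_rows == 0)

    def test_missing_roi_raises(self):
        sset = fr.generate_stimulus_set(2, image_size=(32, 32), seed=0)
        feats = indicator_features(sset)
        with pytest.raises(ConfigurationError):
            EncodingSpec.default(feats.block_dims, roi_names=("V1", "nonexistent"), seed=0)


class TestIO:
    def test_stimulus_round_trip(self, glyph_set, tmp_path):
        split = split_dataset(glyph_set, (49, 14, 7), seed=0)
        save_stimulus_set(split, tmp_path / "stim")
        loaded = load_stimulus_set(tmp_path / "stim")
        assert len(loaded) == len(split)
        for a, b in zip(split.stimuli, loaded.stimuli):
            assert np.array_equal(a.image, b.image)
            assert (a.identity_id, a.expression_id, a.gender_id, a.split) == (
                b.identity_id, b.expression_id, b.gender_id, b.split)
        for k in split.identity_params:
            assert np.allclose(split.identity_params[k], loaded.identity_params[k])

    def test_response_round_trip(self, tmp_path):
        sset = fr.generate_stimulus_set(3, image_size=(32, 32), seed=0)
        feats = indicator_features(sset)
        spec = EncodingSpec.default(feats.block_dims, voxels_per_roi=4, seed=1)
        rset = simulate_roi_responses(feats, spec, n_runs=2, seed=2)
        save_responses(rset, tmp_path / "resp", spec=spec, seed=2)
        loaded = load_responses(tmp_path / "resp")
        assert loaded.n_runs == 2 and loaded.roi_names == rset.roi_names
        for run in range(2):
            for roi in rset.roi_names:
                assert np.allclose(loaded.get(run, roi), rset.get(run, roi))

    def test_feature_table_round_trip(self, glyph_set, tmp_path):
        feats = indicator_features(glyph_set)
        fr.save_features(feats, tmp_path / "feats.csv")
        loaded = fr.load_features(tmp_path / "feats.csv")
        assert np.allclose(loaded.z, feats.z)
        assert loaded.block_dims == feats.block_dims
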