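"""Eigen-space fitting, cross-subject alignment, and the consistency of the
cross-subject pipeline with the intra-subject one."""

import numpy as np
import pytest

import facerecon as fr
from facerecon.intersubject import (
    cross_subject_predict_features,
    fit_cross_subject_map,
    fit_eigenspace,
    fit_procrustes_map,
)
from facerecon.mapping import fit_linear_map


class TestEigenSpace:
    def test_exact_reconstruction_at_full_rank(self, rng):
        latent = rng.normal(size=(30, 5))
        S = latent @ rng.normal(size=(5, 20))
        es = fit_eigenspace(S, k=5)
        assert np.allclose(es.inverse_transform(es.transform(S)), S, atol=1e-8)

    def test_first_component_aligns_with_dominant_axis(self, rng):
        axis = rng.normal(size=12)
        axis /= np.linalg.norm(axis)
        S = rng.normal(size=(100, 1)) * 10 @ axis[None, :] + rng.normal(size=(100, 12)) * 0.05
        es = fit_eigenspace(S, k=1)
        assert abs(es.components[0] @ axis) > 0.99

    def test_reconstruction_error_nonincreasing_in_k(self, rng):
        S = rng.normal(size=(25, 15))
        errs = [
            np.linalg.norm(fit_eigenspace(S, k=k).inverse_transform(fit_eigenspace(S, k=k).transform(S)) - S)
            for k in (1, 3, 6, 10, 14)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(errs, errs[1:]))

    def test_k_too_large_raises(self, rng):
        with pytest.raises(ValueError):
            fit_eigenspace(rng.normal(size=(10, 5)), k=10)

    def test_components_orthonormal(self, rng):
        es = fit_eigenspace(rng.normal(size=(40, 20)), k=8)
        assert np.allclose(es.components @ es.components.T, np.eye(8), atol=1e-10)


class TestCrossSubjectMap:
    def test_identity_when_coordinates_equal(self, rng):
        coords = rng.normal(size=(50, 8))
        cmap = fit_cross_subject_map(coords, coords)
        assert np.allclose(cmap.M, np.eye(8), atol=1e-8)

    def test_recovers_inverse_rotation(self, rng):
        coords_a = rng.normal(size=(60, 6))
        R = rng.normal(size=(6, 6)) + 3 * np.eye(6)
        coords_b = coords_a @ R
        cmap = fit_cross_subject_map(coords_a, coords_b)
        assert np.allclose(cmap.M, np.linalg.inv(R), atol=1e-6)

    def test_minimum_norm_with_few_shared_stimuli(self, rng):
        coords_a = rng.normal(size=(4, 8))
        coords_b = rng.normal(size=(4, 8))
        with pytest.warns(UserWarning, match="minimum-norm"):
            cmap = fit_cross_subject_map(coords_a, coords_b)
        M_oracle = np.linalg.lstsq(coords_b, coords_a, rcond=None)[0]
        assert np.isclose(
            np.linalg.norm(coords_b @ cmap.M - coords_a), np.linalg.norm(coords_b @ M_oracle - coords_a), atol=1e-8
        )

    def test_procrustes_map_is_orthogonal(self, rng):
        coords_a = rng.normal(size=(40, 5))
        Q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        cmap = fit_procrustes_map(coords_a, coords_a @ Q)
        assert np.allclose(cmap.M @ cmap.M.T, np.eye(5), atol=1e-8)
        assert np.allclose(cmap.M, Q.T, atol=1e-6)

    def test_row_misalignment_raises(self, rng):
        with pytest.raises(ValueError):
            fit_cross_subject_map(rng.normal(size=(5, 3)), rng.normal(size=(6, 3)))


def _two_subject_setup(noise_sd, seed=0, shared_encoding=True):
    """Two synthetic subjects; B's voxels are an orthogonal remix of A's
    encoding (or an unrelated encoding) plus independent run noise."""
    sset = fr.generate_stimulus_set(15, image_size=(32, 32), seed=seed)
    feats = fr.indicator_features(sset)
    spec_a = fr.EncodingSpec.default(feats.block_dims, noise_sd=noise_sd, seed=seed + 1)
    rset_a = fr.simulate_roi_responses(feats, spec_a, n_runs=5, seed=seed + 2)
    rng = np.random.default_rng(seed + 3)
    if shared_encoding:
        weights_b = {}
        for roi, W in spec_a.weights.items():
            q, _ = np.linalg.qr(rng.normal(size=(W.shape[1], W.shape[1])))
            weights_b[roi] = W @ q
        spec_b = fr.EncodingSpec(
            weights_b, dict(spec_a.block_dims), noise_sd, spec_a.voxels_per_roi,
            spec_a.roi_names, dict(spec_a.selectivity),
        )
    else:
        spec_b = fr.EncodingSpec.default(feats.block_dims, noise_sd=max(noise_sd, 3.0), seed=seed + 77,
                                         selectivity={r: () for r in spec_a.roi_names})
    rset_b = fr.simulate_roi_responses(feats, spec_b, n_runs=5, seed=seed + 4)
    return sset, feats, rset_a, rset_b


def _cross_subject_identity_accuracy(rset_a, rset_b, feats, k=40):
    SA = fr.assemble_design(rset_a, "proposed", "identity", runs=[0, 1, 2], mode="stack")
    es_a = fit_eigenspace(SA, k=k)
    maps_a = {"identity": fit_linear_map(es_a.transform(SA), np.tile(feats.t_id, (3, 1)))}
    SB = fr.assemble_design(rset_b, "proposed", "identity", runs=[0, 1, 2], mode="stack")
    es_b = fit_eigenspace(SB, k=k)
    SA_sh = fr.assemble_design(rset_a, "proposed", "identity", runs=[0, 1, 2], mode="average")
    SB_sh = fr.assemble_design(rset_b, "proposed", "identity", runs=[0, 1, 2], mode="average")
    cmap = fit_cross_subject_map(es_a.transform(SA_sh), es_b.transform(SB_sh))
    SB_test = fr.assemble_design(rset_b, "proposed", "identity", runs=[3, 4], mode="average")
    coords = cmap(es_b.transform(SB_test))
    pred = maps_a["identity"].predict(coords)
    res = fr.roi_reconstruction_accuracy(pred, feats.t_id, n_repeats=40, seed=9)
    return res


class TestCrossSubjectPipeline:
    def test_b_equals_a_matches_intra_subject_exactly(self):
        sset, feats, rset_a, _ = _two_subject_setup(noise_sd=0.5, seed=1)
        SA = fr.assemble_design(rset_a, "proposed", "identity", runs=[0, 1, 2], mode="stack")
        es = fit_eigenspace(SA, k=30)
        lr = {a: fit_linear_map(es.transform(SA), np.tile(feats.t_id, (3, 1))) for a in
              ("expression", "identity", "gender")}
        S_test = fr.assemble_design(rset_a, "proposed", "identity", runs=[3, 4], mode="average")
        intra = lr["identity"].predict(es.transform(S_test))
        cmap = fit_cross_subject_map(es.transform(SA), es.transform(SA))
        cross = cmap(es.transform(S_test)) @ lr["identity"].W
        assert np.allclose(cross, intra, atol=1e-8)

    def test_shared_encoding_recovers_above_chance(self):
        _sset, feats, rset_a, rset_b = _two_subject_setup(noise_sd=0.5, seed=2)
        res = _cross_subject_identity_accuracy(rset_a, rset_b, feats)
        assert res.mean > 60.0
        assert res.p_raw < 0.001 and res.t > 0

    def test_unrelated_subjects_at_chance(self):
        _sset, feats, rset_a, rset_b = _two_subject_setup(noise_sd=0.5, seed=3, shared_encoding=False)
        res = _cross_subject_identity_accuracy(rset_a, rset_b, feats)
        # identity features repeat across the 7 expressions of an identity, so
        # 6/104 distractor draws tie exactly and count as failures; the
        # effective chance level is 50% of the remaining draws
        n = 105
        chance = 50.0 * (1 - 6 / (n - 1))
        se = 100 * np.sqrt(1 / 12 / n)
        assert abs(res.mean - chance) <= 3 * se

    def test_recovery_degrades_with_noise_on_average(self):
        means = []
        for noise in (0.3, 2.0, 8.0):
            accs = []
            for seed in (5, 6):
                _sset, feats, rset_a, rset_b = _two_subject_setup(noise_sd=noise, seed=seed)
                accs.append(_cross_subject_identity_accuracy(rset_a, rset_b, feats).mean)
            means.append(np.mean(accs))
        assert means[0] > means[2]
        assert means[1] > means[2] - 1e-9

    def test_feature_prediction_dim_chain_error(self, rng):
        from facerecon.utils import ConfigurationError

        es = fit_eigenspace(rng.normal(size=(30, 10)), k=5)
        cmap = fit_cross_subject_map(rng.normal(size=(30, 5)), rng.normal(size=(30, 5)))
        maps = {a: fit_linear_map(rng.normal(size=(30, 7)), rng.normal(size=(30, 2))) for a in
                ("expression", "identity", "gender")}
        with pytest.raises(ConfigurationError):
            cross_subject_predict_features(rng.normal(size=(4, 10)), es, cmap, es, maps, mode="eigen")
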