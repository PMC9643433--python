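"""Cross-subject reconstruction via PCA eigen-space alignment.

Each subject's stimulus x voxel response matrix spans a low-dimensional
eigen-space (mean-centered PCA, default 56 components).  Responses of the
test subject B to stimuli shared with the training subject A determine a
least-squares linear transform between the two eigen-spaces; B's responses
are then projected into A's eigen-space, where A's fitted feature maps (and
generator) carry the rest of the reconstruction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .features import AttributeFeatures
from .mapping import assemble_multidim_features
from .utils import ConfigurationError


@dataclass
class EigenSpace:
    mean: np.ndarray
    components: np.ndarray  # (k, voxels), orthonormal rows
    explained_variance: np.ndarray

    @property
    def k(self):
        return self.components.shape[0]

    def transform(self, S):
        S = np.atleast_2d(np.asarray(S, dtype=float))
        return (S - self.mean) @ self.components.T

    def inverse_transform(self, coords):
        return np.atleast_2d(coords) @ self.components + self.mean


def fit_eigenspace(S, k=56) -> EigenSpace:
    """Mean-centered PCA of a stimuli x voxels matrix, keeping the top k
    components (deterministic sign: each component's largest-magnitude
    loading is positive)."""
    S = np.asarray(S, dtype=float)
    n, v = S.shape
    if k > min(n - 1, v):
        raise ValueError(f"k={k} exceeds the PCA rank bound min(rows-1, cols) = {min(n - 1, v)}")
    mean = S.mean(axis=0)
    centered = S - mean
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    comps = vt[:k]
    signs = np.sign(comps[np.arange(k), np.abs(comps).argmax(axis=1)])
    comps = comps * signs[:, None]
    explained = (svals[:k] ** 2) / max(n - 1, 1)
    return EigenSpace(mean, comps, explained)


@dataclass
class CrossSubjectMap:
    """Linear transform from subject-B eigen-coordinates to subject-A's."""

    M: np.ndarray
    n_shared: int
    residual_norm: float

    def __call__(self, coords_B):
        return np.atleast_2d(coords_B) @ self.M


def fit_cross_subject_map(coords_A, coords_B) -> CrossSubjectMap:
    """Least-squares M minimizing ||coords_B @ M - coords_A||_F over shared stimuli."""
    coords_A = np.asarray(coords_A, dtype=float)
    coords_B = np.asarray(coords_B, dtype=float)
    if coords_A.shape[0] != coords_B.shape[0]:
        raise ValueError("coordinate matrices must be row-aligned by shared stimulus")
    if coords_B.shape[0] < coords_B.shape[1]:
        warnings.warn(
            "fewer shared stimuli than eigen-dimensions; using the minimum-norm solution"
        )
    M, _, _, _ = np.linalg.lstsq(coords_B, coords_A, rcond=None)
    residual = float(np.linalg.norm(coords_B @ M - coords_A))
    return CrossSubjectMap(M, coords_B.shape[0], residual)


def fit_procrustes_map(coords_A, coords_B) -> CrossSubjectMap:
    """Orthogonal-Procrustes alternative to the unconstrained transform."""
    coords_A = np.asarray(coords_A, dtype=float)
    coords_B = np.asarray(coords_B, dtype=float)
    if coords_A.shape[0] != coords_B.shape[0]:
        raise ValueError("coordinate matrices must be row-aligned by shared stimulus")
    u, _, vt = np.linalg.svd(coords_B.T @ coords_A)
    M = u @ vt
    residual = float(np.linalg.norm(coords_B @ M - coords_A))
    return CrossSubjectMap(M, coords_B.shape[0], residual)


def cross_subject_predict_features(
    test_responses_B, eigen_B: EigenSpace, cmap: CrossSubjectMap, eigen_A: EigenSpace, maps_A, mode="eigen"
) -> AttributeFeatures:
    """Map B's voxel responses into A's space and predict features with A's maps.

    ``maps_A`` is a dict attribute -> fitted LinearMapResults.  With
    ``mode='eigen'`` (default) the maps must be trained on A's
    eigen-coordinates; with ``mode='voxel'`` the aligned coordinates are
    back-projected to A's voxel space first and the maps must be trained on
    voxel responses.
    """
    if mode not in ("eigen", "voxel"):
        raise ConfigurationError("mode must be 'eigen' or 'voxel'")
    coords = cmap(eigen_B.transform(test_responses_B))
    design = coords if mode == "eigen" else eigen_A.inverse_transform(coords)
    try:
        preds = {attr: maps_A[attr].predict(design) for attr in ("expression", "identity", "gender")}
    except ValueError as err:
        raise ConfigurationError(f"dimension chain mismatch: {err}") from err
    return assemble_multidim_features(preds["expression"], preds["identity"], preds["gender"])


def cross_subject_reconstruct(
    test_responses_B, eigen_B, cmap, eigen_A, maps_A, generator=None, mode="eigen"
):
    """Full cross-subject pipeline; returns (features, images or None)."""
    feats = cross_subject_predict_features(test_responses_B, eigen_B, cmap, eigen_A, maps_A, mode=mode)
    if generator is None:
        return feats, None
    from .mcgan import reconstruct

    return feats, reconstruct(generator, feats)
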