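"""Closed-form linear mapping between ROI voxel responses and face features.

Each attribute block of the multi-dimensional face features is regressed on
the voxel responses of its ROI group by ordinary least squares,
``W = (S'S)^{-1} S'T`` with no intercept.  The model/results split follows
the statsmodels convention: :class:`LinearFeatureMap` holds the design, its
``fit()`` returns a :class:`LinearMapResults` carrying the weights, rank
diagnostics and prediction methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import N_EXPRESSIONS, N_GENDERS, AttributeFeatures
from .synthetic import ROI_NAMES, ROIResponseSet
from .utils import ConfigurationError

ATTRIBUTES = ("expression", "identity", "gender")

_PROPOSED_GROUPS = {
    "expression": ["V1", "OFA", "amygdala", "pSTS"],
    "identity": ["V1", "OFA", "FFA", "aIT"],
    "gender": ["V1", "OFA", "FFA", "aIT"],
}
_ALL_ROIS = list(ROI_NAMES)


@dataclass
class ROIGroupStrategy:
    """Which ROIs feed each attribute's regression, and which attribute
    blocks survive as generator constraints (omitted blocks are zeroed)."""

    name: str
    roi_groups: dict  # attribute -> list of ROI names
    constraint_blocks: tuple = ("identity", "expression", "gender")

    def rois_for(self, attribute):
        if attribute not in self.roi_groups:
            raise ConfigurationError(f"strategy {self.name!r} has no ROI group for {attribute!r}")
        return self.roi_groups[attribute]


_STRATEGIES = {
    "proposed": ROIGroupStrategy("proposed", _PROPOSED_GROUPS),
    "strategy1": ROIGroupStrategy("strategy1", {a: ["V1"] for a in ATTRIBUTES}),
    "strategy2": ROIGroupStrategy("strategy2", {a: list(_ALL_ROIS) for a in ATTRIBUTES}),
    "strategy3": ROIGroupStrategy("strategy3", {a: list(_ALL_ROIS) for a in ATTRIBUTES}, ("identity",)),
    "strategy4": ROIGroupStrategy(
        "strategy4", {a: list(_ALL_ROIS) for a in ATTRIBUTES}, ("identity", "gender")
    ),
    "strategy5": ROIGroupStrategy(
        "strategy5", {a: list(_ALL_ROIS) for a in ATTRIBUTES}, ("identity", "expression")
    ),
}


def get_strategy(name: str) -> ROIGroupStrategy:
    try:
        return _STRATEGIES[name]
    except KeyError:
        raise ConfigurationError(f"unknown ROI-group strategy {name!r}") from None


def assemble_design(responses: ROIResponseSet, strategy, attribute, runs=None, mode="stack"):
    """Build the design matrix S for one attribute's regression.

    Columns are the concatenated voxels of the strategy's ROI group for that
    attribute; rows are stimuli, repeated per run when ``mode='stack'`` or
    averaged over the selected runs when ``mode='average'``.
    """
    if isinstance(strategy, str):
        strategy = get_strategy(strategy)
    if mode not in ("stack", "average"):
        raise ValueError("mode must be 'stack' or 'average'")
    runs = list(range(responses.n_runs)) if runs is None else list(runs)
    rois = strategy.rois_for(attribute)
    per_run = [np.concatenate([responses.get(run, roi) for roi in rois], axis=1) for run in runs]
    if mode == "average":
        return np.mean(per_run, axis=0)
    return np.concatenate(per_run, axis=0)


class LinearMapResults:
    """Fitted weights of one attribute-block regression."""

    def __init__(self, W, rank, used_pinv, residual_ss, n_obs, meta=None):
        self.W = W
        self.rank = rank
        self.used_pinv = used_pinv
        self.residual_ss = residual_ss
        self.n_obs = n_obs
        self.meta = meta or {}

    @property
    def df_resid(self):
        return self.n_obs - self.rank

    def predict(self, S_new):
        S_new = np.asarray(S_new, dtype=float)
        if S_new.ndim == 1:
            S_new = S_new[None, :]
        if S_new.shape[1] != self.W.shape[0]:
            raise ValueError(
                f"design has {S_new.shape[1]} columns but the map expects {self.W.shape[0]}"
            )
        return S_new @ self.W

    def summary(self):
        lines = [
            "Linear feature map (ordinary least squares, no intercept)",
            "=" * 57,
            f"observations:        {self.n_obs}",
            f"voxels (predictors): {self.W.shape[0]}",
            f"feature dims:        {self.W.shape[1]}",
            f"design rank:         {self.rank}",
            f"solver:              {'minimum-norm pseudoinverse' if self.used_pinv else 'normal equations'}",
            f"residual SS:         {self.residual_ss:.6g}",
        ]
        for k, v in self.meta.items():
            lines.append(f"{k + ':':<21}{v}")
        return "\n".join(lines)


class LinearFeatureMap:
    """OLS model of feature block T on voxel design S (rows aligned)."""

    def __init__(self, S, T, meta=None):
        S = np.asarray(S, dtype=float)
        T = np.asarray(T, dtype=float)
        if T.ndim == 1:
            T = T[:, None]
        if S.shape[0] != T.shape[0]:
            raise ValueError(f"S has {S.shape[0]} rows but T has {T.shape[0]}")
        self.S, self.T = S, T
        self.meta = meta or {}

    def fit(self) -> LinearMapResults:
        S, T = self.S, self.T
        rank = np.linalg.matrix_rank(S)
        used_pinv = rank < S.shape[1]
        if used_pinv:
            warnings.warn(
                "singular design (rank deficiency); falling back to the "
                "minimum-norm pseudoinverse solution"
            )
            W = np.linalg.pinv(S) @ T
        else:
            W = np.linalg.solve(S.T @ S, S.T @ T)
        residual_ss = float(np.sum((S @ W - T) ** 2))
        return LinearMapResults(W, int(rank), used_pinv, residual_ss, S.shape[0], dict(self.meta))


def fit_linear_map(S, T, meta=None) -> LinearMapResults:
    return LinearFeatureMap(S, T, meta=meta).fit()


def predict_features(S_new, results: LinearMapResults):
    return results.predict(S_new)


def fit_strategy_maps(responses, features: AttributeFeatures, strategy, runs=None, mode="stack"):
    """Fit the per-attribute linear maps of one ROI-group strategy.

    Feature targets are tiled to match stacked run rows.  Returns a dict
    attribute -> LinearMapResults.
    """
    if isinstance(strategy, str):
        strategy = get_strategy(strategy)
    runs = list(range(responses.n_runs)) if runs is None else list(runs)
    reps = len(runs) if mode == "stack" else 1
    targets = {
        "expression": features.t_exp,
        "identity": features.t_id,
        "gender": features.t_gen,
    }
    results = {}
    for attribute in ATTRIBUTES:
        S = assemble_design(responses, strategy, attribute, runs=runs, mode=mode)
        T = np.tile(targets[attribute], (reps, 1))
        results[attribute] = fit_linear_map(
            S, T, meta={"attribute": attribute, "rois": ",".join(strategy.rois_for(attribute)), "runs": str(runs)}
        )
    return results


def predict_strategy_features(responses, maps, strategy, runs=None, mode="average") -> AttributeFeatures:
    """Predict all three attribute blocks from held-out runs and assemble z."""
    if isinstance(strategy, str):
        strategy = get_strategy(strategy)
    preds = {}
    for attribute in ATTRIBUTES:
        S = assemble_design(responses, strategy, attribute, runs=runs, mode=mode)
        preds[attribute] = maps[attribute].predict(S)
    feats = assemble_multidim_features(preds["expression"], preds["identity"], preds["gender"])
    return apply_block_constraints(feats, strategy)


def assemble_multidim_features(pred_exp, pred_id, pred_gen) -> AttributeFeatures:
    """Concatenate predicted blocks into z in (t_id, t_exp, t_gen) order,
    clipping the bounded softmax-convention blocks into [0, 1]."""
    pred_exp = np.atleast_2d(np.asarray(pred_exp, dtype=float))
    pred_gen = np.atleast_2d(np.asarray(pred_gen, dtype=float))
    pred_id = np.atleast_2d(np.asarray(pred_id, dtype=float))
    if pred_exp.shape[1] != N_EXPRESSIONS:
        raise ValueError(f"expression block must have {N_EXPRESSIONS} dims, got {pred_exp.shape[1]}")
    if pred_gen.shape[1] != N_GENDERS:
        raise ValueError(f"gender block must have {N_GENDERS} dims, got {pred_gen.shape[1]}")
    clipped = {}
    for name, block in (("expression", pred_exp), ("gender", pred_gen)):
        if block.size and (block.min() < 0.0 or block.max() > 1.0):
            warnings.warn(f"{name} block predictions outside [0, 1]; clipping")
        clipped[name] = np.clip(block, 0.0, 1.0)
    return AttributeFeatures(pred_id, clipped["expression"], clipped["gender"])


def apply_block_constraints(features: AttributeFeatures, strategy) -> AttributeFeatures:
    """Zero the attribute blocks a strategy omits from the generator conditioning."""
    if isinstance(strategy, str):
        strategy = get_strategy(strategy)
    blocks = {
        "identity": features.t_id.copy(),
        "expression": features.t_exp.copy(),
        "gender": features.t_gen.copy(),
    }
    for name in blocks:
        if name not in strategy.constraint_blocks:
            blocks[name][...] = 0.0
    return AttributeFeatures(blocks["identity"], blocks["expression"], blocks["gender"])
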