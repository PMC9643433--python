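"""End-to-end experiment orchestration: intra-/inter-subject reconstruction,
ablation sweeps and the per-ROI contribution analysis, driven by a single
config with one global seed fanned out deterministically to every component.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import mcgan, mtdln
from .evaluation import (
    fdr_adjust,
    image_pair_metrics,
    roi_reconstruction_accuracy,
    ssim_accuracy,
)
from .features import AttributeFeatures
from .mapping import (
    ATTRIBUTES,
    apply_block_constraints,
    assemble_design,
    fit_linear_map,
    fit_strategy_maps,
    get_strategy,
    predict_strategy_features,
)
from .intersubject import fit_cross_subject_map, fit_eigenspace
from .synthetic import (
    EncodingSpec,
    ROI_NAMES,
    generate_stimulus_set,
    indicator_features,
    simulate_roi_responses,
    split_dataset,
)
from .utils import ConfigurationError, fanout_seed

logger = logging.getLogger(__name__)

KINDS = (
    "intra_seen",
    "intra_unseen",
    "inter_seen",
    "inter_unseen",
    "ablation_gan",
    "ablation_strategy",
    "roi_contribution",
)


@dataclass
class ExperimentConfig:
    kind: str = "intra_seen"
    seed: int = 0
    outdir: str = "facerecon_out"
    scale: str = "desk"
    n_identities: int = 20
    image_size: tuple = (32, 32)
    n_runs: int = 5
    noise_sd: float = 1.0
    voxels_per_roi: int = 56
    strategy: str = "proposed"
    feature_source: str = "indicator"  # "indicator" or "mtdln"
    train_runs: tuple = (0, 1, 2)
    predict_runs: tuple = (3, 4)
    n_folds: int = 10
    n_repeats: int = 40
    gan_epochs: int = 15
    gan_mode: str = "mcgan"
    mtdln_epochs: int = 4
    include_white_noise: bool = False
    eigen_k: int = 56

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ConfigurationError(f"unknown experiment kind {self.kind!r}")
        if self.feature_source not in ("indicator", "mtdln"):
            raise ConfigurationError("feature_source must be 'indicator' or 'mtdln'")
        self.image_size = tuple(self.image_size)
        self.train_runs = tuple(self.train_runs)
        self.predict_runs = tuple(self.predict_runs)

    @classmethod
    def from_file(cls, path):
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        data = yaml.safe_load(path.read_text()) or {}
        return cls(**data)

    def to_dict(self):
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


@dataclass
class RunManifest:
    kind: str
    seed: int
    config: dict
    artifacts: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def comparable(self):
        """Everything except wall-clock timestamps (for reproducibility checks)."""
        return {
            "kind": self.kind,
            "seed": self.seed,
            "config": self.config,
            "artifacts": self.artifacts,
            "metrics": self.metrics,
        }

    def write(self, outdir):
        path = Path(outdir) / "manifest.json"
        payload = dict(self.comparable(), started=self.started, finished=self.finished)
        path.write_text(json.dumps(payload, indent=2, default=float))
        return path


def _timestamp():
    return time.strftime("%Y-%m-%dT%H:%M:%S")


def _result_record(res):
    return {
        "mean": res.mean,
        "sd": res.sd,
        "t": res.t,
        "p_raw": res.p_raw,
        "p_fdr": res.p_fdr,
        "units": res.units,
        "n_repeats": res.n_repeats,
    }


def _prepare_assets(config: ExperimentConfig, train_gan=True):
    """Stimuli, features, encoding, responses and (optionally) a generator."""
    sset = generate_stimulus_set(
        config.n_identities, image_size=config.image_size, seed=fanout_seed(config.seed, "stimuli")
    )
    if config.feature_source == "mtdln":
        # open-set training identities, disjoint from the analysis stimuli
        train_ids = max(config.n_identities // 2, 2)
        train_set = generate_stimulus_set(
            train_ids, image_size=config.image_size, seed=fanout_seed(config.seed, "mtdln")
        )
        mconf = mtdln.MTDLNConfig.desk_scale(
            n_identities=train_ids, image_size=config.image_size, epochs=config.mtdln_epochs
        )
        model = mtdln.build_mtdln(mconf, seed=fanout_seed(config.seed, "mtdln"))
        model, _hist = mtdln.train_mtdln(model, train_set, sset, mconf, seed=fanout_seed(config.seed, "mtdln"))
        feats = mtdln.extract_features(model, sset.images())
    else:
        feats = indicator_features(sset)
    spec = EncodingSpec.default(
        feats.block_dims,
        voxels_per_roi=config.voxels_per_roi,
        noise_sd=config.noise_sd,
        seed=fanout_seed(config.seed, "encoding"),
    )
    rset = simulate_roi_responses(feats, spec, n_runs=config.n_runs, seed=fanout_seed(config.seed, "responses"))
    generator = None
    if train_gan:
        gconf = mcgan.McGANConfig.desk_scale(
            id_dim=feats.block_dims["identity"],
            image_size=config.image_size,
            epochs=config.gan_epochs,
            mode=config.gan_mode,
        )
        generator, _disc, _log = mcgan.train_mcgan(
            sset.images(), feats, gconf, seed=fanout_seed(config.seed, "mcgan")
        )
    return sset, feats, spec, rset, generator


def _per_image_metrics(recons, truths):
    rows = [dataclasses.asdict(image_pair_metrics(r, t)) for r, t in zip(recons, truths)]
    return pd.DataFrame(rows)


def _write_recons(recons, outdir, tag):
    from PIL import Image

    rec_dir = Path(outdir) / f"recons_{tag}"
    rec_dir.mkdir(parents=True, exist_ok=True)
    for i, img in enumerate(recons):
        Image.fromarray(img, mode="L").save(rec_dir / f"recon_{i:03d}.png")
    return str(rec_dir)


def _predict_unseen(rset, feats, strategy, n_folds, seed):
    """10-fold cross-validated feature prediction for stimuli unseen by the map."""
    strategy = get_strategy(strategy) if isinstance(strategy, str) else strategy
    n = len(feats)
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(n), n_folds)
    targets = {"expression": feats.t_exp, "identity": feats.t_id, "gender": feats.t_gen}
    pred_blocks = {a: np.zeros_like(targets[a]) for a in ATTRIBUTES}
    all_runs = list(range(rset.n_runs))
    for test_idx in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        for attribute in ATTRIBUTES:
            S_stack = assemble_design(rset, strategy, attribute, runs=all_runs, mode="stack")
            train_rows = np.concatenate([r * n + np.flatnonzero(train_mask) for r in all_runs])
            T_train = np.tile(targets[attribute], (len(all_runs), 1))[train_rows]
            result = fit_linear_map(S_stack[train_rows], T_train)
            S_test = assemble_design(rset, strategy, attribute, runs=all_runs, mode="average")[test_idx]
            pred_blocks[attribute][test_idx] = result.predict(S_test)
    from .mapping import assemble_multidim_features

    pred = assemble_multidim_features(
        pred_blocks["expression"], pred_blocks["identity"], pred_blocks["gender"]
    )
    return apply_block_constraints(pred, strategy)


def run_intra_subject(config: ExperimentConfig) -> RunManifest:
    """Seen mode: maps fitted on the training runs, features predicted from the
    held-out runs of the same stimuli.  Unseen mode: 10-fold cross-validation
    over stimuli using every run."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.kind, config.seed, config.to_dict(), started=_timestamp())
    sset, feats, _spec, rset, generator = _prepare_assets(config)
    logger.info("assets ready: %d stimuli, %d runs", len(sset), rset.n_runs)

    if config.kind == "intra_seen":
        maps = fit_strategy_maps(rset, feats, config.strategy, runs=config.train_runs, mode="stack")
        pred = predict_strategy_features(rset, maps, config.strategy, runs=config.predict_runs, mode="average")
    elif config.kind == "intra_unseen":
        pred = _predict_unseen(rset, feats, config.strategy, config.n_folds, fanout_seed(config.seed, "split"))
    else:
        raise ConfigurationError(f"run_intra_subject cannot handle kind {config.kind!r}")

    recons = mcgan.reconstruct(generator, pred)
    truths = sset.images()
    metrics = _per_image_metrics(recons, truths)
    metrics.to_csv(outdir / "per_image_metrics.csv", index=False)
    acc = ssim_accuracy(recons, truths, n_repeats=config.n_repeats, seed=fanout_seed(config.seed, "evaluation"))
    fdr_adjust([acc])
    manifest.artifacts["per_image_metrics"] = str(outdir / "per_image_metrics.csv")
    manifest.artifacts["reconstructions"] = _write_recons(recons, outdir, config.kind)
    manifest.metrics["ssim_mean"] = float(metrics["ssim"].mean())
    manifest.metrics["mse_mean"] = float(metrics["mse"].mean())
    manifest.metrics["ssim_accuracy"] = _result_record(acc)
    manifest.finished = _timestamp()
    manifest.artifacts["manifest"] = str(manifest.write(outdir))
    return manifest


def run_ablation_suite(config: ExperimentConfig) -> RunManifest:
    """GAN-mode sweep (the four generator/discriminator variants, optionally a
    white-noise-latent row) or ROI-strategy sweep with paired comparisons."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.kind, config.seed, config.to_dict(), started=_timestamp())

    if config.kind == "ablation_gan":
        sset, feats, _spec, _rset, _ = _prepare_assets(config, train_gan=False)
        truths = sset.images()
        rows = []
        for mode in mcgan.MODES:
            gconf = mcgan.McGANConfig.desk_scale(
                id_dim=feats.block_dims["identity"],
                image_size=config.image_size,
                epochs=config.gan_epochs,
                mode=mode,
            )
            gen, _, _ = mcgan.train_mcgan(sset.images(), feats, gconf, seed=fanout_seed(config.seed, "mcgan"))
            recons = mcgan.reconstruct(gen, feats)
            m = _per_image_metrics(recons, truths)
            rows.append({"mode": mode, "mse": m["mse"].mean(), "ssim": m["ssim"].mean(), "psnr": m["psnr"].mean()})
            if mode == "mcgan" and config.include_white_noise:
                rng = np.random.default_rng(fanout_seed(config.seed, "evaluation"))
                noise_z = rng.normal(size=(len(sset), feats.z.shape[1]))
                recons_noise = mcgan.reconstruct(gen, noise_z)
                m = _per_image_metrics(recons_noise, truths)
                rows.append(
                    {"mode": "white_noise", "mse": m["mse"].mean(), "ssim": m["ssim"].mean(), "psnr": m["psnr"].mean()}
                )
        table = pd.DataFrame(rows)
    elif config.kind == "ablation_strategy":
        sset, feats, _spec, rset, generator = _prepare_assets(config)
        truths = sset.images()
        per_strategy_ssim = {}
        rows = []
        for name in ("strategy1", "strategy2", "strategy3", "strategy4", "strategy5", "proposed"):
            maps = fit_strategy_maps(rset, feats, name, runs=config.train_runs, mode="stack")
            pred = predict_strategy_features(rset, maps, name, runs=config.predict_runs, mode="average")
            recons = mcgan.reconstruct(generator, pred)
            m = _per_image_metrics(recons, truths)
            per_strategy_ssim[name] = m["ssim"].to_numpy()
            rows.append({"strategy": name, "mse": m["mse"].mean(), "ssim": m["ssim"].mean(), "psnr": m["psnr"].mean()})
        table = pd.DataFrame(rows)
        for other in ("strategy1", "strategy2"):
            t, p = stats.ttest_rel(per_strategy_ssim["proposed"], per_strategy_ssim[other])
            manifest.metrics[f"paired_t_proposed_vs_{other}"] = {"t": float(t), "p": float(p)}
    else:
        raise ConfigurationError(f"unknown ablation sweep for kind {config.kind!r}")

    table.to_csv(outdir / "ablation_table.csv", index=False)
    manifest.artifacts["ablation_table"] = str(outdir / "ablation_table.csv")
    manifest.metrics["table"] = table.to_dict(orient="records")
    manifest.finished = _timestamp()
    manifest.artifacts["manifest"] = str(manifest.write(outdir))
    return manifest


def run_roi_contribution(config: ExperimentConfig) -> RunManifest:
    """Per-ROI, per-attribute linear decoding followed by the resampled
    feature-space recognizability statistic (40 repeats, FDR across the
    ROI x attribute grid)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.kind, config.seed, config.to_dict(), started=_timestamp())
    _sset, feats, _spec, rset, _ = _prepare_assets(config, train_gan=False)
    targets = {"expression": feats.t_exp, "identity": feats.t_id, "gender": feats.t_gen}
    results, rows = [], []
    for roi in ROI_NAMES:
        for attribute in ATTRIBUTES:
            S_train = np.concatenate([rset.get(r, roi) for r in config.train_runs], axis=0)
            T_train = np.tile(targets[attribute], (len(config.train_runs), 1))
            lmap = fit_linear_map(S_train, T_train)
            S_test = np.mean([rset.get(r, roi) for r in config.predict_runs], axis=0)
            pred = lmap.predict(S_test)
            res = roi_reconstruction_accuracy(
                pred,
                targets[attribute],
                attribute=f"{roi}/{attribute}",
                n_repeats=config.n_repeats,
                seed=fanout_seed(config.seed, "evaluation"),
            )
            results.append(res)
            rows.append({"roi": roi, "attribute": attribute})
    fdr_adjust(results)
    for row, res in zip(rows, results):
        row.update(accuracy=res.mean, sd=res.sd, t=res.t, p_raw=res.p_raw, p_fdr=res.p_fdr)
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "roi_contribution.csv", index=False)
    manifest.artifacts["roi_contribution"] = str(outdir / "roi_contribution.csv")
    manifest.metrics["table"] = table.to_dict(orient="records")
    manifest.finished = _timestamp()
    manifest.artifacts["manifest"] = str(manifest.write(outdir))
    return manifest


def _second_subject_responses(feats, spec, config):
    """Subject B shares A's encoding up to a random orthogonal voxel mixing
    per ROI, with independent run noise."""
    rng = np.random.default_rng(fanout_seed(config.seed, "subject_b"))
    v = spec.voxels_per_roi
    mixes = {}
    for roi in spec.roi_names:
        q, _ = np.linalg.qr(rng.normal(size=(v, v)))
        mixes[roi] = q
    weights_b = {roi: spec.weights[roi] @ mixes[roi] for roi in spec.roi_names}
    spec_b = EncodingSpec(
        weights_b, dict(spec.block_dims), spec.noise_sd, v, tuple(spec.roi_names), dict(spec.selectivity)
    )
    rset_b = simulate_roi_responses(
        feats, spec_b, n_runs=config.n_runs, seed=fanout_seed(config.seed, "subject_b") + 1
    )
    return rset_b


def run_inter_subject(config: ExperimentConfig) -> RunManifest:
    """Train the framework on synthetic subject A, reconstruct from subject B
    after eigen-space alignment on shared stimuli."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config.kind, config.seed, config.to_dict(), started=_timestamp())
    sset, feats, spec, rset_a, generator = _prepare_assets(config)
    rset_b = _second_subject_responses(feats, spec, config)
    strategy = get_strategy(config.strategy)
    targets = {"expression": feats.t_exp, "identity": feats.t_id, "gender": feats.t_gen}

    n = len(sset)
    if config.kind == "inter_unseen":
        rng = np.random.default_rng(fanout_seed(config.seed, "split"))
        order = rng.permutation(n)
        n_test = max(n // config.n_folds, 2)
        test_idx, shared_idx = order[:n_test], order[n_test:]
    elif config.kind == "inter_seen":
        test_idx = shared_idx = np.arange(n)
    else:
        raise ConfigurationError(f"run_inter_subject cannot handle kind {config.kind!r}")

    eigens_a, eigens_b, cmaps, maps_a = {}, {}, {}, {}
    pred_blocks = {}
    for attribute in ATTRIBUTES:
        SA = assemble_design(rset_a, strategy, attribute, runs=config.train_runs, mode="stack")
        k = min(config.eigen_k, SA.shape[0] - 1, SA.shape[1])
        eigens_a[attribute] = fit_eigenspace(SA, k=k)
        coords_a = eigens_a[attribute].transform(SA)
        T = np.tile(targets[attribute], (len(config.train_runs), 1))
        maps_a[attribute] = fit_linear_map(coords_a, T)

        SB = assemble_design(rset_b, strategy, attribute, runs=config.train_runs, mode="stack")
        eigens_b[attribute] = fit_eigenspace(SB, k=k)
        # alignment uses only shared stimuli (averaged over training runs)
        SA_shared = assemble_design(rset_a, strategy, attribute, runs=config.train_runs, mode="average")[shared_idx]
        SB_shared = assemble_design(rset_b, strategy, attribute, runs=config.train_runs, mode="average")[shared_idx]
        cmaps[attribute] = fit_cross_subject_map(
            eigens_a[attribute].transform(SA_shared), eigens_b[attribute].transform(SB_shared)
        )
        SB_test = assemble_design(rset_b, strategy, attribute, runs=config.predict_runs, mode="average")[test_idx]
        coords_test = cmaps[attribute](eigens_b[attribute].transform(SB_test))
        pred_blocks[attribute] = maps_a[attribute].predict(coords_test)

    from .mapping import assemble_multidim_features

    pred = apply_block_constraints(
        assemble_multidim_features(pred_blocks["expression"], pred_blocks["identity"], pred_blocks["gender"]),
        strategy,
    )
    recons = mcgan.reconstruct(generator, pred)
    truths = sset.images()[test_idx]
    metrics = _per_image_metrics(recons, truths)
    metrics.to_csv(outdir / "per_image_metrics.csv", index=False)
    acc = ssim_accuracy(recons, truths, n_repeats=config.n_repeats, seed=fanout_seed(config.seed, "evaluation"))
    feat_res = [
        roi_reconstruction_accuracy(
            pred.block(a), targets[a][test_idx], attribute=a, n_repeats=config.n_repeats,
            seed=fanout_seed(config.seed, "evaluation"),
        )
        for a in ATTRIBUTES
    ]
    fdr_adjust([acc] + feat_res)
    manifest.artifacts["per_image_metrics"] = str(outdir / "per_image_metrics.csv")
    manifest.artifacts["reconstructions"] = _write_recons(recons, outdir, config.kind)
    manifest.metrics["ssim_accuracy"] = _result_record(acc)
    for a, res in zip(ATTRIBUTES, feat_res):
        manifest.metrics[f"reconstruction_accuracy_{a}"] = _result_record(res)
    manifest.finished = _timestamp()
    manifest.artifacts["manifest"] = str(manifest.write(outdir))
    return manifest


def run_experiment(config: ExperimentConfig) -> RunManifest:
    if config.kind in ("intra_seen", "intra_unseen"):
        return run_intra_subject(config)
    if config.kind in ("inter_seen", "inter_unseen"):
        return run_inter_subject(config)
    if config.kind in ("ablation_gan", "ablation_strategy"):
        return run_ablation_suite(config)
    return run_roi_contribution(config)
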