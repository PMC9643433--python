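"""Synthetic attribute-labelled face stimuli and simulated ROI voxel responses.

The stimulus generator draws parameterized grayscale face glyphs with a
factorial identity x expression x gender structure: identity controls six
continuous shape parameters (face outline, eye geometry, nose length),
expression controls mouth curvature and eyebrow angle in seven discrete
settings, and gender controls a dichotomous cue (jaw width plus a hair band).
The response simulator produces per-run voxel responses for six face-network
ROIs as a noisy linear encoding of the stimulus feature blocks, with
ROI-specific attribute selectivity (expression-selective pSTS/amygdala,
identity/gender-selective FFA/aIT, holistic OFA, weakly broadband V1), so the
whole decoding chain can be exercised and checked against known ground truth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .features import EXPRESSIONS, N_EXPRESSIONS, N_GENDERS, AttributeFeatures
from .utils import ConfigurationError, fanout_seed

ROI_NAMES = ("V1", "OFA", "FFA", "aIT", "pSTS", "amygdala")

#: which feature blocks each ROI encodes (nonzero rows of its true weights)
DEFAULT_SELECTIVITY = {
    "V1": ("identity", "expression", "gender"),
    "OFA": ("identity", "expression", "gender"),
    "FFA": ("identity", "gender"),
    "aIT": ("identity", "gender"),
    "pSTS": ("expression",),
    "amygdala": ("expression",),
}

N_IDENTITY_PARAMS = 6

# Mouth-curvature levels are equally spaced over the seven expression
# categories; eyebrow-angle levels use a fixed permutation of equally spaced
# values so the two expression cues are not collinear.
_CURVATURE_LEVELS = np.linspace(-1.0, 1.0, N_EXPRESSIONS)
_BROW_PERMUTATION = (3, 0, 5, 1, 6, 2, 4)
_BROW_LEVELS = np.linspace(-0.6, 0.6, N_EXPRESSIONS)[list(_BROW_PERMUTATION)]


@dataclass
class FaceStimulus:
    image: np.ndarray  # uint8, H x W
    identity_id: int
    expression_id: int
    gender_id: int
    split: str | None = None


@dataclass
class FaceStimulusSet:
    stimuli: list
    identity_params: dict = field(default_factory=dict)  # identity_id -> 6-vector

    def __len__(self):
        return len(self.stimuli)

    def images(self) -> np.ndarray:
        return np.stack([s.image for s in self.stimuli])

    def labels(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "identity_id": [s.identity_id for s in self.stimuli],
                "expression_id": [s.expression_id for s in self.stimuli],
                "gender_id": [s.gender_id for s in self.stimuli],
                "split": [s.split for s in self.stimuli],
            }
        )

    def subset(self, split: str) -> "FaceStimulusSet":
        kept = [s for s in self.stimuli if s.split == split]
        params = {s.identity_id: self.identity_params[s.identity_id] for s in kept}
        return FaceStimulusSet(kept, params)

    @property
    def identities(self):
        return sorted({s.identity_id for s in self.stimuli})

    @property
    def image_size(self):
        return self.stimuli[0].image.shape


def _render_face(params, expression_id, gender_id, image_size):
    h, w = image_size
    y, x = np.mgrid[0:h, 0:w]
    # normalized coordinates in [-1, 1]; y grows downwards
    x = (x - (w - 1) / 2.0) / ((w - 1) / 2.0)
    y = (y - (h - 1) / 2.0) / ((h - 1) / 2.0)

    p = np.tanh(np.asarray(params, dtype=float))
    face_a = 0.62 + 0.08 * p[0]
    face_b = 0.80 + 0.08 * p[1]
    eye_dx = 0.28 + 0.07 * p[2]
    eye_y = -0.28 + 0.05 * p[3]
    eye_r = 0.075 + 0.02 * p[4]
    nose_len = 0.20 + 0.06 * p[5]

    # gender cue: wide jaw for gender 1, hair band for gender 0
    jaw_sign = 1.0 if gender_id == 1 else -1.0
    a_eff = face_a * (1.0 + 0.14 * jaw_sign * np.clip(y, 0.0, 1.0))
    r = np.sqrt((x / a_eff) ** 2 + (y / face_b) ** 2)
    stroke = np.abs(r - 1.0) < 0.07

    for s in (-1.0, 1.0):
        stroke |= (x - s * eye_dx) ** 2 + (y - eye_y) ** 2 < eye_r**2
        brow = _BROW_LEVELS[expression_id]
        near = np.abs(x - s * eye_dx) < 0.13
        stroke |= near & (np.abs(y - (eye_y - 0.16 + s * brow * (x - s * eye_dx))) < 0.035)

    stroke |= (np.abs(x) < 0.028) & (y > eye_y + 0.10) & (y < eye_y + 0.10 + nose_len)

    mouth_w = 0.30
    curve = _CURVATURE_LEVELS[expression_id]
    inside_mouth = np.abs(x) < mouth_w
    mouth_curve = 0.48 + 0.18 * curve * ((x / mouth_w) ** 2 - 1.0)
    stroke |= inside_mouth & (np.abs(y - mouth_curve) < 0.04)

    if gender_id == 0:
        stroke |= (np.abs(y + 0.60) < 0.055) & (r < 0.98)

    return np.where(stroke, 255, 0).astype(np.uint8)


def generate_stimulus_set(n_identities, n_expressions=N_EXPRESSIONS, image_size=(64, 64), seed=0, genders=None):
    """Render ``n_identities * n_expressions`` labelled face glyphs.

    Identity shape parameters are drawn from a seeded standard normal; gender
    defaults to the parity of the identity index.  The output is a pure,
    bit-reproducible function of the arguments.
    """
    if n_identities < 1:
        raise ValueError("n_identities must be >= 1")
    if not 1 <= n_expressions <= N_EXPRESSIONS:
        raise ValueError(f"n_expressions must be in 1..{N_EXPRESSIONS}")
    h, w = image_size
    if h < 16 or w < 16:
        raise ValueError("image size must be at least 16 x 16")
    rng = np.random.default_rng(seed)
    params = rng.normal(size=(n_identities, N_IDENTITY_PARAMS))
    if genders is None:
        genders = [i % N_GENDERS for i in range(n_identities)]
    elif len(genders) != n_identities:
        raise ValueError("genders must have one entry per identity")

    stimuli = []
    for i in range(n_identities):
        for e in range(n_expressions):
            img = _render_face(params[i], e, genders[i], image_size)
            stimuli.append(FaceStimulus(img, i, e, int(genders[i])))
    return FaceStimulusSet(stimuli, {i: params[i] for i in range(n_identities)})


def split_dataset(sset: FaceStimulusSet, counts, seed=0, identity_disjoint=False):
    """Tag stimuli with disjoint ``train`` / ``val_fit`` / ``val_predict`` splits.

    ``counts`` gives the exact split sizes and must sum to the set size.  With
    ``identity_disjoint`` the training identities never occur in either
    validation part (the open-set protocol); this requires the training count
    to be attainable as a union of whole identities.
    """
    n_train, n_fit, n_pred = counts
    if n_train + n_fit + n_pred != len(sset):
        raise ValueError(f"counts {counts} do not sum to set size {len(sset)}")
    if n_fit == 0 and n_pred == 0:
        warnings.warn("empty validation splits: all stimuli assigned to train")
    rng = np.random.default_rng(seed)
    stimuli = [FaceStimulus(s.image, s.identity_id, s.expression_id, s.gender_id) for s in sset.stimuli]

    if identity_disjoint:
        per_id = {}
        for idx, s in enumerate(stimuli):
            per_id.setdefault(s.identity_id, []).append(idx)
        ids = list(per_id)
        rng.shuffle(ids)
        train_idx = []
        for ident in ids:
            if len(train_idx) + len(per_id[ident]) <= n_train:
                train_idx.extend(per_id[ident])
            if len(train_idx) == n_train:
                break
        if len(train_idx) != n_train:
            raise ValueError("train count not attainable with identity-disjoint splitting")
        rest = np.array(sorted(set(range(len(stimuli))) - set(train_idx)))
        rest = rng.permutation(rest)
        order = np.concatenate([np.array(train_idx, dtype=int), rest])
    else:
        order = rng.permutation(len(stimuli))

    for j, idx in enumerate(order):
        if j < n_train:
            stimuli[idx].split = "train"
        elif j < n_train + n_fit:
            stimuli[idx].split = "val_fit"
        else:
            stimuli[idx].split = "val_predict"
    return FaceStimulusSet(stimuli, dict(sset.identity_params))


def indicator_features(sset: FaceStimulusSet) -> AttributeFeatures:
    """Ground-truth attribute features: glyph shape parameters for identity,
    one-hot vectors for expression and gender."""
    t_id = np.stack([sset.identity_params[s.identity_id] for s in sset.stimuli])
    t_exp = np.zeros((len(sset), N_EXPRESSIONS))
    t_gen = np.zeros((len(sset), N_GENDERS))
    for i, s in enumerate(sset.stimuli):
        t_exp[i, s.expression_id] = 1.0
        t_gen[i, s.gender_id] = 1.0
    return AttributeFeatures(t_id, t_exp, t_gen)


@dataclass
class EncodingSpec:
    """Ground-truth linear encoding from feature blocks to ROI voxels.

    ``weights[roi]`` has shape (total feature dim, voxels); rows belonging to
    feature blocks outside the ROI's selectivity are exactly zero.  Per-block
    weight variance is 1/block_dim so each selective block contributes about
    unit signal variance per voxel; ``noise_sd`` is the run-noise SD on that
    scale.
    """

    weights: dict
    block_dims: dict
    noise_sd: float = 1.0
    voxels_per_roi: int = 56
    roi_names: tuple = ROI_NAMES
    selectivity: dict = field(default_factory=lambda: dict(DEFAULT_SELECTIVITY))

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        dim = sum(self.block_dims.values())
        for roi in self.roi_names:
            if roi not in self.weights:
                raise ConfigurationError(f"no weight matrix for ROI {roi!r}")
            if self.weights[roi].shape != (dim, self.voxels_per_roi):
                raise ConfigurationError(
                    f"weights for {roi!r} have shape {self.weights[roi].shape}, "
                    f"expected {(dim, self.voxels_per_roi)}"
                )

    @classmethod
    def default(
        cls,
        block_dims,
        voxels_per_roi=56,
        noise_sd=1.0,
        seed=0,
        roi_names=ROI_NAMES,
        selectivity=None,
        v1_gain=0.5,
    ):
        selectivity = dict(DEFAULT_SELECTIVITY if selectivity is None else selectivity)
        for roi in roi_names:
            if roi not in selectivity:
                raise ConfigurationError(f"no selectivity defined for ROI {roi!r}")
        rng = np.random.default_rng(seed)
        dim = sum(block_dims.values())
        offsets, start = {}, 0
        for name in ("identity", "expression", "gender"):
            offsets[name] = (start, start + block_dims[name])
            start += block_dims[name]
        weights = {}
        for roi in roi_names:
            W = np.zeros((dim, voxels_per_roi))
            gain = v1_gain if roi == "V1" else 1.0
            for blockname in selectivity[roi]:
                lo, hi = offsets[blockname]
                W[lo:hi] = rng.normal(0.0, gain / np.sqrt(block_dims[blockname]), size=(hi - lo, voxels_per_roi))
            weights[roi] = W
        return cls(weights, dict(block_dims), noise_sd, voxels_per_roi, tuple(roi_names), selectivity)


@dataclass
class ROIResponseSet:
    """Per-run, per-ROI stimulus x voxel response matrices."""

    responses: dict  # (run, roi) -> (n_stim, voxels) array
    roi_names: tuple
    n_runs: int
    n_stimuli: int

    def get(self, run, roi):
        if (run, roi) not in self.responses:
            raise ConfigurationError(f"no responses for run {run}, ROI {roi!r}")
        return self.responses[(run, roi)]

    @property
    def voxels_per_roi(self):
        return self.responses[(0, self.roi_names[0])].shape[1]


def simulate_roi_responses(features: AttributeFeatures, spec: EncodingSpec, n_runs=5, seed=0):
    """Simulate ``response(run, stim, roi) = z(stim) @ W_true(roi) + noise``.

    Noise is i.i.d. Gaussian per run/stimulus/voxel with SD ``spec.noise_sd``;
    the signal part is identical across runs.
    """
    z = features.z
    dim = sum(spec.block_dims.values())
    if z.shape[1] != dim:
        raise ConfigurationError(f"feature dim {z.shape[1]} does not match encoding spec dim {dim}")
    rng = np.random.default_rng(seed)
    responses = {}
    for run in range(n_runs):
        for roi in spec.roi_names:
            signal = z @ spec.weights[roi]
            noise = rng.normal(0.0, spec.noise_sd, size=signal.shape) if spec.noise_sd > 0 else 0.0
            responses[(run, roi)] = signal + noise
    return ROIResponseSet(responses, tuple(spec.roi_names), n_runs, len(features))


# ---------------------------------------------------------------------------
# on-disk formats: 8-bit PNGs + delimited label table; per-run response CSVs
# with a JSON sidecar
# ---------------------------------------------------------------------------


def save_stimulus_set(sset: FaceStimulusSet, outdir):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in sset.stimuli:
        fname = f"id{s.identity_id:03d}_exp{s.expression_id}.png"
        Image.fromarray(s.image, mode="L").save(outdir / fname)
        rows.append((fname, s.identity_id, s.expression_id, s.gender_id, s.split or ""))
    pd.DataFrame(rows, columns=["filename", "identity_id", "expression_id", "gender_id", "split"]).to_csv(
        outdir / "labels.csv", index=False
    )
    params = pd.DataFrame(
        {str(k): v for k, v in sorted(sset.identity_params.items())}
    ).T
    params.index.name = "identity_id"
    params.to_csv(outdir / "identity_params.csv")
    return outdir


def load_stimulus_set(indir) -> FaceStimulusSet:
    indir = Path(indir)
    labels = pd.read_csv(indir / "labels.csv", keep_default_na=False)
    params = pd.read_csv(indir / "identity_params.csv", index_col=0)
    stimuli = []
    for row in labels.itertuples():
        img = np.asarray(Image.open(indir / row.filename).convert("L"))
        stimuli.append(
            FaceStimulus(img, int(row.identity_id), int(row.expression_id), int(row.gender_id), row.split or None)
        )
    identity_params = {int(i): params.loc[i].to_numpy(dtype=float) for i in params.index}
    return FaceStimulusSet(stimuli, identity_params)


def save_responses(rset: ROIResponseSet, outdir, spec: EncodingSpec = None, seed=None):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for run in range(rset.n_runs):
        blocks, columns = [], []
        for roi in rset.roi_names:
            mat = rset.get(run, roi)
            blocks.append(mat)
            columns.extend(f"{roi}:{v}" for v in range(mat.shape[1]))
        pd.DataFrame(np.concatenate(blocks, axis=1), columns=columns).to_csv(
            outdir / f"responses_run{run}.csv", index=False
        )
    sidecar = {"roi_names": list(rset.roi_names), "n_runs": rset.n_runs, "n_stimuli": rset.n_stimuli}
    if seed is not None:
        sidecar["seed"] = int(seed)
    if spec is not None:
        sidecar["encoding"] = {
            "block_dims": spec.block_dims,
            "noise_sd": spec.noise_sd,
            "voxels_per_roi": spec.voxels_per_roi,
            "selectivity": {k: list(v) for k, v in spec.selectivity.items()},
        }
    (outdir / "responses.json").write_text(json.dumps(sidecar, indent=2))
    return outdir


def load_responses(indir) -> ROIResponseSet:
    indir = Path(indir)
    sidecar = json.loads((indir / "responses.json").read_text())
    roi_names = tuple(sidecar["roi_names"])
    responses = {}
    for run in range(sidecar["n_runs"]):
        df = pd.read_csv(indir / f"responses_run{run}.csv")
        for roi in roi_names:
            cols = [c for c in df.columns if c.startswith(f"{roi}:")]
            responses[(run, roi)] = df[cols].to_numpy()
    return ROIResponseSet(responses, roi_names, sidecar["n_runs"], sidecar["n_stimuli"])


def default_assets(n_identities=20, image_size=(64, 64), n_runs=5, noise_sd=1.0, seed=0):
    """Convenience bundle: stimuli, their indicator features, a default
    encoding spec and simulated responses, all deterministically seeded."""
    sset = generate_stimulus_set(n_identities, image_size=image_size, seed=fanout_seed(seed, "stimuli"))
    feats = indicator_features(sset)
    spec = EncodingSpec.default(feats.block_dims, noise_sd=noise_sd, seed=fanout_seed(seed, "encoding"))
    rset = simulate_roi_responses(feats, spec, n_runs=n_runs, seed=fanout_seed(seed, "responses"))
    return sset, feats, spec, rset
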