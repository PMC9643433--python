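"""Multi-task attribute network (shared trunk, three branches).

A VGG-style stack of five conv blocks and two fully-connected layers feeds
three classification heads of dims (7, N, 2) for expression, identity and
gender.  The ``split_index`` chooses how many of the seven units are shared
before the network branches; the joint loss is the convex combination
``alpha1*CE_exp + alpha2*CE_id + alpha3*CE_gen``.  Identity generalization is
scored with an open-set verification protocol: Euclidean distances between
penultimate identity-branch activations of image pairs, thresholded with
10-fold cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .features import N_EXPRESSIONS, N_GENDERS, AttributeFeatures
from .synthetic import FaceStimulusSet

N_UNITS = 7  # five conv blocks + two fully-connected layers
TASKS = ("expression", "identity", "gender")


@dataclass
class MTDLNConfig:
    n_identities: int
    split_index: int = 4
    alphas: tuple = (0.4, 0.3, 0.3)
    image_size: tuple = (64, 64)
    channels: tuple = (64, 128, 256, 512, 512)
    fc_width: int = 512
    learning_rate: float = 0.001
    momentum: float = 0.9
    batch_size: int = 32
    epochs: int = 500
    l2_rate: float = 0.001  # first FC layer of each branch
    dropout: float = 0.5  # second FC layer of each branch
    freeze_trunk: bool = False
    openset_pairs: tuple = (900, 900)
    openset_folds: int = 10

    def __post_init__(self):
        if not 0 <= self.split_index <= N_UNITS:
            raise ValueError(f"split_index must be in 0..{N_UNITS}")
        validate_alphas(self.alphas)
        h, w = self.image_size
        if h % 32 or w % 32:
            raise ValueError("image size must be a multiple of 32 (five pooling stages)")

    @property
    def head_dims(self):
        return (N_EXPRESSIONS, self.n_identities, N_GENDERS)

    @classmethod
    def desk_scale(cls, n_identities, image_size=(32, 32), epochs=10, **kwargs):
        """Small-width configuration suitable for CPU-scale experiments."""
        defaults = dict(
            channels=(8, 16, 24, 32, 32),
            fc_width=32,
            epochs=epochs,
            openset_pairs=(100, 100),
        )
        defaults.update(kwargs)
        return cls(n_identities=n_identities, image_size=image_size, **defaults)


def validate_alphas(alphas):
    alphas = tuple(float(a) for a in alphas)
    if len(alphas) != 3 or any(a < 0 for a in alphas):
        raise ValueError("alphas must be three nonnegative reals")
    if abs(sum(alphas) - 1.0) > 1e-8:
        raise ValueError(f"alphas must sum to 1, got {sum(alphas)}")
    return alphas


def multitask_loss(losses, alphas):
    """Convex combination of the three per-task cross-entropies."""
    alphas = validate_alphas(alphas)
    if len(losses) != 3:
        raise ValueError("expected three per-task losses")
    return float(sum(a * l for a, l in zip(alphas, losses)))


def _make_unit(u, config, rng, in_channels):
    """Unit u of 7: conv blocks 0-4 (conv-relu-conv-relu-pool), FC units 5-6."""
    if u < 5:
        c = config.channels[u]
        return (
            [
                nn.Conv2d(in_channels, c, 3, 1, 1, rng=rng),
                nn.ReLU(),
                nn.Conv2d(c, c, 3, 1, 1, rng=rng),
                nn.ReLU(),
                nn.MaxPool2d(2),
            ],
            c,
        )
    h, w = config.image_size
    flat = config.channels[-1] * (h // 32) * (w // 32)
    if u == 5:
        return [nn.Flatten(), nn.Dense(flat, config.fc_width, rng, weight_decay=config.l2_rate), nn.ReLU()], None
    return (
        [
            nn.Dense(config.fc_width, config.fc_width, rng),
            nn.ReLU(),
            nn.Dropout(config.dropout, rng),
        ],
        None,
    )


class MTDLN:
    """Shared trunk + three branch networks with heads of dims (7, N, 2)."""

    def __init__(self, config: MTDLNConfig, seed=0):
        self.config = config
        rng = np.random.default_rng(seed)
        s = config.split_index

        def build_units(u_range, c_in):
            layers = []
            for u in u_range:
                unit, c_out = _make_unit(u, config, rng, c_in)
                layers.extend(unit)
                if c_out is not None:
                    c_in = c_out
            return layers, c_in

        trunk_layers, c_after = build_units(range(s), 1)
        self.trunk = nn.Sequential(trunk_layers)
        self.branches = {}
        for task, head_dim in zip(TASKS, config.head_dims):
            branch_layers, _ = build_units(range(s, N_UNITS), c_after)
            branch_layers.append(nn.Dense(config.fc_width, head_dim, rng))
            self.branches[task] = nn.Sequential(branch_layers)

    # -- bookkeeping -------------------------------------------------------
    def trunk_n_params(self):
        return self.trunk.n_params()

    def branch_exclusive_n_params(self):
        return sum(b.n_params() for b in self.branches.values())

    def params_and_grads(self):
        if not self.config.freeze_trunk:
            yield from self.trunk.params_and_grads()
        for task, branch in self.branches.items():
            for name, v, g, wd in branch.params_and_grads():
                yield (f"{task}.{name}", v, g, wd)

    def zero_grad(self):
        self.trunk.zero_grad()
        for branch in self.branches.values():
            branch.zero_grad()

    # -- forward/backward --------------------------------------------------
    def _preprocess(self, images):
        images = np.asarray(images)
        if images.ndim == 2:
            images = images[None]
        if images.shape[1:] != tuple(self.config.image_size):
            raise ValueError(
                f"image size {images.shape[1:]} does not match model input {tuple(self.config.image_size)}"
            )
        return ((images.astype(float) - 127.5) / 127.5)[:, None]

    def forward(self, images, train=False):
        x = self._preprocess(images)
        shared = self.trunk.forward(x, train=train)
        return {task: branch.forward(shared, train=train) for task, branch in self.branches.items()}

    def backward(self, dlogits):
        dshared = sum(self.branches[task].backward(d) for task, d in dlogits.items())
        self.trunk.backward(dshared)

    def identity_embedding(self, images):
        """Penultimate identity-branch activations (features before the head)."""
        x = self._preprocess(images)
        shared = self.trunk.forward(x, train=False)
        branch = self.branches["identity"]
        for layer in branch.layers[:-1]:
            shared = layer.forward(shared, train=False)
        return shared


def build_mtdln(config: MTDLNConfig, seed=0) -> MTDLN:
    return MTDLN(config, seed=seed)


def save_mtdln(model: MTDLN, path):
    """Checkpoint: npz of weights plus a JSON config manifest alongside."""
    import dataclasses
    import json
    from pathlib import Path

    path = Path(path)
    arrays = {"trunk." + n: v for n, v, _, _ in model.trunk.params_and_grads()}
    for task, branch in model.branches.items():
        arrays.update({f"{task}.{n}": v for n, v, _, _ in branch.params_and_grads()})
    np.savez(path, **arrays)
    cfg = dataclasses.asdict(model.config)
    Path(str(path) + ".json").write_text(json.dumps(cfg, indent=2, default=list))


def load_mtdln(path) -> MTDLN:
    import json
    from pathlib import Path

    cfg = json.loads(Path(str(path) + ".json").read_text())
    for key in ("alphas", "image_size", "channels", "openset_pairs"):
        cfg[key] = tuple(cfg[key])
    model = MTDLN(MTDLNConfig(**cfg))
    data = np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz")
    for n, v, _, _ in model.trunk.params_and_grads():
        v[...] = data["trunk." + n]
    for task, branch in model.branches.items():
        for n, v, _, _ in branch.params_and_grads():
            v[...] = data[f"{task}.{n}"]
    return model


@dataclass
class TrainingHistory:
    """Per-epoch validation accuracies (expression, identity open-set, gender)."""

    expression: list = field(default_factory=list)
    identity: list = field(default_factory=list)
    gender: list = field(default_factory=list)

    def __len__(self):
        return len(self.expression)

    @property
    def peaks(self):
        return {
            "expression": max(self.expression) if self.expression else None,
            "identity": max(self.identity) if self.identity else None,
            "gender": max(self.gender) if self.gender else None,
        }


def _arrays_from_set(sset: FaceStimulusSet, identity_index=None):
    images = sset.images()
    y_exp = np.array([s.expression_id for s in sset.stimuli])
    y_gen = np.array([s.gender_id for s in sset.stimuli])
    if identity_index is None:
        identity_index = {ident: k for k, ident in enumerate(sset.identities)}
    y_id = np.array([identity_index[s.identity_id] for s in sset.stimuli])
    return images, y_exp, y_id, y_gen


def train_mtdln(model: MTDLN, train_set, val_set, config: MTDLNConfig = None, seed=0):
    """SGD training of the joint loss with per-epoch validation logging.

    The identity task uses training identities relabelled 0..N-1; validation
    identity performance is the open-set pair accuracy, so the validation
    identities may (and for the open-set protocol must) be disjoint from
    training.
    """
    config = config or model.config
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("training and validation sets must be non-empty")
    images, y_exp, y_id, y_gen = _arrays_from_set(train_set)
    if y_id.max() >= config.n_identities:
        raise ValueError("more training identities than the identity head has units")
    labels = {"expression": y_exp, "identity": y_id, "gender": y_gen}
    alphas = dict(zip(TASKS, config.alphas))
    optimizer = nn.SGD(lr=config.learning_rate, momentum=config.momentum)
    rng = np.random.default_rng(seed)
    history = TrainingHistory()
    n = len(images)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model.forward(images[idx], train=True)
            dlogits = {}
            for task in TASKS:
                _, dl = nn.softmax_cross_entropy(logits[task], labels[task][idx])
                dlogits[task] = alphas[task] * dl
            model.zero_grad()
            model.backward(dlogits)
            optimizer.step(model)
        history.expression.append(evaluate_category_accuracy(model, val_set, "expression"))
        history.gender.append(evaluate_category_accuracy(model, val_set, "gender"))
        n_same, n_diff = config.openset_pairs
        history.identity.append(
            evaluate_identity_openset(
                model, val_set, n_same=n_same, n_diff=n_diff, folds=config.openset_folds, seed=seed + epoch
            )
        )
    return model, history


def category_accuracy(predicted_labels, true_labels):
    predicted_labels = np.asarray(predicted_labels)
    true_labels = np.asarray(true_labels)
    return float(np.mean(predicted_labels == true_labels))


def evaluate_category_accuracy(model: MTDLN, val_set, task):
    """Fraction of argmax-correct predictions for expression or gender."""
    if task not in ("expression", "gender"):
        raise ValueError(f"unknown task {task!r} (expected 'expression' or 'gender')")
    images, y_exp, _, y_gen = _arrays_from_set(val_set)
    logits = model.forward(images, train=False)[task]
    truth = y_exp if task == "expression" else y_gen
    return category_accuracy(logits.argmax(axis=1), truth)


def openset_accuracy(features, identity_labels, n_same=900, n_diff=900, folds=10, seed=0):
    """Cross-validated pair-verification accuracy on identity features.

    Same/different pairs are drawn (with replacement across draws), Euclidean
    distances computed, pairs partitioned into ``folds`` groups, and for each
    group the distance threshold that maximizes accuracy on the remaining
    groups is applied to it; the smallest such threshold wins ties.
    """
    features = np.asarray(features, dtype=float)
    identity_labels = np.asarray(identity_labels)
    rng = np.random.default_rng(seed)
    by_id = {}
    for i, ident in enumerate(identity_labels):
        by_id.setdefault(int(ident), []).append(i)
    multi = [ident for ident, idxs in by_id.items() if len(idxs) >= 2]
    if n_same > 0 and not multi:
        raise ValueError("no identity has two or more images; cannot form same-identity pairs")
    if n_diff > 0 and len(by_id) < 2:
        raise ValueError("need at least two distinct identities to form different-identity pairs")

    pairs = np.empty((n_same + n_diff, 2), dtype=int)
    for k in range(n_same):
        ident = multi[rng.integers(len(multi))]
        pairs[k] = rng.choice(by_id[ident], size=2, replace=False)
    ids = list(by_id)
    for k in range(n_diff):
        a, b = rng.choice(len(ids), size=2, replace=False)
        pairs[n_same + k, 0] = by_id[ids[a]][rng.integers(len(by_id[ids[a]]))]
        pairs[n_same + k, 1] = by_id[ids[b]][rng.integers(len(by_id[ids[b]]))]
    labels = np.concatenate([np.ones(n_same, bool), np.zeros(n_diff, bool)])

    d = np.linalg.norm(features[pairs[:, 0]] - features[pairs[:, 1]], axis=1)
    order = rng.permutation(len(d))
    fold_of = np.empty(len(d), dtype=int)
    for f, chunk in enumerate(np.array_split(order, folds)):
        fold_of[chunk] = f

    accs = []
    for f in range(folds):
        tr = fold_of != f
        te = ~tr
        cand = np.concatenate(([-1.0], np.unique(d[tr])))
        preds = d[tr][None, :] <= cand[:, None]
        train_acc = (preds == labels[tr][None, :]).mean(axis=1)
        thr = cand[int(np.argmax(train_acc))]  # first max = smallest threshold
        accs.append(np.mean((d[te] <= thr) == labels[te]))
    return float(np.mean(accs))


def evaluate_identity_openset(model: MTDLN, val_set, n_same=900, n_diff=900, folds=10, seed=0):
    images = val_set.images()
    feats = model.identity_embedding(images)
    ids = np.array([s.identity_id for s in val_set.stimuli])
    return openset_accuracy(feats, ids, n_same=n_same, n_diff=n_diff, folds=folds, seed=seed)


def extract_features(model: MTDLN, images) -> AttributeFeatures:
    """Multi-dimensional face features: penultimate identity activations plus
    softmax expression/gender head outputs, concatenated as z."""
    t_id = model.identity_embedding(images)
    logits = model.forward(images, train=False)
    t_exp = nn.softmax(logits["expression"])
    t_gen = nn.softmax(logits["gender"])
    return AttributeFeatures(t_id, t_exp, t_gen)
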