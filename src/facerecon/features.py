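"""Multi-dimensional face features: the (t_id, t_exp, t_gen) triplet.

``t_exp`` is a 7-vector over the basic expressions, ``t_gen`` a 2-vector over
gender, and ``t_id`` an identity embedding whose width depends on where the
features come from (a network's penultimate layer, glyph shape parameters, or
predictions of a linear map).  ``z`` is their concatenation in
(t_id, t_exp, t_gen) order and is what conditions the generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

EXPRESSIONS = ("fear", "anger", "disgust", "happiness", "neutral", "sadness", "surprise")
N_EXPRESSIONS = len(EXPRESSIONS)
N_GENDERS = 2

#: canonical block order inside z
BLOCK_ORDER = ("identity", "expression", "gender")


@dataclass
class AttributeFeatures:
    """Row-aligned feature blocks for a set of stimuli (2-D arrays, n x dim)."""

    t_id: np.ndarray
    t_exp: np.ndarray
    t_gen: np.ndarray

    def __post_init__(self):
        self.t_id = np.atleast_2d(np.asarray(self.t_id, dtype=float))
        self.t_exp = np.atleast_2d(np.asarray(self.t_exp, dtype=float))
        self.t_gen = np.atleast_2d(np.asarray(self.t_gen, dtype=float))
        n = len(self.t_id)
        if len(self.t_exp) != n or len(self.t_gen) != n:
            raise ValueError("feature blocks must have the same number of rows")

    def __len__(self):
        return len(self.t_id)

    @property
    def block_dims(self):
        return {
            "identity": self.t_id.shape[1],
            "expression": self.t_exp.shape[1],
            "gender": self.t_gen.shape[1],
        }

    @property
    def z(self) -> np.ndarray:
        return np.concatenate([self.t_id, self.t_exp, self.t_gen], axis=1)

    def block(self, name: str) -> np.ndarray:
        return {"identity": self.t_id, "expression": self.t_exp, "gender": self.t_gen}[name]

    @classmethod
    def from_z(cls, z, id_dim):
        z = np.atleast_2d(np.asarray(z, dtype=float))
        return cls(z[:, :id_dim], z[:, id_dim : id_dim + N_EXPRESSIONS], z[:, id_dim + N_EXPRESSIONS :])

    def take(self, idx):
        return AttributeFeatures(self.t_id[idx], self.t_exp[idx], self.t_gen[idx])


def save_features(feats: AttributeFeatures, path):
    """Write a delimited feature table (columns t_id_0.., t_exp_0.., t_gen_0..)."""
    import pandas as pd

    cols = (
        [f"t_id_{i}" for i in range(feats.t_id.shape[1])]
        + [f"t_exp_{i}" for i in range(N_EXPRESSIONS)]
        + [f"t_gen_{i}" for i in range(N_GENDERS)]
    )
    pd.DataFrame(feats.z, columns=cols).to_csv(path, index=False)


def load_features(path) -> AttributeFeatures:
    import pandas as pd

    df = pd.read_csv(path)
    id_dim = sum(c.startswith("t_id_") for c in df.columns)
    return AttributeFeatures.from_z(df.to_numpy(dtype=float), id_dim)
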