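"""Shared helpers: errors, seeding, small validation utilities."""

from __future__ import annotations

import numpy as np


class ConfigurationError(ValueError):
    """A config references resources (ROIs, paths, dims) that do not line up."""


#: Fixed offsets fanning one experiment seed out to per-component seeds, so a
#: component can be rerun in isolation and still match the full pipeline.
SEED_OFFSETS = {
    "stimuli": 11,
    "split": 23,
    "encoding": 37,
    "responses": 51,
    "mtdln": 67,
    "mcgan": 83,
    "evaluation": 101,
    "subject_b": 131,
}


def fanout_seed(seed: int, component: str) -> int:
    return (int(seed) + SEED_OFFSETS[component]) % (2**31)


def check_shapes_match(x, y):
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return x, y
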