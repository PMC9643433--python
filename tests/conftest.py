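import numpy as np
import pytest

import facerecon as fr
from facerecon import mcgan, mtdln


@pytest.fixture(scope="session")
def glyph_set():
    """10 identities x 7 expressions at 32 x 32."""
    return fr.generate_stimulus_set(10, image_size=(32, 32), seed=11)


@pytest.fixture(scope="session")
def desk_assets():
    """140-stimulus study conditions: 6 ROIs x 56 voxels, 5 runs, unit noise."""
    return fr.default_assets(n_identities=20, image_size=(32, 32), n_runs=5, noise_sd=1.0, seed=0)


@pytest.fixture(scope="session")
def trained_mtdln():
    """Small multi-task network trained on an identity-disjoint split."""
    sset = fr.generate_stimulus_set(14, image_size=(32, 32), seed=0)
    split = fr.split_dataset(sset, (70, 14, 14), seed=1, identity_disjoint=True)
    train = split.subset("train")
    val_fit, val_pred = split.subset("val_fit"), split.subset("val_predict")
    val = fr.FaceStimulusSet(
        val_fit.stimuli + val_pred.stimuli, {**val_fit.identity_params, **val_pred.identity_params}
    )
    config = mtdln.MTDLNConfig.desk_scale(n_identities=10, epochs=20, learning_rate=0.02)
    model = mtdln.build_mtdln(config, seed=0)
    model, history = mtdln.train_mtdln(model, train, val, config, seed=0)
    return model, history, train, val


@pytest.fixture(scope="session")
def trained_mcgan():
    """Conditional generator trained (full mcgan mode) on 49 toy glyphs."""
    sset = fr.generate_stimulus_set(7, image_size=(32, 32), seed=0)
    feats = fr.indicator_features(sset)
    config = mcgan.McGANConfig.desk_scale(id_dim=feats.block_dims["identity"], image_size=(32, 32), epochs=60)
    generator, discriminator, log = mcgan.train_mcgan(sset.images(), feats, config, seed=0)
    return generator, discriminator, log, sset, feats


@pytest.fixture(scope="session")
def converged_mcgan():
    """Tiny generator trained long enough for expression conditioning to
    emerge (the pixel-MAE loss learns mouth placement late)."""
    sset = fr.generate_stimulus_set(3, image_size=(32, 32), seed=0)
    feats = fr.indicator_features(sset)
    config = mcgan.McGANConfig.desk_scale(id_dim=feats.block_dims["identity"], image_size=(32, 32), epochs=700)
    generator, _disc, _log = mcgan.train_mcgan(sset.images(), feats, config, seed=0)
    return generator, feats


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
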