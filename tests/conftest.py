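import numpy as np
import pytest

from aigs import nets
from aigs.screen import referral_label


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def small_arch(**overrides) -> nets.ArchConfig:
    """64-px test-scale architecture config."""
    base = dict(input_side=64, base_channels=8, encoder_stages=3,
                channel_cap=32, bna_out_channels=4, fc_widths=(32, 16))
    base.update(overrides)
    return nets.ArchConfig(**base)


def balanced_or_dataset(repeats_neg: int = 300, repeats_pos: int = 20):
    """OR-labeled 4-bit decision vectors, rebalanced (the OR table is 15:1)."""
    grid = np.array([[a, b, c, d] for a in (0, 1) for b in (0, 1)
                     for c in (0, 1) for d in (0, 1)], np.float32)
    y = np.array([referral_label(*g) for g in grid])
    neg, pos = grid[y == 0], grid[y == 1]
    X = np.vstack([np.tile(neg, (repeats_neg, 1)),
                   np.tile(pos, (repeats_pos, 1))])
    lab = np.concatenate([np.zeros(repeats_neg, int),
                          np.ones(repeats_pos * len(pos), int)])
    return grid, y, X, lab


@pytest.fixture(scope="session")
def trained_fusion():
    """Fusion FFCN trained to reproduce the OR referral rule."""
    _, _, X, y = balanced_or_dataset()
    model = nets.build_ffcn(4, seed=0)
    model, _ = nets.train_classifier(model, (X, y), epochs=80, seed=0,
                                     lr=3e-3, batch_size=32)
    return model


@pytest.fixture(scope="session")
def tiny_bundle(trained_fusion):
    """Untrained small models + trained fusion: valid, deterministic bundle."""
    mtl = nets.build_mtl_unet(small_arch(
        heads=("segmentation", "classification")))
    bundle = nets.ModelBundle(models={
        "mtl": mtl,
        "cupping_ffcn": nets.build_ffcn(9, seed=1),
        "dh_segmenter": nets.build_lwbna_unet(
            small_arch(heads=("segmentation",))),
        "dh_classifier": nets.build_binary_classifier(
            small_arch(input_channels=6)),
        "rnfld_classifier": nets.build_binary_classifier(small_arch()),
        "fusion_ffcn": trained_fusion,
    })
    return bundle


@pytest.fixture(scope="session")
def phantom_scene():
    """One mid-size phantom with all findings, shared across tests."""
    from aigs.phantom import generate_phantom, sample_spec
    rng = np.random.default_rng(77)
    spec = sample_spec(rng, 256, glaucoma=True, dh_positive=True,
                       rnfld_positive=True)
    image, mask, truth = generate_phantom(spec, seed=5)
    return spec, image, mask, truth
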