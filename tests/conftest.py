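"""Shared fixtures: tiny phantoms and tiny models that run in milliseconds."""

from __future__ import annotations

import numpy as np
import pytest

from collascore import PhantomSpec, generate_phantom
from collascore.network import BackboneConfig, SiameseCollateralNet
from collascore.preprocess import AlignedVolume, orient_affected_right, split_and_mirror


TINY_SHAPE = (12, 16, 16)  # per-hemisphere grid, smallest practical phantom


@pytest.fixture(scope="session")
def tiny_spec() -> PhantomSpec:
    return PhantomSpec(shape=TINY_SHAPE, filling_fraction=0.6, seed=7)


@pytest.fixture(scope="session")
def tiny_sample(tiny_spec):
    return generate_phantom(tiny_spec)


@pytest.fixture(scope="session")
def tiny_pair(tiny_sample):
    vol = AlignedVolume(
        voxels=tiny_sample.full_volume,
        spacing=tiny_sample.spacing,
        affected_side=tiny_sample.affected_side,
        mca_mask=tiny_sample.mca_mask,
    )
    return split_and_mirror(orient_affected_right(vol), overlap=2)


@pytest.fixture(scope="session")
def tiny_backbone() -> BackboneConfig:
    """One resolution level, one residual block, three features."""
    return BackboneConfig(n_features=3, blocks=(1,), full_res_stem=False)


@pytest.fixture()
def tiny_model(tiny_backbone) -> SiameseCollateralNet:
    return SiameseCollateralNet(tiny_backbone, seed=11)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
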