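"""Shared fixtures: a small synthetic PET/CT case and its feature extractor."""

from __future__ import annotations

import numpy as np
import pytest

from texseg.features.maps import FeatureExtractor
from texseg.phantom import (
    OrganSpec,
    PhantomSpec,
    TumorSpec,
    generate_phantom,
)
from texseg.volumes import resample_pet_to_ct


def small_phantom_spec(seed: int = 7) -> PhantomSpec:
    """A compact case (12 x 36 x 36 CT grid) that keeps window-feature
    computations cheap while retaining liver / heart / tumor structure."""
    return PhantomSpec(
        shape=(12, 36, 36),
        organs=[
            OrganSpec("body", (15.0, 17.5, 17.5), (40.0, 17.0, 17.0), 20.0, 0.7, 3.0, 0.05),
            OrganSpec("lung_right", (12.0, 15.0, 10.0), (12.0, 11.0, 8.5), -780.0, 0.25, 10.0, 0.02),
            OrganSpec("liver", (22.0, 20.0, 24.0), (12.0, 12.0, 10.0), 60.0, 2.2, 2.0, 0.08),
            OrganSpec("heart", (8.0, 22.0, 24.0), (9.0, 9.0, 9.0), 45.0, 2.0, 2.0, 0.08),
        ],
        tumor=TumorSpec((12.0, 14.0, 10.0), (8.0, 8.0, 7.0), corr_mm=4.0),
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_case():
    return generate_phantom(small_phantom_spec())


@pytest.fixture(scope="session")
def small_extractor(small_case):
    pet_ct = resample_pet_to_ct(small_case.pet, small_case.ct)
    return FeatureExtractor(small_case.ct, pet_ct)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
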