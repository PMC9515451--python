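"""Shared fixtures: all image data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from histocascade.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """Four small synthetic WSIs with annotations and a manifest."""
    out = tmp_path_factory.mktemp("cohort")
    spec = CohortSpec(n_wsi=4, base_size_px=(1024, 1024), n_levels=3, seed=11)
    wsis, manifest = generate_cohort(spec, out)
    return spec, wsis, manifest


@pytest.fixture(scope="session")
def gradient_image():
    """Deterministic smooth RGB test image, 512 x 512."""
    y = np.linspace(0, 255, 512)
    x = np.linspace(0, 255, 512)
    g = np.add.outer(y, x) / 2.0
    img = np.stack([g, 255 - g, np.full_like(g, 128)], axis=-1)
    return np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
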