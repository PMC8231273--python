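"""Shared fixtures: small synthetic sections and a full-size analyzed cohort.

Session-scoped fixtures cache the expensive artifacts (full default-size
cohort runs) so several tests can share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from lungmsi import (
    DEFAULT_TARGETS,
    GeneratorParams,
    PipelineConfig,
    extract_ion_image,
    normalize_image,
    run_full_pipeline,
    tissue_mask_from_heme,
)


def analyze_section(dataset):
    """Extraction + normalization + masking, as the pipeline does per section."""
    bud = extract_ion_image(dataset, DEFAULT_TARGETS["budesonide"])
    ref = extract_ion_image(dataset, DEFAULT_TARGETS["internal_standard"])
    heme = extract_ion_image(dataset, DEFAULT_TARGETS["heme"])
    mask = tissue_mask_from_heme(heme)
    normalized, _ = normalize_image(bud, ref)
    return normalized, mask


@pytest.fixture(scope="session")
def small_params():
    """A fast, small-grid parameter set for I/O-oriented tests."""
    return GeneratorParams(pattern="dispersed", grid_shape=(20, 40), n_blobs=8, seed=7)


@pytest.fixture(scope="session")
def default_cohort_run(tmp_path_factory):
    """One full-size pipeline run (5 sections per arm + 2 controls, seed 20210612)."""
    out = tmp_path_factory.mktemp("cohort_run")
    cfg = PipelineConfig(n_per_group=5, seed=20210612, output_dir=str(out))
    summary = run_full_pipeline(cfg)
    return cfg, summary


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
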