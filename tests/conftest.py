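"""Shared fixtures: small seeded synthetic datasets at coarse spectral grids."""

import numpy as np
import pytest

import fecalnirs as fn


@pytest.fixture(scope="session")
def small_dataset():
    """120 samples, 3 clusters, 211-channel grid: quick but structured."""
    cfg = fn.SyntheticConfig(n_samples=120, step_nm=10.0, seed=11)
    spectra, reference = fn.generate_dataset(cfg)
    return cfg, spectra, reference


@pytest.fixture(scope="session")
def small_preprocessed(small_dataset):
    cfg, spectra, reference = small_dataset
    return cfg, fn.preprocess(spectra), reference


@pytest.fixture(scope="session")
def two_cluster_xy():
    """Two well-separated clusters with strongly different local slopes,
    preprocessed, split into calibration and test halves."""
    cfg = fn.SyntheticConfig(
        n_samples=240,
        n_clusters=2,
        step_nm=10.0,
        slope_heterogeneity=1.2,
        reference_noise_sd=0.004,
        seed=7,
    )
    spectra, reference = fn.generate_dataset(cfg)
    pp = fn.preprocess(spectra)
    rng = np.random.default_rng(70)
    idx = rng.permutation(cfg.n_samples)
    cal, test = idx[:180], idx[180:]
    return {
        "Xcal": pp.absorbance[cal],
        "ycal": reference.omd[cal],
        "cal_clusters": spectra.cluster_labels[cal],
        "Xtest": pp.absorbance[test],
        "ytest": reference.omd[test],
        "test_clusters": spectra.cluster_labels[test],
        "noise_sd": cfg.reference_noise_sd,
    }
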