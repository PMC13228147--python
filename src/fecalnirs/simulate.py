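"""Seeded generator of synthetic fecal NIR datasets.

The generator emulates the statistical structure that the calibration study
assumes about multi-diet fecal spectra: a handful of diet clusters, each with
its own mean absorbance profile built from Gaussian absorption bands; a single
shared spectral direction that carries the digestibility signal, whose *slope*
differs between clusters (the source of global non-linearity); cluster-specific
nuisance variation orthogonal to the signal; multiplicative and additive
scatter artifacts that derivative + SNV preprocessing removes exactly; and
homoscedastic reference-method noise on the response.

With ``slope_heterogeneity = 0`` every cluster maps the shared signal direction
to OMD with the same slope, so the pooled spectrum -> OMD relationship is
exactly globally linear (cluster intercept offsets are absorbed by the linearly
independent cluster means).  With heterogeneity > 0 the clusters disagree about
the slope on the *same* direction, which no global linear model can resolve —
exactly the regime in which locally weighted calibration pays off.

All random draws come from one ``numpy.random.default_rng(seed)`` generator in
a fixed, documented order (cluster assignment, cluster chemistry, per-sample
latent scores, scatter, spectral noise, reference noise), so a (config, seed)
pair is bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .datasets import ReferenceSet, SpectraSet

__all__ = ["SyntheticConfig", "generate_dataset", "omd_from_intake"]

log = logging.getLogger(__name__)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic fecal-NIR generator.

    OMD distribution defaults reproduce the calibration population the package
    targets (mean 0.709, SD 0.0350, observed range 0.597-0.782 g/g) and the
    reference-method noise (SD 0.0135 g/g).  Spectral defaults give realistic
    absorbance levels (~0.3-1.2) on the 400-2,500 nm @ 2 nm grid.
    """

    n_samples: int = 466
    n_clusters: int = 3
    wavelength_start_nm: float = 400.0
    wavelength_end_nm: float = 2500.0
    step_nm: float = 2.0
    bands_per_cluster: int = 6
    band_center_range_nm: tuple[float, float] = (1000.0, 2450.0)
    band_width_range_nm: tuple[float, float] = (30.0, 150.0)
    omd_mean: float = 0.709
    omd_sd: float = 0.0350
    omd_min: float = 0.597
    omd_max: float = 0.782
    reference_noise_sd: float = 0.0135
    slope_heterogeneity: float = 0.5
    # spectral amplitude (absorbance units) of the digestibility-carrying direction
    signal_amplitude: float = 0.03
    # zero-slope within-cluster spectral variation
    n_nuisance: int = 2
    nuisance_sd: float = 0.015
    # spread of cluster OMD intercepts relative to the within-cluster latent SD
    cluster_omd_spread: float = 1.0
    scatter_mult_sd: float = 0.10
    baseline_offset_sd: float = 0.05
    baseline_tilt_sd: float = 0.05
    spectral_noise_sd: float = 0.002
    trial_fractions: tuple[float, ...] = (0.8, 0.2)
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        span = self.wavelength_end_nm - self.wavelength_start_nm
        n_steps = span / self.step_nm
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError(
                f"step_nm={self.step_nm} does not divide the range {span} nm"
            )
        if not (self.omd_min < self.omd_mean < self.omd_max):
            raise ValueError("require omd_min < omd_mean < omd_max")
        for name in (
            "omd_sd",
            "reference_noise_sd",
            "slope_heterogeneity",
            "nuisance_sd",
            "scatter_mult_sd",
            "baseline_offset_sd",
            "baseline_tilt_sd",
            "spectral_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(sum(self.trial_fractions) - 1.0) > 1e-9:
            raise ValueError("trial_fractions must sum to 1")

    @property
    def wavelengths_nm(self) -> np.ndarray:
        n = int(round((self.wavelength_end_nm - self.wavelength_start_nm) / self.step_nm)) + 1
        return self.wavelength_start_nm + self.step_nm * np.arange(n)


def _gaussian_bands(wl: np.ndarray, centers, widths, amps) -> np.ndarray:
    out = np.zeros_like(wl)
    for c, w, a in zip(centers, widths, amps):
        out += a * np.exp(-0.5 * ((wl - c) / w) ** 2)
    return out


def generate_dataset(config: SyntheticConfig) -> tuple[SpectraSet, ReferenceSet]:
    """Draw one synthetic dataset; deterministic for a given (config, seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    wl = config.wavelengths_nm
    n, n_clu = config.n_samples, config.n_clusters
    c_lo, c_hi = config.band_center_range_nm
    w_lo, w_hi = config.band_width_range_nm

    # 1. cluster assignment (multinomial, equal probabilities)
    clusters = rng.integers(0, n_clu, size=n)

    # 2. cluster chemistry: mean spectra, shared signal loading, slopes, intercepts
    base = 0.35 + 0.25 * np.exp(-0.5 * ((wl - 1940.0) / 120.0) ** 2)  # water band-ish floor
    cluster_means = np.empty((n_clu, len(wl)))
    for c in range(n_clu):
        centers = rng.uniform(c_lo, c_hi, size=config.bands_per_cluster)
        widths = rng.uniform(w_lo, w_hi, size=config.bands_per_cluster)
        amps = rng.uniform(0.05, 0.35, size=config.bands_per_cluster)
        cluster_means[c] = base + _gaussian_bands(wl, centers, widths, amps)

    sig_centers = rng.uniform(c_lo, c_hi, size=4)
    sig_widths = rng.uniform(w_lo, w_hi, size=4)
    sig_amps = rng.uniform(-1.0, 1.0, size=4)
    signal_loading = _gaussian_bands(wl, sig_centers, sig_widths, sig_amps)
    signal_loading /= np.linalg.norm(signal_loading) / np.sqrt(len(wl))

    slopes = 1.0 + config.slope_heterogeneity * rng.standard_normal(n_clu)
    intercepts = config.cluster_omd_spread * rng.standard_normal(n_clu)

    nuisance_loadings = np.zeros((n_clu, max(config.n_nuisance, 1), len(wl)))
    for c in range(n_clu):
        for j in range(config.n_nuisance):
            nc = rng.uniform(c_lo, c_hi, size=3)
            nw = rng.uniform(w_lo, w_hi, size=3)
            na = rng.uniform(-1.0, 1.0, size=3)
            v = _gaussian_bands(wl, nc, nw, na)
            nuisance_loadings[c, j] = v / (np.linalg.norm(v) / np.sqrt(len(wl)))

    # 3. per-sample latent scores
    z = rng.standard_normal(n)  # digestibility-carrying score
    nuis = rng.standard_normal((n, max(config.n_nuisance, 1)))

    # 4. scatter artifacts and spectral noise
    mult = np.exp(config.scatter_mult_sd * rng.standard_normal(n))
    offset = config.baseline_offset_sd * rng.standard_normal(n)
    tilt = config.baseline_tilt_sd * rng.standard_normal(n)
    noise = config.spectral_noise_sd * rng.standard_normal((n, len(wl)))

    # 5. reference-method noise
    ref_noise = config.reference_noise_sd * rng.standard_normal(n)

    # 6. trial labels within clusters (grouping labels only, no trial effect)
    n_trials = len(config.trial_fractions)
    trial_draw = rng.random(n)
    cum = np.cumsum(config.trial_fractions)
    trial_index = np.searchsorted(cum, trial_draw, side="right").clip(max=n_trials - 1)
    trial_ids = np.array(
        [f"C{c}-T{chr(ord('a') + t)}" for c, t in zip(clusters, trial_index)]
    )

    # assemble spectra
    wl_scaled = (wl - wl.mean()) / (wl[-1] - wl[0])
    chem = (
        cluster_means[clusters]
        + (config.signal_amplitude * z)[:, None] * signal_loading
        + config.nuisance_sd
        * np.einsum(
            "ij,ijk->ik",
            nuis[:, : config.n_nuisance],
            nuisance_loadings[clusters][:, : config.n_nuisance],
        )
    )
    absorbance = mult[:, None] * chem + offset[:, None] + tilt[:, None] * wl_scaled + noise

    # assemble OMD: cluster-specific affine law in z, pooled-rescaled, clipped
    raw = intercepts[clusters] + slopes[clusters] * z
    raw_sd = raw.std(ddof=0)
    # target moments describe the *observed* values; the noise-free truth is
    # deflated so that truth + reference noise matches the configured SD
    sd_true = np.sqrt(max(config.omd_sd**2 - config.reference_noise_sd**2,
                          (0.25 * config.omd_sd) ** 2))
    if raw_sd > 0:
        true_omd = config.omd_mean + sd_true * (raw - raw.mean()) / raw_sd
    else:  # degenerate single-sample or zero-variance configuration
        true_omd = np.full(n, config.omd_mean)
    clipped_true = np.clip(true_omd, config.omd_min, config.omd_max)
    frac_true = np.mean(clipped_true != true_omd)
    omd_raw = clipped_true + ref_noise
    omd = np.clip(omd_raw, config.omd_min, config.omd_max)
    frac_obs = np.mean(omd != omd_raw)
    if frac_true or frac_obs:
        log.info(
            "clipped %.1f%% of true and %.1f%% of observed OMD values to [%.3f, %.3f]",
            100 * frac_true, 100 * frac_obs, config.omd_min, config.omd_max,
        )

    ids = np.array([f"S{i:04d}" for i in range(n)])
    spectra = SpectraSet(ids, wl, absorbance, cluster_labels=clusters)
    reference = ReferenceSet(
        sample_ids=ids,
        omd=omd,
        true_omd=clipped_true,
        trial_id=trial_ids,
        cluster_labels=clusters,
    )
    return spectra, reference


def omd_from_intake(om_intake: float, om_feces: float) -> float:
    """Digestibility (%) from organic matter intake and fecal output masses."""
    om_intake = float(om_intake)
    om_feces = float(om_feces)
    if om_intake <= 0:
        raise ValueError("organic matter intake must be positive")
    if om_feces < 0:
        raise ValueError("fecal organic matter cannot be negative")
    if om_feces > om_intake:
        raise ValueError(
            "fecal organic matter exceeds intake (negative digestibility is a data error)"
        )
    return (om_intake - om_feces) * 100.0 / om_intake
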