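"""Spectral pretreatments: log(1/R), Savitzky-Golay derivative, SNV.

The fixed pipeline order is derivative -> SNV.  The first derivative removes
additive baseline structure (offsets become zero, linear tilts become
constants, which the subsequent SNV centering removes) and SNV removes
multiplicative scatter, so ``preprocess(a*x + b) == preprocess(x)`` for any
a > 0 and constant b.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_coeffs

from .datasets import SpectraSet

__all__ = [
    "PreprocessConfig",
    "absorbance_from_reflectance",
    "savgol_derivative",
    "snv",
    "preprocess",
]


@dataclass
class PreprocessConfig:
    """Savitzky-Golay + SNV settings (defaults: 11-point window, 3rd-order
    polynomial, first derivative, SNV on)."""

    do_absorbance_conversion: bool = False
    sg_window: int = 11
    sg_polyorder: int = 3
    sg_deriv_order: int = 1
    do_snv: bool = True

    def validate(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be odd and greater than sg_polyorder")
        if self.sg_deriv_order > self.sg_polyorder:
            raise ValueError("sg_deriv_order cannot exceed sg_polyorder")


def absorbance_from_reflectance(reflectance: np.ndarray) -> np.ndarray:
    """Elementwise log10(1/R); errors name the first offending position."""
    r = np.asarray(reflectance, dtype=float)
    bad = ~(r > 0)
    if np.any(bad):
        where = tuple(int(v) for v in np.argwhere(bad)[0])
        raise ValueError(
            f"reflectance must be strictly positive; first violation at index {where}"
        )
    return np.log10(1.0 / r)


def savgol_derivative(spectrum: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Savitzky-Golay derivative per data-point interval, full windows only.

    Works on a single spectrum or a samples x wavelengths matrix; the output
    loses (window - 1) channels (``(window-1)/2`` at each edge).
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    x = np.asarray(spectrum, dtype=float)
    n = x.shape[-1]
    if n < cfg.sg_window:
        raise ValueError(f"spectrum length {n} shorter than window {cfg.sg_window}")
    # savgol_coeffs is oriented for np.convolve; the derivative sign then
    # follows increasing index
    kernel = savgol_coeffs(cfg.sg_window, cfg.sg_polyorder, deriv=cfg.sg_deriv_order)
    if x.ndim == 1:
        return np.convolve(x, kernel, mode="valid")
    out = np.empty((x.shape[0], n - cfg.sg_window + 1))
    for i in range(x.shape[0]):
        out[i] = np.convolve(x[i], kernel, mode="valid")
    return out


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: per spectrum, (x - mean) / sample SD (n-1)."""
    x = np.asarray(spectrum, dtype=float)
    if x.shape[-1] < 2:
        raise ValueError("SNV needs at least 2 spectral points")
    mean = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, ddof=1, keepdims=True)
    if np.any(sd <= 0):
        idx = np.argwhere(np.squeeze(sd <= 0, axis=-1))
        raise ValueError(
            f"constant spectrum (zero variance) cannot be SNV-scaled; index {idx.ravel().tolist()}"
        )
    return (x - mean) / sd


def preprocess(spectra: SpectraSet, cfg: PreprocessConfig | None = None) -> SpectraSet:
    """Apply (optional) log(1/R) conversion, SG derivative, then row-wise SNV.

    The wavelength grid is trimmed to the full-window positions so matrix and
    grid stay aligned.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    mat = spectra.absorbance
    if cfg.do_absorbance_conversion:
        mat = absorbance_from_reflectance(mat)
    mat = savgol_derivative(mat, cfg)
    half = (cfg.sg_window - 1) // 2
    wl = spectra.wavelengths_nm[half : len(spectra.wavelengths_nm) - half]
    if cfg.do_snv:
        mat = snv(mat)
    return SpectraSet(
        sample_ids=spectra.sample_ids,
        wavelengths_nm=wl,
        absorbance=mat,
        cluster_labels=spectra.cluster_labels,
    )
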