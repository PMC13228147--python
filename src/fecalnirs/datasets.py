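"""In-memory containers for spectra and reference chemistry, with CSV interchange.

A :class:`SpectraSet` holds an absorbance matrix on a common wavelength grid;
a :class:`ReferenceSet` holds the wet-chemistry response (organic matter
digestibility, g/g) and bookkeeping labels.  Both round-trip through plain CSV
so that every pipeline stage is diff-able.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["SpectraSet", "ReferenceSet"]

SUBSET_LABELS = ("calibration", "validation", "test", "unassigned")


@dataclass
class SpectraSet:
    """Samples x wavelengths absorbance matrix (unitless, log10(1/R))."""

    sample_ids: np.ndarray
    wavelengths_nm: np.ndarray
    absorbance: np.ndarray
    cluster_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be a 2-D matrix")
        n, p = self.absorbance.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} spectra")
        if len(self.wavelengths_nm) != p:
            raise ValueError(
                f"{len(self.wavelengths_nm)} wavelengths for {p} spectral channels"
            )
        if np.any(np.diff(self.wavelengths_nm) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance matrix contains non-finite values")
        if self.cluster_labels is not None:
            self.cluster_labels = np.asarray(self.cluster_labels)
            if len(self.cluster_labels) != n:
                raise ValueError("cluster_labels length mismatch")

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.absorbance.shape[1]

    def subset(self, mask_or_ids) -> "SpectraSet":
        """Row subset by boolean mask, integer indices or sample ids."""
        idx = self._resolve(mask_or_ids)
        return SpectraSet(
            sample_ids=self.sample_ids[idx],
            wavelengths_nm=self.wavelengths_nm,
            absorbance=self.absorbance[idx],
            cluster_labels=None if self.cluster_labels is None else self.cluster_labels[idx],
        )

    def _resolve(self, mask_or_ids) -> np.ndarray:
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool or np.issubdtype(arr.dtype, np.integer):
            return arr
        pos = {sid: i for i, sid in enumerate(self.sample_ids)}
        try:
            return np.array([pos[s] for s in arr])
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown sample id {exc.args[0]!r}") from None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.absorbance, columns=[f"{w:g}" for w in self.wavelengths_nm])
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectraSet":
        df = pd.read_csv(path)
        if df.columns[0] != "sample_id":
            raise ValueError("spectra CSV must have 'sample_id' as first column")
        wl = np.array([float(c) for c in df.columns[1:]])
        return cls(
            sample_ids=df["sample_id"].to_numpy(),
            wavelengths_nm=wl,
            absorbance=df.iloc[:, 1:].to_numpy(dtype=float),
        )


@dataclass
class ReferenceSet:
    """Reference organic matter digestibility (g/g) aligned with a SpectraSet."""

    sample_ids: np.ndarray
    omd: np.ndarray
    true_omd: np.ndarray | None = None
    trial_id: np.ndarray | None = None
    subset: np.ndarray | None = None
    cluster_labels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids)
        self.omd = np.asarray(self.omd, dtype=float)
        n = len(self.sample_ids)
        if len(self.omd) != n:
            raise ValueError("omd length mismatch")
        if np.any((self.omd <= 0) | (self.omd >= 1)):
            raise ValueError("omd values must lie strictly inside (0, 1) g/g")
        if self.true_omd is not None:
            self.true_omd = np.asarray(self.true_omd, dtype=float)
        if self.trial_id is None:
            self.trial_id = np.array(["T0"] * n)
        else:
            self.trial_id = np.asarray(self.trial_id)
        if self.subset is None:
            self.subset = np.array(["unassigned"] * n)
        else:
            self.subset = np.asarray(self.subset)
            bad = set(np.unique(self.subset)) - set(SUBSET_LABELS)
            if bad:
                raise ValueError(f"unknown subset labels: {sorted(bad)}")
        if self.cluster_labels is not None:
            self.cluster_labels = np.asarray(self.cluster_labels)

    def aligned_with(self, spectra: SpectraSet) -> bool:
        return bool(np.array_equal(self.sample_ids, spectra.sample_ids))

    def with_subset(self, labels: np.ndarray) -> "ReferenceSet":
        return replace(self, subset=np.asarray(labels))

    def subset_rows(self, mask_or_ids) -> "ReferenceSet":
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool or np.issubdtype(arr.dtype, np.integer):
            idx = arr
        else:
            pos = {sid: i for i, sid in enumerate(self.sample_ids)}
            idx = np.array([pos[s] for s in arr])
        return ReferenceSet(
            sample_ids=self.sample_ids[idx],
            omd=self.omd[idx],
            true_omd=None if self.true_omd is None else self.true_omd[idx],
            trial_id=self.trial_id[idx],
            subset=self.subset[idx],
            cluster_labels=None
            if self.cluster_labels is None
            else self.cluster_labels[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "omd": self.omd,
                "true_omd": np.full(len(self.omd), np.nan)
                if self.true_omd is None
                else self.true_omd,
                "trial_id": self.trial_id,
                "subset": self.subset,
                "cluster": -1 if self.cluster_labels is None else self.cluster_labels,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ReferenceSet":
        df = pd.read_csv(path)
        true_omd = df["true_omd"].to_numpy() if "true_omd" in df else None
        if true_omd is not None and np.all(np.isnan(true_omd)):
            true_omd = None
        cluster = df["cluster"].to_numpy() if "cluster" in df else None
        return cls(
            sample_ids=df["sample_id"].to_numpy(),
            omd=df["omd"].to_numpy(dtype=float),
            true_omd=true_omd,
            trial_id=df["trial_id"].to_numpy() if "trial_id" in df else None,
            subset=df["subset"].to_numpy() if "subset" in df else None,
            cluster_labels=cluster,
        )
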