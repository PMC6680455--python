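"""Spectral and reference-value preprocessing.

Covers the screening steps applied before calibration: transmittance to
absorbance conversion (A = log10(1/T)), restriction to the instrument's
informative "good spectrum" wavenumber regions, ±3 SD reference-value
outlier flagging, Mahalanobis-distance spectral outlier detection on PCA
scores, and a Shapiro-Wilk normality report for each trait.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

__all__ = [
    "SpectraSet",
    "RegionSet",
    "DEFAULT_REGIONS",
    "to_absorbance",
    "select_regions",
    "reference_outliers",
    "spectral_outliers_mahalanobis",
    "normality_check",
]


@dataclass
class SpectraSet:
    """A set of spectra on a common wavenumber grid.

    ``values`` is a samples × variables matrix; ``mode`` is either
    ``"transmittance"`` (values in (0, 1]) or ``"absorbance"``.
    """

    sample_ids: np.ndarray
    wavenumbers: np.ndarray
    values: np.ndarray
    mode: str = "absorbance"

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.mode not in ("transmittance", "absorbance"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x variables)")
        if self.values.shape != (self.sample_ids.size, self.wavenumbers.size):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{self.sample_ids.size} samples x {self.wavenumbers.size} wavenumbers"
            )
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if self.mode == "transmittance" and (
            np.any(self.values <= 0) or np.any(self.values > 1)
        ):
            raise ValueError("transmittance values must lie in (0, 1]")

    @property
    def n_samples(self) -> int:
        return self.sample_ids.size

    @property
    def n_variables(self) -> int:
        return self.wavenumbers.size

    def to_frame(self) -> pd.DataFrame:
        """Wide table: first column sample_id, one column per wavenumber (1 d.p.)."""
        df = pd.DataFrame(
            self.values, columns=[f"{w:.1f}" for w in self.wavenumbers]
        )
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, mode: str = "transmittance") -> "SpectraSet":
        df = pd.read_csv(path)
        ids = df.iloc[:, 0].to_numpy()
        wn = np.array([float(c) for c in df.columns[1:]])
        return cls(sample_ids=ids, wavenumbers=wn,
                   values=df.iloc[:, 1:].to_numpy(dtype=float), mode=mode)


#: Informative wavenumber windows (cm⁻¹) of the mid-infrared milk analyser,
#: excluding the water-dominated bands. Endpoints inclusive.
DEFAULT_REGIONS: tuple[tuple[float, float], ...] = (
    (964.5, 1562.5),
    (1720.7, 2291.7),
    (2415.1, 2970.7),
)


@dataclass
class RegionSet:
    """Sorted, non-overlapping, inclusive wavenumber intervals [lo, hi] cm⁻¹."""

    intervals: tuple[tuple[float, float], ...] = DEFAULT_REGIONS

    def __post_init__(self) -> None:
        ivs = tuple((float(lo), float(hi)) for lo, hi in self.intervals)
        for lo, hi in ivs:
            if lo >= hi:
                raise ValueError(f"interval [{lo}, {hi}] has lo >= hi")
        for (_, hi_prev), (lo, _) in zip(ivs, ivs[1:]):
            if lo <= hi_prev:
                raise ValueError("intervals must be sorted and non-overlapping")
        self.intervals = ivs

    def contains(self, wavenumbers: np.ndarray) -> np.ndarray:
        """Boolean membership mask, endpoints inclusive."""
        w = np.asarray(wavenumbers, dtype=float)
        mask = np.zeros(w.shape, dtype=bool)
        for lo, hi in self.intervals:
            mask |= (w >= lo) & (w <= hi)
        return mask


def to_absorbance(spectra: SpectraSet) -> SpectraSet:
    """Convert transmittance spectra to absorbance, A = log10(1/T).

    Identity on spectra already in absorbance mode. Non-positive
    transmittance anywhere raises, naming the offending sample and
    wavenumber.
    """
    if spectra.mode == "absorbance":
        return spectra
    bad = np.argwhere(spectra.values <= 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-positive transmittance for sample '{spectra.sample_ids[i]}' "
            f"at {spectra.wavenumbers[j]:.1f} cm-1"
        )
    return replace(spectra, values=np.log10(1.0 / spectra.values), mode="absorbance")


def select_regions(spectra: SpectraSet, regions: RegionSet | None = None) -> SpectraSet:
    """Keep only variables whose wavenumber falls inside any region (inclusive)."""
    if spectra.mode != "absorbance":
        raise ValueError("select_regions expects absorbance spectra")
    regions = regions or RegionSet()
    mask = regions.contains(spectra.wavenumbers)
    if not mask.any():
        raise ValueError("region selection would leave no spectral variables")
    return replace(
        spectra, wavenumbers=spectra.wavenumbers[mask], values=spectra.values[:, mask]
    )


def reference_outliers(y: np.ndarray) -> np.ndarray:
    """Flag reference values deviating more than 3 SD from the trait mean.

    Single pass (the mean and n-1-denominator SD are not recomputed after
    removal). A zero-variance trait yields an all-false mask. The mask is
    invariant under affine transforms of y.
    """
    y = np.asarray(y, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 values")
    sd = np.std(y, ddof=1)
    if sd == 0:
        return np.zeros(y.size, dtype=bool)
    return np.abs(y - y.mean()) > 3 * sd


def _mahalanobis_sq(scores: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """Squared Mahalanobis distance given scores with diagonal covariance."""
    return np.sum(scores**2 / variances, axis=1)


def spectral_outliers_mahalanobis(
    spectra: SpectraSet, variance_kept: float = 0.95, quantile: float = 0.975
) -> tuple[np.ndarray, np.ndarray]:
    """Mahalanobis spectral-outlier screen on principal-component scores.

    The sample covariance of a wide spectral matrix (hundreds of variables,
    tens of samples) is singular, so distances are computed on PCA scores
    retaining ``variance_kept`` of the variance; a sample is flagged when its
    squared distance exceeds the chi-square ``quantile`` at the retained
    dimensionality.

    Returns (squared_distances, outlier_mask).
    """
    if spectra.n_samples < 3:
        raise ValueError("need at least 3 samples for spectral outlier detection")
    pca = PCA(n_components=variance_kept, svd_solver="full")
    scores = pca.fit_transform(spectra.values)
    variances = scores.var(axis=0, ddof=1)
    keep = variances > 0
    scores, variances = scores[:, keep], variances[keep]
    d2 = _mahalanobis_sq(scores, variances)
    cutoff = stats.chi2.ppf(quantile, df=scores.shape[1])
    return d2, d2 > cutoff


def normality_check(y: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk test of a trait vector; returns (W, p). Report-only.

    Valid for 3 <= n <= 5000 and non-constant y.
    """
    y = np.asarray(y, dtype=float)
    if not (3 <= y.size <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(y) == 0:
        raise ValueError("trait vector is constant; normality test undefined")
    w, p = stats.shapiro(y)
    return float(w), float(p)
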