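"""Core in-memory containers shared across the pipeline.

The central object is :class:`SpectraMatrix`, a samples × bands reflectance
table with an explicit wavelength axis and per-sample metadata, mirroring how
canopy spectra extracted from a UAV reflectance raster are organised: one row
per (plot, sampling region), one column per spectral band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectraMatrix",
    "BandSubset",
    "CarsTrace",
    "ConfusionMatrix",
    "METADATA_COLUMNS",
]

#: metadata columns carried alongside the reflectance block, in CSV order
METADATA_COLUMNS = ("sample_id", "variety", "n_level", "replicate", "region")


@dataclass
class SpectraMatrix:
    """Samples × bands reflectance with wavelength vector and sample metadata.

    Parameters
    ----------
    reflectance : ndarray, shape (n_samples, n_bands)
        Reflectance values, nominally in [0, 1] (a little calibration slack
        is tolerated on input: [-0.05, 1.5]).
    wavelengths : ndarray, shape (n_bands,)
        Band centres in nm, strictly increasing.
    meta : DataFrame, n_samples rows
        Sample metadata; must contain at least ``variety`` and ``n_level``.
    """

    reflectance: np.ndarray
    wavelengths: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.reflectance.ndim != 2:
            raise ValueError("reflectance must be 2-D (samples × bands)")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.reflectance.shape[1]:
            raise ValueError("wavelengths must match the number of bands")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance contains missing or non-finite values")
        if len(self.meta) != self.reflectance.shape[0]:
            raise ValueError("metadata rows must align with reflectance rows")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[1]

    def select_bands(self, indices: Sequence[int]) -> "SpectraMatrix":
        """Restrict to a band subset (indices into the wavelength axis)."""
        idx = np.asarray(indices, dtype=int)
        if idx.size == 0:
            raise ValueError("band subset is empty")
        order = np.argsort(self.wavelengths[idx])
        idx = idx[order]
        return SpectraMatrix(self.reflectance[:, idx], self.wavelengths[idx], self.meta.copy())

    def select_samples(self, mask: np.ndarray) -> "SpectraMatrix":
        mask = np.asarray(mask)
        return SpectraMatrix(
            self.reflectance[mask], self.wavelengths, self.meta.loc[mask].reset_index(drop=True)
        )

    def to_frame(self) -> pd.DataFrame:
        """Flatten to the CSV schema: metadata columns then band_<wl> columns."""
        # shortest round-trip float repr keeps the wavelength grid lossless
        bands = pd.DataFrame(
            self.reflectance, columns=[f"band_{float(wl)!r}" for wl in self.wavelengths]
        )
        meta = self.meta.copy()
        for col in METADATA_COLUMNS:
            if col not in meta.columns:
                meta[col] = ""
        return pd.concat([meta[list(METADATA_COLUMNS)], bands], axis=1)


@dataclass
class CarsTrace:
    """Per-run record of a CARS refinement: retained sets, ratios, RMSECV."""

    retained_sets: list  # list of ndarray of band indices (into parent matrix)
    ratios: np.ndarray  # forced-reduction ratio r_i per run
    rmsecv: np.ndarray  # cross-validated RMSE per run (NaN where skipped)
    chosen_run: int  # 0-based index of the run with minimum RMSECV

    def sizes(self) -> np.ndarray:
        return np.array([len(s) for s in self.retained_sets])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "run": np.arange(1, len(self.retained_sets) + 1),
                "ratio": self.ratios,
                "n_retained": self.sizes(),
                "rmsecv": self.rmsecv,
                "chosen": np.arange(len(self.retained_sets)) == self.chosen_run,
            }
        )


@dataclass
class BandSubset:
    """An ordered set of selected wavelengths with selection provenance.

    ``stage`` records which selector produced the subset: ``"lasso"``,
    ``"cars"``, ``"lasso_cars"`` or ``"full"``.
    """

    indices: np.ndarray
    wavelengths: np.ndarray
    stage: str
    trace: CarsTrace | None = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if len(self.indices) != len(set(self.indices.tolist())):
            raise ValueError("band indices must be unique")
        if len(self.indices) != len(self.wavelengths):
            raise ValueError("indices and wavelengths must align")
        order = np.argsort(self.wavelengths)
        self.indices = self.indices[order]
        self.wavelengths = self.wavelengths[order]

    def __len__(self) -> int:
        return len(self.indices)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wavelength_nm": np.round(self.wavelengths, 2),
                "band_index": self.indices,
                "stage": self.stage,
            }
        )


@dataclass
class ConfusionMatrix:
    """n_classes × n_classes counts; rows = actual class, columns = predicted."""

    counts: np.ndarray
    classes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if np.any(counts < 0) or not np.all(counts == np.round(counts)):
            raise ValueError("confusion counts must be non-negative integers")
        self.counts = counts.astype(np.int64)
        if not self.classes:
            self.classes = list(range(counts.shape[0]))
        if len(self.classes) != counts.shape[0]:
            raise ValueError("class labels must match matrix size")

    @classmethod
    def from_labels(cls, y_true, y_pred, classes=None) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        if classes is None:
            classes = sorted(set(y_true.tolist()) | set(y_pred.tolist()))
        index = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
        for t, p in zip(y_true, y_pred):
            counts[index[t], index[p]] += 1
        return cls(counts, list(classes))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.classes != other.classes:
            raise ValueError("cannot pool confusion matrices over different classes")
        return ConfusionMatrix(self.counts + other.counts, list(self.classes))
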