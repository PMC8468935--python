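"""Core spectral container and delimited-text I/O.

A :class:`SpectraSet` pairs a strictly increasing wavelength grid (nm) with a
``samples x wavelengths`` reflectance matrix, per-sample identifiers and
optional acquisition metadata (cut type, carcass, day).  All preprocessing
operators consume and return :class:`SpectraSet` instances and never mutate
their input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpectraSet",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_references_csv",
    "write_references_csv",
    "read_metadata_csv",
    "write_metadata_csv",
]

#: Required metadata columns when metadata is supplied.
METADATA_COLUMNS = ("cut_type", "carcass_id", "day")

_FLOAT_FORMAT = "%.10g"


@dataclass
class SpectraSet:
    """Reflectance spectra on a common wavelength grid.

    Parameters
    ----------
    wavelengths : ndarray, shape (p,)
        Strictly increasing wavelength grid in nm.
    reflectance : ndarray, shape (n, p)
        One spectrum per row; unitless reflectance (or a transform of it).
    sample_ids : sequence of str
        Unique per-row labels.
    metadata : DataFrame, optional
        Indexed by sample id with columns ``cut_type``, ``carcass_id``,
        ``day``.  May be empty for data without acquisition metadata.
    attrs : dict
        Free-form annotations set by operators (e.g. the fitted MSC
        reference spectrum).
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    sample_ids: list[str]
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float).ravel()
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.reflectance.ndim != 2:
            raise ValueError("reflectance must be a 2-D samples x wavelengths matrix")
        n, p = self.reflectance.shape
        if p != self.wavelengths.size:
            raise ValueError(
                f"reflectance has {p} columns but grid has {self.wavelengths.size} wavelengths"
            )
        if n != len(self.sample_ids):
            raise ValueError(
                f"reflectance has {n} rows but {len(self.sample_ids)} sample ids given"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance contains non-finite values")
        if not self.metadata.empty:
            missing = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
            if missing:
                raise ValueError(f"metadata is missing columns: {missing}")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.reflectance.shape[1]

    def with_reflectance(
        self, reflectance: np.ndarray, wavelengths: np.ndarray | None = None
    ) -> "SpectraSet":
        """Return a copy with a new matrix (and optionally a new grid)."""
        return SpectraSet(
            wavelengths=self.wavelengths.copy() if wavelengths is None else wavelengths,
            reflectance=np.asarray(reflectance, dtype=float),
            sample_ids=list(self.sample_ids),
            metadata=self.metadata.copy(),
            attrs=dict(self.attrs),
        )

    def subset(self, ids: Sequence[str]) -> "SpectraSet":
        """Return the rows named in ``ids``, in the given order."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        unknown = [s for s in ids if s not in index]
        if unknown:
            raise KeyError(f"unknown sample ids: {unknown[:5]}")
        rows = [index[s] for s in ids]
        meta = self.metadata.loc[list(ids)] if not self.metadata.empty else self.metadata
        return SpectraSet(
            wavelengths=self.wavelengths.copy(),
            reflectance=self.reflectance[rows],
            sample_ids=list(ids),
            metadata=meta.copy() if not self.metadata.empty else pd.DataFrame(),
            attrs=dict(self.attrs),
        )

    def same_grid(self, other: "SpectraSet", rtol: float = 1e-9) -> bool:
        return self.wavelengths.size == other.wavelengths.size and np.allclose(
            self.wavelengths, other.wavelengths, rtol=rtol, atol=1e-9
        )


# ----------------------------------------------------------------------
# Delimited-text I/O.  Spectra files have a ``sample_id`` first column and
# one column per wavelength (header = wavelength in nm).


def write_spectra_csv(spectra: SpectraSet, path: str | Path) -> None:
    frame = pd.DataFrame(
        spectra.reflectance,
        index=pd.Index(spectra.sample_ids, name="sample_id"),
        columns=[_FLOAT_FORMAT % w for w in spectra.wavelengths],
    )
    frame.to_csv(path, float_format=_FLOAT_FORMAT)


def read_spectra_csv(
    path: str | Path, metadata: pd.DataFrame | None = None
) -> SpectraSet:
    frame = pd.read_csv(path, index_col="sample_id")
    try:
        wavelengths = np.array([float(c) for c in frame.columns])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength header in {path}: {exc}") from None
    if np.any(np.diff(wavelengths) <= 0):
        raise ValueError(f"wavelength header in {path} is not strictly increasing")
    if frame.isna().any().any():
        bad = frame.index[frame.isna().any(axis=1)].tolist()
        raise ValueError(f"missing reflectance values for samples {bad[:5]} in {path}")
    return SpectraSet(
        wavelengths=wavelengths,
        reflectance=frame.to_numpy(dtype=float),
        sample_ids=[str(s) for s in frame.index],
        metadata=metadata if metadata is not None else pd.DataFrame(),
    )


def write_references_csv(references: pd.DataFrame, path: str | Path) -> None:
    references.to_csv(path, index_label="sample_id", float_format=_FLOAT_FORMAT)


def read_references_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, index_col="sample_id")
    frame.index = frame.index.astype(str)
    if frame.isna().any().any():
        bad = frame.index[frame.isna().any(axis=1)].tolist()
        raise ValueError(f"missing reference values for samples {bad[:5]} in {path}")
    return frame


def write_metadata_csv(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, index_label="sample_id")


def read_metadata_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, index_col="sample_id")
    frame.index = frame.index.astype(str)
    missing = [c for c in METADATA_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"metadata file {path} is missing columns: {missing}")
    return frame
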