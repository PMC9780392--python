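"""Spectral data containers and wide-table I/O.

A :class:`SpectralDataset` couples a wavelength grid (nm), an absorbance matrix
(``n_spectra x n_channels``) and per-spectrum metadata (storage condition, day,
fruit, measurement position, replicate).  The on-disk dialect is a wide CSV:
metadata columns first, then one column per channel named by its wavelength in
nm.  A JSON sidecar can remap metadata column names from foreign exports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DuplicateRecordError,
    EmptyRegionError,
    OutOfRangeError,
    SchemaError,
    SpectralParseError,
)

#: canonical metadata columns of the storage-study design
META_COLUMNS = ("condition", "day", "fruit_id", "position", "replicate")

#: columns forming the unique measurement key
KEY_COLUMNS = META_COLUMNS


@dataclass
class SpectralDataset:
    """Absorbance spectra plus measurement metadata.

    Parameters
    ----------
    wavelengths
        Channel centres in nm, strictly increasing.
    absorbance
        Matrix of shape ``(n_spectra, n_channels)``, unitless absorbance.
    meta
        One row per spectrum.  The storage-study columns are ``condition``
        (CF/SCF), ``day`` (0 = pre-storage), ``fruit_id``, ``position``
        (front/back) and ``replicate`` (1-3), but derived datasets (e.g. group
        averages) may carry a subset.
    """

    wavelengths: np.ndarray
    absorbance: np.ndarray
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float).ravel()
        self.absorbance = np.atleast_2d(np.asarray(self.absorbance, dtype=float))
        if self.meta is None:
            self.meta = pd.DataFrame(index=range(self.absorbance.shape[0]))
        if self.wavelengths.size != self.absorbance.shape[1]:
            raise SchemaError(
                f"{self.wavelengths.size} wavelengths but "
                f"{self.absorbance.shape[1]} absorbance columns"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise SchemaError("wavelengths must be strictly increasing")
        if len(self.meta) != self.absorbance.shape[0]:
            raise SchemaError(
                f"{len(self.meta)} metadata rows but "
                f"{self.absorbance.shape[0]} spectra"
            )
        if np.isnan(self.absorbance).any():
            bad = int(np.argwhere(np.isnan(self.absorbance))[0, 0])
            raise SpectralParseError(f"NaN absorbance in spectrum row {bad}")
        if "day" in self.meta.columns and (self.meta["day"] < 0).any():
            raise SchemaError("negative storage day in metadata")
        if "replicate" in self.meta.columns and (self.meta["replicate"] < 1).any():
            raise SchemaError("replicate labels start at 1")
        self.meta = self.meta.reset_index(drop=True)

    # -- basic introspection -------------------------------------------------
    @property
    def n_spectra(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.absorbance.shape[1]

    @property
    def step(self) -> float:
        """Median channel spacing in nm."""
        return float(np.median(np.diff(self.wavelengths)))

    def copy(self) -> "SpectralDataset":
        return SpectralDataset(
            self.wavelengths.copy(), self.absorbance.copy(), self.meta.copy()
        )

    def with_absorbance(self, absorbance: np.ndarray) -> "SpectralDataset":
        """New dataset sharing grid and metadata, with replaced absorbance."""
        return SpectralDataset(self.wavelengths.copy(), absorbance, self.meta.copy())

    def select(self, mask) -> "SpectralDataset":
        """Row subset by boolean mask or integer index array."""
        mask = np.asarray(mask)
        return SpectralDataset(
            self.wavelengths.copy(),
            self.absorbance[mask],
            self.meta.iloc[mask].reset_index(drop=True),
        )

    def where(self, **conditions) -> "SpectralDataset":
        """Row subset by metadata equality, e.g. ``ds.where(condition="CF", day=4)``.

        A sequence value keeps rows matching any of its elements.
        """
        mask = np.ones(self.n_spectra, dtype=bool)
        for key, value in conditions.items():
            if key not in self.meta.columns:
                raise SchemaError(f"unknown metadata field {key!r}")
            col = self.meta[key]
            if isinstance(value, (list, tuple, set, np.ndarray, pd.Series)):
                mask &= col.isin(list(value)).to_numpy()
            else:
                mask &= (col == value).to_numpy()
        return self.select(mask)

    # -- I/O -----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Wide-table form: metadata columns, then one column per channel."""
        spectral = pd.DataFrame(
            self.absorbance, columns=[repr(float(w)) for w in self.wavelengths]
        )
        return pd.concat([self.meta.reset_index(drop=True), spectral], axis=1)

    def write_csv(self, path) -> None:
        # %.17g round-trips float64 exactly through the text form
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


@dataclass
class DifferenceSpectrum:
    """Channel-wise difference of two day-averaged (SNV) spectra."""

    wavelengths: np.ndarray
    delta: np.ndarray
    reference_day: int
    target_day: int
    condition: str

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float).ravel()
        self.delta = np.asarray(self.delta, dtype=float).ravel()
        if self.wavelengths.size != self.delta.size:
            raise SchemaError("delta length must equal wavelengths length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"wavelength_nm": self.wavelengths, "delta": self.delta}
        )


def _resolve_schema(schema) -> Mapping[str, str]:
    """Schema maps canonical metadata names -> file column names.

    Accepts a mapping, a path to a JSON sidecar, or ``None`` (identity).
    """
    if schema is None:
        return {c: c for c in META_COLUMNS}
    if isinstance(schema, (str, Path)):
        with open(schema) as fh:
            schema = json.load(fh)
    return {c: schema.get(c, c) for c in META_COLUMNS}


def read_spectra(path, schema=None) -> SpectralDataset:
    """Read a wide spectral CSV into a :class:`SpectralDataset`.

    Metadata columns (per ``schema``) are taken first; every remaining column
    whose name parses as a number is treated as a wavelength channel.  Columns
    are reordered so wavelengths ascend, with the data permuted consistently.

    Raises
    ------
    SchemaError
        If a declared metadata column is absent.
    SpectralParseError
        If an absorbance cell is non-numeric (the row index is reported).
    DuplicateRecordError
        If two rows share the full measurement key.
    """
    mapping = _resolve_schema(schema)
    raw = pd.read_csv(path, float_precision="round_trip")
    missing = [src for src in mapping.values() if src not in raw.columns]
    if missing:
        raise SchemaError(f"missing metadata column(s): {missing}")
    meta = pd.DataFrame({canon: raw[src] for canon, src in mapping.items()})

    wl_cols: list[str] = []
    wls: list[float] = []
    for col in raw.columns:
        if col in mapping.values():
            continue
        try:
            wls.append(float(col))
            wl_cols.append(col)
        except ValueError:
            raise SchemaError(f"column {col!r} is neither metadata nor a wavelength")
    if not wl_cols:
        raise SchemaError("no wavelength columns found")

    try:
        X = raw[wl_cols].to_numpy(dtype=float)
    except (TypeError, ValueError):
        for i in range(len(raw)):
            for col in wl_cols:
                try:
                    float(raw[col].iloc[i])
                except (TypeError, ValueError):
                    raise SpectralParseError(
                        f"non-numeric absorbance at row {i}, column {col!r}"
                    )
        raise
    order = np.argsort(wls, kind="stable")
    wavelengths = np.asarray(wls, dtype=float)[order]
    X = X[:, order]

    dup = meta.duplicated(subset=[c for c in KEY_COLUMNS if c in meta.columns])
    if dup.any():
        raise DuplicateRecordError(
            f"duplicate measurement key at row {int(np.argmax(dup.to_numpy()))}"
        )
    return SpectralDataset(wavelengths, X, meta)


def write_spectra(ds: SpectralDataset, path) -> None:
    """Write ``ds`` in the wide CSV dialect (round-trips through read_spectra)."""
    ds.write_csv(path)


def crop_region(ds: SpectralDataset, lo: float, hi: float) -> SpectralDataset:
    """Retain channels with ``lo <= wavelength <= hi`` (metadata unchanged)."""
    if not lo < hi:
        raise OutOfRangeError(f"need lo < hi, got [{lo}, {hi}]")
    keep = (ds.wavelengths >= lo) & (ds.wavelengths <= hi)
    if not keep.any():
        raise EmptyRegionError(f"no channels in [{lo}, {hi}] nm")
    return SpectralDataset(ds.wavelengths[keep], ds.absorbance[:, keep], ds.meta.copy())


def nearest_channel(ds: SpectralDataset, band: float) -> int:
    """Index of the channel closest to ``band`` nm; ties break toward lower nm.

    ``band`` may overhang the grid by at most one channel step.
    """
    step = ds.step
    if band < ds.wavelengths[0] - step or band > ds.wavelengths[-1] + step:
        raise OutOfRangeError(
            f"band {band} nm outside grid "
            f"[{ds.wavelengths[0]}, {ds.wavelengths[-1]}] (+/- {step:.3f})"
        )
    # argmin returns the first minimiser; wavelengths ascend, so ties go low
    return int(np.argmin(np.abs(ds.wavelengths - band)))


def snap_bands(ds: SpectralDataset, bands: Sequence[float]) -> np.ndarray:
    """Vectorised :func:`nearest_channel` over a band list."""
    return np.array([nearest_channel(ds, b) for b in bands], dtype=int)
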