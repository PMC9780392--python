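"""Spectral pre-treatments.

SNV (per-spectrum standardisation), column mean-centering, per-wavelength
z-scoring (the "normalisation" step of the classical aquagram), group
averaging, and day-vs-reference difference spectra computed on SNV-transformed
group means.

All standard deviations use the sample (n-1) convention.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import DifferenceSpectrum, SpectralDataset
from .exceptions import (
    DegenerateChannelError,
    DegenerateSpectrumError,
    InsufficientDataError,
    MissingGroupError,
    SchemaError,
)


def snv(ds: SpectralDataset) -> SpectralDataset:
    """Standard normal variate: each spectrum to zero mean, unit sample SD.

    Removes per-spectrum additive baseline offsets and multiplicative scatter
    (gain): ``snv(a*x + b) == snv(x)`` for ``a > 0``.
    """
    X = ds.absorbance
    if X.shape[1] < 2:
        raise InsufficientDataError("SNV needs at least 2 channels per spectrum")
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    # constant rows can carry O(eps) round-off spread; treat those as flat too
    floor = 1e-12 * np.maximum(1.0, np.abs(mu))
    flat = np.flatnonzero((sd <= floor).ravel())
    if flat.size:
        raise DegenerateSpectrumError(
            f"zero-spread spectrum at row {int(flat[0])}: SNV undefined"
        )
    return ds.with_absorbance((X - mu) / sd)


def mean_center(X: np.ndarray) -> np.ndarray:
    """Subtract column means; output columns average to zero."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] < 2:
        raise InsufficientDataError("mean-centering needs at least 2 rows")
    return X - X.mean(axis=0, keepdims=True)


def average_by(ds: SpectralDataset, keys: Sequence[str]) -> SpectralDataset:
    """Average spectra over each distinct combination of metadata ``keys``.

    The output carries one spectrum per group; its metadata holds the key
    columns (other metadata fields do not survive the aggregation).
    """
    keys = list(keys)
    if not keys:
        raise SchemaError("need at least one grouping key")
    for k in keys:
        if k not in ds.meta.columns:
            raise SchemaError(f"unknown metadata field {k!r}")
    frame = ds.meta[keys].copy()
    frame["_row"] = np.arange(ds.n_spectra)
    groups = frame.groupby(keys, sort=True, dropna=False)["_row"].apply(list)
    meta_out = groups.index.to_frame(index=False)
    X_out = np.vstack([ds.absorbance[rows].mean(axis=0) for rows in groups])
    return SpectralDataset(ds.wavelengths.copy(), X_out, meta_out)


def replicate_average(ds: SpectralDataset) -> SpectralDataset:
    """Collapse the three consecutive replicates to one spectrum per
    (condition, day, fruit, position)."""
    keys = [k for k in ("condition", "day", "fruit_id", "position") if k in ds.meta]
    return average_by(ds, keys)


def difference_spectrum(
    ds: SpectralDataset,
    condition: str,
    target_day: int,
    reference_day: int = 1,
    apply_snv: bool = True,
) -> DifferenceSpectrum:
    """Day-average difference ``avg(S_target) - avg(S_reference)`` per channel.

    Spectra of the requested condition are SNV-transformed (unless
    ``apply_snv=False``, for input already SNV-treated), averaged within each
    day, and subtracted channel-wise.  The default reference is day 1, the
    first day *in* storage; day 0 (pre-storage) is also meaningful.
    """
    sub = ds.where(condition=condition)
    if apply_snv:
        sub = snv(sub)
    deltas = {}
    for day in (target_day, reference_day):
        grp = sub.where(day=day)
        if grp.n_spectra == 0:
            raise MissingGroupError(f"no spectra for condition={condition} day={day}")
        deltas[day] = grp.absorbance.mean(axis=0)
    return DifferenceSpectrum(
        wavelengths=ds.wavelengths.copy(),
        delta=deltas[target_day] - deltas[reference_day],
        reference_day=int(reference_day),
        target_day=int(target_day),
        condition=condition,
    )


def standardize_per_wavelength(ds: SpectralDataset) -> SpectralDataset:
    """Z-score each channel across all spectra in the dataset.

    The pool is the whole dataset — both storage conditions and all days
    together — so downstream aquagram profiles of CF and SCF share one scale.
    """
    X = ds.absorbance
    if X.shape[0] < 2:
        raise InsufficientDataError("per-wavelength standardisation needs >= 2 spectra")
    mu = X.mean(axis=0, keepdims=True)
    sd = X.std(axis=0, ddof=1, keepdims=True)
    dead = np.flatnonzero((sd <= 1e-12 * np.maximum(1.0, np.abs(mu))).ravel())
    if dead.size:
        raise DegenerateChannelError(
            f"zero-variance channel at index {int(dead[0])} "
            f"({ds.wavelengths[int(dead[0])]:.1f} nm)"
        )
    return ds.with_absorbance((X - mu) / sd)
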