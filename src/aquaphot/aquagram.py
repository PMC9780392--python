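"""Classical aquagram / water spectral pattern (WASP) computation.

Pipeline: SNV per spectrum → per-wavelength z-scoring pooled over the whole
dataset (both conditions, all days, so CF and SCF profiles share one scale) →
averaging per (condition, day) → subtraction of each condition's reference-day
average → restriction to the axis bands (each nominal band snapped to its
nearest channel).

The resulting profile per (condition, day) is the WASP — a multidimensional
biomarker conventionally drawn on a radar chart.  This module emits values and
plot-ready tables; drawing is left to the host environment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .bands import AXES_20
from .dataset import SpectralDataset, snap_bands
from .exceptions import AxisCollisionError, MissingGroupError
from .preprocess import average_by, snv, standardize_per_wavelength


@dataclass
class AquagramProfile:
    """Reference-subtracted standardized day-average absorbance on the axis bands."""

    axes: np.ndarray           # nominal band positions, nm
    wavelengths: np.ndarray    # snapped channel centres, nm
    channels: np.ndarray       # snapped channel indices in the source grid
    values: pd.DataFrame       # index (condition, day), one column per axis
    reference_day: int

    def profile(self, condition, day) -> np.ndarray:
        """The WASP vector for one (condition, day) group."""
        try:
            return self.values.loc[(condition, day)].to_numpy(dtype=float)
        except KeyError:
            raise MissingGroupError(f"no profile for ({condition}, {day})")

    def groups(self) -> list[tuple]:
        return list(self.values.index)

    # -- export ----------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long form: condition, day, band_nm, value."""
        rows = []
        for (cond, day), row in self.values.iterrows():
            for band, val in zip(self.axes, row.to_numpy(dtype=float)):
                rows.append(
                    {"condition": cond, "day": day, "band_nm": float(band),
                     "value": float(val)}
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None):
        payload = {
            "axes_nm": [float(a) for a in self.axes],
            "reference_day": int(self.reference_day),
            "profiles": {
                f"{cond}:{day}": [float(v) for v in row]
                for (cond, day), row in self.values.iterrows()
            },
        }
        if path is None:
            return json.dumps(payload)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    def radar_table(self, condition, day) -> pd.DataFrame:
        """Plot-ready rows (axis band, angle in radians, value) for one group."""
        vals = self.profile(condition, day)
        angles = np.linspace(0.0, 2 * np.pi, len(self.axes), endpoint=False)
        return pd.DataFrame(
            {"band_nm": self.axes, "angle_rad": angles, "value": vals}
        )


def compute_aquagram(
    ds: SpectralDataset,
    axes: Sequence[float] = AXES_20,
    reference_day: int = 1,
    condition_key: str = "condition",
    day_key: str = "day",
) -> AquagramProfile:
    """Compute WASP profiles per (condition, day) on the given axis bands.

    The reference day must be present for every condition; its profile is
    identically zero by construction.
    """
    channels = snap_bands(ds, axes)
    if len(set(channels.tolist())) != len(channels):
        dup = [axes[i] for i in range(len(axes))
               if channels.tolist().count(channels[i]) > 1]
        raise AxisCollisionError(f"axes {dup} snap to the same channel")

    z = standardize_per_wavelength(snv(ds))
    means = average_by(z, [condition_key, day_key])

    rows = {}
    for cond in means.meta[condition_key].unique():
        sub = means.where(**{condition_key: cond})
        days = sub.meta[day_key].tolist()
        if reference_day not in days:
            raise MissingGroupError(
                f"reference day {reference_day} missing for condition {cond!r}"
            )
        ref = sub.absorbance[days.index(reference_day)]
        for day, spec in zip(days, sub.absorbance):
            rows[(cond, day)] = (spec - ref)[channels]

    values = pd.DataFrame.from_dict(rows, orient="index", columns=list(axes))
    values.index = pd.MultiIndex.from_tuples(values.index, names=["condition", "day"])
    values = values.sort_index()
    return AquagramProfile(
        axes=np.asarray(axes, dtype=float),
        wavelengths=ds.wavelengths[channels],
        channels=channels,
        values=values,
        reference_day=int(reference_day),
    )


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 1.0 if na == nb else 0.0
    return float(a @ b / (na * nb))


def compare_profiles(profile: AquagramProfile, pairs) -> pd.DataFrame:
    """Cosine similarity and RMS difference for each requested pair of
    (condition, day) groups."""
    rows = []
    for (ca, da), (cb, db) in pairs:
        a = profile.profile(ca, da)
        b = profile.profile(cb, db)
        rows.append(
            {
                "condition_a": ca, "day_a": da,
                "condition_b": cb, "day_b": db,
                "cosine": _cosine(a, b),
                "rms": float(np.sqrt(((a - b) ** 2).mean())),
            }
        )
    return pd.DataFrame(rows)


def best_matching_day(
    profile: AquagramProfile,
    target: tuple,
    candidate_condition: str,
    candidate_days: Sequence[int],
    metric: str = "rms",
) -> int:
    """The candidate day whose WASP is most similar to the target's.

    ``metric="rms"`` (default) maximises negative RMS difference — profile
    magnitude grows with storage time, so it discriminates neighbouring days
    better than the scale-free cosine (also available, ``metric="cosine"``).
    """
    t = profile.profile(*target)
    if metric == "cosine":
        score = lambda p: _cosine(t, p)  # noqa: E731
    else:
        score = lambda p: -float(np.sqrt(((t - p) ** 2).mean()))  # noqa: E731
    sims = {
        d: score(profile.profile(candidate_condition, d)) for d in candidate_days
    }
    return max(sims, key=sims.get)


def estimate_lag(
    profile: AquagramProfile,
    lagged_condition: str,
    baseline_condition: str,
    target_days: Sequence[int] = (5, 6, 7, 8, 9),
    metric: str = "rms",
) -> float:
    """Mean storage-time lag of one condition behind another.

    For each target day ``d`` of the lagged condition, find the baseline day
    whose WASP best matches, and average ``d - match`` over the targets.
    Positive values mean the lagged condition trails the baseline.
    """
    days_avail = sorted(
        {d for c, d in profile.groups() if c == baseline_condition}
        - {profile.reference_day}
    )
    lags = []
    for td in target_days:
        m = best_matching_day(
            profile, (lagged_condition, td), baseline_condition, days_avail,
            metric=metric,
        )
        lags.append(td - m)
    return float(np.mean(lags))
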