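"""WAMACS catalog, peak picking, and band-importance aggregation.

WAMACS (water matrix coordinates) are narrow wavelength ranges in the
1,300–1,600 nm first overtone of water, each attributed to a water molecular
conformation.  Influential wavelengths surfacing repeatedly across analyses
(difference-spectrum extrema, SIMCA discriminating-power peaks, PLSR
regression-vector peaks) are tallied into a band-importance table, annotated
with the WAMACS region each band belongs to.

Two CSVs ship with the package: the WAMACS region catalog (ranges C1–C12 plus
four tentative single-wavelength coordinates Ci–Cl at 1,503 / 1,528 / 1,534 /
1,559 nm) and the study's influential-band inventory of 28 bands with their
occurrence counts, plus a functional-annotation lookup for the 20-band axis
preset.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.signal import find_peaks as _scipy_find_peaks

from .exceptions import CatalogIntegrityError

#: 20-band aquagram axis preset (full annotation-table band list)
AXES_20 = (
    1348, 1360, 1373, 1385, 1391, 1410, 1428, 1435, 1441, 1447,
    1459, 1466, 1478, 1484, 1490, 1503, 1521, 1528, 1534, 1559,
)

#: 19-band preset: 1,521 and 1,528 nm carry identical functional descriptions;
#: the preset keeps the tentative coordinate (1,528) and drops 1,521.
AXES_19 = tuple(b for b in AXES_20 if b != 1521)


def _data(name: str) -> pd.DataFrame:
    with resources.files("aquaphot.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


@dataclass
class WamacsCatalog:
    """WAMACS regions: ranged entries (lo–hi nm) and tentative single bands."""

    entries: pd.DataFrame  # label, lo_nm, hi_nm, nominal_nm, assignment

    def __post_init__(self) -> None:
        df = self.entries
        ranged = df.dropna(subset=["lo_nm", "hi_nm"]).sort_values("lo_nm")
        bad = ranged[ranged["lo_nm"] >= ranged["hi_nm"]]
        if not bad.empty:
            raise CatalogIntegrityError(f"inverted range for {bad['label'].iloc[0]}")
        lows = ranged["lo_nm"].to_numpy()
        highs = ranged["hi_nm"].to_numpy()
        # strict interior overlap is a catalog defect; shared endpoints are
        # tolerated (adjacent conformation regions touch, e.g. at 1,482 nm)
        if np.any(lows[1:] < highs[:-1]):
            i = int(np.argmax(lows[1:] < highs[:-1]))
            raise CatalogIntegrityError(
                f"overlapping ranges {ranged['label'].iloc[i]} and "
                f"{ranged['label'].iloc[i + 1]}"
            )
        self.entries = df.reset_index(drop=True)

    @classmethod
    def default(cls) -> "WamacsCatalog":
        return cls(_data("wamacs_catalog.csv"))

    def assign(self, band: float, tol: float = 3.0):
        """Label for a band: containing range wins, else a tentative
        coordinate within ``tol`` nm, else ``None``.

        A band on a shared range endpoint goes to the lower region.
        """
        df = self.entries
        ranged = df.dropna(subset=["lo_nm", "hi_nm"]).sort_values("lo_nm")
        hit = ranged[(ranged["lo_nm"] <= band) & (band <= ranged["hi_nm"])]
        if not hit.empty:
            return str(hit["label"].iloc[0])
        tentative = df.dropna(subset=["nominal_nm"])
        d = (tentative["nominal_nm"] - band).abs()
        if not d.empty and d.min() <= tol:
            return str(tentative.loc[d.idxmin(), "label"])
        return None

    def region_key(self, band: float, tol: float = 3.0):
        """Identify the catalog row a band belongs to (label plus range),
        for per-region deduplication; ``None`` if unassigned."""
        df = self.entries
        ranged = df.dropna(subset=["lo_nm", "hi_nm"]).sort_values("lo_nm")
        hit = ranged[(ranged["lo_nm"] <= band) & (band <= ranged["hi_nm"])]
        if not hit.empty:
            row = hit.iloc[0]
            return (str(row["label"]), float(row["lo_nm"]), float(row["hi_nm"]))
        tentative = df.dropna(subset=["nominal_nm"])
        d = (tentative["nominal_nm"] - band).abs()
        if not d.empty and d.min() <= tol:
            row = tentative.loc[d.idxmin()]
            return (str(row["label"]), float(row["nominal_nm"]), float(row["nominal_nm"]))
        return None


def assign_wamacs(band: float, catalog: WamacsCatalog | None = None, tol: float = 3.0):
    """Map a wavelength to its WAMACS label (or ``None``)."""
    catalog = catalog or WamacsCatalog.default()
    return catalog.assign(band, tol=tol)


def important_bands_table() -> pd.DataFrame:
    """The packaged inventory of the 28 storage-relevant bands with their
    occurrence counts and WAMACS labels."""
    return _data("important_bands.csv")


def band_functions_table() -> pd.DataFrame:
    """Static functional annotation of the 20 axis bands (lookup only)."""
    return _data("band_functions.csv")


def find_peaks(v, prominence_frac: float = 0.05):
    """Local extrema of ``|v|`` with prominence >= ``prominence_frac * max|v|``.

    Returns a list of ``(channel, sign, magnitude)``; empty for an all-zero or
    monotone vector (endpoints are never peaks).
    """
    v = np.asarray(v, dtype=float).ravel()
    if v.size < 3 or not np.any(v):
        return []
    mag = np.abs(v)
    peaks, _props = _scipy_find_peaks(mag, prominence=prominence_frac * mag.max())
    return [(int(i), int(np.sign(v[i])), float(mag[i])) for i in peaks]


def tally_importance(peak_sets, catalog: WamacsCatalog | None = None) -> pd.DataFrame:
    """Aggregate influential bands across analyses.

    Parameters
    ----------
    peak_sets
        Iterable of ``(analysis_id, bands)`` with bands in nm, already snapped
        to a common grid (or nominal values shared across analyses).

    Returns
    -------
    DataFrame with columns ``band_nm``, ``importance`` (number of distinct
    analyses citing the band), ``sources`` and ``wamacs`` label, sorted by
    wavelength.
    """
    catalog = catalog or WamacsCatalog.default()
    cited: dict[float, set] = {}
    for analysis_id, bands in peak_sets:
        for band in bands:
            cited.setdefault(float(band), set()).add(analysis_id)
    rows = [
        {
            "band_nm": band,
            "importance": len(sources),
            "sources": sorted(map(str, sources)),
            "wamacs": catalog.assign(band),
        }
        for band, sources in cited.items()
    ]
    out = pd.DataFrame(rows, columns=["band_nm", "importance", "sources", "wamacs"])
    return out.sort_values("band_nm").reset_index(drop=True)


def select_axes(
    importance: pd.DataFrame,
    catalog: WamacsCatalog | None = None,
    min_importance: int = 2,
) -> list[float]:
    """Derive aquagram axes from a band-importance table.

    Rule: keep every band cited by at least ``min_importance`` analyses, plus
    any band matching a tentative WAMACS coordinate; deduplicate to one
    representative per WAMACS region (highest importance wins, the lower
    wavelength breaks ties).  Unassigned bands are kept as their own axes.
    """
    catalog = catalog or WamacsCatalog.default()
    tentative = set(
        catalog.entries.dropna(subset=["nominal_nm"])["nominal_nm"].astype(float)
    )
    best: dict[object, tuple[int, float]] = {}
    for _, row in importance.sort_values("band_nm").iterrows():
        band = float(row["band_nm"])
        imp = int(row["importance"])
        is_tentative = any(abs(band - t) <= 3.0 for t in tentative)
        if imp < min_importance and not is_tentative:
            continue
        key = catalog.region_key(band) or ("unassigned", band, band)
        if key not in best or imp > best[key][0]:
            best[key] = (imp, band)
    return sorted(band for _imp, band in best.values())
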