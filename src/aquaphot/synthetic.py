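"""Synthetic strawberry NIR spectra and weight series.

Emulates the cold-storage study design: two cooling conditions (CF = control
fridge, SCF = fridge with an electric-field generator), 15 storage-day labels
(0 = pre-storage), 24 fruits, 2 measurement positions and 3 consecutive
replicates per position — 2,160 spectra per condition on a 125-channel grid
spanning 908–1,670 nm.

Each spectrum is a sum of Gaussian water-absorbance bands riding on a broad
first-overtone background, with per-condition, per-band absorbance amplitudes
following piecewise-linear day trajectories (e.g. a rise-to-day-4-then-fall at
1,373 nm, monotone free-water decline at 1,404/1,410 nm, a CF-only rise of the
bulk-water bands 1,459–1,484 nm after day 4, a step increase at 1,503 nm upon
storage).  Measurement nuisance comes as per-spectrum additive offset, linear
tilt, multiplicative gain (all removable to first order by SNV) and white
channel noise; biological nuisance as a per-fruit trajectory gain and a
per-(fruit, day, band) amplitude jitter shared by the six spectra of one
fruit-day.

Weights decline linearly with day at a condition-specific rate (steeper in CF)
around a per-fruit initial weight, with day-level measurement noise.

All randomness flows from one seed: ``SeedSequence(seed)`` is split into a
spectra stream and a weights stream, each split again per condition, so either
product is reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .dataset import SpectralDataset
from .exceptions import ConfigError
from .weights import WeightTable

CONDITIONS = ("CF", "SCF")

#: Nominal band centres (nm) of the water-band set used by default (the
#: influential-band inventory of the study region), with one shared width.
DEFAULT_BAND_CENTRES = (
    1348, 1360, 1373, 1379, 1385, 1391, 1397, 1404, 1410, 1416,
    1428, 1435, 1441, 1447, 1453, 1459, 1466, 1472, 1478, 1484,
    1490, 1497, 1503, 1509, 1521, 1528, 1534, 1559,
)

#: Piecewise-linear amplitude offsets (absorbance units) per condition/band,
#: as (day, offset) breakpoints.  Shapes encode the observed storage dynamics:
#: vapour-like bands peaking on day 4, monotone free-water loss, CF-only bulk
#: water rise after day 4, a 1,503 nm step on entering storage, and a CF-only
#: late decline of the strongly-bound-water bands.
DEFAULT_TRAJECTORIES: dict[str, dict[float, tuple[tuple[float, float], ...]]] = {
    "CF": {
        1348: ((0, 0.0), (14, -0.012)),
        1360: ((0, 0.0), (14, 0.022)),
        1373: ((0, 0.0), (4, 0.030), (14, -0.030)),
        1379: ((0, 0.0), (7, 0.010), (14, -0.022)),
        1385: ((0, 0.0), (5, 0.006), (14, -0.050)),
        1391: ((0, 0.0), (5, 0.000), (14, -0.026)),
        1397: ((0, 0.0), (5, 0.000), (14, -0.030)),
        1404: ((0, 0.0), (14, -0.060)),
        1410: ((0, 0.0), (14, -0.030)),
        1428: ((0, 0.0), (4, 0.000), (14, 0.040)),
        1435: ((0, 0.0), (4, 0.000), (14, 0.020)),
        1441: ((0, 0.0), (4, 0.000), (14, 0.020)),
        1447: ((0, 0.0), (4, 0.000), (14, -0.030)),
        1459: ((0, 0.0), (4, 0.000), (14, 0.050)),
        1466: ((0, 0.0), (4, 0.000), (14, 0.045)),
        1472: ((0, 0.0), (4, 0.000), (14, 0.040)),
        1478: ((0, 0.0), (4, 0.000), (14, 0.050)),
        1484: ((0, 0.0), (4, 0.000), (14, 0.045)),
        1490: ((0, 0.0), (4, -0.006), (14, 0.030)),
        1497: ((0, 0.0), (4, 0.000), (14, 0.028)),
        1503: ((0, 0.0), (1, 0.030), (14, 0.036)),
        1509: ((0, 0.0), (14, -0.010)),
        1521: ((0, 0.0), (5, 0.000), (14, -0.040)),
        1528: ((0, 0.0), (5, 0.000), (14, -0.045)),
        1534: ((0, 0.0), (5, 0.000), (14, -0.050)),
        1559: ((0, 0.0), (5, 0.000), (14, -0.045)),
    },
    "SCF": {
        1348: ((0, 0.0), (14, 0.008)),
        1360: ((0, 0.0), (14, 0.028)),
        1373: ((0, 0.0), (4, 0.040), (14, -0.018)),
        1379: ((0, 0.0), (14, 0.012)),
        1385: ((0, 0.0), (14, 0.010)),
        1391: ((0, 0.0), (3, 0.012), (14, -0.020)),
        1397: ((0, 0.0), (14, -0.018)),
        1404: ((0, 0.0), (14, -0.040)),
        1410: ((0, 0.0), (14, -0.045)),
        1428: ((0, 0.0), (14, -0.012)),
        1435: ((0, 0.0), (14, -0.008)),
        1441: ((0, 0.0), (14, -0.008)),
        1447: ((0, 0.0), (14, -0.040)),
        1459: ((0, 0.0), (5, -0.010), (14, 0.012)),
        1466: ((0, 0.0), (5, -0.008), (14, 0.010)),
        1472: ((0, 0.0), (5, -0.008), (14, 0.008)),
        1478: ((0, 0.0), (5, -0.008), (14, 0.010)),
        1484: ((0, 0.0), (5, -0.006), (14, 0.008)),
        1490: ((0, 0.0), (14, -0.020)),
        1497: ((0, 0.0), (14, -0.015)),
        1503: ((0, 0.0), (1, 0.030), (14, 0.040)),
        1509: ((0, 0.0), (14, -0.008)),
        1521: ((0, 0.0), (14, -0.008)),
        1528: ((0, 0.0), (14, -0.006)),
        1534: ((0, 0.0), (14, -0.006)),
        1559: ((0, 0.0), (14, -0.006)),
    },
}


@dataclass
class SyntheticConfig:
    """Everything the generator needs; defaults reproduce the study design."""

    # wavelength grid
    grid_lo: float = 908.0
    grid_hi: float = 1670.0
    n_channels: int = 125

    # spectral structure
    band_centres: tuple = DEFAULT_BAND_CENTRES
    band_width: float = 9.0  # nm, Gaussian sigma
    band_base_amplitude: float = 0.12
    background: tuple = ((1450.0, 75.0, 1.10), (1190.0, 45.0, 0.25))
    trajectories: dict = field(
        default_factory=lambda: {
            c: {b: list(map(list, t)) for b, t in DEFAULT_TRAJECTORIES[c].items()}
            for c in CONDITIONS
        }
    )
    #: optional localized perturbations: dicts with keys
    #: condition, day, centre, width, delta — added to the clean curve
    extra_bumps: list = field(default_factory=list)

    # nuisance scales
    baseline_offset_sd: float = 0.02   # additive, absorbance units
    baseline_slope_sd: float = 3e-5    # absorbance per nm (tilt)
    gain_sd: float = 0.03              # multiplicative scatter
    noise_sd: float = 0.003            # white channel noise
    amp_jitter_sd: float = 0.012       # per (fruit, day, band) amplitude jitter
    fruit_amp_sd: float = 0.15         # per-fruit trajectory gain spread

    # design
    n_days: int = 15                   # labels 0..n_days-1
    n_fruits: int = 24
    n_positions: int = 2
    n_replicates: int = 3
    conditions: tuple = CONDITIONS

    # weight model; rates are daily loss fractions calibrated so day-7 mean
    # losses sit at ~7.3% (CF) and ~5.9% (SCF)
    initial_weight_g: float = 20.0
    weight_fruit_sd: float = 0.12      # per-fruit multiplicative spread
    loss_rate: dict = field(
        default_factory=lambda: {"CF": 0.073 / 7.0, "SCF": 0.059 / 7.0}
    )
    weight_noise_sd: float = 0.0097    # per-day loss-fraction noise

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ConfigError("need at least 2 channels")
        if self.band_width <= 0:
            raise ConfigError("band width must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        for name in ("n_days", "n_fruits", "n_positions", "n_replicates"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for cond in self.conditions:
            rate = self.loss_rate.get(cond, 0.0)
            worst = 1.0 - rate * (self.n_days - 1) - 5 * self.weight_noise_sd
            if worst <= 0:
                raise ConfigError(
                    f"loss rate {rate} for {cond} yields non-positive weights "
                    f"within {self.n_days - 1} days"
                )

    # -- convenience ---------------------------------------------------------
    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.grid_lo, self.grid_hi, self.n_channels)

    @property
    def spectra_per_condition(self) -> int:
        return self.n_days * self.n_fruits * self.n_positions * self.n_replicates

    def replace(self, **kw) -> "SyntheticConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        for key in ("band_centres", "conditions", "background"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(
                    tuple(v) if isinstance(v, list) else v for v in d[key]
                )
        # JSON/YAML mappings stringify numeric keys; normalise them back
        if "trajectories" in d:
            d["trajectories"] = {
                str(cond): {
                    float(band): [[float(p[0]), float(p[1])] for p in traj]
                    for band, traj in bands.items()
                }
                for cond, bands in d["trajectories"].items()
            }
        if "loss_rate" in d:
            d["loss_rate"] = {str(k): float(v) for k, v in d["loss_rate"].items()}
        # YAML 1.1 reads exponent literals without a dot (3e-05) as strings
        for key in (
            "grid_lo", "grid_hi", "band_width", "band_base_amplitude",
            "baseline_offset_sd", "baseline_slope_sd", "gain_sd", "noise_sd",
            "amp_jitter_sd", "fruit_amp_sd", "initial_weight_g",
            "weight_fruit_sd", "weight_noise_sd",
        ):
            if key in d:
                d[key] = float(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "SyntheticConfig":
        """Load a config from JSON or YAML."""
        text = open(path).read()
        data = yaml.safe_load(text)
        return cls.from_dict(data)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def identical_conditions_config(**kw) -> SyntheticConfig:
    """Default config with SCF trajectories replaced by the CF ones, so the two
    conditions are statistically identical (null-comparison experiments)."""
    cfg = SyntheticConfig(**kw)
    cf = cfg.trajectories["CF"]
    cfg.trajectories = {c: {b: [list(p) for p in t] for b, t in cf.items()}
                        for c in cfg.conditions}
    return cfg


def delayed_config(lag_days: float = 3.0, **kw) -> SyntheticConfig:
    """Default config where SCF follows the CF trajectories delayed by
    ``lag_days`` (clamped at day 0), the construction behind the ripening-delay
    comparison."""
    cfg = SyntheticConfig(**kw)
    cf = cfg.trajectories["CF"]
    delayed = {
        band: [[day, _interp_traj(traj, max(0.0, day - lag_days))]
               for day in range(cfg.n_days)]
        for band, traj in cf.items()
    }
    cfg.trajectories = {"CF": {b: [list(p) for p in t] for b, t in cf.items()},
                        "SCF": delayed}
    return cfg


def _interp_traj(breakpoints, day: float) -> float:
    pts = sorted((float(d), float(v)) for d, v in breakpoints)
    days = np.array([p[0] for p in pts])
    vals = np.array([p[1] for p in pts])
    return float(np.interp(day, days, vals))


def _gauss(wl: np.ndarray, centre: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - centre) / width) ** 2)


def generate_spectra(config: SyntheticConfig, seed: int | None = None) -> SpectralDataset:
    """Simulate the full spectral design; deterministic given the seed.

    Row order is acquisition order: condition block, then day, fruit, position,
    replicate — so the six spectra of a fruit-day are contiguous, matching the
    stepwise-exclusion cross-validation blocks.
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed if seed is None else seed)
    spectra_ss, _weights_ss = root.spawn(2)
    cond_streams = dict(zip(cfg.conditions, spectra_ss.spawn(len(cfg.conditions))))

    wl = cfg.wavelengths
    bg = np.zeros_like(wl)
    for centre, width, amp in cfg.background:
        bg += amp * _gauss(wl, centre, width)
    band_shapes = np.stack(
        [_gauss(wl, c, cfg.band_width) for c in cfg.band_centres]
    )  # (n_bands, p)
    n_bands = len(cfg.band_centres)

    rows_meta = []
    rows_X = []
    for cond in cfg.conditions:
        rng = np.random.default_rng(cond_streams[cond])
        traj = cfg.trajectories.get(cond, {})
        fruit_gain = 1.0 + rng.normal(0.0, cfg.fruit_amp_sd, size=cfg.n_fruits)
        # precompute clean trajectory offsets per (day, band)
        offsets = np.zeros((cfg.n_days, n_bands))
        for j, centre in enumerate(cfg.band_centres):
            t = traj.get(centre) or traj.get(float(centre)) or traj.get(int(centre))
            if t:
                for day in range(cfg.n_days):
                    offsets[day, j] = _interp_traj(t, day)
        bumps = np.zeros((cfg.n_days, wl.size))
        for bump in cfg.extra_bumps:
            if bump.get("condition", cond) != cond:
                continue
            bumps[int(bump["day"])] += bump["delta"] * _gauss(
                wl, bump["centre"], bump.get("width", cfg.band_width)
            )
        for day in range(cfg.n_days):
            for f in range(cfg.n_fruits):
                jitter = rng.normal(0.0, cfg.amp_jitter_sd, size=n_bands)
                amps = (
                    cfg.band_base_amplitude
                    + offsets[day] * fruit_gain[f]
                    + jitter
                )
                core = bg + amps @ band_shapes + bumps[day]
                for pos_i in range(cfg.n_positions):
                    pos = "front" if pos_i == 0 else "back" if pos_i == 1 else f"pos{pos_i}"
                    for rep in range(1, cfg.n_replicates + 1):
                        gain = 1.0 + rng.normal(0.0, cfg.gain_sd)
                        offset = rng.normal(0.0, cfg.baseline_offset_sd)
                        slope = rng.normal(0.0, cfg.baseline_slope_sd)
                        noise = rng.normal(0.0, cfg.noise_sd, size=wl.size)
                        spec = gain * core + offset + slope * (wl - wl.mean()) + noise
                        rows_X.append(spec)
                        rows_meta.append((cond, day, f + 1, pos, rep))
    meta = pd.DataFrame(
        rows_meta, columns=["condition", "day", "fruit_id", "position", "replicate"]
    )
    return SpectralDataset(wl, np.vstack(rows_X), meta)


def generate_weights(config: SyntheticConfig, seed: int | None = None) -> WeightTable:
    """Simulate daily fruit weights; loss fraction = rate*day + noise.

    The day-0 weight of each fruit is its fresh weight; CF defaults lose weight
    faster than SCF.
    """
    cfg = config
    root = np.random.SeedSequence(cfg.seed if seed is None else seed)
    _spectra_ss, weights_ss = root.spawn(2)
    cond_streams = dict(zip(cfg.conditions, weights_ss.spawn(len(cfg.conditions))))

    recs = []
    for cond in cfg.conditions:
        rng = np.random.default_rng(cond_streams[cond])
        rate = cfg.loss_rate.get(cond, 0.0)
        fresh = cfg.initial_weight_g * (
            1.0 + rng.normal(0.0, cfg.weight_fruit_sd, size=cfg.n_fruits)
        )
        fresh = np.clip(fresh, 0.2 * cfg.initial_weight_g, None)
        for f in range(cfg.n_fruits):
            recs.append((f + 1, cond, 0, float(fresh[f])))
            for day in range(1, cfg.n_days):
                loss = rate * day + rng.normal(0.0, cfg.weight_noise_sd)
                w = fresh[f] * max(1.0 - loss, 1e-3)
                recs.append((f + 1, cond, day, float(w)))
    return WeightTable(
        pd.DataFrame(recs, columns=["fruit_id", "condition", "day", "weight_g"])
    )
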