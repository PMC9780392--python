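"""End-to-end analysis orchestration.

``run_pipeline`` drives the whole storage-monitoring analysis on either
simulated or loaded data: weight statistics → SNV difference spectra → SIMCA
per storage window → PLSR per window → band-importance tally → aquagrams.
Each stage is isolated: a failure marks that stage failed in the report while
independent stages still run.  The report is a plain JSON-serialisable dict;
CSV artifacts are written when an output directory is given.

Storage-day windows follow the study design: days 1–4, days 1–8, and the full
run 0–14 (day-0 inclusion per window is explicit in the presets).
"""

from __future__ import annotations

import json
import traceback
from pathlib import Path

import numpy as np
import pandas as pd

from . import bands as bands_mod
from .aquagram import best_matching_day, compare_profiles, compute_aquagram
from .dataset import SpectralDataset, crop_region, read_spectra
from .pls import cross_validate
from .preprocess import difference_spectrum
from .simca import fit_simca
from .synthetic import SyntheticConfig, generate_spectra, generate_weights
from .weights import WeightTable, daily_weight_change, equal_variance_ttest, loss_rates

#: analysis region: first overtone of water
REGION = (1300.0, 1600.0)

#: storage-day windows (label, day list)
WINDOWS = (
    ("days1-4", tuple(range(1, 5))),
    ("days1-8", tuple(range(1, 9))),
    ("days0-14", tuple(range(0, 15))),
)


def _round(x, nd=6):
    if isinstance(x, dict):
        return {k: _round(v, nd) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round(v, nd) for v in x]
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if isinstance(x, (float, np.floating)):
        return round(float(x), nd)
    if isinstance(x, (int, np.integer)):
        return int(x)
    return x


def _stage(report: dict, name: str):
    """Decorator-ish context: run fn, capture failure into the report."""
    def runner(fn, *args, **kw):
        try:
            report["stages"][name] = {"status": "ok", **fn(*args, **kw)}
        except Exception as exc:  # stage isolation is the point
            report["stages"][name] = {
                "status": "failed",
                "error": f"{type(exc).__name__}: {exc}",
                "trace": traceback.format_exc(limit=3),
            }
    return runner


def run_pipeline(
    config: SyntheticConfig | None = None,
    spectra: SpectralDataset | None = None,
    weights: WeightTable | None = None,
    spectra_path=None,
    weights_path=None,
    seed: int | None = None,
    reference_day: int = 1,
    axes=bands_mod.AXES_20,
    out_dir=None,
    include_weights: bool = True,
    segment: int = 6,
) -> dict:
    """Run the full analysis and return the machine-readable report.

    Data comes from, in order of precedence: explicit ``spectra``/``weights``
    objects, file paths, or simulation from ``config`` (default config if
    nothing is given).  ``seed`` overrides the config seed.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    report: dict = {"stages": {}}

    # -- stage 1: data --------------------------------------------------------
    def data_stage():
        nonlocal spectra, weights
        source = "provided"
        if spectra is None and spectra_path is not None:
            spectra = read_spectra(spectra_path)
            source = "file"
        if spectra is None:
            cfg = config or SyntheticConfig()
            if seed is not None:
                cfg = cfg.replace(seed=seed)
            spectra = generate_spectra(cfg)
            if include_weights and weights is None and weights_path is None:
                weights = generate_weights(cfg)
            source = "synthetic"
            report["config"] = cfg.to_dict()
        if weights is None and weights_path is not None:
            weights = WeightTable.from_csv(weights_path)
        counts = spectra.meta.groupby("condition").size().to_dict() \
            if "condition" in spectra.meta else {"all": spectra.n_spectra}
        return {
            "source": source,
            "n_spectra": int(spectra.n_spectra),
            "n_channels": int(spectra.n_channels),
            "per_condition": {str(k): int(v) for k, v in counts.items()},
        }

    _stage(report, "data")(data_stage)
    if report["stages"]["data"]["status"] != "ok":
        return report
    conditions = list(spectra.meta["condition"].unique())
    region = crop_region(spectra, *REGION)

    # -- stage 2: weights -----------------------------------------------------
    def weights_stage():
        if weights is None:
            return {"status_note": "no weight table supplied"}
        block: dict = {}
        day7 = {}
        for cond in conditions:
            r = loss_rates(weights, cond, 7)
            day7[cond] = r
            series = {}
            for day in sorted(weights.records["day"].unique()):
                if day == 0:
                    continue
                vals = [
                    daily_weight_change(weights, f, cond, int(day))
                    for f in weights.fruits(cond)
                ]
                series[int(day)] = float(np.mean(vals))
            block[cond] = {
                "day7_loss_mean_pct": float(r.mean()),
                "day7_loss_sd_pct": float(r.std(ddof=1)),
                "mean_daily_change_g": series,
            }
        if len(conditions) == 2:
            t = equal_variance_ttest(day7[conditions[0]], day7[conditions[1]])
            block["ttest_day7_loss"] = {"t": t.t, "df": t.df, "p": t.p}
        if out is not None:
            weights.to_csv(out / "weights.csv")
        return block

    def weights_skip():
        return {}

    if include_weights:
        _stage(report, "weights")(weights_stage)
        if weights is None:
            report["stages"]["weights"]["status"] = "skipped"
    else:
        report["stages"]["weights"] = {"status": "skipped"}

    # -- stage 3: difference spectra -------------------------------------------
    peak_sets: list[tuple[str, list[float]]] = []

    def diff_stage():
        block = {}
        days = sorted(d for d in region.meta["day"].unique() if d != reference_day)
        for cond in conditions:
            tables = {}
            for day in days:
                diff = difference_spectrum(region, cond, int(day), reference_day)
                tables[int(day)] = diff
                if out is not None:
                    diff.to_frame().to_csv(
                        out / f"diffspec_{cond}_day{day}_vs_{reference_day}.csv",
                        index=False,
                    )
            # tally extrema of the last-day and day-4 curves as influential
            for day in (4, days[-1]):
                if day not in tables:
                    continue
                peaks = bands_mod.find_peaks(tables[day].delta)
                wls = [float(region.wavelengths[i]) for i, _s, _m in peaks]
                peak_sets.append((f"diff:{cond}:day{day}", wls))
            final = tables[days[-1]]
            block[cond] = {
                "reference_day": reference_day,
                "days": [int(d) for d in days],
                "final_day_min_nm": float(
                    region.wavelengths[int(np.argmin(final.delta))]
                ),
                "final_day_max_nm": float(
                    region.wavelengths[int(np.argmax(final.delta))]
                ),
            }
        return block

    _stage(report, "difference_spectra")(diff_stage)

    # -- stage 4: SIMCA ---------------------------------------------------------
    def simca_stage():
        block = {}
        for cond in conditions:
            sub = region.where(condition=cond)
            per_window = {}
            for label, day_set in WINDOWS:
                win = sub.where(day=list(day_set))
                if win.n_spectra == 0:
                    continue
                res = fit_simca(win, class_key="day")
                dp = res.discriminating_power
                peaks = bands_mod.find_peaks(dp)
                wls = [float(win.wavelengths[i]) for i, _s, _m in peaks]
                peak_sets.append((f"simca-dp:{cond}:{label}", wls))
                D = res.interclass_distances.to_numpy()
                iu = np.triu_indices(len(res.classes), 1)
                per_window[label] = {
                    "accuracy_pct": 100.0 * res.accuracy(),
                    "n_classes": len(res.classes),
                    "interclass_distance_min": float(D[iu].min()),
                    "interclass_distance_median": float(np.median(D[iu])),
                    "top_dp_nm": [
                        float(win.wavelengths[i])
                        for i in np.argsort(dp)[::-1][:5]
                    ],
                }
                if out is not None:
                    pd.DataFrame(
                        {"wavelength_nm": win.wavelengths, "discriminating_power": dp}
                    ).to_csv(out / f"simca_dp_{cond}_{label}.csv", index=False)
            block[cond] = per_window
        return block

    _stage(report, "simca")(simca_stage)

    # -- stage 5: PLSR ----------------------------------------------------------
    def plsr_stage():
        block = {}
        for cond in conditions:
            sub = region.where(condition=cond)
            per_window = {}
            for label, day_set in (WINDOWS[0], WINDOWS[2]):
                win = sub.where(day=list(day_set))
                if win.n_spectra == 0:
                    continue
                n_lv_max = min(15, max(1, win.n_spectra - segment - 1))
                cv = cross_validate(win, n_lv_max=n_lv_max, segment=segment)
                row = cv.metrics[cv.metrics["n_lv"] == cv.n_lv].iloc[0]
                from .pls import fit_plsr

                fitres = fit_plsr(win, n_lv=cv.n_lv)
                peaks = bands_mod.find_peaks(fitres.coef)
                wls = [float(win.wavelengths[i]) for i, _s, _m in peaks]
                peak_sets.append((f"pls-rv:{cond}:{label}", wls))
                per_window[label] = {
                    "n_lv": int(cv.n_lv),
                    "sec": float(row["sec"]),
                    "secv": float(row["secv"]),
                    "r2c": float(row["r2c"]),
                    "r2cv": float(row["r2cv"]),
                    "jagged_flag": bool(fitres.jagged_flag),
                }
                if out is not None:
                    cv.metrics.to_csv(
                        out / f"plsr_metrics_{cond}_{label}.csv", index=False
                    )
                    pd.DataFrame(
                        {"wavelength_nm": win.wavelengths,
                         "coefficient": fitres.coef}
                    ).to_csv(out / f"plsr_regvec_{cond}_{label}.csv", index=False)
            block[cond] = per_window
        return block

    _stage(report, "plsr")(plsr_stage)

    # -- stage 6: band importance -----------------------------------------------
    def bands_stage():
        table = bands_mod.tally_importance(peak_sets)
        if out is not None:
            exp = table.copy()
            exp["sources"] = exp["sources"].apply(";".join)
            exp.to_csv(out / "band_importance.csv", index=False)
        top = table.sort_values(
            ["importance", "band_nm"], ascending=[False, True]
        ).head(10)
        return {
            "n_bands": int(len(table)),
            "top_bands": [
                {
                    "band_nm": float(r["band_nm"]),
                    "importance": int(r["importance"]),
                    "wamacs": r["wamacs"],
                }
                for _, r in top.iterrows()
            ],
        }

    _stage(report, "band_importance")(bands_stage)

    # -- stage 7: aquagram --------------------------------------------------------
    def aquagram_stage():
        profile = compute_aquagram(region, axes=axes, reference_day=reference_day)
        if out is not None:
            profile.to_csv(out / "aquagram_profiles.csv")
            profile.to_json(out / "aquagram_profiles.json")
        block = {
            "axes_nm": [float(a) for a in axes],
            "reference_day": reference_day,
        }
        if len(conditions) == 2:
            a, b = conditions
            days = sorted(
                set(region.where(condition=a).meta["day"])
                & set(region.where(condition=b).meta["day"])
            )
            days = [d for d in days if d != 0][:7]
            cmp_table = compare_profiles(
                profile, [((a, d), (b, d)) for d in days]
            )
            block["day_by_day"] = {
                int(r["day_a"]): {"cosine": float(r["cosine"]),
                                  "rms": float(r["rms"])}
                for _, r in cmp_table.iterrows()
            }
            candidates = [d for d in days if d != reference_day]
            if 7 in days and candidates:
                match = best_matching_day(profile, (b, 7), a, candidates)
                block["scf_day7_best_cf_match"] = int(match)
                block["estimated_lag_days"] = int(7 - match)
        return block

    _stage(report, "aquagram")(aquagram_stage)

    report = _round(report)
    if out is not None:
        write_report(report, out / "report.json")
    return report


def write_report(report: dict, path) -> None:
    """Deterministic JSON serialisation (sorted keys, fixed separators)."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
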