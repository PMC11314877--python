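"""End-to-end orchestration of the SPAD estimation experiment.

For each treatment group the pipeline: differentiates the preprocessed
spectra at every order of the sweep, runs SPA band selection per order
on the training rows (scored on validation), fits MLR and PLSR on the
selected bands, scores both subsets, flags the order with the best
validation R² per model, and reports the improvement of every order
over the raw (order-0) spectra.  Descriptive SPAD statistics and the
green-peak / red-valley / red-edge spectral features are computed
alongside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .band_selection import BandSelection, selection_table, spa_select
from .dataset import SpectraSet, Spectrum
from .fractional import fractional_derivative_matrix, _order_grid
from .regression import mlr_fit, plsr_fit, score

__all__ = [
    "Split",
    "SpectralFeatures",
    "SweepResult",
    "split_train_validation",
    "spad_summary",
    "spectral_features",
    "run_order_sweep",
    "select_optimal_order",
    "improvement_over_raw",
    "report",
]


@dataclass
class Split:
    """Deterministic train/validation partition of sample ids."""

    train_ids: list[str]
    validation_ids: list[str]
    ratio: float
    seed: int
    stratified_by: str | None = None

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.validation_ids):
            raise ValueError("train and validation ids must be disjoint")

    def train_mask(self, sample_ids) -> np.ndarray:
        tr = set(self.train_ids)
        return np.asarray([s in tr for s in sample_ids])


def split_train_validation(
    sset: SpectraSet, ratio: float = 2 / 3, seed: int = 0, stratify: bool = True
) -> Split:
    """Random per-group proportional split, deterministic given ``seed``."""
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train: list[str] = []
    val: list[str] = []
    strata = (
        {g: np.flatnonzero(sset.group_mask(g)) for g in dict.fromkeys(sset.groups)}
        if stratify
        else {"all": np.arange(len(sset))}
    )
    for g, idx in strata.items():
        if stratify and idx.size < 3:
            raise ValueError(f"stratum {g!r} has {idx.size} samples; need >= 3")
        idx = idx[rng.permutation(idx.size)]
        n_tr = int(round(ratio * idx.size))
        n_tr = min(max(n_tr, 1), idx.size - 1)
        train += [sset.sample_ids[i] for i in np.sort(idx[:n_tr])]
        val += [sset.sample_ids[i] for i in np.sort(idx[n_tr:])]
    return Split(train, val, ratio, seed, "group" if stratify else None)


def spad_summary(sset: SpectraSet, by_group: bool = True) -> pd.DataFrame:
    """Min/max/mean/SD of SPAD, overall or per treatment group (SD uses n−1)."""
    if sset.spad is None:
        raise ValueError("SpectraSet has no SPAD values")
    frame = pd.DataFrame({"group": sset.groups, "spad": sset.spad})
    if not by_group:
        frame["group"] = "all"
    out = (
        frame.groupby("group", sort=False)["spad"]
        .agg(min="min", max="max", mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    return out


@dataclass
class SpectralFeatures:
    """Green-peak / red-valley / red-edge landmarks of one spectrum."""

    green_peak_position: float
    green_peak_height: float
    red_valley_position: float
    red_valley_height: float
    red_edge_position: float

    def __post_init__(self) -> None:
        if not 500 <= self.green_peak_position <= 600:
            raise ValueError("green peak must lie in [500, 600] nm")
        if not 640 <= self.red_valley_position <= 700:
            raise ValueError("red valley must lie in [640, 700] nm")
        if not 680 <= self.red_edge_position <= 760:
            raise ValueError("red edge must lie in [680, 760] nm")


def _window(w: np.ndarray, lo: float, hi: float) -> np.ndarray:
    m = np.flatnonzero((w >= lo) & (w <= hi))
    if m.size == 0:
        raise ValueError(f"wavelength grid does not cover [{lo}, {hi}] nm")
    return m


def spectral_features(spectrum: Spectrum) -> SpectralFeatures:
    """Extract the classic vegetation landmarks from one spectrum.

    Green peak: argmax reflectance in [500, 600]; red valley: argmin in
    [640, 700]; red edge: argmax of the first-difference slope in
    [680, 760].  Ties break toward the lower wavelength.
    """
    w, r = spectrum.wavelengths, spectrum.reflectance
    if w[0] > 500 or w[-1] < 760:
        raise ValueError("grid must cover 500-760 nm for feature extraction")
    g = _window(w, 500, 600)
    v = _window(w, 640, 700)
    e = _window(w, 680, 760)
    gp = g[int(np.argmax(r[g]))]
    rv = v[int(np.argmin(r[v]))]
    slope = np.gradient(r, w)
    re = e[int(np.argmax(slope[e]))]
    return SpectralFeatures(
        float(w[gp]), float(r[gp]), float(w[rv]), float(r[rv]), float(w[re])
    )


def features_table(sset: SpectraSet) -> pd.DataFrame:
    """Spectral features of every sample in a set."""
    rows = []
    for i in range(len(sset)):
        f = spectral_features(sset.spectrum(i))
        rows.append(
            {
                "sample_id": sset.sample_ids[i],
                "group": sset.groups[i],
                "spad": None if sset.spad is None else float(sset.spad[i]),
                "green_peak_position": f.green_peak_position,
                "green_peak_height": f.green_peak_height,
                "red_valley_position": f.red_valley_position,
                "red_valley_height": f.red_valley_height,
                "red_edge_position": f.red_edge_position,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SweepResult:
    """Per-group, per-order, per-model scores of the full sweep."""

    table: pd.DataFrame
    selections: dict[tuple[str, float], BandSelection] = field(default_factory=dict)
    predictions: dict[tuple[str, float, str], pd.DataFrame] = field(
        default_factory=dict
    )
    orders: list[float] = field(default_factory=list)
    n_bands: int = 10


def run_order_sweep(
    sset: SpectraSet,
    split: Split,
    orders=None,
    models: tuple[str, ...] = ("MLR", "PLSR"),
    n_bands: int = 10,
    step_h: float | None = None,
    pls_max_components: int = 10,
) -> SweepResult:
    """The 21-order x 2-model sweep, run independently per treatment group."""
    if sset.spad is None:
        raise ValueError("SpectraSet must carry SPAD values")
    if not models:
        raise ValueError("at least one model kind required")
    for m in models:
        if m not in ("MLR", "PLSR"):
            raise ValueError(f"unknown model kind {m!r}")
    if orders is None:
        orders = _order_grid(0.0, 2.0, 0.1)
    else:
        orders = [round(float(a), 10) for a in orders]
    dw = np.diff(sset.wavelengths)
    if dw.size and not np.allclose(dw, dw[0], rtol=1e-6, atol=1e-9):
        raise ValueError("wavelength grid must be uniform; resample first")
    h = float(dw[0]) if step_h is None and dw.size else float(step_h or 1.0)

    tr_mask = split.train_mask(sset.sample_ids)
    rows = []
    selections: dict[tuple[str, float], BandSelection] = {}
    predictions: dict[tuple[str, float, str], pd.DataFrame] = {}
    for group in dict.fromkeys(sset.groups):
        gmask = sset.group_mask(group)
        Xg = sset.reflectance[gmask]
        yg = sset.spad[gmask]
        ids_g = [s for s, m in zip(sset.sample_ids, gmask) if m]
        tr = tr_mask[gmask]
        for a in orders:
            Xa = fractional_derivative_matrix(Xg, a, h)
            sel = spa_select(
                Xa[tr], yg[tr], Xa[~tr], yg[~tr],
                fixed_n=n_bands, wavelengths=sset.wavelengths,
            )
            sel.order_alpha = a
            selections[(group, a)] = sel
            B_tr = Xa[tr][:, sel.selected_indices]
            B_val = Xa[~tr][:, sel.selected_indices]
            fitted = {}
            if "MLR" in models:
                fitted["MLR"] = mlr_fit(B_tr, yg[tr], sel.selected_indices)
            if "PLSR" in models:
                best = None
                cap = min(pls_max_components, sel.n_selected, int(tr.sum()) - 1)
                for k in range(1, cap + 1):
                    m = plsr_fit(B_tr, yg[tr], k, sel.selected_indices)
                    rm = score(yg[~tr], m.predict(B_val)).rmse
                    if best is None or rm < best[0]:
                        best = (rm, m)
                fitted["PLSR"] = best[1]
            for kind, model in fitted.items():
                for subset, B, y_s, ids_s in (
                    ("train", B_tr, yg[tr], [i for i, m in zip(ids_g, tr) if m]),
                    ("validation", B_val, yg[~tr], [i for i, m in zip(ids_g, tr) if not m]),
                ):
                    pred = model.predict(B)
                    sc = score(y_s, pred, subset)
                    rows.append(
                        {
                            "group": group,
                            "order": a,
                            "model": kind,
                            "subset": subset,
                            "r2": sc.r2,
                            "rmse": sc.rmse,
                            "n": sc.n,
                            "n_bands": sel.n_selected,
                            "wavelengths": ";".join(
                                f"{w:g}" for w in sel.selected_wavelengths
                            ),
                        }
                    )
                    if subset == "validation":
                        predictions[(group, a, kind)] = pd.DataFrame(
                            {
                                "sample_id": ids_s,
                                "measured_spad": y_s,
                                "predicted_spad": pred,
                            }
                        )
    return SweepResult(pd.DataFrame(rows), selections, predictions, orders, n_bands)


def _sweep_frame(sweep) -> pd.DataFrame:
    return sweep.table if isinstance(sweep, SweepResult) else pd.DataFrame(sweep)


def select_optimal_order(sweep) -> pd.DataFrame:
    """Per (group, model): the order with the highest validation R².

    Ties break toward the lower order; the result is invariant to the
    row order of the sweep table.
    """
    frame = _sweep_frame(sweep)
    if frame.empty:
        raise ValueError("empty sweep")
    val = frame[frame["subset"] == "validation"].sort_values(
        ["group", "model", "order"], kind="stable"
    )
    idx = val.groupby(["group", "model"], sort=False)["r2"].idxmax()
    out = val.loc[idx, ["group", "model", "order", "r2", "rmse"]]
    return out.rename(columns={"order": "best_order"}).reset_index(drop=True)


def improvement_over_raw(sweep) -> pd.DataFrame:
    """Percent change of validation R² and RMSE at each order vs order 0."""
    frame = _sweep_frame(sweep)
    val = frame[frame["subset"] == "validation"]
    rows = []
    for (group, model), part in val.groupby(["group", "model"], sort=False):
        base = part[part["order"] == 0.0]
        if base.empty:
            raise ValueError(f"order 0 missing for group={group!r}, model={model!r}")
        r2_0 = float(base["r2"].iloc[0])
        rmse_0 = float(base["rmse"].iloc[0])
        for _, row in part.sort_values("order").iterrows():
            rows.append(
                {
                    "group": group,
                    "model": model,
                    "order": row["order"],
                    "r2_pct_change": (
                        np.nan if r2_0 == 0 else (row["r2"] - r2_0) / r2_0 * 100.0
                    ),
                    "rmse_pct_change": (
                        np.nan
                        if rmse_0 == 0
                        else (row["rmse"] - rmse_0) / rmse_0 * 100.0
                    ),
                }
            )
    return pd.DataFrame(rows)


def run_synthetic_experiment(
    config=None,
    seed: int | None = None,
    analysis_lo: float = 400.0,
    analysis_hi: float = 1350.0,
    orders=None,
    models: tuple[str, ...] = ("MLR", "PLSR"),
    n_bands: int = 10,
    ratio: float = 2 / 3,
    out_dir=None,
    smooth_weights=None,
    max_abs_jump: float = 0.3,
):
    """Generate, preprocess, sweep and (optionally) report in one call.

    Returns a dict with the dataset, QC report, split, sweep result,
    optimal-order table, improvement table, feature table and SPAD
    summary.  ``seed`` overrides ``config.seed`` and also seeds the
    train/validation split.
    """
    from .preprocessing import DEFAULT_WEIGHTS, crop_range, quality_filter, smooth_set
    from .synthetic import SyntheticConfig, generate_dataset

    if config is None:
        config = SyntheticConfig()
    if seed is not None:
        config = SyntheticConfig(**{**config.__dict__, "seed": int(seed)})
    seed = config.seed
    sset = generate_dataset(config)
    filtered, qc = quality_filter(sset, max_abs_jump=max_abs_jump)
    smoothed = smooth_set(filtered, smooth_weights or DEFAULT_WEIGHTS)
    cropped = crop_range(smoothed, analysis_lo, analysis_hi)
    split = split_train_validation(cropped, ratio=ratio, seed=seed)
    sweep = run_order_sweep(cropped, split, orders=orders, models=models, n_bands=n_bands)
    optimal = select_optimal_order(sweep)
    improvement = improvement_over_raw(sweep)
    feats = features_table(smoothed)
    summary = spad_summary(sset)
    result = {
        "config": config,
        "dataset": sset,
        "qc": qc,
        "preprocessed": cropped,
        "split": split,
        "sweep": sweep,
        "optimal": optimal,
        "improvement": improvement,
        "features": feats,
        "spad_summary": summary,
    }
    if out_dir is not None:
        from dataclasses import asdict

        report(
            sweep,
            features=feats,
            out_dir=out_dir,
            config=asdict(config),
            seed=seed,
        )
    return result


def report(
    sweep: SweepResult,
    selections: dict | None = None,
    features: pd.DataFrame | None = None,
    out_dir="spadspec_report",
    config: dict | None = None,
    seed: int | None = None,
) -> list[Path]:
    """Write the sweep, optimal orders, band map, features and scatter data.

    Output is deterministic for a fixed config and seed (no timestamps),
    so identical runs reproduce every file bit-for-bit.
    """
    frame = _sweep_frame(sweep)
    if frame.empty or not frame["model"].nunique():
        raise ValueError("nothing to report: sweep has no fitted models")
    optimal = select_optimal_order(sweep)
    improvement = improvement_over_raw(sweep)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(frame: pd.DataFrame, name: str) -> None:
        path = out_dir / name
        frame.to_csv(path, index=False, float_format="%.10g")
        written.append(path)

    _write(frame, "sweep.csv")
    _write(optimal, "optimal_orders.csv")
    _write(improvement, "improvement_over_raw.csv")
    sel = selections if selections is not None else sweep.selections
    if sel:
        sel_rows = []
        for key, s in sel.items():
            group = key[0] if isinstance(key, tuple) else ""
            tab = selection_table({s.order_alpha if s.order_alpha is not None else 0.0: s})
            tab.insert(0, "group", group)
            sel_rows.append(tab)
        _write(pd.concat(sel_rows, ignore_index=True), "selected_bands.csv")
    if features is not None:
        _write(features, "features.csv")
        num = features.select_dtypes("number").columns
        _write(
            features.groupby("group", sort=False)[list(num)].mean().reset_index(),
            "features_by_group.csv",
        )
    if isinstance(sweep, SweepResult) and sweep.predictions:
        scatter = []
        for _, row in optimal.iterrows():
            key = (row["group"], row["best_order"], row["model"])
            part = sweep.predictions[key].copy()
            part.insert(0, "group", row["group"])
            part.insert(1, "model", row["model"])
            part.insert(2, "order", row["best_order"])
            scatter.append(part)
        _write(pd.concat(scatter, ignore_index=True), "scatter_optimal.csv")
    manifest = {
        "package": "spadspec",
        "version": __version__,
        "seed": seed,
        "config": config,
        "files": [p.name for p in written] + ["manifest.json"],
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    written.append(path)
    return written
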