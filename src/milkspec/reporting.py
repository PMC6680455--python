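"""Pipeline orchestration and table-style reports.

Produces the two standard summaries — descriptive statistics of the mineral
panel and PLS-vs-BiPLS fit statistics per trait — and drives the whole
workflow (preprocess → per-trait model comparison) from a single config.
Numbers are kept at full precision in machine-readable outputs; rounding to
2 decimals happens only in the formatted views.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .bipls import ComparisonResult, compare_models, partition
from .preprocessing import (
    RegionSet,
    SpectraSet,
    normality_check,
    reference_outliers,
    select_regions,
    spectral_outliers_mahalanobis,
    to_absorbance,
)
from .synthetic import ELEMENTS, MineralPanel

__all__ = [
    "descriptive_table",
    "fit_stats_table",
    "format_fit_stats",
    "PipelineConfig",
    "run_pipeline",
]

log = logging.getLogger("milkspec")


def _stats_row(trait: str, y: np.ndarray) -> dict:
    y = np.asarray(y, dtype=float)
    y = y[~np.isnan(y)]
    n = y.size
    mean = float(y.mean())
    sd = float(np.std(y, ddof=1)) if n > 1 else 0.0
    cv = 100.0 * sd / mean if mean != 0 else np.nan
    return {"trait": trait, "mean": mean, "sd": sd, "cv_pct": cv,
            "min": float(y.min()), "max": float(y.max()), "n": n}


def descriptive_table(
    panel: MineralPanel, composition: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Descriptive statistics (mean, SD, CV%, min, max, n) per trait.

    Covers total/diffusible/micellar and micellar/diffusible-ratio rows per
    element; an element whose micellar fraction is identically zero (Na) is
    reported as a total row only. ``composition`` may supply extra columns
    (e.g. fat, protein percentages) reported as-is, one row per column.
    """
    rows = []
    if composition is not None:
        for col in composition.columns:
            if col == "sample_id":
                continue
            rows.append(_stats_row(col, composition[col].to_numpy(dtype=float)))
    for el in ELEMENTS:
        micellar = panel.trait(f"{el}_micellar")
        rows.append(_stats_row(f"{el}_total", panel.trait(f"{el}_total")))
        if np.allclose(micellar, 0.0):
            continue
        rows.append(_stats_row(f"{el}_diffusible", panel.trait(f"{el}_diffusible")))
        rows.append(_stats_row(f"{el}_micellar", micellar))
        rows.append(_stats_row(f"{el}_ratio", panel.trait(f"{el}_ratio")))
    return pd.DataFrame(rows)


def fit_stats_table(comparisons: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Two rows (PLS, BiPLS) per trait with LV, RMSE_CV, R²_CV, RPD_CV, NV, ΔR²_CV.

    Values are unrounded; the internal identities (RPD·RMSE = SD, ΔR²_CV =
    difference of the paired R²_CV) are asserted before emission.
    """
    rows = []
    for comp in comparisons:
        for method, cv in (("PLS", comp.pls), ("BiPLS", comp.bipls)):
            assert abs(cv.rpd_cv * cv.rmse_cv - cv.sd) <= 1e-6 * max(cv.sd, 1.0)
            rows.append({
                "trait": comp.trait, "method": method, "n_lv": cv.n_lv,
                "rmse_cv": cv.rmse_cv, "r2_cv": cv.r2_cv, "rpd_cv": cv.rpd_cv,
                "nv": comp.nv if method == "BiPLS" else None,
                "delta_r2_cv": comp.delta_r2_cv if method == "BiPLS" else None,
            })
        assert abs(comp.delta_r2_cv - (comp.bipls.r2_cv - comp.pls.r2_cv)) <= 1e-12
    return pd.DataFrame(rows)


def format_fit_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Presentation view of :func:`fit_stats_table`, rounded to 2 decimals."""
    out = table.copy()
    for col in ("rmse_cv", "r2_cv", "rpd_cv", "delta_r2_cv"):
        out[col] = out[col].round(2)
    return out


@dataclass
class PipelineConfig:
    """End-to-end run configuration (typically loaded from YAML).

    Either ``simulate`` (keyword arguments for
    :class:`~milkspec.synthetic.GeneratorConfig`) or ``spectra_csv`` +
    ``panel_csv`` must be given. All seeds are explicit; the defaults mirror
    the study settings: 45 intervals, up to 10 latent variables, p > 0.10 in
    the latent-variable randomization test, ±3 SD reference outliers and the
    three standard informative wavenumber regions.
    """

    traits: Sequence[str] = ("Ca_total",)
    spectra_csv: str | None = None
    panel_csv: str | None = None
    spectra_mode: str = "transmittance"
    simulate: Mapping | None = None
    regions: Sequence[Sequence[float]] | None = None
    n_intervals: int = 45
    max_lv: int = 10
    p_threshold: float = 0.10
    n_randomizations: int = 1999
    seed: int = 0
    outlier_sd: float = 3.0
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineResult:
    """Artifact bundle of one pipeline run."""

    descriptive: pd.DataFrame
    fit_stats: pd.DataFrame
    comparisons: list[ComparisonResult]
    qc: dict
    spectra: SpectraSet
    panel: MineralPanel


def _load_inputs(config: PipelineConfig) -> tuple[SpectraSet, MineralPanel]:
    if config.simulate is not None:
        from .synthetic import GeneratorConfig, generate_dataset

        gen = GeneratorConfig(**dict(config.simulate))
        ds = generate_dataset(gen)
        return ds.transmittance, ds.panel
    if not (config.spectra_csv and config.panel_csv):
        raise ValueError(
            "config must provide either 'simulate' or both 'spectra_csv' and 'panel_csv'"
        )
    spectra = SpectraSet.from_csv(config.spectra_csv, mode=config.spectra_mode)
    panel = MineralPanel(pd.read_csv(config.panel_csv))
    return spectra, panel


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute preprocess → per-trait PLS/BiPLS comparison → tables.

    Preprocessing converts to absorbance, restricts to the configured
    regions, screens reference values (±3 SD) and spectra (Mahalanobis on
    PCA scores) and records a Shapiro-Wilk report per trait; samples flagged
    by either screen are dropped before modelling. Deterministic under a
    fixed seed.
    """
    spectra, panel = _load_inputs(config)
    regions = RegionSet(tuple(tuple(iv) for iv in config.regions)) \
        if config.regions else RegionSet()

    spectra = select_regions(to_absorbance(spectra), regions)
    d2, spec_mask = spectral_outliers_mahalanobis(spectra)
    qc: dict = {
        "n_spectral_variables": spectra.n_variables,
        "spectral_outliers": [str(s) for s in spectra.sample_ids[spec_mask]],
        "mahalanobis_sq_max": float(d2.max()),
        "traits": {},
    }

    trait_vectors = {t: panel.trait(t) for t in config.traits}
    ref_mask = np.zeros(spectra.n_samples, dtype=bool)
    for t, y in trait_vectors.items():
        mask = reference_outliers(y)
        w, p = normality_check(y)
        qc["traits"][t] = {
            "reference_outliers": [str(s) for s in spectra.sample_ids[mask]],
            "shapiro_w": w, "shapiro_p": p,
        }
        ref_mask |= mask
    drop = ref_mask | spec_mask
    keep = ~drop
    qc["n_samples_retained"] = int(keep.sum())
    log.info("retained %d/%d samples after screening", keep.sum(), keep.size)

    X = spectra.values[keep]
    part = partition(spectra.n_variables, config.n_intervals)
    comparisons = []
    for t in config.traits:
        log.info("fitting trait %s", t)
        comp = compare_models(
            X, trait_vectors[t][keep], part, max_lv=config.max_lv,
            p_threshold=config.p_threshold,
            n_randomizations=config.n_randomizations,
            seed=config.seed, trait=t,
        )
        for rd in comp.trace.rounds:
            log.info(
                "trait %s round %d: excluded=%s LV=%d PRESS=%.6g RMSE_CV=%.6g",
                t, rd.round_index, rd.excluded, rd.n_lv, rd.press, rd.rmse_cv,
            )
        comparisons.append(comp)

    result = PipelineResult(
        descriptive=descriptive_table(panel),
        fit_stats=fit_stats_table(comparisons),
        comparisons=comparisons,
        qc=qc,
        spectra=spectra,
        panel=panel,
    )
    if config.output_dir:
        _write_outputs(result, config)
    return result


def _selected_interval_table(comp: ComparisonResult, wavenumbers: np.ndarray) -> pd.DataFrame:
    """Wavenumber lo/hi per selected interval — the selection-map analogue."""
    part = comp.trace.partition
    rows = []
    for k in comp.trace.selected_intervals:
        cols = part.columns(k)
        rows.append({"trait": comp.trait, "interval": k,
                     "wavenumber_lo": wavenumbers[cols[0]],
                     "wavenumber_hi": wavenumbers[cols[-1]],
                     "n_variables": cols.size})
    return pd.DataFrame(rows)


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.descriptive.to_csv(out / "descriptive_stats.csv", index=False)
    result.fit_stats.to_csv(out / "fit_stats.csv", index=False)
    format_fit_stats(result.fit_stats).to_csv(out / "fit_stats_rounded.csv", index=False)
    with open(out / "qc_report.json", "w") as fh:
        json.dump(result.qc, fh, indent=2, sort_keys=True)
    traces = {}
    intervals = []
    for comp in result.comparisons:
        traces[comp.trait] = {
            "best_round": comp.trace.best_round,
            "nv": comp.trace.nv,
            "selected_intervals": list(comp.trace.selected_intervals),
            "rounds": [
                {"round": rd.round_index, "excluded": rd.excluded,
                 "surviving": list(rd.surviving), "n_lv": rd.n_lv,
                 "press": rd.press, "rmse_cv": rd.rmse_cv}
                for rd in comp.trace.rounds
            ],
        }
        intervals.append(_selected_interval_table(comp, result.spectra.wavenumbers))
    with open(out / "bipls_traces.json", "w") as fh:
        json.dump(traces, fh, indent=2, sort_keys=True)
    pd.concat(intervals, ignore_index=True).to_csv(
        out / "selected_intervals.csv", index=False
    )
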