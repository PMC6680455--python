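"""Published reference statistics for the 93-cow Holstein milk mineral study.

These tables are inputs to the package: the descriptive statistics calibrate
the synthetic-data generator, and the printed model-fit statistics support
arithmetic consistency checks (RPD_CV = SD / RMSE_CV, ΔR²_CV =
R²_CV(BiPLS) − R²_CV(PLS), micellar shares from trait means). No model
output is ever copied from them.

Concentrations are mg/100 mL; ratios are w/w. Na was found only in the
diffusible phase, so it appears as a total row only.
"""

from __future__ import annotations

__all__ = [
    "DESCRIPTIVE_STATS",
    "FIT_STATS",
    "published_rpd_from_tables",
    "published_delta_r2",
    "micellar_share_percent",
]

# trait -> (mean, SD, CV %, minimum, maximum)
DESCRIPTIVE_STATS: dict[str, tuple[float, float, float, float, float]] = {
    "fat_pct": (4.03, 0.63, 15.63, 2.68, 5.84),
    "protein_pct": (3.47, 0.34, 9.80, 2.54, 4.28),
    "lactose_pct": (4.75, 0.21, 4.42, 4.10, 5.15),
    "pH": (6.65, 0.06, 0.90, 6.49, 6.79),
    "Ca_total": (122.07, 10.29, 8.43, 92.42, 146.68),
    "Ca_diffusible": (27.95, 5.63, 20.13, 19.00, 49.33),
    "Ca_micellar": (94.12, 10.81, 11.48, 66.96, 123.41),
    "Ca_ratio": (3.51, 0.84, 24.03, 1.57, 5.93),
    "P_total": (99.86, 9.03, 9.04, 73.47, 119.20),
    "P_diffusible": (36.51, 4.86, 13.30, 24.28, 48.90),
    "P_micellar": (63.35, 8.98, 14.18, 41.85, 84.39),
    "P_ratio": (1.77, 0.40, 22.35, 1.14, 2.67),
    "K_total": (147.56, 10.63, 7.21, 125.07, 174.25),
    "K_diffusible": (120.94, 10.60, 8.77, 97.43, 147.14),
    "K_micellar": (26.62, 9.42, 35.40, 4.72, 52.33),
    "K_ratio": (0.22, 0.09, 39.46, 0.04, 0.49),
    "Mg_total": (10.99, 1.12, 10.23, 8.79, 14.06),
    "Mg_diffusible": (6.38, 0.82, 12.90, 4.44, 8.51),
    "Mg_micellar": (4.62, 0.94, 20.30, 2.53, 7.01),
    "Mg_ratio": (0.74, 0.19, 25.70, 0.34, 1.40),
    "Na_total": (37.55, 7.94, 21.15, 27.73, 65.71),
}

# trait -> {"pls": (LV, RMSE_CV, R2_CV, RPD_CV),
#           "bipls": (NV, LV, RMSE_CV, R2_CV, RPD_CV), "delta_r2": ΔR²_CV}
FIT_STATS: dict[str, dict] = {
    "Ca_total": {"pls": (9, 5.86, 0.68, 1.76), "bipls": (230, 10, 4.77, 0.79, 2.16), "delta_r2": 0.11},
    "Ca_diffusible": {"pls": (5, 3.15, 0.69, 1.79), "bipls": (180, 9, 2.69, 0.77, 2.09), "delta_r2": 0.08},
    "Ca_micellar": {"pls": (8, 6.35, 0.66, 1.70), "bipls": (160, 10, 5.30, 0.76, 2.04), "delta_r2": 0.10},
    "Ca_ratio": {"pls": (5, 0.58, 0.52, 1.45), "bipls": (90, 6, 0.36, 0.69, 1.78), "delta_r2": 0.17},
    "P_total": {"pls": (5, 5.58, 0.62, 1.62), "bipls": (100, 10, 3.30, 0.87, 2.73), "delta_r2": 0.25},
    "P_diffusible": {"pls": (7, 2.91, 0.64, 1.67), "bipls": (230, 10, 2.56, 0.73, 1.90), "delta_r2": 0.09},
    "P_micellar": {"pls": (5, 6.27, 0.52, 1.43), "bipls": (210, 10, 4.76, 0.73, 1.89), "delta_r2": 0.21},
    "P_ratio": {"pls": (7, 0.27, 0.56, 1.49), "bipls": (220, 10, 0.22, 0.68, 1.77), "delta_r2": 0.12},
    "K_total": {"pls": (10, 8.58, 0.35, 1.24), "bipls": (100, 10, 7.14, 0.55, 1.49), "delta_r2": 0.20},
    "K_diffusible": {"pls": (6, 7.58, 0.49, 1.40), "bipls": (100, 9, 6.92, 0.58, 1.53), "delta_r2": 0.09},
    "K_micellar": {"pls": (7, 8.69, 0.18, 1.08), "bipls": (180, 7, 8.19, 0.25, 1.15), "delta_r2": 0.07},
    "K_ratio": {"pls": (3, 0.09, 0.09, 1.04), "bipls": (90, 7, 0.08, 0.29, 1.17), "delta_r2": 0.20},
    "Mg_total": {"pls": (7, 0.74, 0.57, 1.52), "bipls": (140, 10, 0.64, 0.68, 1.76), "delta_r2": 0.11},
    "Mg_diffusible": {"pls": (5, 0.62, 0.43, 1.32), "bipls": (190, 7, 0.54, 0.57, 1.52), "delta_r2": 0.14},
    "Mg_micellar": {"pls": (5, 0.68, 0.48, 1.38), "bipls": (160, 7, 0.53, 0.68, 1.77), "delta_r2": 0.20},
    "Mg_ratio": {"pls": (4, 0.16, 0.33, 1.22), "bipls": (140, 6, 0.13, 0.56, 1.51), "delta_r2": 0.23},
    "Na_total": {"pls": (8, 4.85, 0.63, 1.64), "bipls": (290, 10, 4.02, 0.75, 1.98), "delta_r2": 0.12},
}

N_CALIBRATION_SAMPLES = 91  # after reference screening, out of 93 collected


def published_rpd_from_tables(trait: str, method: str = "bipls") -> float:
    """Recompute a printed RPD_CV as trait SD divided by printed RMSE_CV.

    ``method`` is "pls" or "bipls". Returned at full precision; round to
    2 d.p. to compare with the printed value.
    """
    sd = DESCRIPTIVE_STATS[trait][1]
    fit = FIT_STATS[trait][method]
    rmse = fit[1] if method == "pls" else fit[2]
    return sd / rmse


def published_delta_r2(trait: str) -> float:
    """Recompute ΔR²_CV as the difference of printed R²_CV values."""
    fit = FIT_STATS[trait]
    return fit["bipls"][3] - fit["pls"][2]


def micellar_share_percent(element: str) -> float:
    """Micellar share of the total, in percent, from the published trait means."""
    micellar = DESCRIPTIVE_STATS[f"{element}_micellar"][0]
    total = DESCRIPTIVE_STATS[f"{element}_total"][0]
    return 100.0 * micellar / total
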