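"""Diffusible / micellar mineral fractionation from the rennet-whey dilution.

The wet-lab protocol renneted v_milk = 10 mL of milk, collected
v_collected = 5 mL of whey, added v_water = 5 mL of ultrapure water,
equilibrated and sampled the diluted whey. Because the curd solids exclude
part of the milk volume, the accessible serum volume V_a differs per sample;
the two concentration measurements solve for it instead of applying a fixed
correction factor:

    C_dw = C_w * (V_a - v_collected) / (V_a - v_collected + v_water)

so V_a = v_collected + r * v_water / (1 - r) with r = C_dw / C_w, and the
diffusible concentration referred to the original milk volume is
D = C_w * V_a / v_milk. At the default 10/5/5 mL volumes this reduces to the
closed form D = C_w² / (2 (C_w - C_dw)). The micellar fraction is
total - diffusible, clamped at zero (negative values arise from measurement
noise, typically for Na, which is essentially absent from the micellar
phase).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "InvalidDilutionError",
    "DilutionResult",
    "diffusible_from_dilution",
    "diffusible_closed_form",
    "micellar_from_total",
    "fractionate",
]


class InvalidDilutionError(ValueError):
    """Raised when C_dw >= C_w, which has no physical mass-balance solution."""


@dataclass(frozen=True)
class DilutionResult:
    diffusible: float          # mg/100 mL of original milk
    v_accessible: float        # implied accessible serum volume, mL
    flag_implied_volume: bool  # V_a > v_milk (possible only through noise)


def diffusible_from_dilution(
    c_whey: float,
    c_diluted_whey: float,
    v_milk: float = 10.0,
    v_collected: float = 5.0,
    v_water: float = 5.0,
) -> DilutionResult:
    """Solve the dilution mass balance for the diffusible concentration.

    Parameters are the whey concentration C_w and diluted-whey concentration
    C_dw (same units, e.g. mg/100 mL) and the protocol volumes in mL.

    Raises :class:`InvalidDilutionError` when C_dw >= C_w. When the implied
    accessible volume exceeds the milk volume (non-physical, but expected
    under measurement noise) the value is still returned with
    ``flag_implied_volume`` set.
    """
    if min(v_milk, v_collected, v_water) <= 0:
        raise ValueError("volumes must be positive")
    if c_diluted_whey < 0 or c_whey < 0:
        raise ValueError("concentrations must be non-negative")
    if c_diluted_whey >= c_whey:
        raise InvalidDilutionError(
            f"C_dw={c_diluted_whey} >= C_w={c_whey}: dilution ratio has no solution"
        )
    r = c_diluted_whey / c_whey
    v_a = v_collected + r * v_water / (1.0 - r)
    diffusible = c_whey * v_a / v_milk
    return DilutionResult(
        diffusible=float(diffusible),
        v_accessible=float(v_a),
        flag_implied_volume=bool(v_a > v_milk),
    )


def diffusible_closed_form(c_whey: float, c_diluted_whey: float) -> float:
    """Default-volume (10/5/5 mL) closed form D = C_w² / (2 (C_w - C_dw))."""
    if c_diluted_whey >= c_whey:
        raise InvalidDilutionError("C_dw >= C_w")
    return c_whey**2 / (2.0 * (c_whey - c_diluted_whey))


def micellar_from_total(total: float, diffusible: float) -> tuple[float, bool]:
    """Micellar = total - diffusible, clamped at 0.

    Returns (micellar, negative_flag); the flag marks a clamped negative
    difference (measurement noise; anticipated for Na, whose micellar
    fraction is nil).
    """
    if total < 0 or diffusible < 0:
        raise ValueError("concentrations must be non-negative")
    micellar = total - diffusible
    if micellar < 0:
        return 0.0, True
    return float(micellar), False


def fractionate(
    whey: pd.DataFrame,
    totals: pd.DataFrame,
    v_milk: float = 10.0,
    v_collected: float = 5.0,
    v_water: float = 5.0,
) -> pd.DataFrame:
    """Per-sample, per-element fractionation of a whey-measurement table.

    ``whey`` needs columns sample_id, element, c_whey, c_diluted_whey;
    ``totals`` needs sample_id, element, total. Returns one row per
    (sample, element) with total, diffusible, micellar, the
    micellar/diffusible ratio and the flag columns ``flag_negative_micellar``
    and ``flag_invalid_dilution`` (invalid rows carry NaN fractions instead
    of raising).
    """
    merged = whey.merge(totals[["sample_id", "element", "total"]],
                        on=["sample_id", "element"], how="left")
    if merged["total"].isna().any():
        missing = merged.loc[merged["total"].isna(), ["sample_id", "element"]]
        raise ValueError(f"missing totals for {len(missing)} whey records")

    rows = []
    for rec in merged.itertuples(index=False):
        row = {
            "sample_id": rec.sample_id,
            "element": rec.element,
            "total": rec.total,
            "flag_negative_micellar": False,
            "flag_invalid_dilution": False,
            "flag_implied_volume": False,
        }
        try:
            res = diffusible_from_dilution(
                rec.c_whey, rec.c_diluted_whey, v_milk, v_collected, v_water
            )
        except InvalidDilutionError:
            row.update(diffusible=np.nan, micellar=np.nan,
                       ratio_micellar_diffusible=np.nan,
                       flag_invalid_dilution=True)
            rows.append(row)
            continue
        micellar, neg = micellar_from_total(rec.total, res.diffusible)
        diffusible = res.diffusible
        ratio = micellar / diffusible if diffusible > 0 else np.nan
        row.update(diffusible=float(diffusible), micellar=micellar,
                   ratio_micellar_diffusible=ratio,
                   flag_negative_micellar=neg,
                   flag_implied_volume=res.flag_implied_volume)
        rows.append(row)
    cols = ["sample_id", "element", "total", "diffusible", "micellar",
            "ratio_micellar_diffusible", "flag_negative_micellar",
            "flag_invalid_dilution", "flag_implied_volume"]
    return pd.DataFrame(rows)[cols]
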