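"""Derived physiological traits from primary pot-trial measurements.

Water uptake (WU, kg) is the loss in sealed-pot weight between the last
irrigation (18 days after sowing) and harvest (35 DAS); with pots sealed
in polyethylene this difference is plant transpiration.  Water-use
efficiency (WUE, g L⁻¹) is shoot dry weight per litre taken up (1 kg
water ≡ 1 L).  %R_SDW is the percent reduction in shoot dry weight under
stress relative to the well-watered control, computed on treatment
means.  RSR is the root:shoot dry-weight ratio and CRPT the number of
crown roots per tiller.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .core import SchemaError, TraitMeanMatrix

__all__ = [
    "PotWeightRecord",
    "compute_wu",
    "compute_wue",
    "percent_reduction",
    "compute_rsr",
    "compute_crpt",
    "read_pot_weights",
    "derive_water_traits",
    "percent_reduction_series",
]


@dataclass(frozen=True)
class PotWeightRecord:
    """Sealed-pot weights bracketing the drying period, in kg."""

    line_id: str
    replicate: int
    weight_at_last_irrigation_kg: float
    weight_at_harvest_kg: float


def compute_wu(rec: PotWeightRecord) -> float:
    """Plant water uptake (kg): pot weight at last irrigation minus at harvest."""
    w0 = rec.weight_at_last_irrigation_kg
    w1 = rec.weight_at_harvest_kg
    if w0 <= 0 or w1 <= 0:
        raise ValueError("pot weights must be positive")
    wu = w0 - w1
    if wu < 0:
        raise ValueError(
            f"pot {rec.line_id!r} rep {rec.replicate} gained weight while drying"
        )
    return wu


def compute_wue(sdw_g: float, wu_kg: float) -> float:
    """Water-use efficiency: shoot dry weight (g) per litre of water taken up."""
    if wu_kg <= 0:
        raise ValueError("water uptake must be positive to define WUE")
    if sdw_g < 0:
        raise ValueError("shoot dry weight must be non-negative")
    return sdw_g / wu_kg


def percent_reduction(control_value: float, stress_value: float) -> float:
    """Percent reduction under stress: 100 × (control − stress) / control.

    Negative when the stressed value exceeds the control.
    """
    if control_value == 0:
        raise ValueError("control value must be non-zero")
    return 100.0 * (control_value - stress_value) / control_value


def compute_rsr(rdw_g: float, sdw_g: float) -> float:
    """Root:shoot dry-weight ratio."""
    if sdw_g <= 0:
        raise ValueError("shoot dry weight must be positive")
    if rdw_g < 0:
        raise ValueError("root dry weight must be non-negative")
    return rdw_g / sdw_g


def compute_crpt(crn: float, tn: float) -> float:
    """Crown roots per tiller (per-plant ratio CRN/TN).

    The per-plant ratio is the default throughout the pipeline; averaging
    these ratios (mean of ratios) differs slightly from dividing the
    treatment means (ratio of means) — both modes are exposed where
    tables are aggregated.
    """
    if tn < 1:
        raise ValueError("tiller number must be at least 1")
    if crn < 0:
        raise ValueError("crown root number must be non-negative")
    return crn / tn


# ---------------------------------------------------------------------------
# Table-level helpers
# ---------------------------------------------------------------------------

def read_pot_weights(path: str | Path) -> pd.DataFrame:
    """Read a pot-weight CSV: ``line_id,replicate,weight_18das_kg,weight_35das_kg``."""
    df = pd.read_csv(path)
    need = ["line_id", "replicate", "weight_18das_kg", "weight_35das_kg"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise SchemaError(f"{path} lacks pot-weight columns {missing}")
    return df.loc[:, need]


def derive_water_traits(obs: pd.DataFrame, weights: pd.DataFrame) -> pd.DataFrame:
    """Append WU and WUE observations (WS treatment only) to a trait table.

    WU comes from each pot-weight record; WUE pairs it with the same
    replicate's WS shoot dry weight where available.
    """
    rows = []
    sdw = obs[(obs["trait"] == "SDW") & (obs["treatment"] == "WS")]
    sdw_map = {
        (r.line_id, int(r.replicate)): float(r.value) for r in sdw.itertuples()
    }
    for r in weights.itertuples():
        rec = PotWeightRecord(
            str(r.line_id), int(r.replicate),
            float(r.weight_18das_kg), float(r.weight_35das_kg),
        )
        wu = compute_wu(rec)
        rows.append((rec.line_id, "WS", rec.replicate, "WU", wu, pd.NA))
        key = (rec.line_id, rec.replicate)
        if key in sdw_map and wu > 0:
            rows.append(
                (rec.line_id, "WS", rec.replicate, "WUE",
                 compute_wue(sdw_map[key], wu), pd.NA)
            )
    extra = pd.DataFrame(rows, columns=list(obs.columns[:6]))
    return pd.concat([obs, extra], ignore_index=True)


def percent_reduction_series(
    matrix: TraitMeanMatrix, trait: str = "SDW"
) -> pd.Series:
    """Per-line %R of a trait, from WW and WS treatment means.

    Defined only for lines with both treatment means present (NaN
    otherwise); named ``PR_SDW`` for the default trait.
    """
    out = {}
    for line in matrix.lines:
        ww = matrix.get(line, "WW", trait)
        ws = matrix.get(line, "WS", trait)
        if pd.isna(ww) or pd.isna(ws) or ww == 0:
            out[line] = float("nan")
        else:
            out[line] = percent_reduction(ww, ws)
    return pd.Series(out, name=f"PR_{trait}")
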